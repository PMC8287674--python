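import itertools

import numpy as np
import pytest
from scipy import stats

from pttkit import thermal
from pttkit.synthetic import SyntheticConfig


@pytest.fixture
def noiseless_config():
    return SyntheticConfig(
        seed=0,
        trace_noise_sd_C=0.0,
        absorbance_noise_sd=0.0,
        caliper_noise_sd_mm=0.0,
        weight_noise_sd_g=0.0,
    )


@pytest.fixture
def default_system():
    return thermal.PhotothermalSystem(
        laser_power=1.0, a808=0.8, solvent_mass=0.2, solvent_heat_capacity=4.18
    )


def euler_trace(system, eta, hS, t_surr, laser_on, laser_off, dt):
    """Forward-Euler integration of the lumped energy balance.

    Independent oracle for the closed-form simulator:
    m*C*dT/dt = eta*I*(1 - 10**-A) + Q_dis - hS*(T - T_surr), with the source
    terms switched off after laser_on.
    """
    mc = system.solvent_mass * system.solvent_heat_capacity
    q_dis = system.q_dis or 0.0
    source = eta * system.laser_power * (1 - 10 ** (-system.a808)) + q_dis
    n_heat = int(round(laser_on / dt))
    n_cool = int(round(laser_off / dt))
    T = t_surr
    times, temps = [0.0], [T]
    for k in range(1, n_heat + n_cool + 1):
        s = source if k <= n_heat else 0.0
        T = T + dt * (s - hS * (T - t_surr)) / mc
        times.append(k * dt)
        temps.append(T)
    return np.array(times), np.array(temps)


def permutation_pvalue(a, b):
    """Exhaustive two-sided permutation p-value of the pooled-t statistic."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pool = np.concatenate([a, b])
    t_obs, _ = stats.ttest_ind(a, b, equal_var=True)
    n = len(a)
    count = total = 0
    for comb in itertools.combinations(range(len(pool)), n):
        ga = pool[list(comb)]
        gb = np.delete(pool, list(comb))
        t, _ = stats.ttest_ind(ga, gb, equal_var=True)
        total += 1
        if abs(t) >= abs(t_obs) - 1e-12:
            count += 1
    return count / total
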