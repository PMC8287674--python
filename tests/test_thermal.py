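"""Lumped-capacitance photothermal model: simulation and inversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pttkit import thermal
from pttkit.errors import (
    DegenerateTraceError,
    DomainError,
    InsufficientDataError,
    NonCoolingTraceError,
)

from conftest import euler_trace


def make_cooling_trace(tau=120.0, t_surr=25.0, dT0=30.0, t_end=600.0, dt=5.0,
                       noise_sd=0.0, seed=None):
    t = np.arange(0.0, t_end + dt / 2, dt)
    temp = t_surr + dT0 * np.exp(-t / tau)
    if noise_sd:
        temp = temp + np.random.default_rng(seed).normal(0, noise_sd, temp.shape)
    phase = np.array(["cooling"] * len(t), dtype=object)
    return thermal.TemperatureTrace(time=t, temp=temp, phase=phase, t_surr=t_surr)


class TestTemperatureTrace:
    def test_rejects_non_increasing_time(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            thermal.TemperatureTrace(
                time=[0, 2, 1], temp=[25, 26, 27],
                phase=["heating"] * 3, t_surr=25.0,
            )

    def test_rejects_out_of_order_phases(self):
        with pytest.raises(ValueError, match="order"):
            thermal.TemperatureTrace(
                time=range(6), temp=[25.0] * 6,
                phase=["cooling"] * 3 + ["heating"] * 3, t_surr=25.0,
            )

    def test_rejects_short_phase(self):
        with pytest.raises(ValueError, match="fewer than 3"):
            thermal.TemperatureTrace(
                time=[0, 1, 2, 3, 4], temp=[25.0] * 5,
                phase=["heating"] * 3 + ["cooling"] * 2, t_surr=25.0,
            )


class TestTheta:
    @pytest.mark.parametrize(
        "temp,t_max,t_surr,expected",
        [(55, 55, 25, 1.0), (25, 55, 25, 0.0), (40, 55, 25, 0.5)],
    )
    def test_driving_force_ratio(self, temp, t_max, t_surr, expected):
        assert thermal.theta(temp, t_max, t_surr) == pytest.approx(expected)

    def test_degenerate_when_tmax_equals_ambient(self):
        with pytest.raises(DegenerateTraceError):
            thermal.theta(30.0, 25.0, 25.0)

    @settings(max_examples=50, derandomize=True)
    @given(
        temps=st.lists(st.integers(0, 1000), min_size=2, max_size=10, unique=True),
        t_surr=st.floats(0, 40),
        dT=st.floats(1, 60),
    )
    def test_strictly_monotone_in_temperature(self, temps, t_surr, dT):
        t_max = t_surr + dT
        ordered = np.sort(np.asarray(temps, dtype=float)) / 10.0
        th = thermal.theta(ordered, t_max, t_surr)
        assert np.all(np.diff(th) > 0)


class TestCoolingFit:
    def test_exact_exponential_recovers_tau(self):
        trace = make_cooling_trace(tau=120.0)
        tau, r2, n = thermal.fit_cooling_time_constant(trace)
        assert tau == pytest.approx(120.0, rel=1e-6)
        assert r2 == pytest.approx(1.0)

    def test_noisy_trace_recovers_tau_within_tolerance(self):
        # tolerance established by a 200-seed pilot: max error ~0.9 s
        for seed in (0, 1, 2, 3, 4):
            trace = make_cooling_trace(tau=120.0, noise_sd=0.1, seed=seed)
            tau, _, _ = thermal.fit_cooling_time_constant(trace)
            assert abs(tau - 120.0) < 3.0

    def test_constant_trace_at_ambient_is_degenerate(self):
        t = np.arange(0, 50, 5.0)
        trace = thermal.TemperatureTrace(
            time=t, temp=np.full_like(t, 25.0),
            phase=np.array(["cooling"] * len(t), dtype=object), t_surr=25.0,
        )
        with pytest.raises(DegenerateTraceError):
            thermal.fit_cooling_time_constant(trace)

    def test_too_few_usable_points(self):
        trace = make_cooling_trace(tau=10.0, t_end=600.0, dt=200.0)
        with pytest.raises(InsufficientDataError):
            thermal.fit_cooling_time_constant(trace)

    def test_warming_trace_rejected(self):
        t = np.arange(0, 60, 5.0)
        temp = 35.0 - 5.0 * np.exp(-t / 20.0)  # rises toward 35 from 30
        trace = thermal.TemperatureTrace(
            time=t, temp=temp,
            phase=np.array(["cooling"] * len(t), dtype=object), t_surr=25.0,
        )
        with pytest.raises((NonCoolingTraceError, InsufficientDataError)):
            thermal.fit_cooling_time_constant(trace)


class TestHS:
    def test_hand_values(self, default_system):
        assert thermal.compute_hS(200.0, default_system) == pytest.approx(0.00418)
        assert thermal.compute_hS(0.836, default_system) == pytest.approx(1.0)

    def test_nonpositive_tau_rejected(self, default_system):
        with pytest.raises(DomainError):
            thermal.compute_hS(-5.0, default_system)


class TestQdis:
    def _control(self, dT, t_surr=25.0, tau=100.0):
        t = np.arange(0.0, 900.0, 5.0)
        temp = t_surr + dT * (1 - np.exp(-t / tau))
        return thermal.TemperatureTrace(
            time=t, temp=temp,
            phase=np.array(["heating"] * len(t), dtype=object), t_surr=t_surr,
        )

    def test_water_control_rise(self):
        # 2.5 degC solvent-only rise at hS=0.01 W/K -> 25 mW
        q = thermal.estimate_qdis(self._control(2.5), hS=0.01)
        assert q == pytest.approx(0.025, rel=1e-3)

    def test_flat_control_gives_zero(self):
        q = thermal.estimate_qdis(self._control(0.0), hS=0.01)
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_zero_hS_rejected(self):
        with pytest.raises(DomainError):
            thermal.estimate_qdis(self._control(2.5), hS=0.0)

    def test_still_rising_control_warns(self):
        t = np.arange(0.0, 60.0, 5.0)
        temp = 25.0 + 0.5 * t  # far from plateau
        trace = thermal.TemperatureTrace(
            time=t, temp=temp,
            phase=np.array(["heating"] * len(t), dtype=object), t_surr=25.0,
        )
        with pytest.warns(UserWarning, match="steady-state"):
            thermal.estimate_qdis(trace, hS=0.01)


class TestEta:
    def _fit(self, hS, t_max, t_surr):
        return thermal.PhotothermalFit(
            tau_s=1.0, hS=hS, t_max=t_max, t_surr=t_surr, eta=np.nan,
            r_squared=1.0, n_points_used=10, q_dis=0.0,
        )

    def test_hand_value(self):
        system = thermal.PhotothermalSystem(
            laser_power=1.0, a808=0.8, solvent_mass=0.2,
            solvent_heat_capacity=4.18, q_dis=0.025,
        )
        eta, flagged = thermal.compute_eta(self._fit(0.01, 56.0, 25.0), system)
        assert eta == pytest.approx(0.285 / (1 - 10**-0.8), rel=1e-4)
        assert eta == pytest.approx(0.3387, abs=5e-5)
        assert not flagged

    def test_numerator_vanishes(self):
        system = thermal.PhotothermalSystem(
            laser_power=1.0, a808=0.8, solvent_mass=0.2,
            solvent_heat_capacity=4.18, q_dis=0.01 * 31.0,
        )
        eta, _ = thermal.compute_eta(self._fit(0.01, 56.0, 25.0), system)
        assert eta == pytest.approx(0.0, abs=1e-12)

    def test_opaque_sample_denominator_tends_to_laser_power(self):
        system = thermal.PhotothermalSystem(
            laser_power=1.0, a808=10.0, solvent_mass=0.2,
            solvent_heat_capacity=4.18, q_dis=0.025,
        )
        eta, _ = thermal.compute_eta(self._fit(0.01, 56.0, 25.0), system)
        assert eta == pytest.approx(0.285, rel=1e-6)

    def test_zero_absorbance_rejected(self):
        system = thermal.PhotothermalSystem(
            laser_power=1.0, a808=0.0, solvent_mass=0.2,
            solvent_heat_capacity=4.18, q_dis=0.0,
        )
        with pytest.raises(DomainError):
            thermal.compute_eta(self._fit(0.01, 56.0, 25.0), system)


class TestSimulator:
    def test_no_source_stays_at_ambient(self, default_system):
        trace = thermal.simulate_temperature_trace(
            default_system, eta_true=0.0, hS_true=0.01, t_surr=25.0,
            laser_on=60.0, laser_off_duration=60.0, dt=1.0,
        )
        assert np.allclose(trace.temp, 25.0)

    def test_plateau_matches_closed_form(self):
        system = thermal.PhotothermalSystem(
            laser_power=1.0, a808=1.0, solvent_mass=0.2,
            solvent_heat_capacity=4.18, q_dis=0.0,
        )
        trace = thermal.simulate_temperature_trace(
            system, eta_true=0.5, hS_true=0.015, t_surr=25.0,
            laser_on=3000.0, laser_off_duration=60.0, dt=1.0,
        )
        # dT_inf = 0.5 * 0.9 / 0.015 = 30 K
        heating = trace.temp[trace.phase == "heating"]
        assert heating[-1] == pytest.approx(55.0, abs=1e-6)

    def test_agrees_with_forward_euler(self, default_system):
        rng = np.random.default_rng(42)
        for _ in range(3):
            eta = rng.uniform(0.1, 0.5)
            hS = rng.uniform(0.005, 0.01)
            trace = thermal.simulate_temperature_trace(
                default_system, eta_true=eta, hS_true=hS, t_surr=25.0,
                laser_on=60.0, laser_off_duration=60.0, dt=0.01,
            )
            t_e, T_e = euler_trace(default_system, eta, hS, 25.0, 60.0, 60.0, 0.01)
            assert np.max(np.abs(trace.temp - np.interp(trace.time, t_e, T_e))) < 1e-3

    def test_seeded_noise_is_reproducible(self, default_system):
        kw = dict(eta_true=0.3, hS_true=0.008, t_surr=25.0, laser_on=60.0,
                  laser_off_duration=60.0, dt=1.0, noise_sd=0.1, seed=5)
        a = thermal.simulate_temperature_trace(default_system, **kw)
        b = thermal.simulate_temperature_trace(default_system, **kw)
        assert np.array_equal(a.temp, b.temp)


class TestAnalyze:
    def _run(self, eta, hS, t_surr=25.0, q_dis=0.0, shift=0.0):
        system = thermal.PhotothermalSystem(
            laser_power=1.0, a808=0.8, solvent_mass=0.2,
            solvent_heat_capacity=4.18, q_dis=q_dis,
        )
        tau = system.heat_capacity_total / hS
        sample = thermal.simulate_temperature_trace(
            system, eta_true=eta, hS_true=hS, t_surr=t_surr,
            laser_on=20 * tau, laser_off_duration=5 * tau, dt=tau / 50,
        )
        control = thermal.simulate_temperature_trace(
            system, eta_true=0.0, hS_true=hS, t_surr=t_surr,
            laser_on=20 * tau, laser_off_duration=5 * tau, dt=tau / 50,
        )
        if shift:
            sample = thermal.TemperatureTrace(
                time=sample.time + shift, temp=sample.temp,
                phase=sample.phase, t_surr=t_surr,
            )
        return thermal.analyze_photothermal(sample, control, system), tau

    def test_noiseless_round_trip_is_exact(self):
        for eta in (0.1, 0.5, 0.9):
            for hS in (0.004, 0.01):
                fit, tau = self._run(eta, hS)
                assert fit.eta == pytest.approx(eta, rel=1e-6)
                assert fit.tau_s == pytest.approx(tau, rel=1e-6)

    def test_eq2_identity(self, default_system):
        fit, _ = self._run(0.3, 0.008)
        mc = 0.2 * 4.18
        assert abs(fit.hS * fit.tau_s - mc) / mc < 1e-9

    def test_invariant_to_time_shift_and_ambient(self):
        fit_a, _ = self._run(0.4, 0.006, t_surr=20.0)
        fit_b, _ = self._run(0.4, 0.006, t_surr=30.0, shift=500.0)
        assert fit_a.eta == pytest.approx(fit_b.eta, rel=1e-9)

    def test_qdis_subtracted_correctly(self):
        fit, _ = self._run(0.22, 0.0065, q_dis=0.01625)
        assert fit.eta == pytest.approx(0.22, rel=1e-6)
        assert fit.q_dis == pytest.approx(0.01625, rel=1e-6)

    def test_missing_cooling_phase_rejected(self, default_system):
        t = np.arange(0.0, 50.0, 5.0)
        sample = thermal.TemperatureTrace(
            time=t, temp=25.0 + t / 10,
            phase=np.array(["heating"] * len(t), dtype=object), t_surr=25.0,
        )
        with pytest.raises(InsufficientDataError):
            thermal.analyze_photothermal(sample, sample, default_system)
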