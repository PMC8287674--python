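"""Lumped-capacitance photothermal model: forward simulation and inversion.

A nanoparticle suspension irradiated by a continuous-wave laser is treated as a
single well-mixed thermal mass.  The energy balance is

    m_D C_D dT/dt = eta * I * (1 - 10**(-A808)) + Q_dis - hS * (T - T_surr)

where ``eta`` is the photothermal conversion efficiency (fraction of absorbed
laser power converted to heat by the agent), ``I`` the incident laser power in
watts, ``A808`` the suspension absorbance at the laser wavelength, ``Q_dis``
the power picked up by the container and solvent alone, and ``hS`` the lumped
heat-transfer coefficient times surface area (W/K).

The efficiency is inferred from a heat/cool trace in four steps:

1. linearized cooling fit: with theta = (T - T_surr) / (T_max - T_surr), the
   laser-off decay satisfies t = -tau_s * ln(theta), giving the time constant
   tau_s from a through-origin regression;
2. hS = m_D * C_D / tau_s;
3. Q_dis = hS * (T_max,control - T_surr) from a solvent-only control trace;
4. eta = [hS * (T_max - T_surr) - Q_dis] / [I * (1 - 10**(-A808))].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    DegenerateTraceError,
    DomainError,
    InsufficientDataError,
    NonCoolingTraceError,
)

__all__ = [
    "TemperatureTrace",
    "PhotothermalSystem",
    "PhotothermalFit",
    "theta",
    "fit_cooling_time_constant",
    "compute_hS",
    "estimate_qdis",
    "compute_eta",
    "simulate_temperature_trace",
    "analyze_photothermal",
]

_PHASES = ("pre", "heating", "cooling")


@dataclass(frozen=True)
class TemperatureTrace:
    """Timestamped temperatures with phase labels and ambient temperature.

    Parameters
    ----------
    time : array of float
        Seconds, non-negative, strictly increasing.
    temp : array of float
        Degrees Celsius.
    phase : array of str
        One of ``pre``, ``heating``, ``cooling``; phases present must appear
        in that order, each with at least 3 points.
    t_surr : float
        Ambient/surrounding temperature, degrees Celsius.
    """

    time: np.ndarray
    temp: np.ndarray
    phase: np.ndarray
    t_surr: float

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        temp = np.asarray(self.temp, dtype=float)
        phase = np.asarray(self.phase, dtype=object)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "temp", temp)
        object.__setattr__(self, "phase", phase)
        if not (time.shape == temp.shape == phase.shape) or time.ndim != 1:
            raise ValueError("time, temp and phase must be 1-D arrays of equal length")
        if time.size and time[0] < 0:
            raise ValueError("time must be non-negative")
        if np.any(np.diff(time) <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.isfinite(temp).all():
            raise ValueError("temp must be finite everywhere")
        if not np.isfinite(self.t_surr):
            raise ValueError("t_surr must be finite")
        labels = set(phase.tolist())
        unknown = labels - set(_PHASES)
        if unknown:
            raise ValueError(f"unknown phase labels: {sorted(unknown)}")
        # phases must be contiguous blocks in pre -> heating -> cooling order
        order = [p for i, p in enumerate(phase) if i == 0 or phase[i - 1] != p]
        if len(order) != len(set(order)):
            raise ValueError("phases must form contiguous blocks")
        ranks = [_PHASES.index(p) for p in order]
        if ranks != sorted(ranks):
            raise ValueError("phases must appear in order pre -> heating -> cooling")
        for p in labels:
            if int(np.sum(phase == p)) < 3:
                raise ValueError(f"phase {p!r} has fewer than 3 points")

    def select(self, phase: str) -> tuple[np.ndarray, np.ndarray]:
        """Return (time, temp) restricted to one phase."""
        m = self.phase == phase
        return self.time[m], self.temp[m]

    def has_phase(self, phase: str) -> bool:
        return bool(np.any(self.phase == phase))


@dataclass
class PhotothermalSystem:
    """Physical constants of one photothermal experiment.

    laser_power is the total power delivered to the sample in watts; a power
    density (W/cm^2) times an illuminated area (cm^2) conversion is done at
    the CLI boundary.  q_dis (watts, heat taken up by container + solvent) is
    optional until estimated from a control trace.
    """

    laser_power: float
    a808: float
    solvent_mass: float
    solvent_heat_capacity: float
    q_dis: float | None = None

    def __post_init__(self) -> None:
        if self.laser_power <= 0:
            raise DomainError("laser_power must be > 0")
        if self.a808 < 0:
            raise DomainError("a808 must be >= 0")
        if self.solvent_mass <= 0:
            raise DomainError("solvent_mass must be > 0")
        if self.solvent_heat_capacity <= 0:
            raise DomainError("solvent_heat_capacity must be > 0")
        if self.q_dis is not None and self.q_dis < 0:
            raise DomainError("q_dis must be >= 0 when set")

    @property
    def heat_capacity_total(self) -> float:
        """m_D * C_D in J/K."""
        return self.solvent_mass * self.solvent_heat_capacity


@dataclass(frozen=True)
class PhotothermalFit:
    """Result of inverting a heat/cool trace to a conversion efficiency."""

    tau_s: float
    hS: float
    t_max: float
    t_surr: float
    eta: float
    r_squared: float
    n_points_used: int
    q_dis: float
    eta_out_of_range: bool = field(default=False)
    warnings: tuple[str, ...] = ()


def theta(temp: float | np.ndarray, t_max: float, t_surr: float) -> float | np.ndarray:
    """Dimensionless temperature driving force (T - T_surr)/(T_max - T_surr).

    No clamping is applied; values outside [0, 1] are returned as computed.
    """
    if t_max == t_surr:
        raise DegenerateTraceError("t_max equals t_surr: theta undefined")
    return (np.asarray(temp, dtype=float) - t_surr) / (t_max - t_surr)


def fit_cooling_time_constant(
    trace: TemperatureTrace,
    theta_min: float = 0.05,
) -> tuple[float, float, int]:
    """Extract the cooling time constant tau_s from the laser-off decay.

    The decay linearizes as t = -tau_s * ln(theta); tau_s is the slope of a
    least-squares regression of elapsed cooling time on -ln(theta), forced
    through the origin (the model has no intercept).  T_max is taken as the
    first cooling-phase temperature.  Points with theta <= theta_min are
    dropped: near ambient, the log transform amplifies noise.

    Returns
    -------
    (tau_s, r_squared, n_points_used)
    """
    if not trace.has_phase("cooling"):
        raise InsufficientDataError("trace has no cooling phase")
    t_cool, temp_cool = trace.select("cooling")
    t_max = temp_cool[0]
    if t_max == trace.t_surr:
        raise DegenerateTraceError("cooling starts at ambient: theta undefined")
    th = theta(temp_cool, t_max, trace.t_surr)
    elapsed = t_cool - t_cool[0]
    usable = (th > theta_min) & (th < 1.0)
    if int(usable.sum()) < 3:
        raise InsufficientDataError(
            f"only {int(usable.sum())} cooling points with theta in "
            f"({theta_min}, 1); need >= 3"
        )
    x = -np.log(th[usable])
    y = elapsed[usable]
    slope = float(x @ y) / float(x @ x)
    if slope <= 0:
        raise NonCoolingTraceError(f"fitted time constant {slope:.3g} s is not positive")
    resid = y - slope * x
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return slope, float(np.clip(r2, 0.0, 1.0)), int(usable.sum())


def compute_hS(tau_s: float, system: PhotothermalSystem) -> float:
    """Lumped heat-transfer coefficient hS = m_D * C_D / tau_s, in W/K."""
    if tau_s <= 0:
        raise DomainError("tau_s must be > 0")
    return system.heat_capacity_total / tau_s


def _tail_mean(values: np.ndarray, k: int) -> float:
    return float(np.mean(values[-min(k, len(values)):]))


def estimate_qdis(
    control_trace: TemperatureTrace,
    hS: float,
    tail_points_k: int = 5,
    slope_threshold: float = 0.01,
) -> float:
    """Power absorbed by container + solvent from a solvent-only control.

    Q_dis = hS * (T_max,control - T_surr), with T_max,control the mean of the
    last ``tail_points_k`` heating-phase points.  Assumes the same hS as the
    sample run (same container and geometry).  If the control is still rising
    faster than ``slope_threshold`` (deg C/s) at its end, a not-at-steady-state
    warning is emitted (non-fatal).
    """
    if hS <= 0:
        raise DomainError("hS must be > 0")
    if not control_trace.has_phase("heating"):
        raise InsufficientDataError("control trace has no heating phase")
    t_heat, temp_heat = control_trace.select("heating")
    if len(t_heat) >= 2:
        # slope over a tail window; a two-point difference would be noise-dominated
        w = min(20, len(t_heat))
        end_slope = float(np.polyfit(t_heat[-w:], temp_heat[-w:], 1)[0])
        if end_slope > slope_threshold:
            warnings.warn(
                f"control trace still rising at {end_slope:.3g} degC/s; "
                "steady-state plateau may not be reached",
                UserWarning,
                stacklevel=2,
            )
    t_max_control = _tail_mean(temp_heat, tail_points_k)
    return hS * (t_max_control - control_trace.t_surr)


def compute_eta(fit: PhotothermalFit, system: PhotothermalSystem) -> tuple[float, bool]:
    """Photothermal conversion efficiency.

    eta = [hS*(T_max - T_surr) - Q_dis] / [I * (1 - 10**(-A808))]

    Returns (eta, out_of_range_flag).  Values outside [0, 1] are returned
    unmodified but flagged.
    """
    if system.a808 == 0:
        raise DomainError("a808 == 0: the agent absorbs no laser power")
    if system.laser_power <= 0:
        raise DomainError("laser_power must be > 0")
    if system.q_dis is None:
        raise DomainError("system.q_dis must be set (run estimate_qdis first)")
    absorbed = system.laser_power * (1.0 - 10.0 ** (-system.a808))
    eta = (fit.hS * (fit.t_max - fit.t_surr) - system.q_dis) / absorbed
    return eta, not (0.0 <= eta <= 1.0)


def simulate_temperature_trace(
    system: PhotothermalSystem,
    eta_true: float,
    hS_true: float,
    t_surr: float,
    laser_on: float,
    laser_off_duration: float,
    dt: float,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> TemperatureTrace:
    """Closed-form heating/cooling trace of the lumped energy balance.

    Heating: T(t) = T_surr + dT_inf * (1 - exp(-t/tau)) with
    dT_inf = (eta*I*(1 - 10**(-A808)) + Q_dis)/hS and tau = m_D*C_D/hS.
    Cooling: pure exponential decay from the laser-off temperature.
    Additive i.i.d. Gaussian noise with the given seed.
    """
    if dt <= 0:
        raise DomainError("dt must be > 0")
    if laser_on <= 0 or laser_off_duration <= 0:
        raise DomainError("durations must be > 0")
    if hS_true <= 0:
        raise DomainError("hS_true must be > 0")
    q_dis = system.q_dis if system.q_dis is not None else 0.0
    tau = system.heat_capacity_total / hS_true
    absorbed = system.laser_power * (1.0 - 10.0 ** (-system.a808))
    dT_inf = (eta_true * absorbed + q_dis) / hS_true

    t_heat = np.arange(0.0, laser_on + dt / 2, dt)
    temp_heat = t_surr + dT_inf * (1.0 - np.exp(-t_heat / tau))
    t_off = t_heat[-1]
    temp_off = temp_heat[-1]
    t_cool = np.arange(dt, laser_off_duration + dt / 2, dt)
    temp_cool = t_surr + (temp_off - t_surr) * np.exp(-t_cool / tau)

    time = np.concatenate([t_heat, t_off + t_cool])
    temp = np.concatenate([temp_heat, temp_cool])
    phase = np.array(["heating"] * len(t_heat) + ["cooling"] * len(t_cool), dtype=object)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        temp = temp + rng.normal(0.0, noise_sd, temp.shape)
    return TemperatureTrace(time=time, temp=temp, phase=phase, t_surr=t_surr)


def analyze_photothermal(
    sample_trace: TemperatureTrace,
    control_trace: TemperatureTrace,
    system: PhotothermalSystem,
    theta_min: float = 0.05,
    tail_points_k: int = 5,
) -> PhotothermalFit:
    """Full inversion chain: cooling fit -> hS -> Q_dis -> eta.

    T_max is the mean of the last ``tail_points_k`` heating-phase points of
    the sample trace; Q_dis comes from the solvent-only control with the
    sample's hS.  Stage failures are re-raised with stage context.
    """
    if not sample_trace.has_phase("heating"):
        raise InsufficientDataError("sample trace has no heating phase")
    try:
        tau_s, r2, n_used = fit_cooling_time_constant(sample_trace, theta_min=theta_min)
    except Exception as exc:
        raise type(exc)(f"cooling fit: {exc}") from exc
    hS = compute_hS(tau_s, system)
    caught: list[str] = []
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        try:
            q_dis = estimate_qdis(control_trace, hS, tail_points_k=tail_points_k)
        except Exception as exc:
            raise type(exc)(f"Q_dis estimation: {exc}") from exc
        caught = [str(w.message) for w in wlist]
    for msg in caught:
        warnings.warn(msg, UserWarning, stacklevel=2)

    _, temp_heat = sample_trace.select("heating")
    t_max = _tail_mean(temp_heat, tail_points_k)
    fit = PhotothermalFit(
        tau_s=tau_s,
        hS=hS,
        t_max=t_max,
        t_surr=sample_trace.t_surr,
        eta=np.nan,
        r_squared=r2,
        n_points_used=n_used,
        q_dis=q_dis,
        warnings=tuple(caught),
    )
    sys_with_q = replace_qdis(system, q_dis)
    try:
        eta, flagged = compute_eta(fit, sys_with_q)
    except Exception as exc:
        raise type(exc)(f"eta computation: {exc}") from exc
    return replace(fit, eta=eta, eta_out_of_range=flagged)


def replace_qdis(system: PhotothermalSystem, q_dis: float) -> PhotothermalSystem:
    """Copy of the system with q_dis set (q_dis below 0 clipped by validation)."""
    return PhotothermalSystem(
        laser_power=system.laser_power,
        a808=system.a808,
        solvent_mass=system.solvent_mass,
        solvent_heat_capacity=system.solvent_heat_capacity,
        q_dis=max(q_dis, 0.0),
    )
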