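"""Synthetic-data generators with known ground truth for every assay.

Each generator emulates one raw-data stream of a chemo-photothermal
nanomedicine study — heat/cool traces, Beer-Lambert calibration tables,
sample-and-replace release logs, hemolysis plates and caliper/body-weight
logs — and returns the ground truth alongside, so every analysis stage can be
exercised end-to-end with no external data.  All generators are deterministic
functions of (config, seed); at zero noise each is the exact inverse of its
analyzer.

Defaults mirror the study conditions the analyses target: a 22% conversion
efficiency agent heating from 23 degC to a 54 degC plateau under a 1 W laser,
a water control rising only 2.5 degC, 24-h release endpoints of 13% (pH 7.4),
26% (pH 5.8) and 68% (pH 5.8 + NIR), hemolysis below 4%, and 8 treatment
groups of 4 animals starting from ~200 mm^3 tumors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bioassay, dosimetry, thermal
from .errors import DomainError, RankDeficiencyError

__all__ = [
    "SyntheticConfig",
    "gen_thermal_experiment",
    "gen_release_experiment",
    "gen_standard_curve_data",
    "gen_tumor_study",
    "gen_hemolysis_plate",
]

TUMOR_GROUPS = (
    "PBS",
    "PBS+NIR",
    "DOX",
    "DOX+NIR",
    "Au@ZIF-8",
    "Au@ZIF-8+NIR",
    "Au@ZIF-8/DOX",
    "Au@ZIF-8/DOX+NIR",
)

# stream offsets so each assay draws from an independent, reproducible stream
_STREAMS = {"thermal": 1, "release": 2, "calibration": 3, "tumor": 4, "hemolysis": 5}


def _default_release_plateaus() -> dict[str, float]:
    # 24-h endpoints; pH7.4+NIR is an assumption (flagged in truth output)
    return {"pH7.4": 0.13, "pH5.8": 0.26, "pH7.4+NIR": 0.35, "pH5.8+NIR": 0.68}


def _default_growth_rates() -> dict[str, float]:
    # per-day exponential rates: untreated groups grow aggressively, chemo
    # groups hold volume, photothermal-alone relapses, combination regresses
    return {
        "PBS": 0.13,
        "PBS+NIR": 0.13,
        "Au@ZIF-8": 0.12,
        "Au@ZIF-8+NIR": 0.05,
        "DOX": 0.01,
        "DOX+NIR": 0.01,
        "Au@ZIF-8/DOX": 0.0,
        "Au@ZIF-8/DOX+NIR": -0.12,
    }


def _default_weight_trends() -> dict[str, float]:
    # g/day drift around the ~20 g starting weight
    return {
        "PBS": 0.05,
        "PBS+NIR": 0.05,
        "Au@ZIF-8": 0.05,
        "Au@ZIF-8+NIR": 0.04,
        "DOX": -0.06,
        "DOX+NIR": -0.06,
        "Au@ZIF-8/DOX": 0.01,
        "Au@ZIF-8/DOX+NIR": 0.02,
    }


@dataclass
class SyntheticConfig:
    """Ground-truth parameters and noise levels for every generator."""

    seed: int = 0

    # noise levels
    trace_noise_sd_C: float = 0.1  # thermal-camera accuracy
    absorbance_noise_sd: float = 0.01
    caliper_noise_sd_mm: float = 0.3

    # thermal truth
    eta_true: float = 0.22
    hS_true: float = 0.0065  # W/K -> tau ~129 s, plateau within 5 min
    t_surr: float = 23.0
    control_delta_t: float = 2.5  # water-control temperature rise, degC
    laser_power_w: float = 1.0  # 1 W/cm^2 over a 1 cm^2 beam
    a808: float = 0.8
    solvent_mass_g: float = 0.2
    heat_capacity_j_g_k: float = 4.18
    heating_s: float = 600.0
    cooling_s: float = 600.0
    dt_s: float = 1.0

    # release truth: F(t) = F_inf * (1 - exp(-k t)); k reaches 90% of the
    # plateau by 12 h
    release_plateaus: dict[str, float] = field(default_factory=_default_release_plateaus)
    release_rate_per_h: float = float(np.log(10) / 12.0)
    release_times_h: tuple[float, ...] = (1.0, 2.0, 4.0, 6.0, 8.0, 12.0, 24.0)
    total_volume_ml: float = 10.0
    withdrawn_volume_ml: float = 1.0
    total_loaded_mass_ug: float = 10000.0  # 1 mg/mL DOX in the 10 mL vessel

    # calibration truth
    calib_slope: float = 0.02  # absorbance per (ug/mL)
    calib_intercept: float = 0.02
    calib_concentrations: tuple[float, ...] = (0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 35.0)

    # tumor truth
    growth_rates_per_day: dict[str, float] = field(default_factory=_default_growth_rates)
    weight_trends_g_per_day: dict[str, float] = field(default_factory=_default_weight_trends)
    initial_volume_mm3: float = 200.0
    initial_weight_g: float = 20.0
    aspect_ratio: float = 1.5  # length/width
    group_size: int = 4
    study_days: tuple[int, ...] = tuple(range(0, 18, 2))
    weight_noise_sd_g: float = 0.1

    # hemolysis truth
    hemolysis_concentrations_ppm: tuple[float, ...] = (25.0, 50.0, 100.0, 200.0)
    hemolysis_max_rate_pct: float = 4.0
    abs_negative: float = 0.1
    abs_positive: float = 0.9

    def __post_init__(self) -> None:
        for name in ("trace_noise_sd_C", "absorbance_noise_sd", "caliper_noise_sd_mm"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")
        for cond, f in self.release_plateaus.items():
            if not (0.0 <= f <= 1.0):
                raise DomainError(f"release plateau for {cond!r} outside [0, 1]")
        if self.release_rate_per_h <= 0:
            raise DomainError("release_rate_per_h must be > 0")
        for g, r in self.growth_rates_per_day.items():
            if not np.isfinite(r):
                raise DomainError(f"growth rate for {g!r} not finite")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[stream]])


def _system(config: SyntheticConfig, q_dis: float | None) -> thermal.PhotothermalSystem:
    return thermal.PhotothermalSystem(
        laser_power=config.laser_power_w,
        a808=config.a808,
        solvent_mass=config.solvent_mass_g,
        solvent_heat_capacity=config.heat_capacity_j_g_k,
        q_dis=q_dis,
    )


def gen_thermal_experiment(
    config: SyntheticConfig,
) -> tuple[thermal.TemperatureTrace, thermal.TemperatureTrace, thermal.PhotothermalSystem, dict]:
    """Sample and solvent-only control heat/cool traces plus ground truth.

    The control trace is the same energy balance with eta = 0: its plateau is
    Q_dis/hS above ambient (default 2.5 degC).  Q_dis is derived from the
    configured control rise, q_dis = hS_true * control_delta_t.
    """
    q_dis_true = config.hS_true * config.control_delta_t
    system = _system(config, q_dis_true)
    rng = config.rng("thermal")
    seeds = rng.integers(0, 2**31 - 1, size=2)
    common = dict(
        hS_true=config.hS_true,
        t_surr=config.t_surr,
        laser_on=config.heating_s,
        laser_off_duration=config.cooling_s,
        dt=config.dt_s,
        noise_sd=config.trace_noise_sd_C,
    )
    sample = thermal.simulate_temperature_trace(
        system, eta_true=config.eta_true, seed=int(seeds[0]), **common
    )
    control = thermal.simulate_temperature_trace(
        system, eta_true=0.0, seed=int(seeds[1]), **common
    )
    truth = {
        "eta_true": config.eta_true,
        "hS_true": config.hS_true,
        "q_dis_true": q_dis_true,
        "tau_true_s": system.heat_capacity_total / config.hS_true,
        "t_surr": config.t_surr,
    }
    return sample, control, system, truth


def gen_release_experiment(config: SyntheticConfig) -> tuple[pd.DataFrame, dict]:
    """Withdrawn-sample concentration logs per condition plus ground truth.

    The cumulative released fraction follows first-order saturation
    F(t) = F_inf*(1 - exp(-k t)); the emitted concentrations are the exact
    inverse of the replacement-corrected cumulative-release formula, so the
    analyzer round-trips the truth at zero noise.  Concentration noise is
    absorbance noise mapped through the calibration slope.
    """
    rng = config.rng("release")
    t = np.asarray(config.release_times_h, dtype=float)
    v, V = config.withdrawn_volume_ml, config.total_volume_ml
    loaded = config.total_loaded_mass_ug
    conc_noise_sd = config.absorbance_noise_sd / config.calib_slope
    rows = []
    truth: dict[str, dict] = {"per_condition": {}, "rate_per_h": config.release_rate_per_h}
    for cond in sorted(config.release_plateaus):
        f_inf = config.release_plateaus[cond]
        frac = f_inf * (1.0 - np.exp(-config.release_rate_per_h * t))
        mass = frac * loaded
        conc = np.empty_like(mass)
        hist = 0.0
        for n in range(len(mass)):
            conc[n] = (mass[n] - v * hist) / V
            hist += conc[n]
        noisy = np.clip(conc + rng.normal(0.0, conc_noise_sd, conc.shape), 0.0, None)
        for ti, ci in zip(t, noisy):
            rows.append({"condition": cond, "time_h": ti, "concentration_ug_ml": ci})
        truth["per_condition"][cond] = {
            "f_inf": f_inf,
            "assumed": cond == "pH7.4+NIR",
            "fraction_at": dict(zip(t.tolist(), frac.tolist())),
        }
    log = pd.DataFrame(rows)
    truth["total_volume_ml"] = V
    truth["withdrawn_volume_ml"] = v
    truth["total_loaded_mass_ug"] = loaded
    return log, truth


def gen_standard_curve_data(config: SyntheticConfig) -> tuple[pd.DataFrame, dict]:
    """Linear calibration table with Gaussian absorbance noise plus truth."""
    conc = np.asarray(config.calib_concentrations, dtype=float)
    if np.unique(conc).size < 2:
        raise RankDeficiencyError("calibration grid needs >= 2 distinct concentrations")
    rng = config.rng("calibration")
    ab = config.calib_slope * conc + config.calib_intercept
    ab = ab + rng.normal(0.0, config.absorbance_noise_sd, ab.shape)
    table = pd.DataFrame({"conc_ug_ml": conc, "absorbance": ab})
    truth = {"slope": config.calib_slope, "intercept": config.calib_intercept}
    return table, truth


def gen_tumor_study(config: SyntheticConfig) -> tuple[bioassay.StudyTable, dict]:
    """Caliper and body-weight logs for 8 treatment groups plus truth.

    Tumor volume grows (or regresses) exponentially per group from the common
    starting volume; volumes are converted to (length, width) caliper pairs at
    a fixed aspect ratio and perturbed with caliper noise.  Body weight is a
    mild random walk around a per-group linear trend.
    """
    rng = config.rng("tumor")
    days = np.asarray(config.study_days, dtype=int)
    aspect = config.aspect_ratio
    rows = []
    for group in TUMOR_GROUPS:
        rate = config.growth_rates_per_day[group]
        trend = config.weight_trends_g_per_day[group]
        for j in range(config.group_size):
            subject = f"{group}-{j + 1}"
            vol = config.initial_volume_mm3 * np.exp(rate * days)
            # V = pi*L*W^2/6 with L = aspect*W  =>  W = (6V/(pi*aspect))^(1/3)
            width = (6.0 * vol / (np.pi * aspect)) ** (1.0 / 3.0)
            length = aspect * width
            length = length + rng.normal(0.0, config.caliper_noise_sd_mm, length.shape)
            width = width + rng.normal(0.0, config.caliper_noise_sd_mm, width.shape)
            length = np.maximum(length, 0.1)
            width = np.minimum(np.maximum(width, 0.1), length)
            weight = np.empty(len(days))
            weight[0] = config.initial_weight_g
            for k in range(1, len(days)):
                step = days[k] - days[k - 1]
                weight[k] = (
                    weight[k - 1]
                    + trend * step
                    + rng.normal(0.0, config.weight_noise_sd_g)
                )
            weight = np.maximum(weight, 1.0)
            for d, l_mm, w_mm, bw in zip(days, length, width, weight):
                rows.append((int(d), subject, group, "tumor_length_mm", float(l_mm)))
                rows.append((int(d), subject, group, "tumor_width_mm", float(w_mm)))
                rows.append((int(d), subject, group, "body_weight_g", float(bw)))
    df = pd.DataFrame(
        rows, columns=["day", "subject_id", "group", "measurement_type", "value"]
    )
    truth = {
        "growth_rates_per_day": dict(config.growth_rates_per_day),
        "initial_volume_mm3": config.initial_volume_mm3,
        "aspect_ratio": aspect,
        "group_size": config.group_size,
    }
    return bioassay.StudyTable(df), truth


def gen_hemolysis_plate(config: SyntheticConfig) -> tuple[bioassay.HemolysisPlate, dict]:
    """Hemolysis plate inverted from truth rates drawn in [0, max_rate]%."""
    rng = config.rng("hemolysis")
    concs = np.asarray(config.hemolysis_concentrations_ppm, dtype=float)
    rates = np.sort(rng.uniform(0.0, config.hemolysis_max_rate_pct, concs.size))
    span = config.abs_positive - config.abs_negative
    samples = []
    for i, (conc, rate) in enumerate(zip(concs, rates)):
        ab = config.abs_negative + rate / 100.0 * span
        ab += rng.normal(0.0, config.absorbance_noise_sd)
        samples.append((f"S{i + 1}", float(conc), float(ab)))
    plate = bioassay.HemolysisPlate(
        abs_samples=tuple(samples),
        abs_negative=config.abs_negative,
        abs_positive=config.abs_positive,
    )
    truth = {"rates_pct": dict(zip([s[0] for s in samples], rates.tolist()))}
    return plate, truth
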