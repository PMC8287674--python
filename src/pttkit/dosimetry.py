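"""Drug-loading and release quantification from absorbance measurements.

Loading of a payload (here doxorubicin, DOX) into a nanoparticle carrier is
expressed as two mass fractions:

    DLC = W_loaded / (W_loaded + W_nanoparticle)   (drug loading content)
    DLE = W_loaded / W_original                    (drug loading efficiency)

with W_loaded = W_original - W_residual, the drug mass taken up by the
carrier.  Concentrations come from a linear Beer-Lambert standard curve.

Cumulative release uses the standard dissolution-testing correction for
sample-and-replace protocols: at each sampling a volume ``v`` is withdrawn
and replaced with fresh medium, so the mass released by sampling n is

    M_n = V_total * C_n + v * sum_{i<n} C_i

(the drug currently in the vessel plus everything carried away by earlier
withdrawals).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DomainError, RankDeficiencyError

__all__ = [
    "StandardCurve",
    "LoadingMeasurement",
    "ReleaseSeries",
    "fit_standard_curve",
    "absorbance_to_concentration",
    "compute_loading",
    "cumulative_release",
    "release_summary",
]


@dataclass(frozen=True)
class StandardCurve:
    """Linear absorbance <-> concentration calibration with fit diagnostics."""

    slope: float  # absorbance per (ug/mL)
    intercept: float
    conc_range: tuple[float, float]  # ug/mL span of the calibration
    r_squared: float

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise DomainError("standard-curve slope must be > 0")
        lo, hi = self.conc_range
        if lo < 0 or lo >= hi:
            raise DomainError("conc_range must satisfy 0 <= min < max")
        if not (0.0 <= self.r_squared <= 1.0):
            raise DomainError("r_squared must lie in [0, 1]")


@dataclass(frozen=True)
class LoadingMeasurement:
    """Masses entering the loading-content / loading-efficiency fractions.

    All three masses must be in the same unit (ug or mg).
    """

    w_original: float
    w_residual: float
    w_nanoparticle: float

    def __post_init__(self) -> None:
        if min(self.w_original, self.w_residual, self.w_nanoparticle) < 0:
            raise DomainError("masses must be >= 0")
        if self.w_residual > self.w_original:
            raise DomainError("w_residual cannot exceed w_original")


@dataclass(frozen=True)
class ReleaseSeries:
    """Per-condition cumulative-release fractions, replacement-corrected."""

    condition: str
    time_h: np.ndarray
    cumulative_fraction: np.ndarray
    withdrawn_volume: float
    total_volume: float
    total_loaded_mass: float
    monotonicity_violated: bool = False
    released_mass: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        t = np.asarray(self.time_h, dtype=float)
        f = np.asarray(self.cumulative_fraction, dtype=float)
        object.__setattr__(self, "time_h", t)
        object.__setattr__(self, "cumulative_fraction", f)
        if np.any(np.diff(t) <= 0):
            raise DomainError("time_h must be strictly increasing")
        if self.withdrawn_volume >= self.total_volume:
            raise DomainError("withdrawn_volume must be < total_volume")


def fit_standard_curve(
    concentrations: np.ndarray, absorbances: np.ndarray
) -> StandardCurve:
    """Ordinary least squares calibration line with free intercept.

    Requires at least 3 calibration points over at least 2 distinct
    concentrations.  Plate-reader baselines are rarely zero, so the intercept
    is not forced through the origin.
    """
    conc = np.asarray(concentrations, dtype=float)
    ab = np.asarray(absorbances, dtype=float)
    if conc.shape != ab.shape or conc.ndim != 1:
        raise DomainError("concentrations and absorbances must be equal-length 1-D")
    if conc.size < 3:
        raise DomainError("need at least 3 calibration points")
    if np.unique(conc).size < 2:
        raise RankDeficiencyError("all calibration concentrations are identical")
    res = stats.linregress(conc, ab)
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        conc_range=(float(conc.min()), float(conc.max())),
        r_squared=float(res.rvalue**2),
    )


def absorbance_to_concentration(
    curve: StandardCurve, absorbance: float
) -> tuple[float, dict[str, bool]]:
    """Invert the calibration line: (absorbance - intercept) / slope.

    Negative estimates are floored at 0 and flagged; estimates outside the
    calibrated concentration range are flagged as extrapolation.
    """
    conc = (absorbance - curve.intercept) / curve.slope
    flags = {"negative_estimate": False, "extrapolated": False}
    if conc < 0:
        flags["negative_estimate"] = True
        conc = 0.0
    lo, hi = curve.conc_range
    if not (lo <= conc <= hi):
        flags["extrapolated"] = True
    return float(conc), flags


def compute_loading(m: LoadingMeasurement) -> tuple[float, float]:
    """Drug loading content and efficiency as fractions.

    DLC = W_loaded/(W_loaded + W_nanoparticle); DLE = W_loaded/W_original,
    with W_loaded = w_original - w_residual.
    """
    if m.w_original == 0:
        raise DomainError("w_original == 0: loading efficiency undefined")
    w_loaded = m.w_original - m.w_residual
    w_total = w_loaded + m.w_nanoparticle
    if w_total == 0:
        raise DomainError("no drug loaded and no carrier: loading content undefined")
    return w_loaded / w_total, w_loaded / m.w_original


def cumulative_release(
    sample_times: np.ndarray,
    sampled_concentrations: np.ndarray,
    total_volume: float,
    withdrawn_volume: float,
    total_loaded_mass: float,
    condition: str = "",
) -> ReleaseSeries:
    """Cumulative released fraction from withdrawn-sample concentrations.

    Released mass at sampling n is V_total*C_n + v*sum_{i<n} C_i; the fraction
    divides by the loaded drug mass.  Noise-induced non-monotonicity is
    flagged, never repaired.
    """
    t = np.asarray(sample_times, dtype=float)
    c = np.asarray(sampled_concentrations, dtype=float)
    if t.shape != c.shape or t.ndim != 1:
        raise DomainError("times and concentrations must be equal-length 1-D")
    if np.any(np.diff(t) <= 0):
        raise DomainError("sample times must be strictly increasing")
    if np.any(c < 0):
        raise DomainError("sampled concentrations must be >= 0")
    if total_loaded_mass <= 0:
        raise DomainError("total_loaded_mass must be > 0")
    if withdrawn_volume >= total_volume:
        raise DomainError("withdrawn_volume must be < total_volume")
    history = np.concatenate([[0.0], np.cumsum(c)[:-1]])  # sum_{i<n} C_i
    mass = total_volume * c + withdrawn_volume * history
    frac = mass / total_loaded_mass
    return ReleaseSeries(
        condition=condition,
        time_h=t,
        cumulative_fraction=frac,
        withdrawn_volume=withdrawn_volume,
        total_volume=total_volume,
        total_loaded_mass=total_loaded_mass,
        monotonicity_violated=bool(np.any(np.diff(frac) < 0)),
        released_mass=mass,
    )


def release_summary(
    series_list: list[ReleaseSeries], at_time: float
) -> dict[str, object]:
    """Per-condition release fraction at ``at_time`` hours plus all pairwise
    differences (linear interpolation between samples)."""
    fractions: dict[str, float] = {}
    for s in series_list:
        if not (s.time_h[0] <= at_time <= s.time_h[-1]):
            raise DomainError(
                f"at_time={at_time} h outside sampled range "
                f"[{s.time_h[0]}, {s.time_h[-1]}] for condition {s.condition!r}"
            )
        fractions[s.condition] = float(np.interp(at_time, s.time_h, s.cumulative_fraction))
    conditions = list(fractions)
    differences = {
        f"{a} - {b}": fractions[a] - fractions[b]
        for i, a in enumerate(conditions)
        for b in conditions[i + 1 :]
    }
    return {"at_time_h": at_time, "fractions": fractions, "differences": differences}
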