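"""Hemolysis, viability, tumor-volume and group-comparison analytics.

Hemolysis is normalized between a PBS negative control (0%) and a deionized
water positive control (100%):

    hemolysis% = 100 * (ABS_sample - ABS_neg) / (ABS_pos - ABS_neg)

MTT viability is the blank-subtracted ratio of treated to untreated mean
absorbance.  Caliper tumor volumes use the ellipsoid approximation
V = pi * L * W^2 / 6 (equivalently (4/3) pi (L/2)(W/2)^2 with the width taken
for both short axes).  Group comparisons use the two-sample Student t-test
(pooled variance), the test named in most animal-study statistics sections;
Welch's correction is available behind a flag.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, InvalidAssayError

__all__ = [
    "HemolysisPlate",
    "StudyTable",
    "hemolysis_rate",
    "viability_percent",
    "tumor_volume",
    "relative_series",
    "compare_groups",
    "SIGNIFICANCE_THRESHOLD",
]

#: reported alongside every p-value, never applied silently
SIGNIFICANCE_THRESHOLD = 0.05

MEASUREMENT_TYPES = (
    "tumor_length_mm",
    "tumor_width_mm",
    "body_weight_g",
    "viability_abs",
)


@dataclass(frozen=True)
class HemolysisPlate:
    """540 nm absorbances of test samples plus PBS/water controls.

    abs_samples: list of (sample_id, concentration_ppm, absorbance).
    """

    abs_samples: tuple[tuple[str, float, float], ...]
    abs_negative: float
    abs_positive: float

    def __post_init__(self) -> None:
        if self.abs_positive <= self.abs_negative:
            raise InvalidAssayError(
                "positive control absorbance must exceed negative control"
            )
        object.__setattr__(self, "abs_samples", tuple(tuple(s) for s in self.abs_samples))


class StudyTable:
    """Long-format animal/plate measurements with group labels.

    Wraps a DataFrame with columns day, subject_id, group, measurement_type,
    value; each (subject_id, day, measurement_type) must be unique.
    """

    COLUMNS = ("day", "subject_id", "group", "measurement_type", "value")

    def __init__(self, df: pd.DataFrame):
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise DomainError(f"StudyTable missing columns: {sorted(missing)}")
        df = df.loc[:, list(self.COLUMNS)].copy()
        df["day"] = df["day"].astype(int)
        df["value"] = df["value"].astype(float)
        unknown = set(df["measurement_type"]) - set(MEASUREMENT_TYPES)
        if unknown:
            raise DomainError(f"unknown measurement types: {sorted(unknown)}")
        physical = df["measurement_type"].isin(
            ["tumor_length_mm", "tumor_width_mm", "body_weight_g"]
        )
        if (df.loc[physical, "value"] <= 0).any():
            raise DomainError("lengths, widths and weights must be > 0")
        dup = df.duplicated(subset=["subject_id", "day", "measurement_type"])
        if dup.any():
            raise DomainError("duplicate (subject, day, measurement_type) records")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def tumor_volumes(self) -> pd.DataFrame:
        """Per-subject per-day ellipsoid volumes from paired L/W records."""
        wide = self.df[
            self.df["measurement_type"].isin(["tumor_length_mm", "tumor_width_mm"])
        ].pivot_table(
            index=["subject_id", "group", "day"],
            columns="measurement_type",
            values="value",
        )
        if wide.isna().any().any():
            raise DomainError("unpaired tumor length/width records")
        vol = [
            tumor_volume(row["tumor_length_mm"], row["tumor_width_mm"])
            for _, row in wide.iterrows()
        ]
        out = wide.reset_index()[["subject_id", "group", "day"]]
        out["value"] = vol
        return out


def hemolysis_rate(plate: HemolysisPlate) -> pd.DataFrame:
    """Per-sample hemolysis percentage with out-of-range flags."""
    span = plate.abs_positive - plate.abs_negative
    rows = []
    for sample_id, conc, ab in plate.abs_samples:
        rate = 100.0 * (ab - plate.abs_negative) / span
        rows.append(
            {
                "sample_id": sample_id,
                "concentration_ppm": conc,
                "hemolysis_pct": rate,
                "out_of_range": not (0.0 <= rate <= 100.0),
            }
        )
    return pd.DataFrame(rows)


def viability_percent(
    abs_treated: np.ndarray, abs_control: np.ndarray, abs_blank: float = 0.0
) -> tuple[float, float]:
    """MTT viability: 100*(mean(treated) - blank)/(mean(control) - blank).

    Returns (viability_pct, sd_pct); the dispersion is propagated from the
    replicate spread of the treated wells.
    """
    treated = np.asarray(abs_treated, dtype=float)
    control = np.asarray(abs_control, dtype=float)
    denom = float(control.mean()) - abs_blank
    if denom <= 0:
        raise InvalidAssayError("mean control absorbance must exceed the blank")
    v = 100.0 * (float(treated.mean()) - abs_blank) / denom
    sd = 100.0 * float(treated.std(ddof=1) if treated.size > 1 else 0.0) / denom
    return v, sd


def tumor_volume(length_mm: float, width_mm: float) -> float:
    """Ellipsoid caliper volume pi * L * W^2 / 8 * 4/3 (= pi*L*W^2/6), mm^3."""
    if length_mm <= 0 or width_mm <= 0:
        raise DomainError("tumor dimensions must be > 0")
    if length_mm < width_mm:
        warnings.warn(
            f"length {length_mm} < width {width_mm}: axes likely swapped",
            UserWarning,
            stacklevel=2,
        )
    return math.pi * length_mm * width_mm**2 / 8.0 * 4.0 / 3.0


def relative_series(
    table: StudyTable, measurement: str, baseline_day: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject trajectories normalized to each subject's own baseline.

    ``measurement`` is one of the study measurement types or ``tumor_volume``
    (volumes computed from paired caliper records first).  Subjects missing a
    baseline record are excluded with a warning.  Returns (per_subject,
    per_group) frames; the group frame carries mean and SD per day.
    """
    if measurement == "tumor_volume":
        data = table.tumor_volumes()
    elif measurement in MEASUREMENT_TYPES:
        data = table.df[table.df["measurement_type"] == measurement][
            ["subject_id", "group", "day", "value"]
        ].copy()
    else:
        raise DomainError(f"unknown measurement {measurement!r}")

    base = data[data["day"] == baseline_day].set_index("subject_id")["value"]
    missing = sorted(set(data["subject_id"]) - set(base.index))
    if missing:
        warnings.warn(
            f"subjects without day-{baseline_day} baseline excluded: {missing}",
            UserWarning,
            stacklevel=2,
        )
        data = data[~data["subject_id"].isin(missing)]
    data = data.copy()
    data["relative"] = data["value"] / data["subject_id"].map(base).to_numpy()
    per_group = (
        data.groupby(["group", "day"])["relative"]
        .agg(mean="mean", sd=lambda x: x.std(ddof=1) if len(x) > 1 else 0.0)
        .reset_index()
    )
    return data, per_group


def compare_groups(
    values_a: np.ndarray, values_b: np.ndarray, welch: bool = False
) -> dict[str, float | bool]:
    """Two-sample t-test between groups.

    Pooled-variance Student form by default; ``welch=True`` drops the
    equal-variance assumption.  Two groups with zero variance and equal means
    return t=0, p=1 by convention; zero combined variance with unequal means
    is degenerate and flagged.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DomainError("each group needs at least 2 values")
    var_a = a.var(ddof=1)
    var_b = b.var(ddof=1)
    if var_a == 0 and var_b == 0:
        if a.mean() == b.mean():
            return {
                "t": 0.0,
                "p_value": 1.0,
                "significant_at_0.05": False,
                "degenerate": False,
            }
        return {
            "t": math.inf if a.mean() > b.mean() else -math.inf,
            "p_value": 0.0,
            "significant_at_0.05": True,
            "degenerate": True,
        }
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return {
        "t": float(t),
        "p_value": float(p),
        "significant_at_0.05": bool(p < SIGNIFICANCE_THRESHOLD),
        "degenerate": False,
    }
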