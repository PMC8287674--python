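"""CSV readers/writers, configuration and the consolidated report.

CSV dialect is fixed for reproducibility: comma separator, '.' decimal,
UTF-8, required headers; anything else is rejected with a schema error that
names the offending line.  JSON report floats are serialized at 10
significant digits so identical inputs yield byte-identical reports.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bioassay, dosimetry, thermal
from .errors import SchemaError

__all__ = [
    "RunConfig",
    "read_trace_csv",
    "write_trace_csv",
    "read_standard_curve_csv",
    "read_release_csv",
    "read_study_csv",
    "read_hemolysis_csv",
    "load_run_config",
    "run_report",
    "dump_json",
]

_TRACE_COLUMNS = ("time_s", "temp_C", "phase")


def _require_columns(df: pd.DataFrame, required: tuple[str, ...], path: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")


def _read_csv(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep=",", encoding="utf-8")
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise SchemaError(f"{path}: cannot parse as comma-separated UTF-8: {exc}") from exc


def read_trace_csv(path: str | Path, t_surr: float | None = None) -> thermal.TemperatureTrace:
    """Read a time/temperature trace.

    Columns: time_s, temp_C, phase (pre|heating|cooling); optional t_surr_C
    (constant column) unless passed explicitly.  Line numbers in errors count
    the header as line 1.
    """
    df = _read_csv(path)
    _require_columns(df, _TRACE_COLUMNS, str(path))
    for i, row in df.iterrows():
        line = i + 2
        if row["phase"] not in ("pre", "heating", "cooling"):
            raise SchemaError(f"{path}: line {line}: unknown phase {row['phase']!r}")
        if not (math.isfinite(row["time_s"]) and math.isfinite(row["temp_C"])):
            raise SchemaError(f"{path}: line {line}: non-finite time or temperature")
    t = df["time_s"].to_numpy(float)
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        raise SchemaError(f"{path}: line {bad[0] + 3}: time not strictly increasing")
    if t_surr is None:
        if "t_surr_C" not in df.columns:
            raise SchemaError(f"{path}: t_surr_C column absent and no t_surr given")
        t_surr = float(df["t_surr_C"].iloc[0])
    return thermal.TemperatureTrace(
        time=t,
        temp=df["temp_C"].to_numpy(float),
        phase=df["phase"].to_numpy(object),
        t_surr=t_surr,
    )


def write_trace_csv(trace: thermal.TemperatureTrace, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "time_s": trace.time,
            "temp_C": trace.temp,
            "phase": trace.phase,
            "t_surr_C": trace.t_surr,
        }
    )
    df.to_csv(path, index=False, encoding="utf-8")


def read_standard_curve_csv(path: str | Path) -> dosimetry.StandardCurve:
    """Fit a calibration line from a conc_ug_ml/absorbance table."""
    df = _read_csv(path)
    _require_columns(df, ("conc_ug_ml", "absorbance"), str(path))
    return dosimetry.fit_standard_curve(
        df["conc_ug_ml"].to_numpy(float), df["absorbance"].to_numpy(float)
    )


def read_release_csv(
    path: str | Path, curve: dosimetry.StandardCurve | None = None
) -> pd.DataFrame:
    """Release sampling log: condition, time_h, and either concentration_ug_ml
    or absorbance (converted through the supplied standard curve)."""
    df = _read_csv(path)
    _require_columns(df, ("condition", "time_h"), str(path))
    if "concentration_ug_ml" in df.columns:
        return df[["condition", "time_h", "concentration_ug_ml"]].copy()
    if "absorbance" not in df.columns:
        raise SchemaError(f"{path}: need concentration_ug_ml or absorbance column")
    if curve is None:
        raise SchemaError(f"{path}: absorbance column requires a standard curve")
    conc = [
        dosimetry.absorbance_to_concentration(curve, a)[0] for a in df["absorbance"]
    ]
    out = df[["condition", "time_h"]].copy()
    out["concentration_ug_ml"] = conc
    return out


def read_study_csv(path: str | Path) -> bioassay.StudyTable:
    df = _read_csv(path)
    _require_columns(df, bioassay.StudyTable.COLUMNS, str(path))
    return bioassay.StudyTable(df)


def read_hemolysis_csv(path: str | Path) -> bioassay.HemolysisPlate:
    """Hemolysis plate: sample_id, concentration_ppm, absorbance; control
    wells have sample_id POS / NEG."""
    df = _read_csv(path)
    _require_columns(df, ("sample_id", "concentration_ppm", "absorbance"), str(path))
    controls = {}
    samples = []
    for _, row in df.iterrows():
        sid = str(row["sample_id"])
        if sid in ("POS", "NEG"):
            controls[sid] = float(row["absorbance"])
        else:
            samples.append((sid, float(row["concentration_ppm"]), float(row["absorbance"])))
    if "POS" not in controls or "NEG" not in controls:
        raise SchemaError(f"{path}: POS and NEG control rows required")
    return bioassay.HemolysisPlate(
        abs_samples=tuple(samples),
        abs_negative=controls["NEG"],
        abs_positive=controls["POS"],
    )


@dataclass
class RunConfig:
    """Paths and parameters for the consolidated report."""

    out_dir: str = "."
    seed: int = 0
    # thermal
    sample_trace: str | None = None
    control_trace: str | None = None
    laser_power_w: float | None = None
    power_density_w_cm2: float | None = None
    beam_area_cm2: float = 1.0
    a808: float = 0.8
    solvent_mass_g: float = 0.2
    heat_capacity_j_g_k: float = 4.18
    t_surr_C: float | None = None
    theta_min: float = 0.05
    tail_points_k: int = 5
    # dosimetry
    standard_curve: str | None = None
    release_log: str | None = None
    total_volume_ml: float = 10.0
    withdrawn_volume_ml: float = 1.0
    total_loaded_mass_ug: float = 10000.0
    loading_w_original: float | None = None
    loading_w_residual: float | None = None
    loading_w_nanoparticle: float | None = None
    # bioassay
    hemolysis_plate: str | None = None
    study_table: str | None = None
    baseline_day: int = 0
    extra: dict = field(default_factory=dict)

    @property
    def laser_power(self) -> float:
        """Watts delivered to the sample: explicit, or density x beam area."""
        if self.laser_power_w is not None:
            return self.laser_power_w
        if self.power_density_w_cm2 is not None:
            return self.power_density_w_cm2 * self.beam_area_cm2
        return 1.0

    def input_paths(self) -> list[str]:
        return [
            p
            for p in (
                self.sample_trace,
                self.control_trace,
                self.standard_curve,
                self.release_log,
                self.hemolysis_plate,
                self.study_table,
            )
            if p is not None
        ]


def load_run_config(path: str | Path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    known = {k: v for k, v in raw.items() if k in RunConfig.__dataclass_fields__}
    extra = {k: v for k, v in raw.items() if k not in RunConfig.__dataclass_fields__}
    cfg = RunConfig(**known)
    cfg.extra = extra
    return cfg


def _round_sig(x: float, sig: int = 10) -> float:
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


def _jsonify(obj):
    """Recursively convert to JSON-serializable with 10-sig-digit floats."""
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, (np.floating, float)):
        return _round_sig(float(obj))
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, pd.DataFrame):
        return _jsonify(obj.to_dict(orient="records"))
    return obj


def dump_json(obj, path: str | Path | None = None) -> str:
    """Serialize with deterministic float formatting; optionally write."""
    text = json.dumps(_jsonify(obj), indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(text + "\n", encoding="utf-8")
    return text


def run_report(config: RunConfig) -> dict:
    """Run every configured analysis stage and consolidate the results.

    Pre-flight checks all referenced inputs before any computation; a stage
    failure aborts with stage context after writing partial results with a
    failure marker.  Every numeric result carries its input provenance.
    """
    from . import __version__

    missing = [p for p in config.input_paths() if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"missing input files: {missing}")

    report: dict = {
        "software_version": __version__,
        "seed": config.seed,
        "stages": {},
        "warnings": [],
    }
    stage = "none"
    try:
        if config.sample_trace and config.control_trace:
            stage = "photothermal"
            sample = read_trace_csv(config.sample_trace, t_surr=config.t_surr_C)
            control = read_trace_csv(config.control_trace, t_surr=config.t_surr_C)
            system = thermal.PhotothermalSystem(
                laser_power=config.laser_power,
                a808=config.a808,
                solvent_mass=config.solvent_mass_g,
                solvent_heat_capacity=config.heat_capacity_j_g_k,
            )
            fit = thermal.analyze_photothermal(
                sample, control, system,
                theta_min=config.theta_min, tail_points_k=config.tail_points_k,
            )
            report["stages"]["photothermal"] = {
                "inputs": {
                    "sample_trace": config.sample_trace,
                    "control_trace": config.control_trace,
                    "laser_power_w": config.laser_power,
                    "a808": config.a808,
                    "solvent_mass_g": config.solvent_mass_g,
                    "heat_capacity_j_g_k": config.heat_capacity_j_g_k,
                    "theta_min": config.theta_min,
                    "tail_points_k": config.tail_points_k,
                },
                "eta": fit.eta,
                "eta_out_of_range": fit.eta_out_of_range,
                "tau_s": fit.tau_s,
                "hS_w_per_k": fit.hS,
                "t_max_C": fit.t_max,
                "q_dis_w": fit.q_dis,
                "r_squared": fit.r_squared,
                "n_points_used": fit.n_points_used,
                "warnings": list(fit.warnings),
            }
        if (
            config.loading_w_original is not None
            and config.loading_w_residual is not None
            and config.loading_w_nanoparticle is not None
        ):
            stage = "loading"
            dlc, dle = dosimetry.compute_loading(
                dosimetry.LoadingMeasurement(
                    config.loading_w_original,
                    config.loading_w_residual,
                    config.loading_w_nanoparticle,
                )
            )
            report["stages"]["loading"] = {
                "inputs": {
                    "w_original": config.loading_w_original,
                    "w_residual": config.loading_w_residual,
                    "w_nanoparticle": config.loading_w_nanoparticle,
                },
                "dlc_pct": 100.0 * dlc,
                "dle_pct": 100.0 * dle,
            }
        if config.release_log:
            stage = "release"
            curve = (
                read_standard_curve_csv(config.standard_curve)
                if config.standard_curve
                else None
            )
            log = read_release_csv(config.release_log, curve=curve)
            series = []
            for cond, grp in log.groupby("condition", sort=True):
                grp = grp.sort_values("time_h")
                series.append(
                    dosimetry.cumulative_release(
                        grp["time_h"].to_numpy(float),
                        grp["concentration_ug_ml"].to_numpy(float),
                        total_volume=config.total_volume_ml,
                        withdrawn_volume=config.withdrawn_volume_ml,
                        total_loaded_mass=config.total_loaded_mass_ug,
                        condition=str(cond),
                    )
                )
            report["stages"]["release"] = {
                "inputs": {
                    "release_log": config.release_log,
                    "standard_curve": config.standard_curve,
                    "total_volume_ml": config.total_volume_ml,
                    "withdrawn_volume_ml": config.withdrawn_volume_ml,
                    "total_loaded_mass_ug": config.total_loaded_mass_ug,
                },
                "series": {
                    s.condition: {
                        "time_h": s.time_h,
                        "cumulative_fraction": s.cumulative_fraction,
                        "monotonicity_violated": s.monotonicity_violated,
                    }
                    for s in series
                },
            }
        if config.hemolysis_plate:
            stage = "hemolysis"
            plate = read_hemolysis_csv(config.hemolysis_plate)
            rates = bioassay.hemolysis_rate(plate)
            report["stages"]["hemolysis"] = {
                "inputs": {"plate": config.hemolysis_plate},
                "rates": rates,
                "max_rate_pct": float(rates["hemolysis_pct"].max()),
            }
        if config.study_table:
            stage = "tumor"
            table = read_study_csv(config.study_table)
            _, vol_group = bioassay.relative_series(
                table, "tumor_volume", baseline_day=config.baseline_day
            )
            _, weight_group = bioassay.relative_series(
                table, "body_weight_g", baseline_day=config.baseline_day
            )
            report["stages"]["tumor"] = {
                "inputs": {
                    "study_table": config.study_table,
                    "baseline_day": config.baseline_day,
                },
                "relative_volume": vol_group,
                "relative_body_weight": weight_group,
            }
    except Exception as exc:
        report["failed_stage"] = stage
        report["error"] = str(exc)
        out = Path(config.out_dir) / "report.partial.json"
        out.parent.mkdir(parents=True, exist_ok=True)
        dump_json(report, out)
        raise type(exc)(f"stage {stage!r}: {exc}") from exc
    return _jsonify(report)
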