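"""Batch workflow: calibrate → analyze every curve → thin-shell enrichment
→ ensemble summaries → group comparisons.

Per-curve failures (malformed files, no contact, glass-like curves) are
logged and flagged, never fatal; a run only fails when zero curves
succeed.  Outputs are deterministic for fixed inputs and seed, and every
output directory carries a run log with the configuration hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .analysis import AnalysisConfig, analyze_curve
from .calibration import CalibrationResult
from .errors import CapsidMechError
from .shell import (
    ShellGeometry,
    default_geometry_registry,
    indentation_at_break,
    load_geometry_registry,
    percent_indentation,
    youngs_modulus,
)
from .stats import EnsembleSummary, GroupComparison, compare, summarize

logger = logging.getLogger("capsidmech")

__all__ = ["RunConfig", "RunResult", "run_pipeline", "DEFAULT_COMPARISONS"]

# Default group comparisons: (reference group, comparison group, metric).
DEFAULT_COMPARISONS: list[tuple[str, str, str]] = [
    ("WT_B", "UL25null_B", "k"),
    ("WT_B", "UL25null_B", "F_break"),
    ("WT_B", "UL17null_B", "k"),
    ("WT_B", "UL17null_B", "F_break"),
    ("WT_A", "UL25null_A", "k"),
    ("WT_A", "UL25null_A", "F_break"),
    ("WT_C", "WT_A", "F_break"),
    ("lambda_procapsid", "lambda_expanded_nogpD", "k"),
    ("lambda_expanded_nogpD", "lambda_expanded_gpD", "k"),
    ("lambda_expanded_nogpD", "lambda_expanded_gpD", "F_break"),
]


@dataclass
class RunConfig:
    """Configuration of one batch run.

    ``calibration`` is the default calibration record; individual curves
    may override it with a ``calibration`` metadata key naming a record
    file relative to the manifest directory (needed when groups were
    measured with different cantilevers).
    """

    manifest: Path
    calibration: Path | None
    output_dir: Path
    geometry: Path | None = None
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    comparisons: list[tuple[str, str, str]] = field(
        default_factory=lambda: list(DEFAULT_COMPARISONS)
    )
    seed: int = 0
    log_level: str = "INFO"

    def config_hash(self) -> str:
        payload = {
            "analysis": dataclasses.asdict(self.analysis),
            "comparisons": self.comparisons,
            "seed": self.seed,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class RunResult:
    curves: pd.DataFrame
    summaries: pd.DataFrame
    comparisons: pd.DataFrame
    n_failed: int
    exit_code: int  # 0 ok, 1 partial failures, 2 fatal


def _per_curve_table(
    entries: list[tuple[Path, str]],
    default_calibration: CalibrationResult | None,
    config: AnalysisConfig,
    base_dir: Path,
) -> pd.DataFrame:
    rows = []
    cal_cache: dict[str, CalibrationResult] = {}
    for path, group in entries:
        row: dict = {"file": str(path.name), "group": group}
        try:
            curve = cio.read_force_curve(path)
            calibration = default_calibration
            cal_ref = curve.metadata.get("calibration")
            if isinstance(cal_ref, str) and cal_ref:
                if cal_ref not in cal_cache:
                    cal_cache[cal_ref] = cio.read_calibration(base_dir / cal_ref)
                calibration = cal_cache[cal_ref]
            result = analyze_curve(curve, calibration, config)
            row.update(
                contact_z0_nm=result.contact_z0,
                k_N_per_m=result.spring_constant_k,
                fit_r_squared=result.fit_r_squared,
                f_break_nN=result.breaking_force,
                indentation_at_break_nm=result.indentation_at_break,
                flags=";".join(result.flags),
                ok=True,
            )
        except (CapsidMechError, ValueError, OSError) as exc:
            logger.warning("curve %s failed: %s", path.name, exc)
            row.update(flags=f"error:{type(exc).__name__}", error=str(exc), ok=False)
        rows.append(row)
    return pd.DataFrame(rows)


def _summaries(
    curves: pd.DataFrame, registry: dict[str, ShellGeometry]
) -> tuple[pd.DataFrame, dict[str, dict[str, EnsembleSummary]]]:
    rows = []
    summaries: dict[str, dict[str, EnsembleSummary]] = {}
    ok = curves[curves["ok"] == True]  # noqa: E712
    # curves whose elastic fit failed the r^2 gate do not contribute:
    # a non-linear loading curve means the linear-elastic model is wrong
    ok = ok[~ok["flags"].str.contains("poor_fit", na=False)]
    for group, sub in ok.groupby("group", sort=True):
        k_values = sub["k_N_per_m"].dropna().to_numpy(float)
        f_values = sub["f_break_nN"].dropna().to_numpy(float)
        entry: dict[str, EnsembleSummary] = {}
        row: dict = {"group": group, "n": int(len(sub))}
        try:
            entry["k"] = summarize(k_values, group)
            row.update(
                k_N_per_m=entry["k"].mean,
                k_sd=entry["k"].sd,
                k_se=entry["k"].standard_error,
            )
        except CapsidMechError:
            pass
        try:
            entry["F_break"] = summarize(f_values, group)
            row.update(
                f_break_nN=entry["F_break"].mean,
                f_break_sd=entry["F_break"].sd,
                f_break_se=entry["F_break"].standard_error,
            )
        except CapsidMechError:
            pass
        geom = registry.get(str(group))
        if "k" in entry and "F_break" in entry:
            delta = indentation_at_break(entry["F_break"].mean, entry["k"].mean)
            row["indentation_nm"] = delta
            if geom is not None:
                row["E_GPa"] = youngs_modulus(entry["k"].mean, geom)
                row["percent_indentation"] = percent_indentation(delta, geom)
                row["geometry"] = (
                    f"R_outer={geom.outer_radius}nm,h={geom.wall_thickness_h}nm,"
                    f"{geom.radius_convention}"
                )
        summaries[str(group)] = entry
        rows.append(row)
    return pd.DataFrame(rows), summaries


def _comparisons(
    summaries: dict[str, dict[str, EnsembleSummary]],
    pairs: list[tuple[str, str, str]],
) -> pd.DataFrame:
    rows = []
    for group_a, group_b, metric in pairs:
        sa = summaries.get(group_a, {}).get(metric)
        sb = summaries.get(group_b, {}).get(metric)
        if sa is None or sb is None:
            logger.warning(
                "comparison %s vs %s (%s) skipped: missing summary",
                group_a, group_b, metric,
            )
            continue
        c: GroupComparison = compare(sa, sb, metric)
        rows.append(
            {
                "group_a": group_a,
                "group_b": group_b,
                "metric": metric,
                "value_a": c.value_a,
                "value_b": c.value_b,
                "percent_change": c.percent_change,
                "fold_ratio": c.fold_ratio,
                "percent_change_display": c.percent_change_display,
                "direction": c.direction,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full batch workflow and write the report bundle.

    Writes ``curves.csv`` (per-curve results), ``summary.csv`` and
    ``summary.json`` (per-group Gaussian summaries with derived thin-shell
    columns), ``comparisons.csv``, and ``run_log.json``.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    entries = cio.read_manifest(config.manifest)
    if not entries:
        raise CapsidMechError("no curves listed in manifest")
    calibration = (
        cio.read_calibration(config.calibration)
        if config.calibration is not None
        else None
    )
    registry = (
        load_geometry_registry(config.geometry)
        if config.geometry is not None
        else default_geometry_registry()
    )

    curves = _per_curve_table(
        entries, calibration, config.analysis, Path(config.manifest).parent
    )
    n_ok = int(curves["ok"].sum())
    n_failed = len(curves) - n_ok
    if n_ok == 0:
        raise CapsidMechError("no curves could be analyzed")

    summary_df, summaries = _summaries(curves, registry)
    comparison_df = _comparisons(summaries, config.comparisons)

    curves.to_csv(out / "curves.csv", index=False, float_format="%.8g")
    summary_df.to_csv(out / "summary.csv", index=False, float_format="%.8g")
    summary_df.to_json(out / "summary.json", orient="records", indent=2)
    comparison_df.to_csv(out / "comparisons.csv", index=False, float_format="%.8g")
    (out / "run_log.json").write_text(
        json.dumps(
            {
                "config_hash": config.config_hash(),
                "seed": config.seed,
                "n_curves": int(len(curves)),
                "n_failed": n_failed,
                "calibration_kc_N_per_m": (
                    calibration.stiffness_kc if calibration is not None else None
                ),
                "calibration_method": (
                    calibration.method if calibration is not None else "per-curve"
                ),
                "numpy_version": np.__version__,
                "pandas_version": pd.__version__,
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    exit_code = 0 if n_failed == 0 else 1
    return RunResult(curves, summary_df, comparison_df, n_failed, exit_code)
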