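"""Text-format I/O: force curves, thermal traces, manifests, calibration
records.

Force-curve files are TSV with ``#``-prefixed ``key=value`` header lines
carrying metadata and two data columns, ``z_nm`` and ``force_nN``.  A
``deflection_nm`` column may replace ``force_nN`` when the header carries
``stiffness_kc`` (and optionally ``deflection_sensitivity``); the force is
then reconstructed as ``k_c * sensitivity * deflection``.

Thermal traces are TSV with ``time_s`` and ``deflection_nm`` columns; the
sampling rate is inferred from the time column and the temperature read
from a ``temperature_K`` header key.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .calibration import CalibrationResult, ThermalTrace
from .constants import ROOM_TEMPERATURE_K
from .curves import ForceCurve

__all__ = [
    "write_force_curve",
    "read_force_curve",
    "write_thermal_trace",
    "read_thermal_trace",
    "write_calibration",
    "read_calibration",
    "write_manifest",
    "read_manifest",
]


def _format_meta_value(value: Any) -> str:
    if isinstance(value, (bool, np.bool_)):
        return "true" if value else "false"
    if isinstance(value, (float, np.floating)):
        return repr(float(value))
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    return str(value)


def _parse_meta_value(raw: str) -> Any:
    if raw == "true":
        return True
    if raw == "false":
        return False
    for cast in (int, float):
        try:
            return cast(raw)
        except ValueError:
            continue
    return raw


def _read_header(path: Path) -> dict[str, Any]:
    meta: dict[str, Any] = {}
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, raw = body.partition("=")
                meta[key.strip()] = _parse_meta_value(raw.strip())
    return meta


def write_force_curve(path: str | Path, curve: ForceCurve) -> None:
    path = Path(path)
    lines = ["# capsidmech force curve; units: z in nm, force in nN"]
    for key in sorted(curve.metadata):
        lines.append(f"# {key}={_format_meta_value(curve.metadata[key])}")
    lines.append("z_nm\tforce_nN")
    for zi, fi in zip(curve.z, curve.force):
        lines.append(f"{zi:.6f}\t{fi:.8f}")
    path.write_text("\n".join(lines) + "\n")


def read_force_curve(path: str | Path) -> ForceCurve:
    path = Path(path)
    meta = _read_header(path)
    table = pd.read_csv(path, sep="\t", comment="#")
    if "z_nm" not in table.columns:
        raise ValueError(f"{path}: missing mandatory column z_nm")
    z = table["z_nm"].to_numpy(float)
    if "force_nN" in table.columns:
        force = table["force_nN"].to_numpy(float)
    elif "deflection_nm" in table.columns:
        kc = meta.get("stiffness_kc", meta.get("true_kc"))
        if kc is None:
            raise ValueError(
                f"{path}: deflection_nm column requires stiffness_kc in the header"
            )
        sensitivity = meta.get("deflection_sensitivity", 1.0)
        force = float(kc) * float(sensitivity) * table["deflection_nm"].to_numpy(float)
    else:
        raise ValueError(f"{path}: need a force_nN or deflection_nm column")
    return ForceCurve(z, force, meta)


def write_thermal_trace(path: str | Path, trace: ThermalTrace) -> None:
    path = Path(path)
    lines = ["# capsidmech thermal deflection trace"]
    meta = dict(trace.metadata)
    meta["temperature_K"] = trace.temperature
    meta["sampling_rate_hz"] = trace.sampling_rate
    for key in sorted(meta):
        lines.append(f"# {key}={_format_meta_value(meta[key])}")
    lines.append("time_s\tdeflection_nm")
    t = np.arange(trace.n_samples) / trace.sampling_rate
    for ti, xi in zip(t, trace.deflection):
        lines.append(f"{ti:.9f}\t{xi:.8f}")
    path.write_text("\n".join(lines) + "\n")


def read_thermal_trace(path: str | Path) -> ThermalTrace:
    path = Path(path)
    meta = _read_header(path)
    table = pd.read_csv(path, sep="\t", comment="#")
    deflection = table["deflection_nm"].to_numpy(float)
    if "sampling_rate_hz" in meta:
        rate = float(meta["sampling_rate_hz"])
    else:
        dt = np.median(np.diff(table["time_s"].to_numpy(float)))
        rate = 1.0 / dt
    temperature = float(meta.get("temperature_K", ROOM_TEMPERATURE_K))
    return ThermalTrace(deflection, rate, temperature, meta)


def write_calibration(path: str | Path, calibration: CalibrationResult) -> None:
    Path(path).write_text(
        json.dumps(dataclasses.asdict(calibration), indent=2, sort_keys=True) + "\n"
    )


def read_calibration(path: str | Path) -> CalibrationResult:
    return CalibrationResult(**json.loads(Path(path).read_text()))


def write_manifest(path: str | Path, entries: list[tuple[str, str]]) -> None:
    """Write a curve manifest: TSV of (file, group) rows, paths relative
    to the manifest's directory."""
    lines = ["file\tgroup"]
    for file, group in entries:
        lines.append(f"{file}\t{group}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_manifest(path: str | Path) -> list[tuple[Path, str]]:
    """Read a manifest; returned paths are resolved against its directory."""
    path = Path(path)
    table = pd.read_csv(path, sep="\t", comment="#")
    if not {"file", "group"}.issubset(table.columns):
        raise ValueError(f"{path}: manifest needs 'file' and 'group' columns")
    base = path.parent
    return [(base / row.file, str(row.group)) for row in table.itertuples()]
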