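"""Readers and writers for the package's interchange formats.

Tabular data travels as CSV with a JSON sidecar carrying metadata and a
schema tag; images as multi-page TIFF (one file per channel). Conventions
are pinned here once: frame indices 0-based, times in seconds, piezo
positions in um, deflections in nm, spring constants in N/m, moduli in kPa,
currents in pA, capacitances in pF. Floats are serialized with 17
significant digits so round trips are exact.

Schema tags look like ``calcimech.traces/1``; readers reject a different
major version.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import tifffile

from .imaging import SegmentationResult
from .indentation import ForceCurve
from .trace_metrics import TraceSet

__all__ = [
    "read_trace_csv",
    "write_trace_csv",
    "read_force_curve",
    "write_force_curve",
    "read_ephys_csv",
    "write_stack_tiffs",
    "read_stack_tiff",
    "write_label_tiff",
]

_FLOAT_FMT = "%.17g"
TRACE_SCHEMA = "calcimech.traces/1"
CURVE_SCHEMA = "calcimech.force_curve/1"


def _check_schema(meta: dict, expected: str, path: Path) -> None:
    tag = meta.get("schema", expected)
    name, _, major = tag.partition("/")
    exp_name, _, exp_major = expected.partition("/")
    if name != exp_name or major != exp_major:
        raise ValueError(
            f"{path}: schema {tag!r} not supported (expected {expected!r})"
        )


def write_trace_csv(
    traces: TraceSet, csv_path: Union[str, Path], meta_path: Optional[Path] = None
) -> None:
    """Frames x cells CSV (header row of cell ids) + JSON sidecar."""
    csv_path = Path(csv_path)
    meta_path = Path(meta_path) if meta_path else csv_path.with_suffix(".json")
    df = pd.DataFrame(traces.values, columns=list(traces.cell_ids))
    df.to_csv(csv_path, index=False, float_format=_FLOAT_FMT)
    meta = {
        "schema": TRACE_SCHEMA,
        "dt_s": traces.dt,
        "stim_frame": traces.stim_frame,
        "units": "ratio",
    }
    meta_path.write_text(json.dumps(meta, indent=2) + "\n")


def read_trace_csv(
    csv_path: Union[str, Path], meta_path: Optional[Union[str, Path]] = None
) -> TraceSet:
    """Read a trace table with its sidecar; rejects NaNs with their location."""
    csv_path = Path(csv_path)
    meta_path = Path(meta_path) if meta_path else csv_path.with_suffix(".json")
    if not meta_path.exists():
        raise FileNotFoundError(f"missing sidecar JSON: {meta_path}")
    meta = json.loads(meta_path.read_text())
    _check_schema(meta, TRACE_SCHEMA, meta_path)
    for key in ("dt_s", "stim_frame"):
        if key not in meta:
            raise ValueError(f"{meta_path}: sidecar is missing required field {key!r}")
    df = pd.read_csv(csv_path)
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        r, c = np.argwhere(np.isnan(values))[0]
        raise ValueError(
            f"{csv_path}: non-numeric value at row {r}, column {df.columns[c]!r}"
        )
    return TraceSet(
        values=values,
        stim_frame=int(meta["stim_frame"]),
        dt=float(meta["dt_s"]),
        cell_ids=tuple(df.columns),
    )


def write_force_curve(
    curve: ForceCurve, csv_path: Union[str, Path], meta_path: Optional[Path] = None
) -> None:
    """CSV columns ``z_um, deflection_nm`` + probe-metadata sidecar."""
    csv_path = Path(csv_path)
    meta_path = Path(meta_path) if meta_path else csv_path.with_suffix(".json")
    df = pd.DataFrame({"z_um": curve.z_um, "deflection_nm": curve.deflection_nm})
    df.to_csv(csv_path, index=False, float_format=_FLOAT_FMT)
    meta = {
        "schema": CURVE_SCHEMA,
        "k_N_per_m": curve.k_N_per_m,
        "R_um": curve.R_um,
        "nu": curve.nu,
    }
    meta_path.write_text(json.dumps(meta, indent=2) + "\n")


def read_force_curve(
    csv_path: Union[str, Path],
    meta_path: Optional[Union[str, Path]] = None,
    strict: bool = True,
) -> ForceCurve:
    """Read a force curve; the column headers are a bit-exact unit contract.

    Non-monotone z is rejected when ``strict`` (the default) and otherwise
    sorted ascending with a warning.
    """
    import warnings

    csv_path = Path(csv_path)
    meta_path = Path(meta_path) if meta_path else csv_path.with_suffix(".json")
    if not meta_path.exists():
        raise FileNotFoundError(f"missing probe sidecar JSON: {meta_path}")
    meta = json.loads(meta_path.read_text())
    _check_schema(meta, CURVE_SCHEMA, meta_path)
    for key in ("k_N_per_m", "R_um"):
        if key not in meta:
            raise ValueError(f"{meta_path}: sidecar is missing required field {key!r}")
    df = pd.read_csv(csv_path)
    expected = ["z_um", "deflection_nm"]
    if list(df.columns[:2]) != expected:
        raise ValueError(
            f"{csv_path}: columns {list(df.columns[:2])} != {expected}; headers "
            "carry the units (um, nm) — convert the data, not the header"
        )
    z = df["z_um"].to_numpy(dtype=float)
    d = df["deflection_nm"].to_numpy(dtype=float)
    if np.any(np.diff(z) <= 0):
        if strict:
            raise ValueError(f"{csv_path}: z is not strictly increasing")
        warnings.warn(f"{csv_path}: z not monotone; sorting ascending")
        order = np.argsort(z, kind="stable")
        z, d = z[order], d[order]
        keep = np.concatenate([[True], np.diff(z) > 0])
        z, d = z[keep], d[keep]
    return ForceCurve(
        z_um=z,
        deflection_nm=d,
        k_N_per_m=float(meta["k_N_per_m"]),
        R_um=float(meta["R_um"]),
        nu=float(meta.get("nu", 0.5)),
    )


def read_ephys_csv(path: Union[str, Path]) -> pd.DataFrame:
    """Per-cell ephys table: either raw (I_pA, C_pF) or pre-normalized
    (density_pA_pF), keyed by cell_id / line / condition / V_mV."""
    df = pd.read_csv(path)
    required = {"cell_id", "line", "condition", "V_mV"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if "density_pA_pF" not in df.columns:
        if not {"I_pA", "C_pF"} <= set(df.columns):
            raise ValueError(
                f"{path}: need either density_pA_pF or both I_pA and C_pF"
            )
        if (df["C_pF"] <= 0).any():
            raise ValueError(f"{path}: non-positive capacitance")
        df = df.assign(density_pA_pF=df["I_pA"] / df["C_pF"])
    return df


def write_stack_tiffs(
    green: np.ndarray, red: np.ndarray, out_dir: Union[str, Path],
    prefix: str = "stack",
) -> tuple[Path, Path]:
    """One multi-page float32 TIFF per channel."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gpath = out_dir / f"{prefix}_green.tif"
    rpath = out_dir / f"{prefix}_red.tif"
    tifffile.imwrite(gpath, np.asarray(green, dtype=np.float32))
    tifffile.imwrite(rpath, np.asarray(red, dtype=np.float32))
    return gpath, rpath


def read_stack_tiff(path: Union[str, Path]) -> np.ndarray:
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise ValueError(f"{path}: expected a (T, Y, X) stack, got {stack.shape}")
    return np.asarray(stack, dtype=float)


def write_label_tiff(seg: SegmentationResult, path: Union[str, Path]) -> None:
    """Label image as 16-bit TIFF (sufficient for <= 65535 cells)."""
    if seg.labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels cannot be stored as 16-bit")
    tifffile.imwrite(Path(path), seg.labels.astype(np.uint16))
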