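"""End-to-end runs driven by a single validated configuration.

A :class:`RunConfig` selects stages and carries every stage's parameters
(defaults come from the stage modules). Each run writes its outputs, a
resolved copy of the configuration, and a JSON run report (package version,
seed, per-stage counts and failures) into the output directory, so any
output file is reproducible from (config, seed) alone.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .ephys import EphysGroup, delta_current, unitary_current
from .imaging import extract_traces, ratio_stack, segment_cells
from .indentation import analyze_map, make_grid
from .io import (
    _FLOAT_FMT,
    write_label_tiff,
    write_stack_tiffs,
    write_trace_csv,
)
from .synth import (
    CurveSynthConfig,
    PatchSynthConfig,
    StackSynthConfig,
    TraceSynthConfig,
    gen_ephys_groups,
    gen_force_curve,
    gen_image_stack,
    gen_patch_trace,
    gen_traces,
)
from .trace_metrics import analyze_traces, summarize_traces

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


class StackGridParams(BaseModel):
    """Grid layout for the synthetic imaging stage."""

    model_config = ConfigDict(extra="forbid")

    n_cells: int = Field(default=25, ge=1)
    radius_px: float = Field(default=7.0, gt=0.0)
    spacing_px: float = Field(default=20.0, gt=0.0)
    noise_sigma: float = Field(default=10.0, ge=0.0)
    min_area_px: int = Field(default=100, ge=1)


class IndentParams(BaseModel):
    """Synthetic stiffness-map stage: one curve per grid point."""

    model_config = ConfigDict(extra="forbid")

    E_true_kPa: float = Field(default=15.0, gt=0.0)
    side_um: float = Field(default=2.0, gt=0.0)
    spacing_um: float = Field(default=0.5, gt=0.0)
    noise_sigma_nN: float = Field(default=1.0, ge=0.0)


class EphysParams(BaseModel):
    """Synthetic group-table stage: basal vs inhibited current densities."""

    model_config = ConfigDict(extra="forbid")

    label: str = "demo"
    voltage_mV: float = -70.0
    basal_mean: float = 50.13
    inhibited_mean: float = 13.8
    sd: float = Field(default=5.0, ge=0.0)
    n_per_group: int = Field(default=20, ge=1)


class RunConfig(BaseModel):
    """Stage selection plus per-stage parameter blocks.

    Unknown keys anywhere in the document are rejected.
    """

    model_config = ConfigDict(extra="forbid")

    seed: int = Field(default=0, ge=0, lt=2**31)
    out_dir: Path
    stages: tuple[str, ...] = ("traces",)
    traces: TraceSynthConfig = TraceSynthConfig(n_cells=50)
    stack: StackGridParams = StackGridParams()
    indent: IndentParams = IndentParams()
    ephys: EphysParams = EphysParams()
    patch: PatchSynthConfig = PatchSynthConfig()
    log_level: str = "INFO"


_KNOWN_STAGES = ("traces", "imaging", "indent", "ephys")


def _write_results_csv(results, path: Path) -> None:
    rows = [
        {
            "cell_id": r.cell_id,
            "baseline_mean": r.baseline.mean,
            "baseline_sd": r.baseline.sd,
            "threshold": r.baseline.threshold,
            "responder": r.responder,
            "onset_time_s": "" if r.onset_time_s is None else r.onset_time_s,
            "auc": r.auc,
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)


def _stage_traces(cfg: RunConfig, out: Path) -> dict:
    trace_cfg = cfg.traces.model_copy(update={"seed": cfg.seed})
    traces, truth = gen_traces(trace_cfg)
    write_trace_csv(traces, out / "traces.csv")
    results = analyze_traces(traces)
    _write_results_csv(results, out / "trace_results.csv")
    summary = summarize_traces(results)
    summary["true_responder_fraction"] = float(truth.responder_mask.mean())
    (out / "trace_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return {"n_cells": traces.n_cells, "n_responders": summary["n_responders"]}


def _stage_imaging(cfg: RunConfig, out: Path) -> dict:
    trace_cfg = cfg.traces.model_copy(
        update={"seed": cfg.seed + 1, "n_cells": cfg.stack.n_cells}
    )
    stack_cfg = StackSynthConfig.grid(
        n_cells=cfg.stack.n_cells,
        radius=cfg.stack.radius_px,
        spacing=cfg.stack.spacing_px,
        noise_sigma=cfg.stack.noise_sigma,
        trace=trace_cfg,
    )
    pair, truth = gen_image_stack(stack_cfg)
    write_stack_tiffs(pair.green, pair.red, out, prefix="stack")
    seg = segment_cells(pair.red, min_area=cfg.stack.min_area_px)
    write_label_tiff(seg, out / "labels.tif")
    ratio = ratio_stack(pair)
    traces = extract_traces(ratio, seg, trace_cfg.n_pre, trace_cfg.dt)
    write_trace_csv(traces, out / "extracted_traces.csv")
    results = analyze_traces(traces)
    _write_results_csv(results, out / "imaging_results.csv")
    summary = summarize_traces(results)
    summary["n_labels"] = seg.n_cells
    summary["n_true_cells"] = int(truth.label_image.max())
    (out / "imaging_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return {"n_labels": seg.n_cells, "n_cells_traced": traces.n_cells}


def _stage_indent(cfg: RunConfig, out: Path) -> dict:
    points = make_grid(cfg.indent.side_um, cfg.indent.spacing_um)
    curves = []
    for i in range(points.shape[0]):
        curve_cfg = CurveSynthConfig(
            E_true_kPa=cfg.indent.E_true_kPa,
            noise_sigma_nN=cfg.indent.noise_sigma_nN,
            seed=cfg.seed + 1000 + i,
        )
        curves.append(gen_force_curve(curve_cfg)[0])
    imap = analyze_map(curves, points)
    rows = []
    for i, (fit, fail) in enumerate(zip(imap.fits, imap.failures)):
        rows.append(
            {
                "curve": i,
                "x_um": points[i, 0],
                "y_um": points[i, 1],
                "z0_um": "" if fit is None else fit.z0_um,
                "E_kPa": "" if fit is None else fit.E_kPa,
                "rms_nN": "" if fit is None else fit.residual_rms_nN,
                "status": "ok" if fail is None else fail,
            }
        )
    pd.DataFrame(rows).to_csv(out / "fits.csv", index=False, float_format=_FLOAT_FMT)
    summary = {
        "n_curves": len(curves),
        "n_failures": imap.n_failures,
        "mean_E_kPa": imap.mean_E_kPa,
        "median_E_kPa": imap.median_E_kPa,
    }
    (out / "indent_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return summary


def _stage_ephys(cfg: RunConfig, out: Path) -> dict:
    p = cfg.ephys
    table, truth = gen_ephys_groups(
        [
            ("basal", p.basal_mean, p.sd, p.n_per_group),
            ("inhibited", p.inhibited_mean, p.sd, p.n_per_group),
        ],
        seed=cfg.seed + 2000,
    )
    table.to_csv(out / "ephys_cells.csv", index=False, float_format=_FLOAT_FMT)
    basal = EphysGroup(p.label, p.voltage_mV,
                       table.loc[table.group == "basal", "density_pA_pF"].to_numpy())
    inhibited = EphysGroup(
        p.label, p.voltage_mV,
        table.loc[table.group == "inhibited", "density_pA_pF"].to_numpy(),
    )
    delta = delta_current(basal, inhibited)
    patch_cfg = cfg.patch.model_copy(update={"seed": cfg.seed + 3000})
    trace, patch_truth = gen_patch_trace(patch_cfg)
    est = unitary_current(trace)
    summary = {
        "delta_mean_pA_pF": delta.mean,
        "delta_sem_pA_pF": delta.sem,
        "inhibited_mean_pA_pF": delta.inhibited_mean,
        "unitary_current_pA": est.i_u_pA,
        "unitary_detected": est.detected,
        "true_unitary_pA": abs(patch_truth.i_u_pA),
    }
    (out / "ephys_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return summary


_STAGE_FNS = {
    "traces": _stage_traces,
    "imaging": _stage_imaging,
    "indent": _stage_indent,
    "ephys": _stage_ephys,
}


def run_pipeline(config: Union[RunConfig, dict]) -> dict:
    """Execute the configured stages; return (and persist) the run report.

    Any stage failure halts the run with the stage named; outputs of stages
    already completed are kept on disk.
    """
    if isinstance(config, dict):
        config = RunConfig.model_validate(config)
    unknown = [s for s in config.stages if s not in _KNOWN_STAGES]
    if unknown:
        raise ValueError(f"unknown stages {unknown}; choose from {_KNOWN_STAGES}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    (out / "resolved_config.json").write_text(
        config.model_dump_json(indent=2) + "\n"
    )
    report: dict = {
        "calcimech_version": __version__,
        "seed": config.seed,
        "stages": {},
    }
    for stage in config.stages:
        logger.info("running stage %s", stage)
        try:
            report["stages"][stage] = _STAGE_FNS[stage](config, out)
        except Exception as err:
            report["stages"][stage] = {"error": str(err)}
            (out / "report.json").write_text(json.dumps(report, indent=2) + "\n")
            raise RuntimeError(f"stage {stage!r} failed: {err}") from err
    (out / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    return report
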