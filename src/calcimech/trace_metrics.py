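"""Per-cell calcium-transient statistics for ratiometric fluorescence traces.

A trace is the Fluo-4 / Fura Red intensity ratio of one cell sampled at a
fixed frame interval, with a known number of pre-stimulus (baseline) frames.
The quantities computed here mirror a common confocal Ca2+-imaging workflow:

* baseline mean and SD over the pre-stimulus frames;
* responder classification — a post-stimulus frame "responds" when its value
  strictly exceeds baseline mean + k*SD (k = 3 by default), and a cell is a
  responder when at least a fraction ``frac`` (default 0.25) of its
  post-stimulus frames respond;
* response onset — time of the first post-stimulus frame that starts a run of
  at least two consecutive responding frames, measured from stimulus addition
  (the first post-stimulus frame is at time ``dt``, not 0);
* area under the curve of the baseline-subtracted trace, counting only
  above-baseline peaks whose height is at least 10 % of the trace's
  min-to-max range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "TraceSet",
    "BaselineStats",
    "AUCParams",
    "CellTraceResult",
    "baseline_stats",
    "classify_responder",
    "response_time",
    "auc",
    "analyze_traces",
    "summarize_traces",
]


@dataclass(frozen=True)
class TraceSet:
    """Ratiometric fluorescence for a cohort of cells.

    values
        Array of shape (n_frames, n_cells), dimensionless ratio.
    stim_frame
        0-based index of the first post-stimulus frame. Frames
        ``[0, stim_frame)`` are baseline.
    dt
        Seconds per frame.
    cell_ids
        One identifier per column.
    """

    values: np.ndarray
    stim_frame: int
    dt: float
    cell_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D (n_frames, n_cells) array")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite trace value at frame {bad[0]}, cell column {bad[1]}"
            )
        if not (1 <= self.stim_frame < values.shape[0]):
            raise ValueError(
                f"stim_frame {self.stim_frame} outside [1, {values.shape[0]})"
            )
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        ids = tuple(self.cell_ids) or tuple(
            f"cell{i:04d}" for i in range(values.shape[1])
        )
        if len(ids) != values.shape[1]:
            raise ValueError("cell_ids length must match the number of columns")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "cell_ids", ids)

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @property
    def n_post(self) -> int:
        return self.n_frames - self.stim_frame


@dataclass(frozen=True)
class BaselineStats:
    """Baseline mean/SD and the derived responding-frame threshold."""

    mean: float
    sd: float
    k_sigma: float = 3.0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("baseline SD cannot be negative")

    @property
    def threshold(self) -> float:
        return self.mean + self.k_sigma * self.sd


@dataclass(frozen=True)
class AUCParams:
    """Parameters of the peak-filtered area-under-curve statistic.

    baseline_y
        Explicit baseline to subtract before integrating; ``None`` (default)
        subtracts the cell's own baseline mean, which makes "baseline of
        Y = 0" hold by construction.
    min_peak_frac
        Peaks whose maximum height is below this fraction of the trace's
        min-to-max range are ignored.
    full_trace
        Integrate the whole trace instead of the post-stimulus window.
    """

    baseline_y: Optional[float] = None
    min_peak_frac: float = 0.10
    full_trace: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.min_peak_frac < 1:
            raise ValueError("min_peak_frac must lie in [0, 1)")


@dataclass(frozen=True)
class CellTraceResult:
    cell_id: str
    baseline: BaselineStats
    responder: bool
    responding_frame_mask: np.ndarray = field(repr=False)
    onset_time_s: Optional[float]
    auc: float

    def __post_init__(self) -> None:
        if self.onset_time_s is not None and not self.responder:
            raise ValueError("onset time present for a non-responder")
        if self.auc < 0:
            raise ValueError("AUC cannot be negative")


def baseline_stats(
    trace: np.ndarray, stim_frame: int, k_sigma: float = 3.0
) -> BaselineStats:
    """Mean and sample SD (n-1) over the pre-stimulus frames.

    Requires at least two baseline frames so the SD is defined.
    """
    trace = np.asarray(trace, dtype=float)
    if stim_frame < 2:
        raise ValueError("need at least 2 baseline frames to estimate the SD")
    base = trace[:stim_frame]
    return BaselineStats(
        mean=float(base.mean()), sd=float(base.std(ddof=1)), k_sigma=k_sigma
    )


def classify_responder(
    trace: np.ndarray,
    baseline: BaselineStats,
    stim_frame: int,
    frac: float = 0.25,
) -> tuple[bool, np.ndarray]:
    """Responder flag and per-frame responding mask for the post-stimulus window.

    A frame responds when its value strictly exceeds ``baseline.threshold``;
    the cell is a responder when the responding fraction of post-stimulus
    frames is at least ``frac`` (boundary inclusive).
    """
    trace = np.asarray(trace, dtype=float)
    post = trace[stim_frame:]
    if post.size < 1:
        raise ValueError("no post-stimulus frames")
    mask = post > baseline.threshold
    return bool(mask.mean() >= frac), mask


def response_time(
    trace: np.ndarray,
    baseline: BaselineStats,
    stim_frame: int,
    dt: float,
    frac: float = 0.25,
) -> Optional[float]:
    """Onset of the response, in seconds from stimulus addition.

    The onset frame is the first post-stimulus frame starting a run of at
    least two consecutive supra-threshold frames. The stimulus event sits at
    the boundary before ``stim_frame``, so the first post-stimulus frame has
    elapsed time ``dt``. Returns ``None`` for non-responders and for
    responders with no two-consecutive run (an anomaly at realistic
    responding fractions).
    """
    responder, mask = classify_responder(trace, baseline, stim_frame, frac)
    if not responder:
        return None
    pairs = mask[:-1] & mask[1:]
    idx = np.flatnonzero(pairs)
    if idx.size == 0:
        return None
    return float((idx[0] + 1) * dt)


def _positive_run_area(y: np.ndarray, dt: float, start: int, stop: int) -> float:
    """Trapezoidal area of one above-zero run y[start:stop], with the entry and
    exit zero-crossings interpolated linearly onto the time axis."""
    area = float(np.trapezoid(y[start:stop], dx=dt)) if stop - start > 1 else 0.0
    # entry crossing between start-1 and start
    if start > 0:
        y0, y1 = y[start - 1], y[start]
        # y0 <= 0 < y1; triangle from the crossing to the first positive sample
        width = dt * y1 / (y1 - y0)
        area += 0.5 * width * y1
    # exit crossing between stop-1 and stop
    if stop < y.size:
        y0, y1 = y[stop - 1], y[stop]
        width = dt * y0 / (y0 - y1)
        area += 0.5 * width * y0
    return area


def auc(
    trace: np.ndarray,
    baseline: BaselineStats,
    stim_frame: int,
    dt: float,
    params: AUCParams = AUCParams(),
) -> float:
    """Peak-filtered area under the baseline-subtracted trace (ratio*seconds).

    Works on ``y = trace - baseline`` over the post-stimulus window (or the
    whole trace when ``params.full_trace``). Peaks are maximal runs with
    y > 0; a peak is kept when its maximum height is at least
    ``min_peak_frac`` times the min-to-max range of y over the analyzed
    window. The area is the sum of trapezoidal integrals of the kept peaks'
    positive parts, with zero-crossings interpolated linearly.
    """
    trace = np.asarray(trace, dtype=float)
    base = baseline.mean if params.baseline_y is None else params.baseline_y
    window = trace if params.full_trace else trace[stim_frame:]
    y = window - base
    if y.size == 0 or not np.any(y > 0):
        return 0.0
    y_range = float(y.max() - y.min())
    cutoff = params.min_peak_frac * y_range

    pos = y > 0
    # run boundaries of the positive mask
    edges = np.flatnonzero(np.diff(pos.astype(np.int8)))
    starts = [0] if pos[0] else []
    starts += [e + 1 for e in edges if pos[e + 1]]
    stops = [e + 1 for e in edges if pos[e]]
    if pos[-1]:
        stops.append(y.size)

    total = 0.0
    for start, stop in zip(starts, stops):
        height = float(y[start:stop].max())
        if height < cutoff:
            continue
        total += _positive_run_area(y, dt, start, stop)
    return max(total, 0.0)


def analyze_traces(
    traces: TraceSet,
    k_sigma: float = 3.0,
    frac: float = 0.25,
    auc_params: AUCParams = AUCParams(),
) -> list[CellTraceResult]:
    """Run the full per-cell analysis over a trace set."""
    results = []
    for j, cid in enumerate(traces.cell_ids):
        col = traces.values[:, j]
        base = baseline_stats(col, traces.stim_frame, k_sigma)
        responder, mask = classify_responder(col, base, traces.stim_frame, frac)
        onset = (
            response_time(col, base, traces.stim_frame, traces.dt, frac)
            if responder
            else None
        )
        area = auc(col, base, traces.stim_frame, traces.dt, auc_params)
        results.append(
            CellTraceResult(
                cell_id=cid,
                baseline=base,
                responder=responder,
                responding_frame_mask=mask,
                onset_time_s=onset,
                auc=area,
            )
        )
    return results


def _mean_sem(values: np.ndarray) -> tuple[float, Optional[float]]:
    mean = float(np.mean(values))
    if values.size < 2:
        return mean, None
    return mean, float(np.std(values, ddof=1) / math.sqrt(values.size))


def summarize_traces(results: Sequence[CellTraceResult]) -> dict:
    """Cohort summary: responder count/fraction, AUC mean +/- SEM over all
    cells, onset mean +/- SEM over responders with a measured onset."""
    if not results:
        raise ValueError("no cells to summarize")
    n = len(results)
    responders = [r for r in results if r.responder]
    aucs = np.array([r.auc for r in results])
    auc_mean, auc_sem = _mean_sem(aucs)
    onsets = np.array(
        [r.onset_time_s for r in responders if r.onset_time_s is not None]
    )
    summary = {
        "n_cells": n,
        "n_responders": len(responders),
        "responder_fraction": len(responders) / n,
        "auc_mean": auc_mean,
        "auc_sem": auc_sem,
        "onset_mean_s": None,
        "onset_sem_s": None,
        "onset_n": int(onsets.size),
    }
    if onsets.size:
        summary["onset_mean_s"], summary["onset_sem_s"] = _mean_sem(onsets)
    return summary
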