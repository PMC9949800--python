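"""Two-channel time-lapse processing: ratioing, segmentation, trace extraction.

Reimplements a standard ImageJ/Fiji workflow for ratiometric calcium imaging
of adhered cells:

1. median-filter both channels frame by frame, then divide green by red
   pixelwise (:func:`ratio_stack`);
2. max-intensity project the red (reference dye) channel over time — the
   reference dye marks every cell whether or not it signals — threshold,
   split touching cells with a distance-transform watershed, and discard
   particles below a minimum area (:func:`segment_cells`);
3. average the ratio inside each cell mask per frame to obtain one trace per
   cell (:func:`extract_traces`).

Cells are assumed stationary over the recording; there is no tracking.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu, threshold_triangle
from skimage.segmentation import watershed

from .trace_metrics import TraceSet

__all__ = [
    "ImageStackPair",
    "RatioStack",
    "SegmentationResult",
    "ratio_stack",
    "segment_cells",
    "extract_traces",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ImageStackPair:
    """Green and red time-lapse stacks of identical (T, Y, X) shape."""

    green: np.ndarray
    red: np.ndarray
    pixel_size_um: Optional[float] = None

    def __post_init__(self) -> None:
        g = np.asarray(self.green, dtype=float)
        r = np.asarray(self.red, dtype=float)
        if g.shape != r.shape or g.ndim != 3:
            raise ValueError("green and red must be (T, Y, X) stacks of equal shape")
        if not (np.all(np.isfinite(g)) and np.all(np.isfinite(r))):
            raise ValueError("stacks must be finite")
        object.__setattr__(self, "green", g)
        object.__setattr__(self, "red", r)


@dataclass(frozen=True)
class RatioStack:
    """Pixelwise green/red ratio with a validity mask (False where red ~ 0)."""

    values: np.ndarray = field(repr=False)
    valid: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class SegmentationResult:
    """Label image (0 = background, labels 1..N by descending area) plus
    per-label area and centroid."""

    labels: np.ndarray = field(repr=False)
    areas_px: np.ndarray
    centroids: np.ndarray

    @property
    def n_cells(self) -> int:
        return int(self.areas_px.size)


def ratio_stack(
    pair: ImageStackPair,
    median_radius: int = 1,
    red_eps_frac: float = 1e-6,
) -> RatioStack:
    """Median-filter both channels per frame, then divide green by red.

    The filter neighborhood is a square of side 2*median_radius + 1. Pixels
    whose filtered red value is at or below ``red_eps_frac`` of the red
    maximum are masked invalid instead of clamped, so downstream cell means
    exclude them; a fully masked frame triggers a warning.
    """
    if median_radius < 0:
        raise ValueError("median_radius must be >= 0")
    size = 2 * median_radius + 1
    if median_radius > 0:
        green = np.stack([ndi.median_filter(f, size=size) for f in pair.green])
        red = np.stack([ndi.median_filter(f, size=size) for f in pair.red])
    else:
        green, red = pair.green, pair.red
    eps = red_eps_frac * float(red.max()) if red.max() > 0 else 0.0
    valid = red > eps
    values = np.zeros_like(green)
    np.divide(green, red, out=values, where=valid)
    for t in np.flatnonzero(~valid.any(axis=(1, 2))):
        warnings.warn(f"frame {t}: red channel entirely below threshold; masked")
    return RatioStack(values=values, valid=valid)


def _threshold(projection: np.ndarray, method: Union[str, float]) -> float:
    if isinstance(method, (int, float)) and not isinstance(method, bool):
        return float(method)
    if method == "otsu":
        return float(threshold_otsu(projection))
    if method == "triangle":
        return float(threshold_triangle(projection))
    raise ValueError(f"unknown threshold method {method!r}")


def segment_cells(
    red_stack: np.ndarray,
    threshold_method: Union[str, float] = "otsu",
    min_area: int = 100,
    seed_min_distance: int = 5,
) -> SegmentationResult:
    """Segment cells from the max projection of the red channel.

    Max-intensity projection over time, global threshold (Otsu by default,
    or "triangle", or an explicit value), then a binary watershed seeded at
    local maxima of the distance transform (minimum seed separation
    ``seed_min_distance`` px) to split touching cells. Components smaller
    than ``min_area`` px are discarded; surviving labels are renumbered
    1..N by descending area, ties broken by centroid (row, col). An empty
    foreground is a valid zero-label result.
    """
    red_stack = np.asarray(red_stack, dtype=float)
    if red_stack.ndim != 3 or red_stack.shape[0] < 1:
        raise ValueError("red stack must be (T, Y, X) with at least one frame")
    projection = red_stack.max(axis=0)
    binary = projection > _threshold(projection, threshold_method)
    empty = SegmentationResult(
        labels=np.zeros(projection.shape, dtype=np.int32),
        areas_px=np.array([], dtype=int),
        centroids=np.empty((0, 2)),
    )
    if not binary.any():
        return empty
    distance = ndi.distance_transform_edt(binary)
    coords = peak_local_max(
        distance,
        min_distance=seed_min_distance,
        labels=binary,
        exclude_border=False,
    )
    if coords.shape[0] == 0:
        return empty
    markers = np.zeros(binary.shape, dtype=np.int32)
    markers[tuple(coords.T)] = np.arange(1, coords.shape[0] + 1)
    raw = watershed(-distance, markers, mask=binary)

    ids, counts = np.unique(raw[raw > 0], return_counts=True)
    keep = ids[counts >= min_area]
    if keep.size == 0:
        return empty
    centroids = np.array(ndi.center_of_mass(binary, raw, keep))
    areas = counts[np.isin(ids, keep)]
    # stable ordering: area descending, then centroid row, then col
    order = np.lexsort((centroids[:, 1], centroids[:, 0], -areas))
    relabel = np.zeros(int(raw.max()) + 1, dtype=np.int32)
    relabel[keep[order]] = np.arange(1, keep.size + 1)
    labels = relabel[raw]
    return SegmentationResult(
        labels=labels,
        areas_px=areas[order].astype(int),
        centroids=centroids[order],
    )


def extract_traces(
    ratio: RatioStack,
    seg: SegmentationResult,
    stim_frame: int,
    dt: float,
) -> TraceSet:
    """Mean valid-pixel ratio inside each cell mask, per frame.

    Cells whose mask has no valid ratio pixel in some frame cannot yield a
    complete trace and are dropped with a logged reason.
    """
    labels = seg.labels
    if ratio.values.shape[1:] != labels.shape:
        raise ValueError("label image does not match the stack's spatial shape")
    n_labels = seg.n_cells
    if n_labels == 0:
        raise ValueError("segmentation contains no cells")
    n_frames = ratio.values.shape[0]
    sums = np.zeros((n_frames, n_labels))
    counts = np.zeros((n_frames, n_labels))
    for t in range(n_frames):
        m = ratio.valid[t] & (labels > 0)
        lab = labels[m]
        sums[t] = np.bincount(lab, weights=ratio.values[t][m],
                              minlength=n_labels + 1)[1:]
        counts[t] = np.bincount(lab, minlength=n_labels + 1)[1:]
    complete = (counts > 0).all(axis=0)
    for j in np.flatnonzero(~complete):
        bad_frame = int(np.argmax(counts[:, j] == 0))
        logger.warning(
            "dropping cell %d: no valid ratio pixels in frame %d", j + 1, bad_frame
        )
    if not complete.any():
        raise ValueError("every cell mask was invalid in at least one frame")
    with np.errstate(invalid="ignore"):
        traces = sums[:, complete] / counts[:, complete]
    ids = tuple(f"cell{j + 1:04d}" for j in np.flatnonzero(complete))
    return TraceSet(values=traces, stim_frame=stim_frame, dt=dt, cell_ids=ids)
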