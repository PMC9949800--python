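"""Tests for the ratio/segment/extract imaging pipeline."""

import numpy as np
import pytest

from calcimech.imaging import (
    ImageStackPair,
    extract_traces,
    ratio_stack,
    segment_cells,
)
from calcimech.synth import StackSynthConfig, TraceSynthConfig, gen_image_stack


def _disk_stack(centers, radius=10.0, shape=(64, 64), n_frames=3, level=100.0):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    img = np.zeros(shape)
    for r, c in centers:
        img[(yy - r) ** 2 + (xx - c) ** 2 <= radius**2] = level
    return np.broadcast_to(img, (n_frames, *shape)).copy()


def test_ratio_constant_factor():
    red = _disk_stack([(32, 32)]) + 1.0
    pair = ImageStackPair(green=2.0 * red, red=red)
    ratio = ratio_stack(pair)
    assert np.allclose(ratio.values[ratio.valid], 2.0)


def test_median_filter_removes_impulse():
    red = np.full((1, 16, 16), 50.0)
    green = red.copy()
    green[0, 8, 8] = 5000.0  # single hot pixel
    ratio = ratio_stack(ImageStackPair(green=green, red=red), median_radius=1)
    assert np.allclose(ratio.values, 1.0)


def test_ratio_masks_zero_red():
    red = np.zeros((1, 8, 8))
    red[0, :4] = 100.0
    green = np.full_like(red, 50.0)
    ratio = ratio_stack(ImageStackPair(green=green, red=red), median_radius=0)
    assert not ratio.valid[0, 6, 6]
    assert ratio.valid[0, 1, 1]


def test_segment_blank_image():
    seg = segment_cells(np.zeros((2, 32, 32)), threshold_method=10.0)
    assert seg.n_cells == 0


def test_segment_well_separated_disks():
    centers = [(16, 16), (16, 48), (48, 16), (48, 48), (32, 80)]
    stack = _disk_stack(centers, radius=10.0, shape=(64, 96))
    seg = segment_cells(stack)
    assert seg.n_cells == 5
    for area in seg.areas_px:
        assert abs(area - np.pi * 100) <= 4 * np.pi * 10


def test_watershed_splits_overlapping_disks():
    """Two disks with centers 1.5 radii apart merge into one blob that the
    watershed must split back into two labels."""
    radius = 10.0
    stack = _disk_stack([(32, 24), (32, 24 + 1.5 * radius)], radius=radius)
    seg = segment_cells(stack)
    assert seg.n_cells == 2


def test_label_count_non_increasing_in_min_area():
    centers = [(16, 16), (16, 48), (48, 32)]
    stack = _disk_stack(centers, radius=8.0)
    counts = [
        segment_cells(stack, min_area=m).n_cells for m in (10, 100, 150, 300)
    ]
    assert counts == sorted(counts, reverse=True)
    assert counts[0] == 3


def test_otsu_invariant_to_affine_rescale():
    centers = [(16, 16), (48, 48)]
    stack = _disk_stack(centers, radius=9.0)
    seg1 = segment_cells(stack)
    seg2 = segment_cells(3.7 * stack + 11.0)
    assert np.array_equal(seg1.labels, seg2.labels)


def test_extract_mean_of_mask_pixels():
    from calcimech.imaging import RatioStack, SegmentationResult

    values = np.zeros((2, 4, 4))
    values[:, 0, :4] = [1.0, 2.0, 3.0, 4.0]
    labels = np.zeros((4, 4), dtype=np.int32)
    labels[0, :4] = 1
    ratio = RatioStack(values=values, valid=np.ones_like(values, dtype=bool))
    seg = SegmentationResult(
        labels=labels, areas_px=np.array([4]), centroids=np.array([[0.0, 1.5]])
    )
    ts = extract_traces(ratio, seg, stim_frame=1, dt=1.0)
    assert np.allclose(ts.values, 2.5)


def test_uniform_ratio_gives_constant_traces():
    values = np.full((3, 8, 8), 2.0)
    labels = np.zeros((8, 8), dtype=np.int32)
    labels[2:5, 2:5] = 1
    from calcimech.imaging import RatioStack, SegmentationResult

    ratio = RatioStack(values=values, valid=np.ones_like(values, dtype=bool))
    seg = SegmentationResult(
        labels=labels, areas_px=np.array([9]), centroids=np.array([[3.0, 3.0]])
    )
    ts = extract_traces(ratio, seg, stim_frame=1, dt=1.0)
    assert np.allclose(ts.values, 2.0)


def test_round_trip_trace_correlation():
    """Extracted traces correlate > 0.99 with the generating traces at 1 %
    noise on a small synthetic stack."""
    trace_cfg = TraceSynthConfig(
        n_cells=9, responder_frac=1.0, seed=17, n_pre=20, n_post=60
    )
    cfg = StackSynthConfig.grid(
        n_cells=9, radius=7.0, spacing=20.0, noise_sigma=10.0, trace=trace_cfg
    )
    pair, truth = gen_image_stack(cfg)
    seg = segment_cells(pair.red, min_area=100)
    assert seg.n_cells == 9
    ts = extract_traces(ratio_stack(pair), seg, trace_cfg.n_pre, trace_cfg.dt)
    from calcimech.synth import gen_traces

    source, _ = gen_traces(trace_cfg)
    # match segmented label to generating cell by centroid
    yy_xx = [(int(r), int(c)) for r, c in seg.centroids]
    for j, (r, c) in enumerate(yy_xx):
        src_idx = int(truth.label_image[r, c]) - 1
        rho = np.corrcoef(ts.values[:, j], source.values[:, src_idx])[0, 1]
        assert rho > 0.99
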