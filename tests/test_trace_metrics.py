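"""Unit and property tests for the per-cell calcium-trace statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from calcimech.trace_metrics import (
    AUCParams,
    BaselineStats,
    TraceSet,
    analyze_traces,
    auc,
    baseline_stats,
    classify_responder,
    response_time,
    summarize_traces,
)

# ---------------------------------------------------------------- reference


def brute_force_cell(trace, stim, dt, k_sigma=3.0, frac=0.25, min_peak_frac=0.10):
    """Frame-by-frame pure-Python reference for responder/onset/AUC.

    Integration goes through dense piecewise-linear resampling rather than
    the analytic trapezoid/crossing formulas of the implementation.
    """
    base = [float(v) for v in trace[:stim]]
    mu = sum(base) / len(base)
    sd = math.sqrt(sum((b - mu) ** 2 for b in base) / (len(base) - 1))
    thr = mu + k_sigma * sd
    post = [float(v) for v in trace[stim:]]
    resp = [v > thr for v in post]
    responder = sum(resp) / len(resp) >= frac
    onset = None
    if responder:
        for i in range(len(post) - 1):
            if resp[i] and resp[i + 1]:
                onset = (i + 1) * dt
                break
    y = [v - mu for v in post]
    runs, start = [], None
    for i, v in enumerate(y):
        if v > 0 and start is None:
            start = i
        elif v <= 0 and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(y)))
    rng_y = max(y) - min(y) if y else 0.0
    area = 0.0
    for a, b in runs:
        if max(y[a:b]) < min_peak_frac * rng_y:
            continue
        lo = max(a - 1, 0)
        hi = min(b + 1, len(y))
        t_coarse = np.arange(lo, hi) * dt
        t_fine = np.linspace(t_coarse[0], t_coarse[-1], 20001)
        y_fine = np.interp(t_fine, t_coarse, y[lo:hi])
        area += np.trapezoid(np.clip(y_fine, 0, None), t_fine)
    return responder, onset, area


# ------------------------------------------------------------------- units


def test_baseline_stats_closed_form():
    trace = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 9.9])
    b = baseline_stats(trace, stim_frame=5)
    assert b.mean == pytest.approx(3.0)
    assert b.sd == pytest.approx(math.sqrt(2.5))
    assert b.threshold == pytest.approx(3.0 + 3 * math.sqrt(2.5))


def test_baseline_stats_constant_and_errors():
    b = baseline_stats(np.ones(10), stim_frame=5)
    assert (b.mean, b.sd, b.threshold) == (1.0, 0.0, 1.0)
    with pytest.raises(ValueError):
        baseline_stats(np.ones(10), stim_frame=1)


@pytest.mark.parametrize(
    "n_hot, expected",
    [(74, False), (75, True), (300, True), (0, False)],
    ids=["just-below-quarter", "exactly-a-quarter", "all-frames", "flat"],
)
def test_responder_boundary_inclusive(n_hot, expected):
    """A cell responding in exactly a quarter of post-stimulus frames counts."""
    base = BaselineStats(mean=1.0, sd=0.1)
    trace = np.ones(400)
    trace[100 : 100 + n_hot] = base.threshold + 1.0
    responder, mask = classify_responder(trace, base, stim_frame=100)
    assert responder is expected
    assert mask.sum() == n_hot


def test_responder_threshold_is_strict():
    base = BaselineStats(mean=1.0, sd=0.1)
    trace = np.full(400, base.threshold)  # exactly at threshold: not responding
    responder, mask = classify_responder(trace, base, stim_frame=100)
    assert not responder and not mask.any()


def test_response_time_convention():
    """First run of >= 2 supra-threshold frames, stimulus at the window edge."""
    base = BaselineStats(mean=0.0, sd=0.1)
    trace = np.zeros(20)
    trace[12:] = 1.0  # frames 12.. exceed threshold; stim at frame 10
    assert response_time(trace, base, stim_frame=10, dt=4.0, frac=0.25) == 12.0


def test_response_time_needs_two_consecutive_frames():
    base = BaselineStats(mean=0.0, sd=0.1)
    trace = np.zeros(16)
    trace[4::2] = 1.0  # alternating: 50 % of frames respond but never twice in a row
    responder, _ = classify_responder(trace, base, stim_frame=4)
    assert responder
    assert response_time(trace, base, stim_frame=4, dt=1.0) is None


def test_auc_rectangular_pulse():
    y = np.concatenate([np.zeros(5), np.full(10, 2.0), np.zeros(5)])
    base = BaselineStats(mean=0.0, sd=0.0)
    assert auc(y, base, stim_frame=1, dt=1.0, params=AUCParams(full_trace=True)) == (
        pytest.approx(20.0)
    )


def test_auc_small_peak_excluded():
    """A peak at 9 % of the min-to-max range is dropped; 11 % survives."""
    base = BaselineStats(mean=0.0, sd=0.0)
    big = np.concatenate([np.zeros(3), [10.0], np.zeros(3)])
    for frac_height, included in [(0.9, False), (1.1, True)]:
        y = np.concatenate([big, [frac_height * 10 * 0.1], np.zeros(3)])
        area = auc(y, base, stim_frame=1, dt=1.0, params=AUCParams(full_trace=True))
        big_area = auc(big, base, stim_frame=1, dt=1.0,
                       params=AUCParams(full_trace=True))
        if included:
            assert area > big_area
        else:
            assert area == pytest.approx(big_area)


def test_auc_zero_and_all_negative():
    base = BaselineStats(mean=0.0, sd=0.0)
    assert auc(np.zeros(10), base, 1, 1.0) == 0.0
    assert auc(np.full(10, -3.0), base, 1, 1.0) == 0.0


def test_auc_additive_over_disjoint_peaks():
    base = BaselineStats(mean=0.0, sd=0.0)
    p1 = np.concatenate([np.zeros(2), [4.0, 4.0], np.zeros(6)])
    p2 = np.concatenate([np.zeros(6), [3.0, 3.0], np.zeros(2)])
    both = p1 + p2
    kwargs = dict(stim_frame=1, dt=1.0, params=AUCParams(full_trace=True))
    assert auc(both, base, **kwargs) == pytest.approx(
        auc(p1, base, **kwargs) + auc(p2, base, **kwargs)
    )


def test_summarize_flat_cohort_has_no_onset_summary():
    results = analyze_traces(
        TraceSet(
            values=np.column_stack([np.ones(10), np.ones(10) * 2]),
            stim_frame=5,
            dt=1.0,
        )
    )
    s = summarize_traces(results)
    assert s["n_cells"] == 2 and s["n_responders"] == 0
    assert s["onset_mean_s"] is None and s["onset_n"] == 0


# --------------------------------------------------------------- properties


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    scale=st.floats(min_value=1e-3, max_value=1e3),
    seed=st.integers(min_value=0, max_value=2**16),
)
def test_auc_scale_covariance(scale, seed):
    """Scaling a baseline-subtracted trace by c scales AUC by c and leaves
    responder status and onset unchanged (the peak filter is ratio-based)."""
    rng = np.random.default_rng(seed)
    y = rng.normal(0, 1, 30)
    base = BaselineStats(mean=0.0, sd=0.1)
    kwargs = dict(stim_frame=5, dt=2.0)
    a1 = auc(y, base, **kwargs)
    a2 = auc(scale * y, BaselineStats(0.0, 0.1 * scale), **kwargs)
    assert a2 == pytest.approx(scale * a1, rel=1e-9)
    r1, _ = classify_responder(y, base, 5)
    r2, _ = classify_responder(scale * y, BaselineStats(0.0, 0.1 * scale), 5)
    assert r1 == r2


def test_amplitude_monotonicity():
    """Raising the transient never demotes a responder at fixed threshold."""
    base = BaselineStats(mean=0.0, sd=0.1)
    bump = np.concatenate([np.zeros(10), np.ones(90)])
    for amp in [0.5, 1.0, 2.0, 8.0]:
        trace = amp * bump
        small, _ = classify_responder(trace, base, 10)
        larger, _ = classify_responder(2 * trace, base, 10)
        assert larger or not small


def test_brute_force_agreement_random_short_traces(rng):
    """Responder, onset, and AUC agree with the frame-by-frame reference on
    random traces of at most 20 frames."""
    for _ in range(300):
        n = int(rng.integers(6, 21))
        stim = int(rng.integers(2, n - 1))
        trace = rng.normal(1.0, 0.3, n)
        dt = float(rng.uniform(0.5, 5.0))
        base = baseline_stats(trace, stim)
        responder, _ = classify_responder(trace, base, stim)
        onset = response_time(trace, base, stim, dt)
        area = auc(trace, base, stim, dt)
        ref_resp, ref_onset, ref_area = brute_force_cell(trace, stim, dt)
        assert responder == ref_resp
        assert onset == ref_onset
        assert area == pytest.approx(ref_area, abs=1e-5 * max(1.0, ref_area))


def test_traceset_validation():
    with pytest.raises(ValueError):
        TraceSet(values=np.array([[np.nan]] * 3), stim_frame=1, dt=1.0)
    with pytest.raises(ValueError):
        TraceSet(values=np.ones((5, 2)), stim_frame=0, dt=1.0)
    with pytest.raises(ValueError):
        TraceSet(values=np.ones((5, 2)), stim_frame=2, dt=-1.0)
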