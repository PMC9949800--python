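"""Tests of the synthetic-data generators: determinism, construction
guarantees, and parameter recovery by the downstream estimators."""

import numpy as np
import pytest

from calcimech.indentation import find_contact_point, fit_hertz
from calcimech.synth import (
    CurveSynthConfig,
    PatchSynthConfig,
    StackSynthConfig,
    TraceSynthConfig,
    _hertz_coeff,
    gen_ephys_groups,
    gen_force_curve,
    gen_image_stack,
    gen_patch_trace,
    gen_traces,
)
from calcimech.trace_metrics import analyze_traces, summarize_traces


def test_traces_deterministic():
    cfg = TraceSynthConfig(n_cells=20, seed=5)
    t1, tr1 = gen_traces(cfg)
    t2, tr2 = gen_traces(cfg)
    assert np.array_equal(t1.values, t2.values)
    assert np.array_equal(tr1.responder_mask, tr2.responder_mask)


def test_no_responders_means_pure_noise():
    cfg = TraceSynthConfig(n_cells=100, responder_frac=0.0, seed=3)
    traces, truth = gen_traces(cfg)
    assert not truth.responder_mask.any()
    s = summarize_traces(analyze_traces(traces))
    assert s["responder_fraction"] == 0.0


def test_responder_fraction_recovery(default_cohort):
    cfg, traces, truth = default_cohort
    s = summarize_traces(analyze_traces(traces))
    assert truth.responder_mask.mean() == pytest.approx(0.6)
    assert abs(s["responder_fraction"] - 0.6) < 0.05


def test_invalid_trace_config_rejected():
    with pytest.raises(Exception):
        TraceSynthConfig(n_cells=10, responder_frac=1.5)
    with pytest.raises(Exception):
        TraceSynthConfig(n_cells=10, rise_tau_s=-1.0)
    with pytest.raises(Exception):
        TraceSynthConfig(n_cells=10, unknown_knob=1)


def test_force_curve_matches_closed_form_in_rigid_limit():
    """With an effectively rigid cantilever the generated force equals the
    closed-form Hertz relation in (z - z0) to 1e-9 relative."""
    cfg = CurveSynthConfig(
        E_true_kPa=15.0, k_N_per_m=1e9, noise_sigma_nN=0.0, z0_true_um=1.0
    )
    curve, _ = gen_force_curve(cfg)
    c = _hertz_coeff(15.0, cfg.nu, cfg.R_um)
    delta = np.clip(curve.z_um - 1.0, 0, None)
    expected = c * delta**1.5
    np.testing.assert_allclose(curve.force_nN, expected, rtol=1e-9, atol=1e-9)


def test_cantilever_deflection_at_full_load():
    """300 nN on a 7.83 N/m cantilever bends it 300/7.83 = 38.3 nm."""
    curve, _ = gen_force_curve(CurveSynthConfig(E_true_kPa=15.0, noise_sigma_nN=0.0))
    assert curve.deflection_nm.max() == pytest.approx(300.0 / 7.83, rel=1e-6)


def test_noisy_curve_modulus_recovery_many_seeds():
    errs = []
    for seed in range(50):
        curve, truth = gen_force_curve(
            CurveSynthConfig(E_true_kPa=15.0, noise_sigma_nN=1.0, seed=seed)
        )
        fit = fit_hertz(curve, find_contact_point(curve))
        errs.append(abs(fit.E_kPa - truth.E_true_kPa) / truth.E_true_kPa)
    assert np.median(errs) < 0.05


def test_patch_trace_levels_and_controls():
    noiseless = PatchSynthConfig(noise_sigma_pA=0.0, seed=1)
    trace, truth = gen_patch_trace(noiseless)
    levels = np.unique(trace)
    assert set(levels) <= {0.0, truth.i_u_pA}
    assert abs(levels.max() - levels.min()) == pytest.approx(abs(truth.i_u_pA))
    closed_only, _ = gen_patch_trace(
        PatchSynthConfig(noise_sigma_pA=0.0, open_prob_override=0.0)
    )
    assert np.all(closed_only == 0.0)
    with pytest.raises(Exception):
        PatchSynthConfig(i_u_pA=0.0)


def test_ephys_groups_exact_and_sampling():
    table, truth = gen_ephys_groups(
        [("basal", 50.13, 0.0, 5), ("inhibited", 13.8, 0.0, 5)], seed=0
    )
    assert np.all(table.loc[table.group == "basal", "density_pA_pF"] == 50.13)
    assert truth.group_means == {"basal": 50.13, "inhibited": 13.8}
    big, _ = gen_ephys_groups([("g", 10.0, 5.0, 10_000)], seed=1)
    sem = 5.0 / np.sqrt(10_000)
    assert abs(big.density_pA_pF.mean() - 10.0) < 3 * sem


def test_stack_truth_geometry():
    trace_cfg = TraceSynthConfig(n_cells=5, seed=9, n_pre=5, n_post=10)
    cfg = StackSynthConfig.grid(n_cells=5, radius=10.0, spacing=30.0,
                                trace=trace_cfg)
    _, truth = gen_image_stack(cfg)
    labels = truth.label_image
    assert labels.max() == 5
    for lab in range(1, 6):
        area = (labels == lab).sum()
        assert abs(area - np.pi * 100) <= 4 * np.pi * 10
    assert truth.touching_pairs == ()


def test_stack_zero_cells_and_touching_pair():
    empty = StackSynthConfig(
        height=32, width=32, centers=(), radii=(),
        trace=TraceSynthConfig(n_cells=0, n_pre=3, n_post=3),
    )
    _, truth = gen_image_stack(empty)
    assert truth.label_image.max() == 0
    touching = StackSynthConfig(
        height=64, width=64,
        centers=((20.0, 20.0), (20.0, 40.0)),
        radii=(10.0, 10.0),
        trace=TraceSynthConfig(n_cells=2, n_pre=3, n_post=3),
    )
    _, truth = gen_image_stack(touching)
    assert truth.touching_pairs == ((1, 2),)


def test_stack_out_of_bounds_rejected():
    with pytest.raises(Exception):
        StackSynthConfig(
            height=32, width=32, centers=((1.0, 1.0),), radii=(5.0,),
            trace=TraceSynthConfig(n_cells=1),
        )
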