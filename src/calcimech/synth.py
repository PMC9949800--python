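"""Synthetic data with known ground truth for every analysis stage.

The generators emulate the statistical structure of the study's raw
recordings, none of which ship with the package:

* ratiometric calcium traces — Gaussian baseline plus, for a configurable
  fraction of responder cells, a sustained agonist-evoked transient
  A*(1 - exp(-s/rise_tau))*exp(-s/decay_tau) starting at a truncated-normal
  latency after the stimulus;
* two-channel image stacks — disk-shaped cells with a constant reference-dye
  (red) level whose green/red ratio follows the generated traces;
* AFM approach curves — Hertzian spherical contact with the cantilever
  deflection F/k solved self-consistently, a flat pre-contact baseline, and
  additive force noise;
* single-channel patch records — a two-level telegraph process with
  exponential dwell times plus Gaussian noise;
* per-cell current-density group tables with specified means.

Every generator takes one explicit integer seed and is bit-reproducible for
a fixed (config, seed). Ground truth travels with each object in a
:class:`SynthTruth`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import stats as sps

from .imaging import ImageStackPair
from .indentation import ForceCurve
from .trace_metrics import TraceSet

__all__ = [
    "TraceSynthConfig",
    "StackSynthConfig",
    "CurveSynthConfig",
    "PatchSynthConfig",
    "SynthTruth",
    "gen_traces",
    "gen_image_stack",
    "gen_force_curve",
    "gen_patch_trace",
    "gen_ephys_groups",
]


@dataclass(frozen=True)
class SynthTruth:
    """Ground truth attached to a generated object, for recovery tests."""

    responder_mask: Optional[np.ndarray] = None
    latencies_s: Optional[np.ndarray] = None
    label_image: Optional[np.ndarray] = field(default=None, repr=False)
    touching_pairs: Optional[tuple[tuple[int, int], ...]] = None
    E_true_kPa: Optional[float] = None
    z0_true_um: Optional[float] = None
    i_u_pA: Optional[float] = None
    open_states: Optional[np.ndarray] = field(default=None, repr=False)
    group_means: Optional[dict[str, float]] = None


class TraceSynthConfig(BaseModel):
    """Parameters of the ratiometric-trace generator.

    Defaults mirror the imaging protocol being emulated: 100 baseline frames
    followed by 300 post-stimulus frames at 4 s per frame, baseline ratio
    1.0 with SD 0.05, and a sustained transient of amplitude 10x the
    baseline SD for responders. Latency is normal truncated at zero.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    n_cells: int = Field(ge=0)
    responder_frac: float = Field(default=0.6, ge=0.0, le=1.0)
    n_pre: int = Field(default=100, ge=2)
    n_post: int = Field(default=300, ge=1)
    dt: float = Field(default=4.0, gt=0.0)
    baseline_mu: float = 1.0
    baseline_sigma: float = Field(default=0.05, ge=0.0)
    transient_amplitude: float = Field(default=0.5, ge=0.0)
    latency_mean_s: float = Field(default=40.0, ge=0.0)
    latency_sd_s: float = Field(default=10.0, ge=0.0)
    rise_tau_s: float = Field(default=2.0, gt=0.0)
    decay_tau_s: float = Field(default=600.0, gt=0.0)
    seed: int = 0


def _draw_latencies(cfg: TraceSynthConfig, n: int, rng: np.random.Generator):
    if n == 0:
        return np.empty(0)
    if cfg.latency_sd_s == 0:
        return np.full(n, cfg.latency_mean_s)
    a = (0.0 - cfg.latency_mean_s) / cfg.latency_sd_s
    return sps.truncnorm.rvs(
        a, np.inf, loc=cfg.latency_mean_s, scale=cfg.latency_sd_s,
        size=n, random_state=rng,
    )


def gen_traces(config: TraceSynthConfig) -> tuple[TraceSet, SynthTruth]:
    """Generate a cohort of traces; exactly round(frac*n) cells respond.

    Post-stimulus frame j (0-based within the window) sits at elapsed time
    (j + 1)*dt from stimulus addition; a responder's transient is added for
    frame times past its latency.
    """
    rng = np.random.default_rng(config.seed)
    n_frames = config.n_pre + config.n_post
    values = rng.normal(
        config.baseline_mu, config.baseline_sigma, size=(n_frames, config.n_cells)
    )
    n_resp = round(config.responder_frac * config.n_cells)
    responder_mask = np.zeros(config.n_cells, dtype=bool)
    responder_mask[rng.permutation(config.n_cells)[:n_resp]] = True
    latencies = np.full(config.n_cells, np.nan)
    latencies[responder_mask] = _draw_latencies(config, n_resp, rng)
    t_post = (np.arange(config.n_post) + 1) * config.dt
    for j in np.flatnonzero(responder_mask):
        s = t_post - latencies[j]
        active = s > 0
        transient = np.zeros(config.n_post)
        transient[active] = (
            config.transient_amplitude
            * (1.0 - np.exp(-s[active] / config.rise_tau_s))
            * np.exp(-s[active] / config.decay_tau_s)
        )
        values[config.n_pre:, j] += transient
    traces = TraceSet(
        values=values,
        stim_frame=config.n_pre,
        dt=config.dt,
        cell_ids=tuple(f"cell{i:04d}" for i in range(config.n_cells)),
    )
    return traces, SynthTruth(responder_mask=responder_mask, latencies_s=latencies)


class StackSynthConfig(BaseModel):
    """Geometry and noise of a synthetic two-channel image stack.

    Cells are disks with a constant red (reference-dye) intensity; the green
    channel is red times each cell's generated ratio trace. Centers are
    (row, col) pixel coordinates.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    height: int = Field(ge=8)
    width: int = Field(ge=8)
    centers: tuple[tuple[float, float], ...]
    radii: tuple[float, ...]
    red_intensity: float = Field(default=1000.0, gt=0.0)
    noise_sigma: float = Field(default=10.0, ge=0.0)
    background: float = Field(default=20.0, ge=0.0)
    trace: TraceSynthConfig

    @model_validator(mode="after")
    def _check_geometry(self) -> "StackSynthConfig":
        if len(self.centers) != len(self.radii):
            raise ValueError("one radius per center required")
        if len(self.centers) != self.trace.n_cells:
            raise ValueError("trace config n_cells must equal the number of disks")
        for (r, c), rad in zip(self.centers, self.radii):
            if rad <= 0:
                raise ValueError("radii must be positive")
            if not (0 <= r - rad and r + rad < self.height
                    and 0 <= c - rad and c + rad < self.width):
                raise ValueError(f"disk at ({r}, {c}) r={rad} exceeds image bounds")
        return self

    @classmethod
    def grid(
        cls,
        n_cells: int,
        radius: float = 7.0,
        spacing: float = 20.0,
        trace: Optional[TraceSynthConfig] = None,
        **kwargs,
    ) -> "StackSynthConfig":
        """Convenience layout: n_cells disks of one radius on a square grid."""
        per_side = int(np.ceil(np.sqrt(n_cells)))
        centers = []
        for i in range(n_cells):
            row, col = divmod(i, per_side)
            centers.append(((row + 0.5) * spacing, (col + 0.5) * spacing))
        side = int(np.ceil(per_side * spacing))
        trace = trace or TraceSynthConfig(n_cells=n_cells)
        return cls(
            height=side,
            width=side,
            centers=tuple(centers),
            radii=(radius,) * n_cells,
            trace=trace,
            **kwargs,
        )


def _rasterize_disks(cfg: StackSynthConfig) -> np.ndarray:
    labels = np.zeros((cfg.height, cfg.width), dtype=np.int32)
    yy, xx = np.mgrid[0 : cfg.height, 0 : cfg.width]
    for i, ((r, c), rad) in enumerate(zip(cfg.centers, cfg.radii), start=1):
        inside = (yy - r) ** 2 + (xx - c) ** 2 <= rad**2
        labels[inside] = i
    return labels


def _touching_pairs(cfg: StackSynthConfig) -> tuple[tuple[int, int], ...]:
    pairs = []
    for i in range(len(cfg.centers)):
        for j in range(i + 1, len(cfg.centers)):
            d = float(np.hypot(
                cfg.centers[i][0] - cfg.centers[j][0],
                cfg.centers[i][1] - cfg.centers[j][1],
            ))
            if d <= cfg.radii[i] + cfg.radii[j] + 1.0:
                pairs.append((i + 1, j + 1))
    return tuple(pairs)


def gen_image_stack(config: StackSynthConfig) -> tuple[ImageStackPair, SynthTruth]:
    """Two-channel stack whose in-cell green/red ratio follows gen_traces.

    The red channel is background + constant disks + noise; the green
    channel multiplies the noiseless red disks by each cell's ratio trace
    before adding its own noise. Truth carries the trace ground truth, the
    label image, and any touching/overlapping disk pairs.
    """
    traces, trace_truth = gen_traces(config.trace)
    labels = _rasterize_disks(config)
    # a fresh stream, decoupled from the trace RNG, keeps traces identical
    # whether or not a stack is rendered around them
    rng = np.random.default_rng(np.random.SeedSequence([config.trace.seed, 1]))
    n_frames = traces.n_frames
    red_clean = np.where(labels > 0, config.red_intensity, config.background)
    # per-frame per-cell ratio lookup; background ratio 1 keeps green finite
    ratio_lut = np.ones((n_frames, len(config.centers) + 1))
    ratio_lut[:, 1:] = traces.values
    green = red_clean[None, :, :] * ratio_lut[:, labels]
    red = np.broadcast_to(red_clean, (n_frames, *red_clean.shape)).copy()
    if config.noise_sigma > 0:
        green = green + rng.normal(0, config.noise_sigma, green.shape)
        red = red + rng.normal(0, config.noise_sigma, red.shape)
    np.clip(green, 0, None, out=green)
    np.clip(red, 0, None, out=red)
    truth = SynthTruth(
        responder_mask=trace_truth.responder_mask,
        latencies_s=trace_truth.latencies_s,
        label_image=labels,
        touching_pairs=_touching_pairs(config),
    )
    return ImageStackPair(green=green, red=red), truth


class CurveSynthConfig(BaseModel):
    """Parameters of the Hertzian force-curve generator.

    Defaults match a stiff-cantilever nanoindentation setup: 5 um spherical
    tip (R = 2.5 um), k = 7.83 N/m, loading to 300 nN, incompressible
    sample.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    E_true_kPa: float = Field(gt=0.0)
    R_um: float = Field(default=2.5, gt=0.0)
    nu: float = Field(default=0.5, ge=0.0, le=0.5)
    k_N_per_m: float = Field(default=7.83, gt=0.0)
    z0_true_um: float = Field(default=1.0, ge=0.0)
    F_max_nN: float = Field(default=300.0, gt=0.0)
    n_points: int = Field(default=500, ge=16)
    noise_sigma_nN: float = Field(default=1.0, ge=0.0)
    seed: int = 0


def _hertz_coeff(E_kPa: float, nu: float, R_um: float) -> float:
    """C in F = C*delta^(3/2); nN/um^(3/2) for E in kPa, R in um."""
    return (4.0 / 3.0) * (E_kPa / (1.0 - nu**2)) * np.sqrt(R_um)


def _force_at(z: np.ndarray, cfg: CurveSynthConfig, tol_nN: float = 1e-6,
              max_iter: int = 100) -> np.ndarray:
    """Self-consistent Hertz force at piezo positions z (fixed point in F).

    delta = (z - z0) - F/k couples force and deflection; the fixed-point map
    F <- C*max(delta, 0)^(3/2) contracts for physical parameters.
    """
    c = _hertz_coeff(cfg.E_true_kPa, cfg.nu, cfg.R_um)
    k_nN_per_um = cfg.k_N_per_m * 1000.0
    f = np.zeros_like(z)
    for _ in range(max_iter):
        delta = np.clip((z - cfg.z0_true_um) - f / k_nN_per_um, 0.0, None)
        f_new = c * delta**1.5
        if np.max(np.abs(f_new - f)) < tol_nN:
            return f_new
        f = f_new
    raise RuntimeError(
        f"force self-consistency did not converge within {max_iter} iterations "
        f"(last update {np.max(np.abs(f_new - f)):.3g} nN)"
    )


def gen_force_curve(config: CurveSynthConfig) -> tuple[ForceCurve, SynthTruth]:
    """Synthetic approach curve: flat baseline, Hertzian contact, force noise.

    The z range spans from 0 to the piezo position where the force reaches
    F_max (contact indentation plus cantilever deflection). Noise is added
    to the force and propagated to deflection through the spring constant.
    """
    c = _hertz_coeff(config.E_true_kPa, config.nu, config.R_um)
    delta_max = (config.F_max_nN / c) ** (2.0 / 3.0)
    k_nN_per_um = config.k_N_per_m * 1000.0
    z_max = config.z0_true_um + delta_max + config.F_max_nN / k_nN_per_um
    z = np.linspace(0.0, z_max, config.n_points)
    force = _force_at(z, config)
    rng = np.random.default_rng(config.seed)
    if config.noise_sigma_nN > 0:
        force = force + rng.normal(0, config.noise_sigma_nN, force.shape)
    deflection_nm = force / config.k_N_per_m
    curve = ForceCurve(
        z_um=z,
        deflection_nm=deflection_nm,
        k_N_per_m=config.k_N_per_m,
        R_um=config.R_um,
        nu=config.nu,
    )
    truth = SynthTruth(E_true_kPa=config.E_true_kPa, z0_true_um=config.z0_true_um)
    return curve, truth


class PatchSynthConfig(BaseModel):
    """Two-level single-channel record: telegraph gating plus Gaussian noise.

    Kinetics are set by the mean open and closed dwell times (exponential);
    the steady-state open probability is the derived tau_o/(tau_o + tau_c).
    The default unitary current is -8 pA (inward at a negative potential).
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    i_u_pA: float = -8.0
    open_dwell_ms: float = Field(default=10.0, gt=0.0)
    closed_dwell_ms: float = Field(default=20.0, gt=0.0)
    sampling_hz: float = Field(default=5000.0, gt=0.0)
    n_samples: int = Field(default=10000, ge=1000)
    noise_sigma_pA: float = Field(default=0.5, ge=0.0)
    open_prob_override: Optional[float] = Field(default=None, ge=0.0, le=1.0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "PatchSynthConfig":
        if self.i_u_pA == 0:
            raise ValueError("unitary current must be nonzero")
        return self

    @property
    def open_prob(self) -> float:
        if self.open_prob_override is not None:
            return self.open_prob_override
        return self.open_dwell_ms / (self.open_dwell_ms + self.closed_dwell_ms)


def gen_patch_trace(config: PatchSynthConfig) -> tuple[np.ndarray, SynthTruth]:
    """Current record (pA) sampled from a two-state telegraph process.

    ``open_prob_override`` of 0 or 1 pins the channel in one state (used for
    single-level controls); otherwise alternating exponential dwells with
    the configured means are sampled onto the acquisition grid.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    dt_ms = 1000.0 / config.sampling_hz
    total_ms = n * dt_ms
    open_states = np.zeros(n, dtype=bool)
    if config.open_prob_override in (0.0, 1.0):
        open_states[:] = bool(config.open_prob_override)
    else:
        state = rng.random() < config.open_prob
        t = 0.0
        edges = [0.0]
        states = [state]
        while t < total_ms:
            mean = config.open_dwell_ms if state else config.closed_dwell_ms
            t += rng.exponential(mean)
            state = not state
            edges.append(t)
            states.append(state)
        sample_t = (np.arange(n) + 0.5) * dt_ms
        seg = np.searchsorted(np.array(edges), sample_t, side="right") - 1
        open_states = np.array(states, dtype=bool)[seg]
    trace = np.where(open_states, config.i_u_pA, 0.0)
    if config.noise_sigma_pA > 0:
        trace = trace + rng.normal(0, config.noise_sigma_pA, n)
    truth = SynthTruth(i_u_pA=config.i_u_pA, open_states=open_states)
    return trace, truth


def gen_ephys_groups(
    group_specs: Sequence[tuple[str, float, float, int]], seed: int = 0
) -> tuple[pd.DataFrame, SynthTruth]:
    """Per-cell current-density table from (label, mean, sd, n) group specs.

    Returns a DataFrame with columns ``group``, ``cell_id``,
    ``density_pA_pF`` and a truth object recording the specified means.
    """
    rng = np.random.default_rng(seed)
    rows = []
    means: dict[str, float] = {}
    for label, mean, sd, n in group_specs:
        if n < 1:
            raise ValueError(f"group {label!r}: n must be >= 1")
        if sd < 0:
            raise ValueError(f"group {label!r}: sd must be >= 0")
        if label in means:
            raise ValueError(f"duplicate group label {label!r}")
        means[label] = float(mean)
        draws = rng.normal(mean, sd, n) if sd > 0 else np.full(n, float(mean))
        for i, v in enumerate(draws):
            rows.append({"group": label, "cell_id": f"{label}_{i:03d}",
                         "density_pA_pF": float(v)})
    return pd.DataFrame(rows), SynthTruth(group_means=means)
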