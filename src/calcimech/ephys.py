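"""Patch-clamp summary statistics.

Covers three whole-cell / excised-patch quantities:

* current density — whole-cell current normalized by membrane capacitance
  (pA/pF), making cells of different sizes comparable;
* the basal-minus-inhibited channel current: per cell,
  delta_i = basal_i - mean(inhibited group), isolating the current carried by
  the channel of interest from the leak that remains under a specific
  antagonist;
* unitary current — the single-channel current step, read from the
  separation of the two modes of an all-points amplitude histogram fitted
  with a two-component Gaussian mixture.

Sign convention: inward currents are negative; the unitary current is
reported as a magnitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.mixture import GaussianMixture

__all__ = [
    "EphysGroup",
    "DeltaResult",
    "UnitaryCurrentEstimate",
    "current_density",
    "delta_current",
    "unitary_current",
]


def current_density(I_pA: np.ndarray, C_pF: np.ndarray) -> np.ndarray:
    """Elementwise I/C in pA/pF; capacitances must be strictly positive."""
    I_pA = np.asarray(I_pA, dtype=float)
    C_pF = np.asarray(C_pF, dtype=float)
    if np.any(C_pF <= 0):
        raise ValueError("membrane capacitance must be positive")
    return I_pA / C_pF


@dataclass(frozen=True)
class EphysGroup:
    """Per-cell current densities for one cell line x condition x voltage."""

    label: str
    voltage_mV: float
    density_pA_pF: np.ndarray

    def __post_init__(self) -> None:
        d = np.atleast_1d(np.asarray(self.density_pA_pF, dtype=float))
        if d.size < 1:
            raise ValueError("group must contain at least one cell")
        if not np.all(np.isfinite(d)):
            raise ValueError("non-finite current density")
        object.__setattr__(self, "density_pA_pF", d)

    @classmethod
    def from_raw(
        cls, label: str, voltage_mV: float, I_pA: np.ndarray, C_pF: np.ndarray
    ) -> "EphysGroup":
        return cls(label, voltage_mV, current_density(I_pA, C_pF))

    @property
    def n(self) -> int:
        return self.density_pA_pF.size

    @property
    def mean(self) -> float:
        return float(self.density_pA_pF.mean())


@dataclass(frozen=True)
class DeltaResult:
    """Per-cell basal-minus-inhibited currents and their group summary.

    The SEM uses the basal group's n: the inhibited-group mean is treated as
    a constant reference, matching the per-cell-minus-group-average
    construction of the statistic.
    """

    deltas_pA_pF: np.ndarray = field(repr=False)
    mean: float
    sem: Optional[float]
    inhibited_mean: float
    label: str
    voltage_mV: float


def delta_current(basal: EphysGroup, inhibited: EphysGroup) -> DeltaResult:
    """Channel-specific current: basal cells minus the mean inhibited current.

    Groups must share cell-line label and holding potential. The group mean
    of the deltas equals mean(basal) - mean(inhibited) identically.
    """
    if basal.label != inhibited.label:
        raise ValueError(
            f"cell-line label mismatch: basal {basal.label!r} vs "
            f"inhibited {inhibited.label!r}"
        )
    if basal.voltage_mV != inhibited.voltage_mV:
        raise ValueError(
            f"holding-potential mismatch: {basal.voltage_mV} mV vs "
            f"{inhibited.voltage_mV} mV"
        )
    ref = inhibited.mean
    deltas = basal.density_pA_pF - ref
    sem = (
        float(deltas.std(ddof=1) / math.sqrt(deltas.size))
        if deltas.size > 1
        else None
    )
    return DeltaResult(
        deltas_pA_pF=deltas,
        mean=float(deltas.mean()),
        sem=sem,
        inhibited_mean=ref,
        label=basal.label,
        voltage_mV=basal.voltage_mV,
    )


@dataclass(frozen=True)
class UnitaryCurrentEstimate:
    detected: bool
    i_u_pA: Optional[float]
    level_means_pA: Optional[tuple[float, float]]
    weights: Optional[tuple[float, float]]
    log_likelihood: Optional[float]
    message: str = ""


def unitary_current(
    trace_pA: np.ndarray,
    min_weight: float = 0.01,
    seed: int = 0,
    n_init: int = 10,
) -> UnitaryCurrentEstimate:
    """Unitary current from the all-points amplitude histogram of a record.

    Fits a two-component Gaussian mixture (k-means initialization, several
    restarts, best likelihood kept) to the sample amplitudes; the unitary
    current is |mu_open - mu_closed|. Reports "no second level" when the
    mixture degenerates or the minor component's weight falls below
    ``min_weight``. Invariant to any constant offset of the trace.
    """
    trace = np.asarray(trace_pA, dtype=float).ravel()
    if trace.size < 1000:
        raise ValueError("record too short: need at least 1000 samples")
    span = float(trace.max() - trace.min())
    if span == 0:
        return UnitaryCurrentEstimate(
            False, None, None, None, None, "no second level detected: constant trace"
        )
    gmm = GaussianMixture(
        n_components=2,
        init_params="kmeans",
        n_init=n_init,
        random_state=seed,
        covariance_type="full",
    )
    gmm.fit(trace[:, None])
    means = gmm.means_.ravel()
    weights = gmm.weights_.ravel()
    order = np.argsort(np.abs(means - np.median(trace)))  # closed level first
    means, weights = means[order], weights[order]
    sep = float(abs(means[1] - means[0]))
    if weights.min() < min_weight:
        return UnitaryCurrentEstimate(
            False,
            None,
            (float(means[0]), float(means[1])),
            (float(weights[0]), float(weights[1])),
            float(gmm.lower_bound_),
            f"no second level detected: minor weight {weights.min():.4f} < {min_weight}",
        )
    # two levels are only resolved when the modes separate by more than the
    # component widths; a single noisy level otherwise splits into two
    # overlapping Gaussians
    width = float(np.sqrt(gmm.covariances_.ravel().max()))
    if sep <= max(2.0 * width, 1e-12):
        return UnitaryCurrentEstimate(
            False,
            None,
            (float(means[0]), float(means[1])),
            (float(weights[0]), float(weights[1])),
            float(gmm.lower_bound_),
            "no second level detected: unresolved or degenerate mixture",
        )
    return UnitaryCurrentEstimate(
        detected=True,
        i_u_pA=sep,
        level_means_pA=(float(means[0]), float(means[1])),
        weights=(float(weights[0]), float(weights[1])),
        log_likelihood=float(gmm.lower_bound_),
    )
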