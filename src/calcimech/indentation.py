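"""AFM force-curve analysis: contact-point extrapolation and Hertz fitting.

An approach curve records cantilever deflection d (nm) against piezo
extension z (um, increasing toward the sample). Force is F = k*d (nN for k
in N/m and d in nm). For a spherical tip of radius R on an elastic
half-space, post-contact force follows the Hertz relation

    F = (4/3) * E/(1 - nu^2) * sqrt(R) * delta^(3/2),

where the true indentation depth corrects for cantilever bending:
delta = (z - z0) - F/k. With F in nN and delta, R in um, E comes out in kPa.

The contact point z0 is found by "contact point extrapolation": F^(2/3) is
linear in the deflection-corrected position z - F/k past contact, so a
straight-line fit over a mid-force window extrapolates to the z-intercept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "ForceCurve",
    "HertzFit",
    "IndentationMap",
    "ContactPointError",
    "HertzFitError",
    "find_contact_point",
    "fit_hertz",
    "make_grid",
    "analyze_map",
]

#: nm of deflection per (nN / (N/m)); F[nN]/k[N/m] is already in nm, and
#: dividing by 1000 converts to um.
_NM_PER_UM = 1000.0


class ContactPointError(RuntimeError):
    """Raised when no contact point can be extrapolated from a curve."""


class HertzFitError(RuntimeError):
    """Raised when the Hertz model cannot be fitted to a curve."""


@dataclass(frozen=True)
class ForceCurve:
    """One approach force curve plus probe metadata.

    z_um : piezo extension (um), strictly increasing toward the sample.
    deflection_nm : cantilever deflection (nm).
    k_N_per_m : cantilever spring constant.
    R_um : spherical tip radius.
    nu : sample Poisson's ratio (0.5 = incompressible).
    """

    z_um: np.ndarray
    deflection_nm: np.ndarray
    k_N_per_m: float
    R_um: float
    nu: float = 0.5

    def __post_init__(self) -> None:
        z = np.asarray(self.z_um, dtype=float)
        d = np.asarray(self.deflection_nm, dtype=float)
        if z.ndim != 1 or z.shape != d.shape:
            raise ValueError("z and deflection must be 1-D arrays of equal length")
        if z.size < 4:
            raise ValueError("need at least 4 samples")
        if np.any(np.diff(z) <= 0):
            raise ValueError("z must be strictly increasing")
        if self.k_N_per_m <= 0 or self.R_um <= 0:
            raise ValueError("spring constant and tip radius must be positive")
        if not 0 <= self.nu <= 0.5:
            raise ValueError("Poisson's ratio must lie in [0, 0.5]")
        object.__setattr__(self, "z_um", z)
        object.__setattr__(self, "deflection_nm", d)

    @property
    def force_nN(self) -> np.ndarray:
        return self.k_N_per_m * self.deflection_nm

    def z_corrected_um(self) -> np.ndarray:
        """Piezo position minus cantilever deflection, i.e. tip position."""
        return self.z_um - self.deflection_nm / _NM_PER_UM


@dataclass(frozen=True)
class HertzFit:
    z0_um: float
    E_kPa: float
    window: tuple[float, float]
    residual_rms_nN: float
    n_points: int

    def __post_init__(self) -> None:
        if self.E_kPa <= 0:
            raise ValueError("fitted modulus must be positive")
        if not math.isfinite(self.residual_rms_nN):
            raise ValueError("residual must be finite")


@dataclass(frozen=True)
class IndentationMap:
    """Per-grid-point fits and their summary over successful fits only."""

    points_um: np.ndarray
    fits: tuple[Optional[HertzFit], ...] = field(repr=False)
    failures: tuple[Optional[str], ...]

    @property
    def n_failures(self) -> int:
        return sum(f is not None for f in self.failures)

    @property
    def moduli_kPa(self) -> np.ndarray:
        return np.array([f.E_kPa for f in self.fits if f is not None])

    @property
    def mean_E_kPa(self) -> float:
        return float(self.moduli_kPa.mean())

    @property
    def median_E_kPa(self) -> float:
        return float(np.median(self.moduli_kPa))


def _noise_rms(force: np.ndarray) -> float:
    """Robust per-sample noise estimate from first differences (MAD-based)."""
    diffs = np.diff(force)
    mad = np.median(np.abs(diffs - np.median(diffs)))
    return float(1.4826 * mad / math.sqrt(2.0))


def find_contact_point(
    curve: ForceCurve,
    f_lo: float = 0.10,
    f_hi: float = 0.90,
    min_snr: float = 10.0,
) -> float:
    """Extrapolate the tip-sample contact point z0 (um).

    Regresses F^(2/3) on the deflection-corrected position z - F/k over the
    points with force in [f_lo, f_hi] of the curve maximum; z0 is the
    regression line's z-intercept. One refinement pass re-selects the window
    to points past the first-pass z0 and repeats the regression.
    """
    if not 0 <= f_lo < f_hi <= 1:
        raise ValueError("require 0 <= f_lo < f_hi <= 1")
    force = curve.force_nN
    f_max = float(force.max())
    noise = _noise_rms(force)
    if noise > 0 and f_max < min_snr * noise:
        raise ContactPointError(
            f"curve never rises {min_snr}x above baseline noise "
            f"(max {f_max:.3g} nN, noise RMS {noise:.3g} nN)"
        )
    if f_max <= 0:
        raise ContactPointError("curve contains no positive force")
    z_eff = curve.z_corrected_um()

    def _regress(extra_mask: np.ndarray) -> float:
        sel = (force >= f_lo * f_max) & (force <= f_hi * f_max) & extra_mask
        if sel.sum() < 2:
            raise ContactPointError("fewer than 2 points in the fit window")
        slope, intercept = np.polyfit(z_eff[sel], force[sel] ** (2.0 / 3.0), 1)
        if slope <= 0:
            raise ContactPointError(
                f"non-positive linearized slope ({slope:.3g}); "
                "curve is not Hertz-like in the window"
            )
        return float(-intercept / slope)

    z0 = _regress(np.ones_like(force, dtype=bool))
    return _regress(z_eff > z0)


def fit_hertz(
    curve: ForceCurve,
    z0_um: float,
    window: tuple[float, float] = (0.10, 0.90),
    max_iter: int = 200,
) -> HertzFit:
    """Fit the spherical Hertz model over a force window, given z0.

    The indentation depth uses the cantilever-deflection correction
    delta = (z - z0) - F/k. Nonlinear least squares of F = C*delta^(3/2) is
    initialized from the closed-form linear solution in C; the modulus is
    E = 3*C*(1 - nu^2) / (4*sqrt(R)), in kPa for nN/um inputs.
    """
    f_lo, f_hi = window
    force = curve.force_nN
    f_max = float(force.max())
    delta = curve.z_corrected_um() - z0_um
    sel = (force >= f_lo * f_max) & (force <= f_hi * f_max) & (delta > 0)
    if sel.sum() < 2:
        raise HertzFitError(
            "no usable points: indentation depth non-positive over the window"
        )
    d, f = delta[sel], force[sel]
    d32 = d**1.5
    c0 = float(d32 @ f / (d32 @ d32))  # linear LSQ in C
    if c0 <= 0:
        raise HertzFitError("linearized stiffness non-positive")
    try:
        (c_hat,), _ = curve_fit(
            lambda x, c: c * x**1.5, d, f, p0=(c0,), maxfev=max_iter
        )
    except RuntimeError as err:
        resid = float(np.sqrt(np.mean((f - c0 * d32) ** 2)))
        raise HertzFitError(
            f"Hertz fit did not converge in {max_iter} evaluations "
            f"(linearized residual RMS {resid:.3g} nN)"
        ) from err
    if c_hat <= 0:
        raise HertzFitError("fitted stiffness non-positive")
    e_kpa = 3.0 * c_hat * (1.0 - curve.nu**2) / (4.0 * math.sqrt(curve.R_um))
    resid = float(np.sqrt(np.mean((f - c_hat * d32) ** 2)))
    return HertzFit(
        z0_um=float(z0_um),
        E_kPa=float(e_kpa),
        window=(f_lo, f_hi),
        residual_rms_nN=resid,
        n_points=int(sel.sum()),
    )


def make_grid(side_um: float = 10.0, spacing_um: float = 0.5) -> np.ndarray:
    """Square indentation lattice over a side_um x side_um region.

    floor(side/spacing) points per axis, centered in their cells at
    (i + 1/2)*spacing. Spacing larger than the side degenerates to the single
    center point. The default 10 um side at 0.5 um spacing gives the standard
    20 x 20 = 400-indentation map.
    """
    if side_um <= 0 or spacing_um <= 0:
        raise ValueError("side and spacing must be positive")
    n = int(side_um / spacing_um)
    if n == 0:
        return np.array([[side_um / 2.0, side_um / 2.0]])
    axis = (np.arange(n) + 0.5) * spacing_um
    xx, yy = np.meshgrid(axis, axis, indexing="ij")
    return np.column_stack([xx.ravel(), yy.ravel()])


def analyze_map(
    curves: Sequence[ForceCurve],
    points_um: Optional[np.ndarray] = None,
    window: tuple[float, float] = (0.10, 0.90),
) -> IndentationMap:
    """Contact-point + Hertz fit for every curve of a stiffness map.

    Failed fits are counted and reported per curve, never silently dropped;
    the map summary statistics cover successful fits only.
    """
    if len(curves) == 0:
        raise ValueError("need at least one curve")
    if points_um is None:
        points_um = np.full((len(curves), 2), np.nan)
    points_um = np.asarray(points_um, dtype=float)
    if points_um.shape[0] != len(curves):
        raise ValueError("grid point count must match the number of curves")
    fits: list[Optional[HertzFit]] = []
    failures: list[Optional[str]] = []
    for i, curve in enumerate(curves):
        try:
            z0 = find_contact_point(curve, window[0], window[1])
            fits.append(fit_hertz(curve, z0, window))
            failures.append(None)
        except (ContactPointError, HertzFitError, ValueError) as err:
            fits.append(None)
            failures.append(f"curve {i}: {err}")
    if all(f is None for f in fits):
        raise HertzFitError(
            "all curves failed: " + "; ".join(f for f in failures if f)
        )
    return IndentationMap(
        points_um=points_um, fits=tuple(fits), failures=tuple(failures)
    )
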