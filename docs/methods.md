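# Methods

This note records the models implemented, the defaults chosen where a
choice was genuinely open, the numerical details, and what the synthetic
benchmarks do and do not demonstrate.

## Calcium-trace statistics

A trace is the per-cell Fluo-4/Fura Red intensity ratio sampled at dt
seconds per frame, with frames `[0, stim_frame)` pre-stimulus. All
statistics use the sample (n−1) SD.

* **Threshold.** Responding frames are those strictly above
  μ_b + k·σ_b with k = 3 by default. Strict comparison makes the
  flat-trace case unambiguous (a constant trace never responds).
* **Responder rule.** A cell is a responder when at least a fraction 0.25
  of its *post-stimulus* frames respond. The boundary is inclusive
  ("at least a quarter"), and the denominator is the post-stimulus window
  only — the rule describes behavior after stimulation.
* **Onset convention.** The stimulus event sits at the boundary before
  `stim_frame`; elapsed time counts whole frames, so the first
  post-stimulus frame is at dt, not 0. The onset is the first frame of the
  first ≥2-consecutive-frame supra-threshold run. A responder with no such
  run (possible only near the 25 % boundary with isolated frames) yields no
  onset and is flagged.
* **AUC.** Computed on the baseline-subtracted post-stimulus window, so
  "baseline Y = 0" holds by construction; an explicit baseline and a
  full-trace window are available by parameter. Peaks are maximal runs
  with y > 0; a peak is dropped when its maximum height is below 10 % of
  the window's min-to-max range (strictly below: a peak at exactly 10 %
  is kept). Integration is trapezoidal with entry/exit zero-crossings
  interpolated linearly; this makes the AUC exactly additive over disjoint
  kept peaks and exactly covariant under positive scaling (the peak filter
  is ratio-based).

## Imaging pipeline

The segmentation operates on the max-intensity projection over time of the
red (reference-dye) channel, so cells that never signal are still found.
Unreported processing parameters are configurable with these defaults:
median filter radius 1 px (3×3); threshold method Otsu (triangle or a fixed
value selectable); watershed seeded at local maxima of the Euclidean
distance transform with a 5 px minimum seed separation, which reproduces
binary-watershed splitting of touching convex cells; minimum particle area
100 px² (an uncalibrated-pixel reading of a "size 100–infinity" particle
filter; a µm² mode applies when a pixel size is supplied). Division by a
near-zero red pixel masks the pixel invalid rather than clamping it, and
cell means are taken over valid pixels only; labels are renumbered by
descending area with centroid tie-breaks so output ordering is
deterministic.

## AFM force curves

Force is F = k·d (nN for k in N/m, d in nm). The spherical-indenter Hertz
model with cantilever-deflection correction is

F = (4/3)·E/(1−ν²)·√R·δ^{3/2}, δ = (z − z₀) − F/k.

* **Contact point.** F^{2/3} is linear in the corrected position z − F/k
  everywhere past contact, at any spring constant — so the contact point is
  the z-intercept of a straight-line regression of F^{2/3} on z − F/k over
  the points with 10–90 % of the maximum force, refined once by restricting
  the window to points past the first-pass z₀. The 10 % floor keeps
  baseline noise out; the 90 % ceiling avoids deep-indentation
  nonlinearity. A curve must rise at least 10× above its baseline noise
  RMS (MAD of first differences) to be fit at all.
* **Modulus.** Nonlinear least squares of F = C·δ^{3/2} over the same
  window (δ > 0 enforced), initialized at the closed-form linear solution
  for C; E = 3C(1−ν²)/(4√R). With F in nN and δ, R in µm, E is in kPa.
  Poisson's ratio defaults to 0.5 (incompressible soft tissue) and enters
  only through the factor (1−ν²).
* **Grid.** `make_grid(side, spacing)` places floor(side/spacing) points
  per axis at cell centers; 10 µm at 0.5 µm spacing gives the 400-point
  map. A spacing wider than the side degenerates to the single center
  point.
* **Maps.** Per-curve failures (no contact, non-Hertzian window, δ ≤ 0)
  are counted and reported per curve; summary statistics cover successful
  fits only.

## Patch-clamp statistics

Inward currents are negative; the unitary current is reported as a
magnitude. The Δ statistic subtracts the *mean* of the inhibited group
from each basal cell, so mean(Δ) ≡ mean(basal) − mean(inhibited) exactly,
and the SEM uses the basal group's n (the reference mean is treated as a
constant). The unitary-current estimator fits a two-component Gaussian
mixture (k-means initialization, 10 restarts, fixed seed) to the all-points
amplitude histogram; it declares "no second level" when the minor
component's weight is below 1 % or when the mode separation does not exceed
twice the widest component SD — the resolvability condition a single noisy
level cannot meet. The estimate is invariant to constant offsets.

## ROUT outlier removal

For column data the robust "fit" is the median (the constant-model special
case of robust regression); the robust scale is
RSDR = P₆₈.₂₇(|residuals|) · n/(n−K) with K = 1, which simulation shows is
unbiased for σ within 1 % at n = 20. Residual t-ratios (df = n−K) are
tested from the most extreme inward against per-rank thresholds Q·i/n,
stopping at the first non-rejection, with at most 30 % of points
flaggable. Flagged points are always reported next to the kept ones.
Because the percentile-based scale estimate is noisier than the χ-based SD
the t reference distribution assumes, the realized dataset-wise false-flag
rate on clean normal data runs slightly above the nominal Q at small n
(≈1.4 % at Q = 1 %, n = 20); this is a property of the published
procedure's constants, and the flag-rate benchmark therefore uses 10⁵
replicates so the rate itself, not binomial noise, is what is measured.

## ΔΔCt

ΔCt = Ct(target) − Ct(housekeeping) per condition, ΔΔCt relative to the
reference condition, fold change 2^−ΔΔCt. Swapping sample and reference
inverts the fold change exactly.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *statistical structure* the estimators rely
on, with one explicit integer seed per call and bit-reproducible output.

* **Traces.** Gaussian baseline (default μ = 1.0, σ = 0.05 ratio units)
  over 100 pre- plus 300 post-stimulus frames at dt = 4.0 s — the
  experiment being emulated reports ~6 min of baseline over 100 frames and
  ~20 min over 300 frames, which imply slightly different frame clocks
  (3.6 vs 4.0 s); dt is therefore a single configurable value with 4.0 s
  as the documented default. An exact round(frac·n) subset of cells
  receives a transient A·(1 − e^{−s/τ_rise})·e^{−s/τ_decay} at a latency
  drawn from a normal (mean 40 s, SD 10 s) truncated at zero. Defaults
  A = 0.5 (10σ), τ_rise = 2 s (calcium influx rises within seconds),
  τ_decay = 600 s: a *sustained* agonist response, which is what makes a
  ≥25 %-of-300-frames responder criterion satisfiable by construction.
* **Stacks.** Disk-shaped stationary cells, constant red level 1000 with
  additive Gaussian noise (default σ = 10, i.e. 1 %), green = red × ratio
  trace. No point-spread function, photobleaching, motility, or Poisson
  photon statistics — the analysis under test assumes none of these, so
  passing recovery tests shows pipeline correctness, not robustness to
  optical artifacts.
* **Force curves.** Flat pre-contact baseline, Hertzian contact with the
  deflection coupling solved by fixed-point iteration (tolerance 10⁻⁶ nN,
  max 100 iterations; the map is strongly contractive for physical
  parameters), truncated at F_max = 300 nN; defaults R = 2.5 µm,
  k = 7.83 N/m, ν = 0.5, 1 nN force noise. No viscoelasticity, adhesion,
  or substrate (bottom) effects.
* **Patch records.** Two-state telegraph process with exponential dwell
  times (defaults 10 ms open / 20 ms closed at 5 kHz), unitary step
  −8 pA, Gaussian noise 0.5 pA. Kinetics are parameterized by dwell times;
  the open probability is the derived τ_o/(τ_o+τ_c), with an override for
  pinned-state controls. No capacitive transients or multi-channel
  superposition.
* **Group tables.** Gaussian per-cell current densities at specified
  (mean, SD, n).

Benchmark problem sizes (200-cell cohorts, 100-cell stacks, 50 curves per
modulus, 10⁵ outlier replicates) were chosen so each recovery statistic's
sampling noise is small against the tolerance it is checked to — they are
the package's validation conditions, stated here so they can be scaled up
or down deliberately.

## Known limitations

* The 25 % responder boundary is implemented inclusively; data exactly on
  the boundary are classified "responder" by that convention.
* The contact-point search assumes a single contact event and an
  approach-only curve; retraction/adhesion analysis is out of scope.
* The ROUT constant-model adaptation applies to univariate samples only,
  and its small-n false-flag rate modestly exceeds Q (see above).
* Proprietary microscope (`.czi`) and AFM vendor formats are not read;
  inputs are TIFF and CSV with JSON sidecars.
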