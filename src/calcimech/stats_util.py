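"""Cross-cutting study statistics: robust outlier removal, mean +/- SEM, and
the delta-delta-Ct fold-change transform for RT-qPCR.

The outlier routine is a univariate form of the ROUT procedure (robust fit +
outlier removal at a false-discovery rate Q): the robust "fit" of column data
is its median, the robust scale (RSDR) comes from the 68.27th percentile of
the absolute residuals with an n/(n-K) small-sample correction, and the
residual t-ratios are tested from the most extreme inward with
Benjamini-Hochberg-style per-rank thresholds Q*i/n, stopping at the first
non-rejection. At most 30 % of the points can be flagged.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats as sps

__all__ = [
    "OutlierReport",
    "MeanSem",
    "FoldChange",
    "rout_outliers",
    "mean_sem",
    "ddct",
]

#: percentile of |residuals| that estimates one SD for Gaussian data
_SD_PERCENTILE = 68.27
#: never flag more than this fraction of the sample
_MAX_OUTLIER_FRAC = 0.30


@dataclass(frozen=True)
class OutlierReport:
    """Partition of a sample into kept and flagged values.

    ``q_values`` gives, for each flagged point, its FDR-adjusted q (the
    t-tail p-value scaled by n/rank); flagged points always satisfy q < Q.
    """

    kept: np.ndarray
    flagged: np.ndarray
    q_values: np.ndarray
    Q: float
    center: float
    rsdr: float
    flagged_idx: np.ndarray = field(repr=False)

    @property
    def n_flagged(self) -> int:
        return self.flagged.size


def rout_outliers(values: np.ndarray, Q: float = 0.01) -> OutlierReport:
    """Flag outliers in column data at false-discovery rate Q (default 1 %).

    With fewer than 3 values no testing is possible; everything is kept and
    a warning is issued. Flagged points are reported alongside the kept
    ones, never silently deleted. The decision is invariant to affine
    transforms a*x + b (a != 0) of the data.
    """
    x = np.asarray(values, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    if not 0 < Q < 1:
        raise ValueError("Q must lie in (0, 1)")
    n = x.size
    if n < 3:
        warnings.warn("fewer than 3 values: outlier test skipped, all kept")
        return OutlierReport(
            kept=x,
            flagged=x[:0],
            q_values=x[:0],
            Q=Q,
            center=float(np.median(x)) if n else math.nan,
            rsdr=math.nan,
            flagged_idx=np.array([], dtype=int),
        )
    k_params = 1  # constant (median) model
    center = float(np.median(x))
    resid = x - center
    abs_resid = np.abs(resid)
    p68 = float(np.percentile(abs_resid, _SD_PERCENTILE))
    rsdr = p68 * n / (n - k_params)
    if rsdr == 0:
        # majority of points exactly at the median: any nonzero residual is
        # infinitely many robust SDs out
        flagged_idx = np.flatnonzero(abs_resid > 0)
        if flagged_idx.size > int(_MAX_OUTLIER_FRAC * n):
            flagged_idx = flagged_idx[
                np.argsort(abs_resid[flagged_idx])[::-1][: int(_MAX_OUTLIER_FRAC * n)]
            ]
        keep_mask = np.ones(n, dtype=bool)
        keep_mask[flagged_idx] = False
        return OutlierReport(
            kept=x[keep_mask],
            flagged=x[flagged_idx],
            q_values=np.zeros(flagged_idx.size),
            Q=Q,
            center=center,
            rsdr=0.0,
            flagged_idx=flagged_idx,
        )
    df = n - k_params
    t_ratio = abs_resid / rsdr
    pvals = 2.0 * sps.t.sf(t_ratio, df)
    order = np.argsort(abs_resid)[::-1]  # most extreme first
    max_flag = int(_MAX_OUTLIER_FRAC * n)
    flagged: list[int] = []
    qvals: list[float] = []
    for rank, idx in enumerate(order[:max_flag], start=1):
        threshold = Q * rank / n
        if pvals[idx] >= threshold:
            break
        flagged.append(int(idx))
        qvals.append(float(pvals[idx] * n / rank))
    flagged_idx = np.array(flagged, dtype=int)
    keep_mask = np.ones(n, dtype=bool)
    keep_mask[flagged_idx] = False
    return OutlierReport(
        kept=x[keep_mask],
        flagged=x[flagged_idx],
        q_values=np.array(qvals),
        Q=Q,
        center=center,
        rsdr=float(rsdr),
        flagged_idx=flagged_idx,
    )


@dataclass(frozen=True)
class MeanSem:
    mean: float
    sem: Optional[float]
    n: int


def mean_sem(values: np.ndarray) -> MeanSem:
    """Mean +/- standard error of the mean; SEM = sample SD (n-1) / sqrt(n).

    The SEM is absent (None) for a single value.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("cannot summarize an empty sample")
    if x.size == 1:
        return MeanSem(float(x[0]), None, 1)
    return MeanSem(
        float(x.mean()), float(x.std(ddof=1) / math.sqrt(x.size)), int(x.size)
    )


@dataclass(frozen=True)
class FoldChange:
    dct_sample: float
    dct_reference: float
    ddct: float
    fold: float


def ddct(
    ct_target: float,
    ct_housekeeping: float,
    ref_ct_target: float,
    ref_ct_housekeeping: float,
) -> FoldChange:
    """Relative qPCR quantification by the delta-delta-Ct method.

    dCt = Ct(target) - Ct(housekeeping) per condition;
    ddCt = dCt(sample) - dCt(reference); fold change = 2^(-ddCt).
    Swapping sample and reference inverts the fold change.
    """
    cts = (ct_target, ct_housekeeping, ref_ct_target, ref_ct_housekeeping)
    if not all(math.isfinite(c) for c in cts):
        raise ValueError("all Ct values must be finite")
    dct_s = ct_target - ct_housekeeping
    dct_r = ref_ct_target - ref_ct_housekeeping
    dd = dct_s - dct_r
    return FoldChange(dct_s, dct_r, dd, 2.0 ** (-dd))
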