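"""Expression-distribution comparison framework.

Implements the genotype-comparison machinery applied to FPKM tables:
the expressed-gene filter, the Fisher exact test on zero-expression
frequencies, the two-sample Kolmogorov-Smirnov comparison with the
D-obs/D-crit conjunction decision rule, log2 expression binning with
cumulative curves, and the Mann-Whitney rank comparison used per TE
superfamily.

Zeros never enter the K-S test or the histograms: they are diverted to
the zero-fraction contingency analysis, so the distributional tests see
only FPKM > 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = ["KSResult", "BinnedDistribution", "filter_expressed",
           "zero_fraction_test", "ks_compare", "binned_distribution",
           "max_cumulative_distance", "rank_compare", "KS_COEFF_ALPHA_001"]

# two-sample asymptotic K-S critical coefficient c(alpha):
# d_crit = c(alpha) * sqrt((n1 + n2) / (n1 * n2))
KS_COEFF_ALPHA_001 = 1.62762
_KS_COEFFS = {0.10: 1.22385, 0.05: 1.35810, 0.01: KS_COEFF_ALPHA_001}
P_FLOOR = 1e-15


@dataclass(frozen=True)
class KSResult:
    """Two-sample K-S outcome under the conjunction decision rule.

    The distributions are called different only when both D-obs exceeds
    the critical distance at ``alpha`` and the asymptotic p-value is
    below ``alpha``.
    """

    d_obs: float
    d_crit: float
    p: float
    n1: int
    n2: int
    alpha: float
    p_floored: bool = False
    warning: str | None = None

    @property
    def significant(self) -> bool:
        return self.d_obs > self.d_crit and self.p < self.alpha


@dataclass(frozen=True)
class BinnedDistribution:
    """Unit-width log2-FPKM histogram plus cumulative curve.

    Bin ``k`` covers log2 FPKM in ``[k - 0.5, k + 0.5)`` so that bin 0
    is centred on FPKM = 1, bin 2 on FPKM = 4, and so on.  Zeros are
    held apart in ``zero_fraction``; frequencies are normalised over the
    positive values only.
    """

    bin_centers: tuple[int, ...]
    frequencies: tuple[float, ...]
    cumulative: tuple[float, ...]
    zero_fraction: float
    n_positive: int


def filter_expressed(
    table: pd.DataFrame,
    status_cols: list[str] | None = None,
    fpkm_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Drop rows never testable: no OK status in any analysis.

    With ``status_cols`` present, a row survives iff at least one status
    is ``OK``.  Without statuses the FPKM fallback applies: keep rows
    with FPKM >= 1 in at least one genotype (the not-expressed rows
    roughly correspond to FPKM < 1 everywhere).
    """
    if status_cols is None:
        status_cols = [c for c in table.columns if c.startswith("status")]
    if status_cols:
        keep = (table[status_cols] == "OK").any(axis=1)
        return table.loc[keep].reset_index(drop=True)
    if fpkm_cols is None:
        fpkm_cols = [c for c in table.columns if c.startswith("fpkm")]
    if not fpkm_cols:
        raise ValueError("table has neither status nor FPKM columns")
    keep = (table[fpkm_cols] >= 1.0).any(axis=1)
    return table.loc[keep].reset_index(drop=True)


def zero_fraction_test(
    table: pd.DataFrame, genotypes: tuple[str, str] = ("wt", "mut")
) -> dict:
    """Fisher exact test on the 2x2 zero-vs-nonzero x genotype table.

    Compares the frequency of genes with 0 FPKM between genotypes.  The
    two-sided p sums hypergeometric probabilities no larger than that of
    the observed table (scipy's two-sided convention).
    """
    counts = []
    for g in genotypes:
        col = f"fpkm_{g}"
        if col not in table.columns:
            raise ValueError(f"missing column {col}")
        values = table[col].to_numpy()
        if values.size == 0:
            raise ValueError(f"no rows for genotype {g}")
        n_zero = int(np.count_nonzero(values == 0))
        counts.append([n_zero, int(values.size - n_zero)])
    contingency = np.asarray(counts)
    if contingency[0, 0] == 0 and contingency[1, 0] == 0:
        return {
            "table": contingency,
            "odds_ratio": None,
            "odds_ratio_undefined": True,
            "p": 1.0,
        }
    odds, p = stats.fisher_exact(contingency, alternative="two-sided")
    return {
        "table": contingency,
        "odds_ratio": float(odds),
        "odds_ratio_undefined": False,
        "p": float(p),
    }


def _ecdf_sup_distance(x: np.ndarray, y: np.ndarray) -> float:
    """sup_t |ECDF_x(t) - ECDF_y(t)| over the pooled sample points."""
    xs, ys = np.sort(x), np.sort(y)
    pooled = np.concatenate([xs, ys])
    cdf_x = np.searchsorted(xs, pooled, side="right") / xs.size
    cdf_y = np.searchsorted(ys, pooled, side="right") / ys.size
    return float(np.max(np.abs(cdf_x - cdf_y)))


def ks_compare(
    x, y, alpha: float = 0.01
) -> KSResult:
    """Two-sample K-S on positive FPKM samples with the conjunction rule.

    D-obs is the maximum vertical ECDF distance (computed on the raw
    values; it is invariant to the monotone log2 display transform),
    D-crit is ``c(alpha) * sqrt((n1 + n2)/(n1 * n2))``, and p comes from
    the asymptotic Kolmogorov distribution.  p is floored at 1e-15 and
    never reported as an exact zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("nonpositive FPKM values; remove zeros upstream")
    if alpha not in _KS_COEFFS:
        raise ValueError(f"alpha must be one of {sorted(_KS_COEFFS)}")
    n1, n2 = int(x.size), int(y.size)
    warning = "sample size below 8; asymptotics unreliable" if min(n1, n2) < 8 else None
    d_obs = _ecdf_sup_distance(x, y)
    en = np.sqrt(n1 * n2 / (n1 + n2))
    p = float(special.kolmogorov(en * d_obs))
    floored = p < P_FLOOR
    p = max(p, P_FLOOR)
    d_crit = _KS_COEFFS[alpha] * np.sqrt((n1 + n2) / (n1 * n2))
    return KSResult(
        d_obs=d_obs, d_crit=float(d_crit), p=p, n1=n1, n2=n2,
        alpha=alpha, p_floored=floored, warning=warning,
    )


def binned_distribution(fpkm) -> BinnedDistribution:
    """Histogram positive FPKM on integer-centred log2 bins.

    Zeros are split off into ``zero_fraction``; an all-zero sample
    yields empty bins with zero_fraction 1.
    """
    fpkm = np.asarray(fpkm, dtype=float)
    if np.any(fpkm < 0):
        raise ValueError("negative FPKM")
    n_total = fpkm.size
    positive = fpkm[fpkm > 0]
    zero_fraction = 1.0 - positive.size / n_total if n_total else 0.0
    if positive.size == 0:
        return BinnedDistribution((), (), (), zero_fraction, 0)
    # bin k covers [k - 0.5, k + 0.5) on the log2 scale
    bins = np.floor(np.log2(positive) + 0.5).astype(int)
    lo, hi = int(bins.min()), int(bins.max())
    centers = np.arange(lo, hi + 1)
    freq = np.bincount(bins - lo, minlength=centers.size) / positive.size
    cum = np.cumsum(freq)
    return BinnedDistribution(
        bin_centers=tuple(int(c) for c in centers),
        frequencies=tuple(float(f) for f in freq),
        cumulative=tuple(float(c) for c in cum),
        zero_fraction=float(zero_fraction),
        n_positive=int(positive.size),
    )


def max_cumulative_distance(a: BinnedDistribution, b: BinnedDistribution) -> float:
    """Maximum vertical distance between two cumulative curves, percent.

    The two curves are evaluated on the union bin grid (a cumulative
    curve is a step function: 0 below its first bin, 1 above its last).
    """
    if not a.bin_centers and not b.bin_centers:
        return 0.0
    grid = sorted(set(a.bin_centers) | set(b.bin_centers))

    def cum_at(dist: BinnedDistribution, k: int) -> float:
        if not dist.bin_centers:
            return 1.0
        if k < dist.bin_centers[0]:
            return 0.0
        if k >= dist.bin_centers[-1]:
            return 1.0
        idx = k - dist.bin_centers[0]
        return dist.cumulative[idx]

    return 100.0 * max(abs(cum_at(a, k) - cum_at(b, k)) for k in grid)


def rank_compare(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U for x versus y.

    Exact enumeration when ``n1 * n2 <= 400`` and there are no cross-
    sample ties; otherwise the tie-corrected normal approximation with
    continuity correction.  Returns (U statistic for x, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    has_ties = np.intersect1d(x, y).size > 0 or (
        np.unique(x).size < x.size or np.unique(y).size < y.size
    )
    method = "exact" if (x.size * y.size <= 400 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)
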