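"""Shared statistics: rank correlations on masked lower triangles, Fisher z,
group t-tests with effect sizes, and residual-based partial correlation.

Scalar tests delegate to scipy.stats; the only hand-rolled numerics are the
batched rank transform used inside permutation loops (verified against
scipy.stats.spearmanr in the test suite) and the partial correlation, which
is defined here directly as the Pearson correlation of covariate residuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .types import ConfigError, SimilarityMatrix

FISHER_CLIP = 1.0 - 1e-7


def fisher_z(r) -> np.ndarray | float:
    """atanh with |r| clipped to 1 - 1e-7 so z stays finite."""
    return np.arctanh(np.clip(r, -FISHER_CLIP, FISHER_CLIP))


def rankdata_rows(x: np.ndarray) -> np.ndarray:
    """Average ranks along the last axis for a 2-D batch."""
    return sps.rankdata(x, axis=-1)


def pearson_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation between (B, n) x and (n,) or (B, n) y."""
    x = x - x.mean(axis=-1, keepdims=True)
    y = y - y.mean(axis=-1, keepdims=True)
    num = (x * y).sum(axis=-1)
    den = np.sqrt((x * x).sum(axis=-1) * (y * y).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def spearman_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Spearman rho (average ranks on ties) for a 2-D batch."""
    return pearson_rows(rankdata_rows(np.atleast_2d(x)),
                        rankdata_rows(np.atleast_2d(y)))


def masked_lower_triangles(a: SimilarityMatrix, b: SimilarityMatrix,
                           min_cells: int = 3):
    """Vectors of strictly-lower-triangle values at the intersection of the
    two matrices' masks. Raises if fewer than ``min_cells`` cells remain."""
    rows, cols = np.tril_indices(a.n, k=-1)
    if b.n != a.n:
        raise ConfigError("matrices must share the event dimension")
    ok = a.mask[rows, cols] & b.mask[rows, cols]
    if ok.sum() < min_cells:
        raise ConfigError(
            f"only {int(ok.sum())} jointly masked lower-triangle cells "
            f"(need >= {min_cells})")
    r, c = rows[ok], cols[ok]
    return a.values[r, c], b.values[r, c]


def spearman_masked(a: SimilarityMatrix, b: SimilarityMatrix,
                    min_cells: int = 3) -> float:
    """Spearman rho over the jointly masked strictly-lower triangles."""
    va, vb = masked_lower_triangles(a, b, min_cells)
    rho, _ = sps.spearmanr(va, vb)
    return float(rho)


# ---------------------------------------------------------------------------
# Group tests


@dataclass
class GroupTest:
    t: float
    p: float
    df: int
    cohen_d: float
    ci_low: float
    ci_high: float
    degenerate: bool = False


def _d_ci(d: float, n: int, level: float = 0.95):
    """Approximate CI of a standardized one-sample/paired difference via the
    large-sample variance of d (Hedges & Olkin form)."""
    se = np.sqrt(1.0 / n + d * d / (2.0 * n))
    zc = sps.norm.ppf(0.5 + level / 2.0)
    return d - zc * se, d + zc * se


def one_sample_test(values, popmean: float = 0.0,
                    alternative: str = "two-sided") -> GroupTest:
    """One-sample t-test against ``popmean`` with Cohen's d and 95% CI of d."""
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise ConfigError("one-sample test needs n >= 3")
    sd = x.std(ddof=1)
    if sd == 0:
        return GroupTest(t=0.0 if x.mean() == popmean else np.inf,
                         p=np.nan, df=n - 1, cohen_d=np.nan,
                         ci_low=np.nan, ci_high=np.nan, degenerate=True)
    res = sps.ttest_1samp(x, popmean, alternative=alternative)
    d = float((x.mean() - popmean) / sd)
    lo, hi = _d_ci(d, n)
    return GroupTest(t=float(res.statistic), p=float(res.pvalue), df=n - 1,
                     cohen_d=d, ci_low=float(lo), ci_high=float(hi))


def paired_test(a, b, alternative: str = "two-sided") -> GroupTest:
    """Paired t-test (equivalently one-sample on differences a - b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ConfigError("paired samples must have equal length")
    return one_sample_test(a - b, 0.0, alternative=alternative)


# ---------------------------------------------------------------------------
# Partial correlation


def _residualize(y: np.ndarray, z: np.ndarray) -> np.ndarray:
    zd = np.column_stack([np.ones(len(y)), z])
    beta, *_ = np.linalg.lstsq(zd, y, rcond=None)
    return y - zd @ beta


def partial_correlation(x, y, covariates=None,
                        alternative: str = "greater"):
    """Pearson correlation of x and y after linearly removing covariates.

    One-tailed by default (positive association), with df = n - k - 2 where k
    is the number of covariates. With no covariates this reduces to the plain
    Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None or (np.size(covariates) == 0):
        z = np.empty((x.size, 0))
    else:
        z = np.atleast_2d(np.asarray(covariates, dtype=float))
        if z.shape[0] != x.size:
            z = z.T
        if z.shape[0] != x.size:
            raise ConfigError("covariates must align with x/y")
    n, k = x.size, z.shape[1]
    if n <= k + 2:
        raise ConfigError("need n > n_covariates + 2")
    if k:
        zc = z - z.mean(axis=0)
        if np.linalg.matrix_rank(np.column_stack([np.ones(n), zc])) < k + 1:
            raise ConfigError("collinear covariates")
        sx, sy = x.std(), y.std()
        x = _residualize(x, z)
        y = _residualize(y, z)
        # a variable fully explained by the covariates has no residual
        # variance left to correlate
        if x.std() <= 1e-10 * max(sx, 1.0) or y.std() <= 1e-10 * max(sy, 1.0):
            x = np.zeros_like(x)
    r = float(pearson_rows(x[None, :], y[None, :])[0])
    if not np.isfinite(r):
        r = 0.0
    df = n - k - 2
    r_c = np.clip(r, -FISHER_CLIP, FISHER_CLIP)
    t = r_c * np.sqrt(df / (1.0 - r_c * r_c))
    if alternative == "greater":
        p = float(sps.t.sf(t, df))
    elif alternative == "less":
        p = float(sps.t.cdf(t, df))
    else:
        p = float(2 * sps.t.sf(abs(t), df))
    return r, p


# ---------------------------------------------------------------------------
# Jaccard


def jaccard(a, b) -> float:
    """|a AND b| / |a OR b| for binary vectors; two empty vectors give 0
    (no shared recall signal)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ConfigError("binary vectors must share length")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)
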