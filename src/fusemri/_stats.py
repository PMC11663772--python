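"""Vectorized statistical primitives for the per-fold feature screens.

The nested cross-validation reruns the univariate screen (Shapiro-Wilk
normality gate, pooled two-sample t, Wilcoxon rank-sum) on every inner
training fold, and the permutation test reruns the whole pipeline hundreds
of times.  These column-vectorized implementations keep that affordable.
Each one reproduces the corresponding scipy routine (same algorithm, same
approximations) and is checked against it in the test suite:

- ``shapiro_pvalues``    ~ scipy.stats.shapiro       (Royston 1995, AS R94)
- ``ttest_ind_columns``  ~ scipy.stats.ttest_ind     (pooled variance)
- ``ranksum_columns``    ~ scipy.stats.ranksums      (normal approximation)
- ``auc_from_scores``    ~ Mann-Whitney pair counting, ties count 1/2
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import special as _spec
from scipy import stats as _sps

__all__ = [
    "shapiro_pvalues",
    "ttest_ind_columns",
    "ranksum_columns",
    "auc_from_scores",
    "benjamini_hochberg",
]

# Royston's polynomial coefficients for the weights of the two extreme
# order statistics (AS R94).
_C1 = np.array([-2.706056, 4.434685, -2.071190, -0.147981, 0.221157])
_C2 = np.array([-3.582633, 5.682633, -1.752461, -0.293762, 0.042981])


@lru_cache(maxsize=None)
def _shapiro_weights(n: int) -> np.ndarray:
    """Approximate coefficients a_i of the Shapiro-Wilk W statistic."""
    if n == 3:
        r = np.sqrt(0.5)
        return np.array([-r, 0.0, r])
    i = np.arange(1, n + 1)
    m = _sps.norm.ppf((i - 0.375) / (n + 0.25))
    ssq = float(m @ m)
    rsn = 1.0 / np.sqrt(n)
    a = m.copy()
    an = np.polyval(_C1, rsn) * rsn + m[-1] / np.sqrt(ssq)
    if n > 5:
        an1 = np.polyval(_C2, rsn) * rsn + m[-2] / np.sqrt(ssq)
        phi = (ssq - 2 * m[-1] ** 2 - 2 * m[-2] ** 2) / (
            1 - 2 * an**2 - 2 * an1**2
        )
        a /= np.sqrt(phi)
        a[-1], a[-2] = an, an1
        a[0], a[1] = -an, -an1
    else:
        phi = (ssq - 2 * m[-1] ** 2) / (1 - 2 * an**2)
        a /= np.sqrt(phi)
        a[-1] = an
        a[0] = -an
    return a


def shapiro_pvalues(X: np.ndarray) -> np.ndarray:
    """Shapiro-Wilk p-value per column of ``X`` (shape n x p, n >= 3).

    Implements Royston's AS R94 approximation (the algorithm behind
    ``scipy.stats.shapiro``) vectorized over columns.  Columns with zero
    range return p = 0 (treated as maximally non-normal by the gate).
    """
    X = np.asarray(X, dtype=np.float64)
    n, p = X.shape
    if n < 3:
        raise ValueError("Shapiro-Wilk requires at least 3 observations")
    xs = np.sort(X, axis=0)
    rng = xs[-1] - xs[0]
    a = _shapiro_weights(n)
    num = (a @ xs) ** 2
    den = ((X - X.mean(axis=0)) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        W = np.where(den > 0, num / den, 0.0)
    W = np.clip(W, 0.0, 1.0 - 1e-12)

    if n == 3:
        pw = 6.0 / np.pi * (np.arcsin(np.sqrt(W)) - np.arcsin(np.sqrt(0.75)))
        pw = np.clip(pw, 0.0, 1.0)
    elif n <= 11:
        gamma = -2.273 + 0.459 * n
        wln = -np.log(np.maximum(gamma - np.log1p(-W), 1e-300))
        mu = 0.5440 - 0.39978 * n + 0.025054 * n**2 - 0.0006714 * n**3
        sigma = np.exp(1.3822 - 0.77857 * n + 0.062767 * n**2 - 0.0020322 * n**3)
        pw = _spec.ndtr(-(wln - mu) / sigma)
    else:
        ln_n = np.log(n)
        wln = np.log1p(-W)
        mu = -1.5861 - 0.31082 * ln_n - 0.083751 * ln_n**2 + 0.0038915 * ln_n**3
        sigma = np.exp(-0.4803 - 0.082676 * ln_n + 0.0030302 * ln_n**2)
        pw = _spec.ndtr(-(wln - mu) / sigma)
    return np.where(rng > 0, pw, 0.0)


def ttest_ind_columns(A: np.ndarray, B: np.ndarray):
    """Pooled-variance two-sample t statistic and two-sided p, per column."""
    A = np.asarray(A, dtype=np.float64)
    B = np.asarray(B, dtype=np.float64)
    na, nb = A.shape[0], B.shape[0]
    df = na + nb - 2
    va = A.var(axis=0, ddof=1)
    vb = B.var(axis=0, ddof=1)
    sp = np.sqrt(((na - 1) * va + (nb - 1) * vb) / df)
    denom = sp * np.sqrt(1.0 / na + 1.0 / nb)
    diff = A.mean(axis=0) - B.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, diff / denom, 0.0)
    p = 2.0 * _spec.stdtr(df, -np.abs(t))
    return t, p


def _rankdata_columns(X: np.ndarray) -> np.ndarray:
    """Average ranks per column; fast ordinal path when a column has no ties."""
    n = X.shape[0]
    order = np.argsort(X, axis=0, kind="stable")
    ranks = np.empty_like(X)
    np.put_along_axis(ranks, order, np.arange(1.0, n + 1)[:, None], axis=0)
    xs = np.take_along_axis(X, order, axis=0)
    tied = (np.diff(xs, axis=0) == 0).any(axis=0)
    for c in np.where(tied)[0]:
        ranks[:, c] = _sps.rankdata(X[:, c])
    return ranks


def ranksum_columns(A: np.ndarray, B: np.ndarray):
    """Wilcoxon rank-sum z statistic and two-sided p, per column.

    Normal approximation without tie or continuity correction, matching
    ``scipy.stats.ranksums``.
    """
    A = np.asarray(A, dtype=np.float64)
    B = np.asarray(B, dtype=np.float64)
    na, nb = A.shape[0], B.shape[0]
    n = na + nb
    ranks = _rankdata_columns(np.vstack([A, B]))
    r1 = ranks[:na].sum(axis=0)
    expected = na * (n + 1) / 2.0
    sd = np.sqrt(na * nb * (n + 1) / 12.0)
    z = (r1 - expected) / sd
    p = 2.0 * _spec.ndtr(-np.abs(z))
    return z, p


def auc_from_scores(scores: np.ndarray, y: np.ndarray) -> float:
    """AUC of continuous scores for binary labels, Mann-Whitney convention.

    ``y`` is boolean/0-1 with 1 the positive class; tied scores between a
    positive and a negative count 1/2 of a concordant pair.
    """
    scores = np.asarray(scores, dtype=np.float64)
    y = np.asarray(y).astype(bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: one class absent")
    ranks = _rankdata_columns(scores[:, None])[:, 0]
    r_pos = ranks[y].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def benjamini_hochberg(pvalues: np.ndarray, alpha: float = 0.05):
    """BH step-up FDR decision and adjusted p-values.

    Thin wrapper over statsmodels' ``multipletests(method='fdr_bh')``.
    """
    from statsmodels.stats.multitest import multipletests

    pvalues = np.asarray(pvalues, dtype=np.float64)
    if pvalues.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    reject, p_adj, _, _ = multipletests(pvalues, alpha=alpha, method="fdr_bh")
    return reject, p_adj
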