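"""Double feature ranking: univariate screen, then MRMR or CV-SVM.

The pipeline selects features in two stages inside every training fold:

1. **Initial selection** — per element, a two-sample test of group
   difference picks the ``k_initial`` smallest p-values.  The test is a
   pooled-variance t-test when both class samples pass a Shapiro-Wilk
   normality check (alpha = 0.05), a Wilcoxon rank-sum test otherwise.
2. **Final ranking** — the surviving elements are ordered either by
   minimum-redundancy-maximum-relevance (MRMR) or by the sparse
   separating plane of feature selection via concave minimization with a
   linear SVM (CV-SVM).  Candidate models then grow the ranked list one
   element at a time up to ``k_final``.

All orderings are deterministic: ties break by p-value, then |statistic|,
then element index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from ._stats import ranksum_columns, shapiro_pvalues, ttest_ind_columns
from .errors import ParameterError

__all__ = [
    "RankingConfig",
    "RankingResult",
    "univariate_screen",
    "univariate_rank",
    "mrmr_rank",
    "cvsvm_rank",
    "double_rank",
    "incremental_candidates",
]


@dataclass
class RankingConfig:
    """Settings for the double ranking procedure.

    ``k_initial=None`` means "All": no initial truncation.
    """

    method: str = "mrmr"           # "mrmr" or "cvsvm"
    k_initial: int | None = 10
    k_final: int = 5
    sw_alpha: float = 0.05
    cvsvm_alpha: float = 5.0       # steepness of the concave penalty
    cvsvm_lambda: float = 0.5      # error-vs-sparsity trade-off
    cvsvm_max_iter: int = 50

    def validate(self) -> None:
        if self.method not in ("mrmr", "cvsvm"):
            raise ParameterError(f"unknown ranking method {self.method!r}")
        if self.k_final < 1:
            raise ParameterError("k_final must be >= 1")
        if self.k_initial is not None and self.k_initial < self.k_final:
            raise ParameterError("k_final cannot exceed k_initial")


@dataclass
class RankingResult:
    order: np.ndarray          # element indices, best first
    scores: np.ndarray         # per-element score aligned with ``order``
    method: str
    k_initial: int | None = None
    flags: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.order)


def _split(X, y):
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ParameterError("need exactly two classes")
    return X[y == classes[0]], X[y == classes[1]]


def univariate_screen(X: np.ndarray, y: np.ndarray, sw_alpha: float = 0.05):
    """Per-element group-difference p-values with a normality gate.

    Returns ``(p, stat, used_ranksum, flags)``.  With fewer than 3
    observations in a class the Shapiro-Wilk gate cannot run and the
    rank-sum branch is used throughout (flagged).
    """
    X = np.asarray(X, dtype=np.float64)
    A, B = _split(X, y)
    flags = []
    if len(A) < 3 or len(B) < 3:
        flags.append("normality gate skipped: a class has <3 observations")
        normal = np.zeros(X.shape[1], dtype=bool)
    else:
        normal = (shapiro_pvalues(A) > sw_alpha) & (shapiro_pvalues(B) > sw_alpha)
    t, pt = ttest_ind_columns(A, B)
    z, pz = ranksum_columns(A, B)
    p = np.where(normal, pt, pz)
    stat = np.where(normal, t, z)
    return p, stat, ~normal, flags


def _ordered_by_p(p: np.ndarray, stat: np.ndarray) -> np.ndarray:
    # ascending p, then descending |stat|, then index
    return np.lexsort((np.arange(p.size), -np.abs(stat), p))


def univariate_rank(X: np.ndarray, y: np.ndarray, k_initial: int | None = None,
                    sw_alpha: float = 0.05) -> RankingResult:
    """Initial selection: the ``k_initial`` most significant elements."""
    p, stat, _, flags = univariate_screen(X, y, sw_alpha)
    order = _ordered_by_p(p, stat)
    if k_initial is not None:
        order = order[:k_initial]
    return RankingResult(order, p[order], "univariate", k_initial, flags)


def mrmr_rank(X: np.ndarray, y: np.ndarray, candidates=None) -> RankingResult:
    """Greedy minimum-redundancy-maximum-relevance ordering.

    Relevance is the absolute point-biserial correlation of an element
    with the class labels; redundancy the mean absolute Pearson
    correlation with the elements already chosen (difference form).
    Both terms live on the same [0, 1] scale, so a perfect duplicate of
    a chosen element (redundancy 1) is always pushed behind any weakly
    relevant independent element.  Features here are continuous and
    cohorts small, so this correlation form replaces the histogram
    mutual information of the discrete formulation.  Deterministic:
    exact score ties resolve to the lowest element index.
    """
    X = np.asarray(X, dtype=np.float64)
    cand = np.arange(X.shape[1]) if candidates is None else np.asarray(candidates)
    Xc = X[:, cand]
    y01 = np.asarray(y)
    y01 = (y01 == np.unique(y01)[1]).astype(np.float64)
    yc = y01 - y01.mean()
    Xd = Xc - Xc.mean(axis=0)
    denom = np.sqrt((Xd**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        relevance = np.abs(np.where(denom > 0, Xd.T @ yc / denom, 0.0))
    m = len(cand)
    if m == 1:
        return RankingResult(cand.copy(), relevance, "mrmr")
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.abs(np.corrcoef(Xc, rowvar=False))
    corr[~np.isfinite(corr)] = 0.0  # constant columns carry no redundancy
    chosen = [int(np.argmax(relevance))]
    scores = [float(relevance[chosen[0]])]
    remaining = [j for j in range(m) if j != chosen[0]]
    red_sum = corr[:, chosen[0]].copy()
    while remaining:
        rem = np.array(remaining)
        score = relevance[rem] - red_sum[rem] / len(chosen)
        best = int(rem[np.argmax(score)])
        chosen.append(best)
        scores.append(float(score[np.argmax(score)]))
        remaining.remove(best)
        red_sum += corr[:, best]
    return RankingResult(cand[np.array(chosen)], np.array(scores), "mrmr")


def _fsv_lp(A: np.ndarray, B: np.ndarray, v_cost: np.ndarray, lam: float):
    """One linearized step of the concave feature-selection program.

    Variables: w (n), gamma (1), slacks y (m1), z (m2), v (n).
    min (1-lam)(sum y/m1 + sum z/m2) + v_cost . v
    s.t.  -A w + gamma + 1 <= y ;  B w - gamma + 1 <= z ;  |w| <= v.
    """
    m1, n = A.shape
    m2 = B.shape[0]
    n_var = n + 1 + m1 + m2 + n
    c = np.zeros(n_var)
    c[n + 1:n + 1 + m1] = (1.0 - lam) / m1
    c[n + 1 + m1:n + 1 + m1 + m2] = (1.0 - lam) / m2
    c[n + 1 + m1 + m2:] = v_cost

    rows = m1 + m2 + 2 * n
    A_ub = np.zeros((rows, n_var))
    b_ub = np.empty(rows)
    A_ub[:m1, :n] = -A
    A_ub[:m1, n] = 1.0
    A_ub[:m1, n + 1:n + 1 + m1] = -np.eye(m1)
    b_ub[:m1] = -1.0
    A_ub[m1:m1 + m2, :n] = B
    A_ub[m1:m1 + m2, n] = -1.0
    A_ub[m1:m1 + m2, n + 1 + m1:n + 1 + m1 + m2] = -np.eye(m2)
    b_ub[m1:m1 + m2] = -1.0
    r0 = m1 + m2
    A_ub[r0:r0 + n, :n] = np.eye(n)
    A_ub[r0:r0 + n, n + 1 + m1 + m2:] = -np.eye(n)
    b_ub[r0:r0 + n] = 0.0
    A_ub[r0 + n:, :n] = -np.eye(n)
    A_ub[r0 + n:, n + 1 + m1 + m2:] = -np.eye(n)
    b_ub[r0 + n:] = 0.0

    bounds = [(None, None)] * (n + 1) + [(0, None)] * (m1 + m2 + n)
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=bounds, method="highs")
    return res


def cvsvm_rank(X: np.ndarray, y: np.ndarray, candidates=None,
               alpha: float = 5.0, lam: float = 0.5,
               max_iter: int = 50, tol: float = 1e-6) -> RankingResult:
    """Feature ordering from the concave-minimization sparse plane.

    Solves the feature-selection-via-concave-minimization program: a
    separating plane that trades the average bound-plane violation of
    the two classes against the (concave, exponentially approximated)
    count of nonzero weights, by successive linear programming.
    Elements are ordered by descending |weight|; zero-weight elements
    follow, ordered by univariate p-value.
    """
    X = np.asarray(X, dtype=np.float64)
    cand = np.arange(X.shape[1]) if candidates is None else np.asarray(candidates)
    Xc = X[:, cand]
    A, B = _split(Xc, y)
    n = Xc.shape[1]
    flags = []
    v = np.zeros(n)
    w = np.zeros(n)
    prev_obj = np.inf
    prev_support = None
    for it in range(max_iter):
        if it == 0:
            # plain 1-norm warm start; the steep exponential cost at v = 0
            # would otherwise lock the all-zero plane in immediately
            v_cost = lam * np.ones(n)
        else:
            v_cost = lam * alpha * np.exp(-alpha * v)
        res = _fsv_lp(A, B, v_cost, lam)
        if not res.success:
            flags.append(f"LP failed ({res.status}); kept previous iterate")
            break
        w = res.x[:n]
        v = res.x[-n:]
        obj = (1.0 - lam) * (
            res.x[n + 1:n + 1 + A.shape[0]].sum() / A.shape[0]
            + res.x[n + 1 + A.shape[0]:n + 1 + A.shape[0] + B.shape[0]].sum() / B.shape[0]
        ) + lam * np.sum(1.0 - np.exp(-alpha * v))
        support = frozenset(np.where(np.abs(w) > 1e-8)[0])
        if support == prev_support and prev_obj - obj < tol:
            break
        prev_obj, prev_support = obj, support
    else:
        flags.append("concave program did not converge; using last iterate")

    absw = np.abs(w)
    nonzero = absw > 1e-8
    p, stat, _, _ = univariate_screen(Xc, y)
    # nonzero weights first (by |w| desc, ties by index), then the rest by p
    nz_order = np.lexsort((np.arange(n), -absw))
    nz_order = nz_order[nonzero[nz_order]]
    rest = np.array([j for j in _ordered_by_p(p, stat) if not nonzero[j]], dtype=int)
    order = np.concatenate([nz_order, rest]) if rest.size else nz_order
    scores = np.concatenate([absw[nz_order], -p[rest] if rest.size else []])
    return RankingResult(cand[order], scores, "cvsvm", flags=flags)


def double_rank(X: np.ndarray, y: np.ndarray, cfg: RankingConfig) -> np.ndarray:
    """Initial univariate selection followed by the final ranking.

    Returns ordered element indices (length <= k_initial).  Only training
    data may be passed here; the engine enforces that.
    """
    cfg.validate()
    p, stat, _, _ = univariate_screen(X, y, cfg.sw_alpha)
    order = _ordered_by_p(p, stat)
    if cfg.k_initial is not None:
        order = order[:cfg.k_initial]
    if len(order) <= 1:
        return order
    if cfg.method == "mrmr":
        final = mrmr_rank(X, y, candidates=order)
    else:
        final = cvsvm_rank(
            X, y, candidates=initial.order, alpha=cfg.cvsvm_alpha,
            lam=cfg.cvsvm_lambda, max_iter=cfg.cvsvm_max_iter,
        )
    return final.order


def incremental_candidates(order: np.ndarray, k_final: int) -> list:
    """Nested prefix sets of sizes 1..min(k_final, len(order))."""
    if len(order) == 0:
        raise ParameterError("empty ranking")
    kmax = min(k_final, len(order))
    return [np.asarray(order[:k]) for k in range(1, kmax + 1)]
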