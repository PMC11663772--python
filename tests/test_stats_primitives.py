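"""The vectorized statistics must reproduce their scipy/sklearn references.

These primitives sit inside the per-fold loops; correctness is anchored
to the library implementations they replace (dual-route checks).
"""

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC

from fusemri._stats import (auc_from_scores, benjamini_hochberg,
                            ranksum_columns, shapiro_pvalues,
                            ttest_ind_columns)
from fusemri._svm import linear_svm_fit


@pytest.mark.parametrize("n", [3, 4, 5, 7, 8, 11, 12, 25, 60])
def test_shapiro_matches_scipy(n, rng):
    X = rng.normal(size=(n, 24))
    X[:, :8] = rng.exponential(size=(n, 8))
    X[:, 8:12] = rng.standard_cauchy(size=(n, 4))
    ref = np.array([stats.shapiro(X[:, j]).pvalue for j in range(X.shape[1])])
    np.testing.assert_allclose(shapiro_pvalues(X), ref, atol=1e-6)


def test_shapiro_constant_column_is_nonnormal(rng):
    X = rng.normal(size=(10, 3))
    X[:, 1] = 4.2
    assert shapiro_pvalues(X)[1] == 0.0


def test_ttest_and_ranksum_match_scipy(rng):
    A = rng.normal(size=(9, 30))
    B = rng.normal(0.4, 1.3, size=(13, 30))
    A[:, :6] = np.round(A[:, :6])  # provoke ties in the rank path
    B[:, :6] = np.round(B[:, :6])
    t, pt = ttest_ind_columns(A, B)
    tr, pr = stats.ttest_ind(A, B, axis=0)
    np.testing.assert_allclose(t, tr, rtol=1e-12)
    np.testing.assert_allclose(pt, pr, rtol=1e-10)
    z, pz = ranksum_columns(A, B)
    for j in range(30):
        ref = stats.ranksums(A[:, j], B[:, j])
        assert z[j] == pytest.approx(ref.statistic, abs=1e-12)
        assert pz[j] == pytest.approx(ref.pvalue, abs=1e-12)


def _auc_pair_counting(scores, y):
    """Brute-force Mann-Whitney oracle: ties count 1/2."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def test_auc_worked_example():
    scores = np.array([0.9, 0.8, 0.4, 0.2])
    y = np.array([1, 1, 0, 1])
    assert auc_from_scores(scores, y) == pytest.approx(2 / 3)


def test_auc_matches_pair_counting_and_sklearn(rng):
    for _ in range(20):
        n = int(rng.integers(6, 20))
        scores = np.round(rng.normal(size=n), 1)  # ties likely
        y = rng.integers(0, 2, n)
        if y.sum() in (0, n):
            continue
        a = auc_from_scores(scores, y)
        assert a == pytest.approx(_auc_pair_counting(scores, y), abs=1e-12)
        assert a == pytest.approx(roc_auc_score(y, scores), abs=1e-12)


def test_auc_requires_both_classes():
    with pytest.raises(ValueError):
        auc_from_scores(np.array([1.0, 2.0]), np.array([1, 1]))


def _bh_brute_force(p, alpha):
    """Benjamini-Hochberg by its step-up definition."""
    m = len(p)
    order = np.argsort(p)
    k_star = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * alpha / m:
            k_star = rank
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject


def test_bh_worked_examples():
    p = np.array([0.001, 0.01, 0.02, 0.03, 0.04])
    reject, _ = benjamini_hochberg(p, alpha=0.05)
    assert reject.all()
    reject, _ = benjamini_hochberg(np.ones(10), alpha=0.05)
    assert not reject.any()


def test_bh_matches_definition_and_dominates_bonferroni(rng):
    for _ in range(25):
        m = int(rng.integers(1, 20))
        p = rng.random(m)
        reject, _ = benjamini_hochberg(p, alpha=0.05)
        assert np.array_equal(reject, _bh_brute_force(p, 0.05))
        bonf = p <= 0.05 / m
        assert np.all(reject[bonf])  # BH rejections cover Bonferroni's


def _primal_objective(w, b, X, y, C=1.0):
    margins = 1 - y * (X @ w + b)
    return 0.5 * w @ w + C * np.maximum(margins, 0).sum()


def test_svm_matches_sklearn(rng):
    """Same C-SVC dual as libsvm: objectives agree to solver tolerance."""
    for seed in range(15):
        r = np.random.default_rng(seed)
        n, k = int(r.integers(8, 40)), int(r.integers(1, 6))
        X = r.normal(size=(n, k))
        y = np.where(r.random(n) < 0.5, -1.0, 1.0)
        if not (np.any(y > 0) and np.any(y < 0)):
            continue
        X[y > 0] += r.normal(0.5, 0.5, size=k)
        w, b = linear_svm_fit(X, y, C=1.0)
        svc = SVC(kernel="linear", C=1.0).fit(X, y)
        mine = _primal_objective(w, b, X, y)
        ref = _primal_objective(svc.coef_.ravel(), svc.intercept_[0], X, y)
        assert mine == pytest.approx(ref, abs=2e-3, rel=1e-3)


def test_svm_single_class_rejected():
    X = np.ones((4, 2))
    with pytest.raises(ValueError):
        linear_svm_fit(X, np.ones(4))
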