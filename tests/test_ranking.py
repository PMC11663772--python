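"""Double feature ranking: univariate gate, MRMR, CV-SVM, prefixes."""

import numpy as np
import pytest

from fusemri import (RankingConfig, cvsvm_rank, double_rank,
                     incremental_candidates, mrmr_rank, univariate_rank)
from fusemri.ranking import univariate_screen
from fusemri.errors import ParameterError


def test_identical_samples_ranked_last(rng):
    X = rng.normal(size=(20, 5))
    X[:10, 2] = X[10:, 2]  # element 2 identical across groups
    y = np.array([0] * 10 + [1] * 10)
    rr = univariate_rank(X, y)
    assert rr.order[-1] == 2
    assert rr.scores[-1] == pytest.approx(1.0, abs=1e-9)


def test_planted_dominant_element_ranked_first():
    hits = 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(40, 30))
        y = np.array([0] * 20 + [1] * 20)
        X[y == 1, 7] += 3.0
        hits += univariate_rank(X, y).order[0] == 7
    assert hits >= 95


def test_heavy_tailed_element_uses_ranksum(rng):
    X = rng.normal(size=(30, 3))
    X[:, 1] = rng.standard_cauchy(30) * 50
    y = np.array([0] * 15 + [1] * 15)
    _, _, used_ranksum, _ = univariate_screen(X, y)
    assert used_ranksum[1]


def test_tiny_class_skips_gate(rng):
    X = rng.normal(size=(6, 4))
    y = np.array([0, 0, 0, 0, 1, 1])
    _, _, used_ranksum, flags = univariate_screen(X, y)
    assert used_ranksum.all()
    assert any("gate skipped" in f for f in flags)


def test_mrmr_penalizes_exact_copy(rng):
    f = rng.normal(size=40)
    y = np.array([0] * 20 + [1] * 20)
    f[y == 1] += 2.0
    X = np.column_stack([f, f.copy(), rng.normal(size=40)])
    rr = mrmr_rank(X, y)
    assert rr.order[0] in (0, 1)
    assert rr.order[1] == 2  # the copy never comes second


def test_mrmr_single_candidate(rng):
    X = rng.normal(size=(12, 4))
    y = np.array([0] * 6 + [1] * 6)
    rr = mrmr_rank(X, y, candidates=np.array([2]))
    assert list(rr.order) == [2]


def _mrmr_oracle(X, y):
    """Independent greedy re-implementation (relevance - mean |corr|)."""
    m = X.shape[1]
    rel = np.array([
        abs(np.corrcoef(X[:, j], y)[0, 1]) for j in range(m)
    ])
    chosen = [int(np.argmax(rel))]
    while len(chosen) < m:
        best, best_score = None, -np.inf
        for j in range(m):
            if j in chosen:
                continue
            red = np.mean([abs(np.corrcoef(X[:, j], X[:, c])[0, 1]) for c in chosen])
            score = rel[j] - red
            if score > best_score + 1e-12:
                best, best_score = j, score
        chosen.append(best)
    return chosen


def test_mrmr_matches_greedy_oracle(rng):
    for _ in range(5):
        X = rng.normal(size=(24, 6))
        y = np.array([0] * 12 + [1] * 12)
        X[y == 1, 0] += 1.0
        X[:, 3] = X[:, 0] * 0.9 + 0.3 * rng.normal(size=24)
        assert list(mrmr_rank(X, y).order) == _mrmr_oracle(X, y)


def test_cvsvm_prefers_separating_dimension(rng):
    """Only dimension 0 separates; the sparse plane should drop dim 1."""
    n = 30
    y = np.array([0] * (n // 2) + [1] * (n // 2))
    X = rng.normal(size=(n, 2))
    X[y == 1, 0] += 4.0
    rr = cvsvm_rank(X, y)
    assert rr.order[0] == 0
    # weight on dim 1 driven to (near) zero by the concave penalty
    assert rr.scores[0] > 0
    assert len(rr.order) == 2


def test_cvsvm_no_signal_falls_back_to_univariate(rng):
    X = rng.normal(size=(20, 3))
    y = np.array([0] * 10 + [1] * 10)
    rr = cvsvm_rank(X, y)
    assert sorted(rr.order.tolist()) == [0, 1, 2]


def test_cvsvm_duplicate_column_sparsity(rng):
    f = rng.normal(size=30)
    y = np.array([0] * 15 + [1] * 15)
    f[y == 1] += 3.0
    X = np.column_stack([f, f.copy(), rng.normal(size=30)])
    rr = cvsvm_rank(X, y)
    weights = dict(zip(rr.order.tolist(), rr.scores.tolist()))
    w0, w1 = abs(weights.get(0, 0.0)), abs(weights.get(1, 0.0))
    assert min(w0, w1) < 0.15 * max(w0, w1) + 1e-9


def test_incremental_candidates_prefix_chain():
    order = np.array([4, 1, 2])
    sets = incremental_candidates(order, k_final=5)
    assert [s.tolist() for s in sets] == [[4], [4, 1], [4, 1, 2]]
    assert len(incremental_candidates(order, k_final=1)) == 1
    with pytest.raises(ParameterError):
        incremental_candidates(np.array([]), 3)


def test_reported_operating_point_yields_five_candidates(rng):
    X = rng.normal(size=(30, 40))
    y = np.array([0] * 15 + [1] * 15)
    order = double_rank(X, y, RankingConfig(k_initial=10, k_final=5))
    assert len(order) == 10
    sets = incremental_candidates(order, k_final=5)
    assert len(sets) == 5


def test_double_rank_deterministic(rng, small_cohort):
    X, y = small_cohort
    cfg = RankingConfig(k_initial=10, k_final=5)
    a = double_rank(X, y, cfg)
    b = double_rank(X.copy(), y.copy(), cfg)
    assert np.array_equal(a, b)


def test_k_initial_all_means_no_truncation(small_cohort):
    X, y = small_cohort
    order = double_rank(X, y, RankingConfig(k_initial=None, k_final=5))
    assert len(order) == X.shape[1]
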