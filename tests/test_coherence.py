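"""Wavelet-coherence network features: sFC, nCC, leadCoh, edge vectors."""

import numpy as np
import pytest

from fusemri import (CoherenceMap, count_coherence_clusters, lead_coherence,
                     static_fc, unvectorize_edge_matrix, vectorize_edge_matrix,
                     wavelet_coherence)
from fusemri.coherence import (WcaParams, directed_pair_labels, pair_labels,
                               subject_network_features)
from fusemri.errors import DegenerateSeriesError, ParameterError, SchemaError

PARAMS = WcaParams(dt=1.0, fmin=0.02, fmax=0.25, n_scales=18)


@pytest.fixture(scope="module")
def noise_series():
    return np.random.default_rng(77).standard_normal((4, 320))


def test_pairwise_element_counts():
    assert len(pair_labels()) == 105
    assert len(directed_pair_labels()) == 210
    assert len(set(pair_labels())) == 105


def test_static_fc_count_and_cap(noise_series):
    rng = np.random.default_rng(1)
    series = rng.standard_normal((15, 120))
    assert static_fc(series).shape == (105,)
    # identical channels: raw r = 1, z capped (finite)
    dup = np.vstack([noise_series[0], noise_series[0]])
    z = static_fc(dup)
    assert np.isfinite(z[0]) and z[0] > 6


def test_static_fc_null_correlations(noise_series):
    rng = np.random.default_rng(2)
    series = rng.standard_normal((15, 200))
    r = np.tanh(static_fc(series))
    assert np.mean(np.abs(r) < 0.3) >= 0.95


def test_static_fc_constant_channel_rejected():
    series = np.vstack([np.ones(100), np.random.default_rng(0).normal(size=100)])
    with pytest.raises(DegenerateSeriesError):
        static_fc(series)


def test_identical_series_full_coherence(noise_series):
    cmap = wavelet_coherence(noise_series[0], noise_series[0], PARAMS)
    inside = cmap.valid
    assert cmap.magnitude[inside].min() > 0.999
    assert np.abs(cmap.phase[inside]).max() < 1e-8
    assert count_coherence_clusters(cmap) == 1


def test_quarter_period_lag_phase():
    """A quarter-period delay shows up as ~pi/2 phase at the driving scale."""
    rng = np.random.default_rng(5)
    t = np.arange(400.0)
    f0 = 0.05
    common = np.sin(2 * np.pi * f0 * t)
    x = common + 0.2 * rng.standard_normal(400)
    y = np.sin(2 * np.pi * f0 * (t - 0.25 / f0)) + 0.2 * rng.standard_normal(400)
    cmap = wavelet_coherence(x, y, PARAMS)
    k = int(np.argmin(np.abs(cmap.frequencies - f0)))
    row_phase = cmap.phase[k][cmap.significant[k]]
    assert row_phase.size > 0
    assert np.median(row_phase) == pytest.approx(np.pi / 2, abs=0.35)
    # positive phase = first series leads
    assert lead_coherence(cmap) > lead_coherence(cmap.swapped())


def test_null_significance_rate_near_nominal():
    rates = []
    for seed in range(10):
        rng = np.random.default_rng(seed)
        cmap = wavelet_coherence(rng.standard_normal(320),
                                 rng.standard_normal(320), PARAMS)
        rates.append(cmap.significant[cmap.valid].mean())
    assert np.mean(rates) == pytest.approx(0.05, abs=0.03)


def test_magnitude_invariant_under_rescaling(noise_series):
    x, y = noise_series[0], noise_series[1]
    a = wavelet_coherence(x, y, PARAMS)
    b = wavelet_coherence(5.0 * x, 0.2 * y, PARAMS)
    np.testing.assert_allclose(a.magnitude, b.magnitude, atol=1e-10)


def test_series_too_short_for_largest_scale():
    params = WcaParams(dt=1.0, fmin=0.005, fmax=0.2)
    with pytest.raises(ParameterError):
        wavelet_coherence(np.random.default_rng(0).normal(size=100),
                          np.random.default_rng(1).normal(size=100), params)


def _make_map(sig, phase):
    sig = np.asarray(sig, dtype=bool)
    return CoherenceMap((0, 1), np.ones(sig.shape[0]),
                        sig.astype(float), np.asarray(phase, dtype=float),
                        np.ones_like(sig, dtype=bool), sig)


def _flood_fill_count(mask):
    """Brute-force 4-neighbour component count (oracle)."""
    mask = mask.copy()
    count = 0
    while mask.any():
        count += 1
        stack = [tuple(np.argwhere(mask)[0])]
        while stack:
            i, j = stack.pop()
            if i < 0 or j < 0 or i >= mask.shape[0] or j >= mask.shape[1]:
                continue
            if not mask[i, j]:
                continue
            mask[i, j] = False
            stack += [(i + 1, j), (i - 1, j), (i, j + 1), (i, j - 1)]
    return count


def test_cluster_count_examples():
    empty = _make_map(np.zeros((4, 6)), np.zeros((4, 6)))
    assert count_coherence_clusters(empty) == 0

    blob = np.zeros((4, 6), dtype=bool)
    blob[1:3, 1:4] = True
    assert count_coherence_clusters(_make_map(blob, np.zeros((4, 6)))) == 1

    two = np.zeros((4, 8), dtype=bool)
    two[1, 0:2] = True
    two[1, 5:7] = True
    cmap = _make_map(two, np.zeros((4, 8)))
    assert count_coherence_clusters(cmap) == _flood_fill_count(two) == 2


def test_clusters_split_by_phase_category():
    """One contiguous region counts twice when its halves differ in kind."""
    sig = np.zeros((3, 8), dtype=bool)
    sig[1, 1:7] = True
    phase = np.zeros((3, 8))
    phase[1, 4:7] = np.pi / 2  # leading, the rest in-phase
    assert count_coherence_clusters(_make_map(sig, phase)) == 2


def test_cluster_count_matches_flood_fill_oracle(rng):
    for _ in range(10):
        sig = rng.random((8, 20)) < 0.3
        cmap = _make_map(sig, np.zeros(sig.shape))
        assert count_coherence_clusters(cmap) == _flood_fill_count(sig)


def test_leadcoh_zero_phase_symmetric():
    sig = np.ones((3, 5), dtype=bool)
    cmap = _make_map(sig, np.zeros((3, 5)))
    assert lead_coherence(cmap) == lead_coherence(cmap.swapped())


def test_leadcoh_strict_leader():
    sig = np.ones((2, 4), dtype=bool)
    cmap = _make_map(sig, np.full((2, 4), 0.8))
    assert lead_coherence(cmap) == 1.0
    assert lead_coherence(cmap.swapped()) == 0.0
    # phase-weighted variant preserves the ordering
    assert lead_coherence(cmap, "weighted") > lead_coherence(cmap.swapped(), "weighted")


def test_subject_feature_vector_lengths():
    rng = np.random.default_rng(9)
    series = rng.standard_normal((15, 320))
    feats = subject_network_features(series, PARAMS)
    assert feats["sFC"].shape == (105,)
    assert feats["nCC"].shape == (105,)
    assert feats["leadCoh"].shape == (210,)


def test_vectorize_edge_matrix_counts_and_roundtrip(rng):
    M = rng.normal(size=(84, 84))
    M = (M + M.T) / 2
    v = vectorize_edge_matrix(M)
    assert v.shape == (3486,)
    back = unvectorize_edge_matrix(v)
    off = ~np.eye(84, dtype=bool)
    np.testing.assert_allclose(back[off], M[off])

    assert vectorize_edge_matrix(np.array([[0.0, 3.0], [3.0, 0.0]])).shape == (1,)


def test_vectorize_rejects_asymmetry():
    M = np.array([[0.0, 1.0], [2.0, 0.0]])
    with pytest.raises(SchemaError):
        vectorize_edge_matrix(M)
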