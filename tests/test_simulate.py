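"""Synthetic cohort generator: shapes, planted effects, determinism."""

import numpy as np
import pytest
from scipy import stats

from fusemri import (Coupling, HdrsModel, STUDY_SET_DIMS, SyntheticSpec,
                     TimeSeriesSpec, generate_cohort, generate_feature_tables,
                     generate_hdrs, generate_rsn_timeseries, label_outcome)
from fusemri.errors import ParameterError


def test_study_dimensions_and_shapes():
    spec = SyntheticSpec(n_group_a=5, n_group_b=6)
    tables = generate_feature_tables(spec)
    assert set(tables) == set(STUDY_SET_DIMS)
    for name, fs in tables.items():
        assert fs.data.shape == (11, STUDY_SET_DIMS[name])
        assert not fs.data.isna().any().any()


def test_fixed_seed_reproducible():
    spec = SyntheticSpec(n_group_a=6, n_group_b=6, set_dims={"s": 30}, seed=5)
    a = generate_feature_tables(spec)["s"].data
    b = generate_feature_tables(spec)["s"].data
    assert (a.to_numpy() == b.to_numpy()).all()
    c = generate_feature_tables(
        SyntheticSpec(n_group_a=6, n_group_b=6, set_dims={"s": 30}, seed=6)
    )["s"].data
    assert (a.to_numpy() != c.to_numpy()).any()


def test_null_t_statistics_follow_null_distribution():
    """With d = 0 everywhere, per-element t statistics are central t."""
    spec = SyntheticSpec(n_group_a=50, n_group_b=50, set_dims={"s": 400},
                         within_set_correlation=0.0, seed=2)
    X = generate_feature_tables(spec)["s"].values
    t = stats.ttest_ind(X[:50], X[50:], axis=0).statistic
    ks = stats.kstest(t, stats.t(df=98).cdf)
    assert ks.pvalue > 0.01


def test_planted_effect_size_recovered():
    spec = SyntheticSpec(n_group_a=50, n_group_b=50, set_dims={"s": 10},
                         informative={"s": [(0, 2.0, 1)]}, seed=3)
    X = generate_feature_tables(spec)["s"].values
    a, b = X[:50, 0], X[50:, 0]
    pooled_sd = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
    d = (b.mean() - a.mean()) / pooled_sd
    assert 1.4 <= d <= 2.6


def test_within_set_equicorrelation():
    spec = SyntheticSpec(n_group_a=150, n_group_b=150, set_dims={"s": 12},
                         within_set_correlation=0.4, seed=4)
    X = generate_feature_tables(spec)["s"].values
    r = np.corrcoef(X, rowvar=False)
    off = r[np.triu_indices(12, k=1)]
    assert off.mean() == pytest.approx(0.4, abs=0.06)


def test_informative_index_out_of_range():
    spec = SyntheticSpec(set_dims={"s": 5}, informative={"s": [(7, 1.0, 1)]})
    with pytest.raises(IndexError):
        generate_feature_tables(spec)


def test_hdrs_baseline_distribution_and_range():
    spec = SyntheticSpec(n_group_a=100, n_group_b=100, set_dims={"s": 2}, seed=8)
    assignment = np.array(["PO", "NO"] * 100)
    scores = generate_hdrs(spec, assignment)
    b = scores["hdrs_baseline"]
    se = 4.62 / np.sqrt(len(b))
    assert abs(b.mean() - 24.4) < 3 * se
    assert (b >= 0).all() and (b <= 52).all()
    assert (scores["hdrs_followup"] >= 0).all() and (scores["hdrs_followup"] <= 52).all()
    assert (b == np.round(b)).all()  # integer instrument


def test_hdrs_label_recovery_exact_without_noise():
    spec = SyntheticSpec(n_group_a=40, n_group_b=40, set_dims={"s": 2}, seed=9)
    assignment = np.array(["PO"] * 40 + ["NO"] * 40)
    scores = generate_hdrs(spec, assignment)
    recovered = [
        label_outcome(b, f).value
        for b, f in zip(scores["hdrs_baseline"], scores["hdrs_followup"])
    ]
    assert list(assignment) == recovered


def test_hdrs_label_noise_rate():
    spec = SyntheticSpec(
        n_group_a=300, n_group_b=300, set_dims={"s": 2}, seed=10,
        hdrs_model=HdrsModel(label_noise=0.25),
    )
    assignment = np.array(["PO", "NO"] * 300)
    scores = generate_hdrs(spec, assignment)
    recovered = np.array([
        label_outcome(b, f).value
        for b, f in zip(scores["hdrs_baseline"], scores["hdrs_followup"])
    ])
    flip_rate = np.mean(recovered != assignment)
    assert flip_rate == pytest.approx(0.25, abs=0.06)


def test_generate_cohort_outcome_task():
    spec = SyntheticSpec(n_group_a=19, n_group_b=12, set_dims={"s": 2}, seed=0)
    cohort = generate_cohort(spec, task="outcome")
    assert list(cohort.clinical["group"]).count("PO") == 12
    assert cohort.clinical["hdrs_followup"].notna().all()


def test_generate_cohort_diagnosis_task():
    spec = SyntheticSpec(n_group_a=31, n_group_b=32, set_dims={"s": 2}, seed=0)
    cohort = generate_cohort(spec, task="diagnosis")
    groups = cohort.clinical["group"]
    assert (groups == "HC").sum() == 31 and (groups == "MDD").sum() == 32
    assert cohort.clinical.loc[groups == "HC", "hdrs_followup"].isna().all()


def test_band_above_nyquist_rejected():
    ts = TimeSeriesSpec(n_networks=3, n_samples=128, dt=2.0,
                        couplings=[Coupling((0, 1), freq=0.3)])
    with pytest.raises(ParameterError):
        generate_rsn_timeseries(ts, seed=0)


def test_uncoupled_networks_independent():
    ts = TimeSeriesSpec(n_networks=4, n_samples=600, dt=1.0)
    series = generate_rsn_timeseries(ts, seed=1)
    r = np.corrcoef(series)
    off = np.abs(r[np.triu_indices(4, k=1)])
    assert off.max() < 0.15


def test_coupled_pair_correlated_at_zero_lag():
    ts = TimeSeriesSpec(
        n_networks=3, n_samples=600, dt=1.0,
        couplings=[Coupling((0, 1), freq=0.05, phase_lag=0.0, strength=2.0)],
    )
    series = generate_rsn_timeseries(ts, seed=2)
    r = np.corrcoef(series)
    assert r[0, 1] > 0.5
    assert abs(r[0, 2]) < 0.2
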