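import numpy as np
import pytest

from fusemri import RankingConfig, SyntheticSpec, generate_feature_tables


@pytest.fixture
def rng():
    return np.random.default_rng(20240617)


@pytest.fixture
def small_cohort():
    """12+12 subjects, 20 elements, 3 planted effects (d = 1.5)."""
    spec = SyntheticSpec(
        n_group_a=12, n_group_b=12, set_dims={"demo": 20},
        informative={"demo": [(0, 1.5, 1), (1, 1.5, -1), (2, 1.5, 1)]},
        seed=11,
    )
    X = generate_feature_tables(spec)["demo"].values
    y = np.array([0] * 12 + [1] * 12)
    return X, y


@pytest.fixture
def fast_cfg():
    return RankingConfig(method="mrmr", k_initial=10, k_final=5)
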