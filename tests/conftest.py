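import numpy as np
import pytest

from enetfamily import ElasticNetFamily, SyntheticSpec, make_dataset


@pytest.fixture(scope="session")
def linear_data():
    """Small sparse-signal linear dataset: 3 true features out of 15."""
    spec = SyntheticSpec(
        n_samples=60, n_features=15, n_true_features=3,
        effect_size=1.0, noise_sd=1.0, seed=3,
    )
    return make_dataset(spec, "linear")


@pytest.fixture(scope="session")
def linear_results(linear_data):
    """A fitted small linear family reused across table/plot/archive tests."""
    x, y, _ = linear_data
    model = ElasticNetFamily(
        x, y, family="linear", alphas=(0.0, 1.0),
        n_runs=3, n_folds=5, n_perm_per_run=5, n_lambda=30,
    )
    return model.fit(seed=11)


@pytest.fixture(scope="session")
def multinomial_results():
    """A fitted small 3-class family (strong signal)."""
    spec = SyntheticSpec(
        n_samples=75, n_features=18, n_true_features=3,
        effect_size=2.0, n_classes=3, seed=5,
    )
    x, y, _ = make_dataset(spec, "multinomial")
    model = ElasticNetFamily(
        x, y, family="multinomial", alphas=(0.2,),
        n_runs=2, n_folds=5, n_perm_per_run=3, n_lambda=12,
    )
    return model.fit(seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
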