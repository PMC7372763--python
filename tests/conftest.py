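import numpy as np
import pytest

from svgae import RunConfig, SyntheticSpec, generate_dataset, make_worked_fixture


@pytest.fixture(scope="session")
def fixture_dataset():
    """Hand-verifiable 8-protein dataset (6 positive / 6 negative pairs)."""
    return make_worked_fixture()


@pytest.fixture(scope="session")
def small_planted():
    """A small planted dataset for fast end-to-end tests (not the default
    study size; unit tests only need learnable structure, not scale)."""
    spec = SyntheticSpec(n_proteins=100, n_blocks=5, p_within=0.6,
                         p_between=0.01, seed=11)
    return generate_dataset(spec)


@pytest.fixture
def quick_config():
    """Full hyperparameter defaults but only 2 repeats, for speed."""
    return RunConfig(seed=7, n_repeats=2)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
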