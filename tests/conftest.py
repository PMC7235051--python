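import pytest

from dyadconflict.model import build_predictor_matrix, dyad_item_matrix
from dyadconflict.scoring import score_parents
from dyadconflict.simulate import SimulationConfig, generate_dataset, synthetic_norms


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_families=12, seed=7)


@pytest.fixture(scope="session")
def small_study(small_config):
    """A 12-family synthetic study with the default missingness pattern."""
    dataset, truth = generate_dataset(small_config)
    return dataset, truth


@pytest.fixture(scope="session")
def small_norms(small_config):
    return synthetic_norms(small_config, n=4000)


@pytest.fixture(scope="session")
def small_scores(small_study, small_norms):
    dataset, _ = small_study
    return score_parents(dataset, small_norms, seed=1)


@pytest.fixture(scope="session")
def small_matrix(small_study, small_scores):
    dataset, _ = small_study
    return build_predictor_matrix(dataset, small_scores)


@pytest.fixture(scope="session")
def small_items(small_study):
    dataset, _ = small_study
    return dyad_item_matrix(dataset)
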