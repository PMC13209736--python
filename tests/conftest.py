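import numpy as np
import pytest

from mpff.model import ActivityModel, ModelConfig
from mpff.synthetic import SyntheticSpec, generate_activity_dataset, generate_protein


@pytest.fixture(scope="session")
def model_params():
    """Freshly initialized (untrained) parameter set, seed 0."""
    return ActivityModel(ModelConfig(seed=0)).params


@pytest.fixture(scope="session")
def small_dataset():
    """200 pharmacophore-labeled records over 40 scaffolds (seed 3)."""
    spec = SyntheticSpec(n_molecules=200, seed=3, scaffold_pool_size=40, positive_rate=0.4)
    return generate_activity_dataset(spec)


@pytest.fixture(scope="session")
def protein48():
    return generate_protein(48, 5, id="T1")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
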