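import numpy as np
import pytest

from chronolux.config import PipelineConfig
from chronolux.synthetic import generate_study


@pytest.fixture(scope="session")
def cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def study10():
    """A small deterministic synthetic study shared across tests."""
    return generate_study(10, n_obs=8, noise_sd=0.1, seed=123, size=(64, 96))


@pytest.fixture(scope="session")
def study10_dir(study10, tmp_path_factory):
    d = tmp_path_factory.mktemp("study10")
    study10.write(d)
    return d


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
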