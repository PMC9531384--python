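import numpy as np
import pytest

from cardiot1tex.core import NormalRange
from cardiot1tex.phantom import PhantomConfig, generate_t1_study
from cardiot1tex.segmental import build_study_masks


@pytest.fixture(scope="session")
def noiseless_config() -> PhantomConfig:
    return PhantomConfig(noise_sd=0.0, baseline_t1=1000.0)


@pytest.fixture(scope="session")
def default_config() -> PhantomConfig:
    return PhantomConfig()


@pytest.fixture(scope="session")
def noiseless_study(noiseless_config):
    return generate_t1_study(noiseless_config, seed=0)


@pytest.fixture(scope="session")
def noiseless_rois(noiseless_study, noiseless_config):
    return build_study_masks(noiseless_study, noiseless_config)


@pytest.fixture(scope="session")
def normal_range() -> NormalRange:
    return NormalRange()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
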