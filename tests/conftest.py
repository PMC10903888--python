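import numpy as np
import pytest

from dendroval.config import SimConfig, StudyConfig


@pytest.fixture(scope="session")
def small_cfg() -> StudyConfig:
    """A small but full-featured study: 12 sites, 2 regions, 3 products."""
    return StudyConfig(
        sim=SimConfig(n_sites=12, n_regions=2, years=(1951, 2000), seed=42)
    )


@pytest.fixture(scope="session")
def small_study(small_cfg):
    from dendroval.simulate import simulate_study

    return simulate_study(small_cfg.sim)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
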