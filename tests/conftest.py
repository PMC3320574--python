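import numpy as np
import pytest

from cgpgwas.popgen import PopulationConfig, build_layout, generate_population


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_layout():
    return build_layout(2, 300, 5000, 1.0)


@pytest.fixture(scope="session")
def small_population(small_layout):
    """400 individuals, 600 loci, default structure; shared across tests."""
    cfg = PopulationConfig(n_final=400, n_subpops=4, seed=42)
    return generate_population(small_layout, cfg, ld_corr=0.7, fast=True)


@pytest.fixture(scope="session")
def study_layout():
    return build_layout(20, 2000, 5000, 1.0)


@pytest.fixture(scope="session")
def study_population(study_layout):
    """Study-scale population (5,000 x 40,000), fast mode, fixed seed."""
    cfg = PopulationConfig(seed=17)
    return generate_population(study_layout, cfg, ld_corr=0.7, fast=True)
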