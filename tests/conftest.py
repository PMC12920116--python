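import numpy as np
import pytest

from aavstruct import KmerIndex, SimConfig, build_panel, simulate_reads


@pytest.fixture(scope="session")
def panel():
    return build_panel(seed=1)


@pytest.fixture(scope="session")
def kindex(panel):
    return KmerIndex(panel, k=15)


@pytest.fixture(scope="session")
def vector_region(panel):
    return panel.vector_region()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def clean_config():
    """Error-free, artifact-free simulation settings."""
    return SimConfig(
        seed=7, n_reads=50,
        substitution_rate=0.0, insertion_rate=0.0, deletion_rate=0.0,
    )


@pytest.fixture(scope="session")
def clean_reads(panel, clean_config):
    reads, truth = simulate_reads(clean_config, panel)
    return reads, truth
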