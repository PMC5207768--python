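import numpy as np
import pytest
from hypothesis import settings

import srnafrac as sf

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    """Compact reference for unit tests: same structure, fewer loci."""
    return sf.SyntheticConfig(
        n_chroms=2,
        chrom_length=60_000,
        n_mir=10,
        n_tas=3,
        n_p4_windows=40,
        n_genes=6,
        rrna_length=4000,
    )


@pytest.fixture(scope="session")
def small_reference(small_config):
    return sf.generate_reference(small_config, seed=11)


@pytest.fixture(scope="session")
def default_reference():
    """Reference at the default study conditions (used by acceptance tests)."""
    return sf.generate_reference(seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
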