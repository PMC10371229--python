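import numpy as np
import pytest

from musclemap import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_cfg():
    """A fast desk-scale study design for unit tests."""
    return SimConfig(
        n_mice=60,
        n_chromosomes=3,
        markers_per_chromosome=20,
        n_proteins_per_fraction=15,
        n_latent_factors=3,
        n_causal_proteins=4,
        n_confounded_proteins=3,
        n_compounds=25,
        n_reversers=3,
        seed=123,
    )
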