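import numpy as np
import pytest

from ervdiff import (
    EvolutionParams,
    evolve_clone_family,
    random_root_sequence,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_family():
    """A small evolved family: 8 sequences of 1000 nt at rate 1e-3."""
    root = random_root_sequence(1000, seed=11)
    return evolve_clone_family(
        root,
        EvolutionParams(
            substitution_rate=1e-3, generations=3, sequence_length=1000, seed=12
        ),
    )
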