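import numpy as np
import pytest

from tc1scope.synthdata import (
    ElementArchitecture,
    SignatureParams,
    build_consensus_element,
    plant_copies,
)


@pytest.fixture(scope="session")
def consensus():
    """Default synthetic consensus element (seed 1)."""
    return build_consensus_element(ElementArchitecture(seed=1))


@pytest.fixture(scope="session")
def small_fixture(consensus):
    """10 substitution-only copies (6 intact) planted in a 60 kb genome."""
    genome, truth = plant_copies(
        60_000, 1, consensus, n_copies=10, sub_rate=0.015, n_intact=6, seed=42
    )
    return genome, truth


@pytest.fixture(scope="session")
def default_params():
    return SignatureParams(seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
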