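import numpy as np
import pytest

from polyplexmc.composition import (
    SystemComposition,
    build_dna,
    g2_template,
)
from polyplexmc.energy import InteractionParams
from polyplexmc.engine import build_system, initialize_state


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_system():
    """A 20-bead DNA plus one G2 with counterions in a 400 A cell."""
    comp = SystemComposition().add(build_dna(20)).add(g2_template())
    return build_system(comp)


@pytest.fixture
def small_params():
    return InteractionParams(cell_radius=400.0)


@pytest.fixture
def small_state(small_system, small_params, rng):
    return initialize_state(small_system, small_params, rng)
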