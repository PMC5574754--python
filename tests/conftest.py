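import numpy as np
import pytest

from qfasajoint import (
    generate_predators,
    make_diet_grid,
    random_cc,
    synth_prey_library,
)


@pytest.fixture(scope="session")
def small_library():
    """I=3 prey types, K=8 fatty-acid slots, 20 specimens per type."""
    return synth_prey_library(3, 8, 20, separation=1.0, seed=1)


@pytest.fixture(scope="session")
def small_truth(small_library):
    """Noise-free predators from a known diet grid and coefficient draw."""
    cc = random_cc(8, seed=2)
    diets = make_diet_grid(3, 0.25)          # 15 diets
    predators = generate_predators(diets, small_library, cc)
    return {"library": small_library, "cc": cc, "diets": diets, "predators": predators}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
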