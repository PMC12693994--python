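import numpy as np
import pytest

from neurotwist import (
    CUBE_COORDS,
    GeneratorSpec,
    NetworkSpec,
    enumerate_rules,
    expanded_cube,
    generate,
    simulate_network,
)


@pytest.fixture(scope="session")
def cube_points():
    """Vertex index -> 3D ±1 coordinates."""
    return {i: np.array(c, dtype=float) for i, c in CUBE_COORDS.items()}


@pytest.fixture(scope="session")
def expanded_points():
    """Vertex index -> 7D twist-expanded coordinates."""
    return expanded_cube()


@pytest.fixture(scope="session")
def all_rules():
    return enumerate_rules()


@pytest.fixture(scope="session")
def acts_d1():
    """One full-diversity network simulation (93 neurons, 100 repeats)."""
    return simulate_network(NetworkSpec(d=1.0), np.random.default_rng(101))


@pytest.fixture(scope="session")
def acts_d0():
    """One zero-diversity network simulation."""
    return simulate_network(NetworkSpec(d=0.0), np.random.default_rng(102))


@pytest.fixture(scope="session")
def small_synth():
    """A reduced synthetic pseudopopulation for decoding tests.

    Shorter trial window and fewer coherence levels keep the SVM pipeline
    fast; all conditions retained so labelings stay balanced.
    """
    spec = GeneratorSpec(
        n_neurons=48,
        n_coherences=2,
        t_stop_ms=620.0,
        stim_offset_ms=520.0,
        n_retained_conditions=32,
        seed=7,
    )
    return generate(spec)
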