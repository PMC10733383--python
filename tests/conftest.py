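import numpy as np
import pytest

from platefold import SimConfig2D, assign_constriction, build_hex_lattice


@pytest.fixture(scope="session")
def small_tissue():
    """A 20x12 tissue with a centered 10x6 plate (no constriction yet)."""
    return build_hex_lattice(20, 12, (10, 6))


@pytest.fixture(scope="session")
def constricted_small_tissue(small_tissue):
    """The 20x12 tissue with P_c = 0.5 constriction at a fixed seed."""
    cfg = SimConfig2D(p_c=0.5, seed=7)
    return assign_constriction(small_tissue, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
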