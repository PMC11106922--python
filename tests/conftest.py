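import numpy as np
import pytest

from hillode import (
    GroundTruthGRN,
    init_parameters,
    random_grn,
)


@pytest.fixture(scope="session")
def chain_grn():
    """A -> B -> C activation chain."""
    return GroundTruthGRN(
        ("A", "B", "C"),
        frozenset({("A", "B", +1), ("B", "C", +1)}),
    )


@pytest.fixture(scope="session")
def mixed_grn():
    """Five genes, activating and repressive edges, one isolated gene."""
    return GroundTruthGRN(
        ("A", "B", "C", "D", "E"),
        frozenset({("A", "B", +1), ("A", "C", -1), ("B", "C", +1),
                   ("C", "D", -1), ("B", "D", +1)}),
    )


@pytest.fixture(scope="session")
def parent_grn():
    """Benchmark-shaped parent network (scaled down)."""
    return random_grn(138, 219, seed=7)


@pytest.fixture
def tiny_params():
    """3 genes, width 2, random but reproducible."""
    return init_parameters(("g0", "g1", "g2"), m=2, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
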