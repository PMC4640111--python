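import numpy as np
import pytest

import parsimotif as pm


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_benchmark():
    """A small strong-motif benchmark shared by several integration tests."""
    return pm.make_benchmark(pm.BenchmarkSpec(n_pos=40, length=50, seed=42))


@pytest.fixture
def random_sites(rng):
    """60 random width-6 sites (no planted structure)."""
    enc = rng.integers(0, 4, size=(60, 6))
    return pm.SiteSet(6, ["".join("ACGT"[a] for a in row) for row in enc])


def fig1_pct():
    """The depth-2 PCT organizing the 16 dinucleotide contexts into 5 groups.

    Root partition {A,G,T} | {C} on the proximal symbol; the {A,G,T} branch merges
    distal {A,C} vs {G,T}; the {C} branch splits the distal symbol into
    {A,G} | {C} | {T}.
    """
    from parsimotif.pct import PCT, PCTNode

    agt = PCTNode((0, 2, 3), (PCTNode((0, 1), ()), PCTNode((2, 3), ())))
    c = PCTNode((1,), (PCTNode((0, 2), ()), PCTNode((1,), ()), PCTNode((3,), ())))
    return PCT((agt, c))
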