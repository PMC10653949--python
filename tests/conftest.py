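import numpy as np
import pandas as pd
import pytest

from magdyn.distill import PathwayDefinition
from magdyn.io import MagRecord, Phylogeny
from magdyn.simulate import default_config, generate_study


@pytest.fixture(scope="session")
def bundle():
    """One default synthetic study shared by read-only tests."""
    return generate_study(default_config(seed=7))


@pytest.fixture
def toy_db():
    """Three hand-built pathways spanning alternatives and combination sizes."""
    return [
        PathwayDefinition(
            "pwy1",
            "fA",
            steps=(
                (frozenset({"K1", "K2"}),),
                (frozenset({"K3"}), frozenset({"K4", "K5"})),
            ),
        ),
        PathwayDefinition(
            "pwy2",
            "fA",
            steps=((frozenset({"K6"}),), (frozenset({"K7"}),), (frozenset({"K8"}),)),
        ),
        PathwayDefinition("pwy3", "fB", steps=((frozenset({"K9", "K10"}),),)),
    ]


@pytest.fixture
def star_tree():
    return Phylogeny.from_newick("(A:1.0,B:1.0,C:1.0,D:1.0);")


@pytest.fixture
def balanced_tree():
    return Phylogeny.from_newick("((A:1.0,B:1.0):1.0,(C:1.0,D:1.0):1.0);")


def make_mag(mag_id="m1", genes=(), completeness=1.0, contamination=0.0, length=2_000_000):
    return MagRecord(
        mag_id=mag_id,
        genome_length=length,
        completeness=completeness,
        contamination=contamination,
        genes=frozenset(genes),
    )


@pytest.fixture
def make_mag_factory():
    return make_mag


def random_simplex(rng, n):
    v = rng.dirichlet(np.ones(n))
    return v / v.sum()


@pytest.fixture
def simplex():
    return random_simplex
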