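import random

import pytest
from hypothesis import settings

import sprmix as sx

settings.register_profile("ci", derandomize=True, max_examples=30, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def four_taxon_topologies():
    """All 3 unrooted topologies on {a, b, c, d}."""
    return sx.enumerate_topologies(list("abcd"))


@pytest.fixture(scope="session")
def five_taxon_topologies():
    """All 15 unrooted topologies on {a, b, c, d, e}."""
    return sx.enumerate_topologies(list("abcde"))


@pytest.fixture()
def rng():
    return random.Random(20240901)


def make_trace(seq, interval=1, run_id="run1"):
    return sx.ChainTrace(run_id=run_id, topologies=list(seq), interval=interval)


@pytest.fixture(scope="session")
def correlated_sample():
    """The correlated-resolution construction: two sampled trees whose
    resolutions of the {a,b,c}-side and {d,e,f}-side clades are perfectly
    linked, so sister clades are *not* conditionally independent."""
    t_ab_de = sx.Topology.from_newick("(((a,b),c),((d,e),f));")
    t_ac_df = sx.Topology.from_newick("(((a,c),b),((d,f),e));")
    t_ab_df = sx.Topology.from_newick("(((a,b),c),((d,f),e));")
    t_ac_de = sx.Topology.from_newick("(((a,c),b),((d,e),f));")
    return t_ab_de, t_ac_df, t_ab_df, t_ac_de
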