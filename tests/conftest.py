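import numpy as np
import pytest

from tandemfill.io import UnitigGraph


def make_graph(edges, nodes, seqs=None):
    """Directed all-plus graph helper used across graph tests."""
    g = UnitigGraph()
    for n in nodes:
        g.add_node(n, (seqs or {}).get(n, "ACGT"))
    for u, v in edges:
        g.add_edge(u, "+", v, "+", 0)
    return g


@pytest.fixture
def loop_graph_simple():
    """A solvable loop: one contig E-A-B-C-A-D despite the branching at A."""
    return make_graph(
        [("E", "A"), ("A", "B"), ("B", "C"), ("C", "A"), ("A", "D")], "EABCD"
    )


@pytest.fixture
def loop_graph_nested():
    """An unsolvable branching node (B) nested in a solvable loop; expects
    contigs E-A-B, C-A-D and the singleton F."""
    return make_graph(
        [("E", "A"), ("A", "B"), ("B", "C"), ("B", "F"), ("C", "A"),
         ("A", "D")],
        "EABCDF",
    )


def random_dna(rng, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
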