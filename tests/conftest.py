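import io

import pytest

from gafpan import PangenomeGraph, load_gfa, set_reference
from gafpan.fixtures import FixtureSpec, make_bubble_graph

TINY_GFA = (
    "S\t1\tACG\n"
    "S\t2\tT\n"
    "S\t3\tAAAA\n"
    "L\t1\t+\t2\t+\t0M\n"
    "L\t2\t+\t3\t+\t0M\n"
    "P\tP\t1+,2+,3+\t*\n"
)


@pytest.fixture
def tiny_graph() -> PangenomeGraph:
    """Three-node linear graph: 1=ACG, 2=T, 3=AAAA, path P spelling ACGTAAAA."""
    return load_gfa(io.StringIO(TINY_GFA))


@pytest.fixture
def tiny_ref_graph(tiny_graph) -> PangenomeGraph:
    return set_reference(tiny_graph, "P")


@pytest.fixture
def bubble_graph():
    """Deterministic 10-bubble graph with truth table (seed 42)."""
    return make_bubble_graph(FixtureSpec(n_bubbles=10, seed=42))
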