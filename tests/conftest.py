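import numpy as np
import pytest

from chemopath.io import InteractionRecord
from chemopath.network import BioNetwork, CondensedNetwork, build_network, condense


def records_from_edges(edges, kind="unspecified", directed=True):
    return [InteractionRecord(u, v, kind, directed=directed) for u, v in edges]


def network_from_edges(edges, kind="unspecified"):
    return build_network(records_from_edges(edges, kind=kind))


def condensed_from_edges(edges, mode="none"):
    """A CondensedNetwork straight from an edge list (no merging by default)."""
    return condense(network_from_edges(edges), mode)


def random_digraph(rng, n_max=8, p=0.3):
    """Random directed edge set over a few labeled vertices, no self-loops."""
    n = int(rng.integers(2, n_max + 1))
    vertices = [f"v{i}" for i in range(n)]
    edges = {
        (u, v)
        for u in vertices
        for v in vertices
        if u != v and rng.random() < p
    }
    return set(vertices), edges


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def toy_condensed():
    """Diamond with a long detour: s->t (1 hop), s->a->t, s->b->a->t."""
    return condensed_from_edges(
        [("s", "t"), ("s", "a"), ("a", "t"), ("s", "b"), ("b", "a")])


@pytest.fixture
def mutual_pair_network():
    """Two mutual regulators with private targets, as in a 2-cycle merge."""
    return build_network([
        InteractionRecord("AR", "DDIT3", "regulation_positive"),
        InteractionRecord("DDIT3", "AR", "regulation_positive"),
        InteractionRecord("AR", "T1", "regulation_positive"),
        InteractionRecord("DDIT3", "T2", "regulation_positive"),
    ])
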