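import numpy as np
import pytest

from lbdrank.kg_core import RELATION_VOCABULARY, EntityRecord, KnowledgeGraph, Triple
from lbdrank.synthetic import glyburide_fixture


@pytest.fixture(scope="session")
def glyburide_graph() -> KnowledgeGraph:
    return glyburide_fixture()


def random_graph(rng: np.random.Generator, max_nodes: int = 12) -> KnowledgeGraph:
    """A small random typed multigraph for oracle comparisons."""
    n = int(rng.integers(4, max_nodes + 1))
    g = KnowledgeGraph()
    for i in range(n):
        g.add_node(EntityRecord(f"n{i:02d}", "compound"))
    n_edges = int(rng.integers(n, 3 * n))
    for _ in range(n_edges):
        a, b = rng.integers(0, n, size=2)
        if a == b:
            continue
        r = RELATION_VOCABULARY[rng.integers(0, len(RELATION_VOCABULARY))]
        g.add_triple(Triple(f"n{a:02d}", r, f"n{b:02d}"))
    return g


def brute_force_paths(graph: KnowledgeGraph, sources, target, depth):
    """Exhaustive recursion over node sequences and connecting edges.

    Independent of the production DFS: enumerates every distinct node
    sequence, then every way of joining consecutive nodes by an edge in
    either direction.
    """
    import itertools

    names = sorted(graph.nodes)
    results = []
    for source in sorted(set(sources)):
        if source not in graph.nodes:
            continue
        interiors = [v for v in names if v not in (source, target)]
        for mid in itertools.permutations(interiors, depth - 1):
            seq = (source, *mid, target)
            # every consecutive pair: collect all connecting oriented edges
            options = []
            for a, b in zip(seq[:-1], seq[1:]):
                cands = []
                for (h, r, t) in graph.edges:
                    if (h, t) == (a, b):
                        cands.append((h, r, t, True))
                    elif (h, t) == (b, a):
                        cands.append((h, r, t, False))
                options.append(cands)
            for combo in itertools.product(*options):
                results.append((seq, tuple((h, r, t) for h, r, t, _ in combo)))
    return sorted(results)
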