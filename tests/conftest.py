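import numpy as np
import pytest

from molcgnn import MolecularGraph
from molcgnn.synthetic import GROUP_REPRESENTATIVES


def make_graph(elements, edges, *, node_labels=None, edge_labels=None,
               targets=(0.0,), graph_id="g"):
    n = len(elements)
    if node_labels is None:
        node_labels = np.zeros((n, 0))
    if edge_labels is None:
        edge_labels = np.zeros((len(edges), 0))
    return MolecularGraph(
        node_elements=list(elements),
        node_labels=np.asarray(node_labels, dtype=float),
        edges=np.asarray(edges, dtype=int).reshape(-1, 2),
        edge_labels=np.asarray(edge_labels, dtype=float),
        targets=np.asarray(targets, dtype=float),
        graph_id=graph_id,
    )


def random_graph(rng, *, n_min=2, n_max=6, label_dim=2, edge_label_dim=1,
                 n_tasks=1, graph_id="g"):
    """Connected random typed graph with random labels for property tests."""
    n = int(rng.integers(n_min, n_max + 1))
    elements = [GROUP_REPRESENTATIVES[t] for t in rng.integers(0, 8, size=n)]
    edges = {(int(rng.integers(0, i)), i) for i in range(1, n)}
    for _ in range(int(rng.integers(0, n))):
        a, b = rng.integers(0, n, size=2)
        if a != b:
            edges.add((min(int(a), int(b)), max(int(a), int(b))))
    edges = sorted(edges)
    return make_graph(
        elements,
        np.asarray(edges, dtype=int).reshape(-1, 2),
        node_labels=rng.normal(size=(n, label_dim)),
        edge_labels=rng.normal(size=(len(edges), edge_label_dim)),
        targets=rng.random(n_tasks).round(),
        graph_id=graph_id,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
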