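"""Molecular graph containers, heterogenization/homogenization, batching.

A molecule is an undirected labeled graph: nodes are heavy atoms carrying an
element symbol (and optionally extra feature vectors), edges are bonds
(optionally labeled), and each graph carries a vector of graph-level targets
(one per prediction task; missing entries are NaN).

Two views feed the two model families:

* :func:`homogenize` — for the standard recurrent GNN: the species is
  one-hot encoded over the 8 element groups and appended to the node label.
* :func:`heterogenize` — for the composite GNN: each node is assigned a
  type (its element group) and the label does *not* encode the species; the
  per-type state-updating networks carry that information instead.

Batches are disjoint unions with block-diagonal adjacency, so per-graph
outputs are independent of co-batched graphs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .grouping import ElementGrouping, N_GROUPS, UnsupportedElementError, default_grouping

__all__ = [
    "MolecularGraph",
    "CompositeGraph",
    "GraphBatch",
    "heterogenize",
    "homogenize",
    "batch_graphs",
    "unbatch",
]


def _as_2d(arr, n_rows: int, what: str) -> np.ndarray:
    a = np.asarray(arr, dtype=float)
    if a.ndim == 1 and a.size == 0:
        a = a.reshape(n_rows, 0) if n_rows else a.reshape(0, 0)
    if a.ndim != 2 or a.shape[0] != n_rows:
        raise ValueError(f"{what} must be a ({n_rows}, dim) array, got shape {a.shape}")
    return a


@dataclass
class MolecularGraph:
    """An undirected molecular graph with graph-level targets.

    Parameters
    ----------
    node_elements:
        Element symbol per node.
    node_labels:
        ``(node_count, l_dim)`` float array of per-node features; ``l_dim``
        may be zero.
    edges:
        ``(n_edges, 2)`` int array of unordered node-index pairs
        (0-based).  Self-loops and duplicate undirected edges are rejected.
    edge_labels:
        ``(n_edges, e_dim)`` float array; ``e_dim`` may be zero.
    targets:
        ``(n_tasks,)`` float vector; missing entries are ``NaN``.
    graph_id:
        Identifier used in error messages and serialization.
    """

    node_elements: list[str]
    node_labels: np.ndarray
    edges: np.ndarray
    edge_labels: np.ndarray
    targets: np.ndarray
    graph_id: str = ""

    def __post_init__(self) -> None:
        n = len(self.node_elements)
        if n < 1:
            raise ValueError(f"graph {self.graph_id!r}: at least one node required")
        self.node_labels = _as_2d(self.node_labels, n, "node_labels")
        edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        if edges.size:
            if edges.min() < 0 or edges.max() >= n:
                raise ValueError(
                    f"graph {self.graph_id!r}: edge endpoint outside 0..{n - 1}"
                )
            if np.any(edges[:, 0] == edges[:, 1]):
                raise ValueError(f"graph {self.graph_id!r}: self-loop found")
            canon = np.sort(edges, axis=1)
            if len(np.unique(canon, axis=0)) != len(canon):
                raise ValueError(
                    f"graph {self.graph_id!r}: duplicate undirected edge"
                )
        self.edges = edges
        self.edge_labels = _as_2d(self.edge_labels, len(edges), "edge_labels")
        self.targets = np.asarray(self.targets, dtype=float).reshape(-1)

    @property
    def node_count(self) -> int:
        return len(self.node_elements)

    @property
    def label_dim(self) -> int:
        return self.node_labels.shape[1]

    @property
    def edge_label_dim(self) -> int:
        return self.edge_labels.shape[1]

    @property
    def n_tasks(self) -> int:
        return self.targets.shape[0]

    def __eq__(self, other) -> bool:
        if not isinstance(other, MolecularGraph):
            return NotImplemented
        return (
            self.graph_id == other.graph_id
            and self.node_elements == other.node_elements
            and self.node_labels.shape == other.node_labels.shape
            and np.array_equal(self.node_labels, other.node_labels)
            and np.array_equal(self.edges, other.edges)
            and self.edge_labels.shape == other.edge_labels.shape
            and np.array_equal(self.edge_labels, other.edge_labels)
            and np.array_equal(self.targets, other.targets, equal_nan=True)
        )


@dataclass
class CompositeGraph:
    """A :class:`MolecularGraph` plus per-node type assignments (1..8)."""

    underlying: MolecularGraph
    node_types: np.ndarray
    per_type_index: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.node_types = np.asarray(self.node_types, dtype=int).reshape(-1)
        if self.node_types.shape[0] != self.underlying.node_count:
            raise ValueError("node_types length must equal node_count")
        if self.node_types.size and (
            self.node_types.min() < 1 or self.node_types.max() > N_GROUPS
        ):
            bad = int(self.node_types[(self.node_types < 1) | (self.node_types > N_GROUPS)][0])
            raise ValueError(f"node type {bad} outside 1..{N_GROUPS}")
        if not self.per_type_index:
            self.per_type_index = {
                int(t): np.flatnonzero(self.node_types == t)
                for t in np.unique(self.node_types)
            }

    @property
    def node_count(self) -> int:
        return self.underlying.node_count

    def __eq__(self, other) -> bool:
        if not isinstance(other, CompositeGraph):
            return NotImplemented
        return self.underlying == other.underlying and np.array_equal(
            self.node_types, other.node_types
        )


def heterogenize(
    g: MolecularGraph, grouping: ElementGrouping | None = None
) -> CompositeGraph:
    """Assign each node the type of its element group.

    The underlying graph is left unmodified: node labels keep any
    non-species features but do not encode the species — the node type
    carries it.
    """
    grouping = grouping or default_grouping()
    types = np.empty(g.node_count, dtype=int)
    for i, sym in enumerate(g.node_elements):
        try:
            types[i] = grouping.group_of(sym)
        except UnsupportedElementError:
            raise UnsupportedElementError(
                sym, extra=f" at node {i} of graph {g.graph_id!r}"
            ) from None
    return CompositeGraph(underlying=g, node_types=types)


def homogenize(
    g: MolecularGraph, grouping: ElementGrouping | None = None
) -> MolecularGraph:
    """Append an 8-long one-hot encoding of the element group to node labels.

    Structure, edge labels and targets are unchanged; only the node labels
    grow by 8 columns.
    """
    comp = heterogenize(g, grouping)
    onehot = np.zeros((g.node_count, N_GROUPS))
    onehot[np.arange(g.node_count), comp.node_types - 1] = 1.0
    return MolecularGraph(
        node_elements=list(g.node_elements),
        node_labels=np.hstack([g.node_labels, onehot]),
        edges=g.edges.copy(),
        edge_labels=g.edge_labels.copy(),
        targets=g.targets.copy(),
        graph_id=g.graph_id,
    )


def _underlying(g) -> MolecularGraph:
    return g.underlying if isinstance(g, CompositeGraph) else g


class GraphBatch:
    """Disjoint union of graphs with block-diagonal adjacency.

    Precomputes the stacked arrays message passing operates on: node labels,
    the directed-arc adjacency matrix (each undirected bond contributes two
    arcs), the per-node sum of incident edge labels, and the per-node graph
    membership. ``unbatch`` reconstructs the input graphs exactly from the
    stacked arrays.
    """

    def __init__(self, graphs: list):
        if not graphs:
            raise ValueError("cannot batch an empty list of graphs")
        composite = isinstance(graphs[0], CompositeGraph)
        for g in graphs:
            if isinstance(g, CompositeGraph) != composite:
                raise ValueError("cannot mix composite and plain graphs in a batch")
        self.graphs = list(graphs)
        self.is_composite = composite
        unders = [_underlying(g) for g in graphs]
        ldim = unders[0].label_dim
        edim = unders[0].edge_label_dim
        ntasks = unders[0].n_tasks
        for u in unders[1:]:
            if u.label_dim != ldim:
                raise ValueError(
                    f"mismatched node-label dimensions: {ldim} vs {u.label_dim}"
                )
            if u.edge_label_dim != edim:
                raise ValueError(
                    f"mismatched edge-label dimensions: {edim} vs {u.edge_label_dim}"
                )
            if u.n_tasks != ntasks:
                raise ValueError(f"mismatched task counts: {ntasks} vs {u.n_tasks}")

        counts = np.array([u.node_count for u in unders])
        self.node_offsets = np.concatenate([[0], np.cumsum(counts)])[:-1]
        self.node_counts = counts
        self.total_nodes = int(counts.sum())
        self.n_graphs = len(graphs)
        self.graph_membership = np.repeat(np.arange(self.n_graphs), counts)

        self.node_labels = (
            np.vstack([u.node_labels for u in unders])
            if self.total_nodes
            else np.zeros((0, ldim))
        )
        self.targets = np.vstack([u.targets for u in unders])

        src, dst, elab = [], [], []
        for off, u in zip(self.node_offsets, unders):
            for (a, b), e in zip(u.edges, u.edge_labels):
                src += [off + a, off + b]
                dst += [off + b, off + a]
                elab += [e, e]
        self.arc_src = np.asarray(src, dtype=int)
        self.arc_dst = np.asarray(dst, dtype=int)
        self.arc_edge_labels = (
            np.asarray(elab, dtype=float).reshape(len(elab), edim)
            if elab
            else np.zeros((0, edim))
        )
        n = self.total_nodes
        self.adjacency = sp.csr_matrix(
            (np.ones(len(self.arc_src)), (self.arc_dst, self.arc_src)), shape=(n, n)
        )
        # per-node sum of incident edge labels (constant across iterations)
        self.edge_label_sums = np.zeros((n, edim))
        np.add.at(self.edge_label_sums, self.arc_dst, self.arc_edge_labels)
        self.neighbor_label_sums = self.adjacency @ self.node_labels

        if composite:
            self.node_types = np.concatenate([g.node_types for g in graphs])
        else:
            self.node_types = None

    @property
    def label_dim(self) -> int:
        return self.node_labels.shape[1]

    @property
    def edge_label_dim(self) -> int:
        return self.arc_edge_labels.shape[1]

    def graph_slices(self):
        for i, (off, cnt) in enumerate(zip(self.node_offsets, self.node_counts)):
            yield i, slice(int(off), int(off + cnt))


def batch_graphs(graphs: list) -> GraphBatch:
    """Build a :class:`GraphBatch` (disjoint union) from a non-empty list."""
    return GraphBatch(graphs)


def unbatch(batch: GraphBatch) -> list:
    """Reconstruct the individual graphs from the batch's stacked arrays."""
    out = []
    for i, sl in batch.graph_slices():
        orig = _underlying(batch.graphs[i])
        off = batch.node_offsets[i]
        arc_mask = (batch.arc_src >= sl.start) & (batch.arc_src < sl.stop)
        # each undirected edge was stored as two consecutive arcs; take evens
        pair_src = batch.arc_src[arc_mask][0::2] - off
        pair_dst = batch.arc_dst[arc_mask][0::2] - off
        elabs = batch.arc_edge_labels[arc_mask][0::2]
        g = MolecularGraph(
            node_elements=list(orig.node_elements),
            node_labels=batch.node_labels[sl].copy(),
            edges=np.stack([pair_src, pair_dst], axis=1)
            if len(pair_src)
            else np.zeros((0, 2), dtype=int),
            edge_labels=elabs.copy(),
            targets=batch.targets[i].copy(),
            graph_id=orig.graph_id,
        )
        if batch.is_composite:
            out.append(CompositeGraph(underlying=g, node_types=batch.node_types[sl].copy()))
        else:
            out.append(g)
    return out
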