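"""Seeded generator of molecule-like typed graphs with planted targets.

The generator emulates the shape of molecular benchmark data without any
chemistry perception: connected sparse undirected graphs of 2-40 nodes,
each node drawn from the 8 element groups (via a representative symbol per
group), and graph-level targets that are pure functions of node types so a
label oracle can recompute them.  Connectivity comes from a random
spanning tree topped up with extra edges to a target density; valence
limits are deliberately not enforced — the models under test respond to
typed-graph structure, not chemistry.

Target rules:

* ``type-fraction`` — binary label 1 iff the fraction of nodes of a chosen
  group exceeds a threshold (per task, for multi-task specs); label noise
  flips labels with probability ``noise_level``.
* ``type-weighted-sum`` — regression target: sum over nodes of a per-group
  weight, plus Gaussian noise of standard deviation ``noise_level``.
* ``type-pair-sum`` — regression target: sum over bonds of a symmetric
  per-type-pair interaction weight, plus Gaussian noise.  This is the rule
  that rewards type-specialized state updates: the target depends on how
  the types of *bonded* atoms interact, not on type counts alone (which a
  species one-hot read out at the node level already captures).

Splits are 80/10/10 by graph, seeded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graphs import MolecularGraph
from .io import Dataset

__all__ = ["FixtureSpec", "label_oracle", "generate", "generate_dataset"]

# one representative element per group 1..8
GROUP_REPRESENTATIVES = ("Na", "Si", "Cl", "C", "N", "O", "P", "S")

#: default per-group weights for the "type-weighted-sum" rule
DEFAULT_GROUP_WEIGHTS = (2.0, 1.5, 1.0, 0.1, -0.5, 1.2, -1.5, 0.8)

#: carbon-dominated group mix loosely shaped like organic molecules
DEFAULT_GROUP_PROBABILITIES = (0.02, 0.02, 0.05, 0.55, 0.12, 0.14, 0.03, 0.07)


def _default_pair_weights() -> np.ndarray:
    """Fixed symmetric 8x8 type-pair interaction matrix (unit scale)."""
    m = np.random.default_rng(7).normal(0.0, 1.0, (8, 8))
    return (m + m.T) / 2.0


@dataclass(frozen=True)
class FixtureSpec:
    n_graphs: int = 100
    node_count_range: tuple[int, int] = (5, 15)
    edge_density: float = 0.3
    group_probabilities: tuple = DEFAULT_GROUP_PROBABILITIES
    task: str = "binary"  # binary | multitask | regression
    n_tasks: int = 1
    target_rule: str = "type-fraction"
    rule_params: dict = field(default_factory=dict)
    noise_level: float = 0.0
    bond_indicator: bool = False  # emit a constant 1.0 edge label per bond
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.node_count_range
        if not (1 <= lo <= hi):
            raise ValueError(f"degenerate node_count_range {self.node_count_range}")
        if not 0 < self.edge_density <= 1:
            raise ValueError("edge_density must lie in (0, 1]")
        p = np.asarray(self.group_probabilities, dtype=float)
        if p.shape != (8,) or p.min() < 0 or not np.isclose(p.sum(), 1.0):
            raise ValueError("group_probabilities must be 8 non-negatives summing to 1")
        if self.task not in ("binary", "multitask", "regression"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")
        if self.n_graphs < 1:
            raise ValueError("n_graphs must be >= 1")


def _resolve_rule_params(spec_task: str, n_tasks: int, rule: str, params: dict) -> dict:
    if rule == "type-fraction":
        out = {
            "groups": params.get("groups", [6] * n_tasks),
            "threshold": params.get("threshold", 0.15),
        }
        if len(out["groups"]) != n_tasks:
            raise ValueError("type-fraction: need one group per task")
        return out
    if rule == "type-weighted-sum":
        w = np.asarray(params.get("weights", DEFAULT_GROUP_WEIGHTS), dtype=float)
        if w.shape != (8,):
            raise ValueError("type-weighted-sum: weights must have length 8")
        return {"weights": w}
    if rule == "type-pair-sum":
        w = np.asarray(params.get("pair_weights", _default_pair_weights()), dtype=float)
        if w.shape != (8, 8) or not np.allclose(w, w.T):
            raise ValueError("type-pair-sum: pair_weights must be symmetric 8x8")
        return {"pair_weights": w}
    raise ValueError(f"unknown target rule {rule!r}")


def _node_groups(g: MolecularGraph) -> np.ndarray:
    rep = {s: i + 1 for i, s in enumerate(GROUP_REPRESENTATIVES)}
    try:
        return np.array([rep[s] for s in g.node_elements])
    except KeyError as exc:
        raise ValueError(f"element {exc} is not a group representative") from None


def label_oracle(g: MolecularGraph, rule: str, rule_params: dict) -> np.ndarray:
    """Noise-free target vector for a generated graph (pure function)."""
    groups = _node_groups(g)
    if rule == "type-fraction":
        thr = rule_params["threshold"]
        return np.array(
            [float(np.mean(groups == grp) > thr) for grp in rule_params["groups"]]
        )
    if rule == "type-weighted-sum":
        w = np.asarray(rule_params["weights"], dtype=float)
        return np.array([float(w[groups - 1].sum())])
    if rule == "type-pair-sum":
        w = np.asarray(rule_params["pair_weights"], dtype=float)
        total = sum(w[groups[a] - 1, groups[b] - 1] for a, b in g.edges)
        return np.array([float(total)])
    raise ValueError(f"unknown target rule {rule!r}")


def _random_connected_graph(rng: np.random.Generator, n: int, density: float):
    """Random spanning tree plus extra edges up to the target density."""
    tree = {(int(rng.integers(0, i)), i) for i in range(1, n)}
    edges = {(min(a, b), max(a, b)) for a, b in tree}
    max_edges = n * (n - 1) // 2
    want = max(len(edges), int(round(density * max_edges)))
    if want > max_edges:
        raise ValueError(f"infeasible density {density} for {n} nodes")
    while len(edges) < want:
        a, b = rng.integers(0, n, size=2)
        if a != b:
            edges.add((min(int(a), int(b)), max(int(a), int(b))))
    return np.array(sorted(edges), dtype=int).reshape(-1, 2)


def generate(spec: FixtureSpec):
    """Generate ``(train, valid, test)`` lists of graphs (80/10/10)."""
    ds = generate_dataset(spec)
    return ds.train, ds.valid, ds.test


def generate_dataset(spec: FixtureSpec, name: str = "synthetic") -> Dataset:
    """Generate a full :class:`Dataset` with metadata and 80/10/10 splits."""
    rng = np.random.default_rng(spec.seed)
    n_tasks = spec.n_tasks if spec.task == "multitask" else 1
    params = _resolve_rule_params(spec.task, n_tasks, spec.target_rule, spec.rule_params)
    probs = np.asarray(spec.group_probabilities, dtype=float)

    graphs = []
    for gi in range(spec.n_graphs):
        lo, hi = spec.node_count_range
        n = int(rng.integers(lo, hi + 1))
        groups = rng.choice(8, size=n, p=probs) + 1
        elements = [GROUP_REPRESENTATIVES[t - 1] for t in groups]
        edges = (
            _random_connected_graph(rng, n, spec.edge_density)
            if n > 1
            else np.zeros((0, 2), dtype=int)
        )
        edim = 1 if spec.bond_indicator else 0
        g = MolecularGraph(
            node_elements=elements,
            node_labels=np.zeros((n, 0)),
            edges=edges,
            edge_labels=np.ones((len(edges), edim)),
            targets=np.zeros(n_tasks),
            graph_id=f"{name}-{gi}",
        )
        y = label_oracle(g, spec.target_rule, params)
        if spec.noise_level > 0:
            if spec.task == "regression":
                y = y + rng.normal(0.0, spec.noise_level, size=y.shape)
            else:
                flip = rng.random(y.shape) < spec.noise_level
                y = np.where(flip, 1.0 - y, y)
        g.targets = y
        graphs.append(g)

    order = rng.permutation(spec.n_graphs)
    n_valid = max(1, round(spec.n_graphs * 0.1)) if spec.n_graphs >= 3 else 0
    n_test = n_valid
    n_train = spec.n_graphs - n_valid - n_test
    idx_train = order[:n_train]
    idx_valid = order[n_train : n_train + n_valid]
    idx_test = order[n_train + n_valid :]

    task_type = "regression" if spec.task == "regression" else "binary-multitask"
    metric = "RMSE" if spec.task == "regression" else "AUROC"
    prov = {
        "generator": "molcgnn.synthetic",
        "spec": {
            "n_graphs": spec.n_graphs,
            "node_count_range": list(spec.node_count_range),
            "edge_density": spec.edge_density,
            "group_probabilities": list(spec.group_probabilities),
            "task": spec.task,
            "n_tasks": n_tasks,
            "target_rule": spec.target_rule,
            "rule_params": {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in params.items()
            },
            "noise_level": spec.noise_level,
            "bond_indicator": spec.bond_indicator,
            "seed": spec.seed,
        },
    }
    return Dataset(
        name=name,
        task_type=task_type,
        n_tasks=n_tasks,
        metric=metric,
        splits={
            "train": [graphs[i] for i in idx_train],
            "valid": [graphs[i] for i in idx_valid],
            "test": [graphs[i] for i in idx_test],
        },
        provenance=prov,
    )
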