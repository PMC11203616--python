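"""Graph serialization: the package's JSON dialect and an OGB-layout reader.

JSON dialect
------------
One file per dataset split: a top-level list of graph records

    {"id": str,
     "elements": [symbol, ...],
     "node_features": [[...], ...],   # may be [] per node (zero-dim)
     "edges": [[u, v], ...],          # 0-based, unordered pairs
     "edge_features": [[...], ...],
     "targets": [number | null, ...]} # null encodes a missing task label

A dataset directory holds ``meta.json`` (name, task_type, n_tasks, metric,
generator provenance) plus ``train.json`` / ``valid.json`` / ``test.json``.

OGB adapter
-----------
:func:`read_ogb_dir` reads the raw CSV layout materialized on disk by the
OGB python package for graph-property-prediction molecule datasets
(``num-node-list``, ``num-edge-list``, ``edge``, ``node-feat``,
``graph-label`` CSVs, plain or gzipped).  The first node-feature column is
the OGB atomic-number index (atomic number minus one) and is mapped to an
element symbol; remaining columns are kept as node features.  The adapter
is optional and never required by the test suite.
"""

from __future__ import annotations

import gzip
import json
import os
from dataclasses import dataclass, field

import numpy as np

from .graphs import MolecularGraph

__all__ = [
    "graph_to_record",
    "record_to_graph",
    "write_graphs",
    "read_graphs",
    "read_ogb_dir",
    "Dataset",
    "write_dataset",
    "load_dataset",
]

# element symbols indexed by atomic number (1-based), for the OGB adapter
_SYMBOLS = (
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co "
    "Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb "
    "Te I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re "
    "Os Ir Pt Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf Es "
    "Fm Md No Lr"
).split()


def graph_to_record(g: MolecularGraph) -> dict:
    targets = [None if np.isnan(t) else float(t) for t in g.targets]
    return {
        "id": g.graph_id,
        "elements": list(g.node_elements),
        "node_features": g.node_labels.tolist(),
        "edges": [[int(a), int(b)] for a, b in g.edges],
        "edge_features": g.edge_labels.tolist(),
        "targets": targets,
    }


def record_to_graph(rec: dict) -> MolecularGraph:
    gid = rec.get("id", "")
    try:
        targets = np.array(
            [np.nan if t is None else float(t) for t in rec["targets"]], dtype=float
        )
        n = len(rec["elements"])
        feats = rec.get("node_features") or [[] for _ in range(n)]
        efeats = rec.get("edge_features") or [[] for _ in rec["edges"]]
        return MolecularGraph(
            node_elements=list(rec["elements"]),
            node_labels=np.asarray(feats, dtype=float).reshape(n, -1),
            edges=np.asarray(rec["edges"], dtype=int).reshape(-1, 2),
            edge_labels=np.asarray(efeats, dtype=float).reshape(len(rec["edges"]), -1),
            targets=targets,
            graph_id=gid,
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"invalid graph record {gid!r}: {exc}") from exc


def write_graphs(graphs: list[MolecularGraph], path) -> None:
    with open(path, "w") as fh:
        json.dump([graph_to_record(g) for g in graphs], fh)


def read_graphs(path, format: str = "json-dialect") -> list[MolecularGraph]:
    """Read a list of graphs from ``path`` in the declared format."""
    if format == "json-dialect":
        with open(path) as fh:
            try:
                records = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ValueError(f"cannot parse {path}: {exc}") from exc
        if not isinstance(records, list):
            raise ValueError(f"{path}: expected a top-level list of graph records")
        return [record_to_graph(r) for r in records]
    if format == "ogb-adapter":
        return read_ogb_dir(path)
    raise ValueError(f"unknown format {format!r}")


def _read_csv(dirpath: str, stem: str, dtype=float) -> np.ndarray:
    """Read ``<stem>.csv`` or ``<stem>.csv.gz`` (headerless) from a dir."""
    for name, opener in ((f"{stem}.csv", open), (f"{stem}.csv.gz", gzip.open)):
        p = os.path.join(dirpath, name)
        if os.path.exists(p):
            with opener(p, "rt") as fh:
                rows = [line.strip().split(",") for line in fh if line.strip()]
            return np.asarray(rows, dtype=dtype)
    raise FileNotFoundError(f"{stem}.csv(.gz) not found under {dirpath}")


def read_ogb_dir(path) -> list[MolecularGraph]:
    """Read molecule graphs from an OGB-package raw CSV directory.

    ``path`` may point at the dataset root (containing ``raw/``) or at the
    ``raw`` directory itself.
    """
    raw = os.path.join(path, "raw") if os.path.isdir(os.path.join(path, "raw")) else path
    n_nodes = _read_csv(raw, "num-node-list", dtype=int).reshape(-1)
    n_edges = _read_csv(raw, "num-edge-list", dtype=int).reshape(-1)
    edges = _read_csv(raw, "edge", dtype=int).reshape(-1, 2)
    node_feat = _read_csv(raw, "node-feat", dtype=float)
    labels = _read_csv(raw, "graph-label", dtype=str)
    try:
        efeat = _read_csv(raw, "edge-feat", dtype=float)
    except FileNotFoundError:
        efeat = np.zeros((edges.shape[0], 0))
    targets = np.array(
        [[np.nan if v in ("", "nan") else float(v) for v in row] for row in labels]
    )

    graphs = []
    node_off = edge_off = 0
    for gi, (nn, ne) in enumerate(zip(n_nodes, n_edges)):
        feats = node_feat[node_off : node_off + nn]
        atomic_nums = feats[:, 0].astype(int) + 1  # OGB stores Z - 1
        elements = []
        for z in atomic_nums:
            if not 1 <= z <= len(_SYMBOLS):
                raise ValueError(f"graph {gi}: atomic number {z} out of range")
            elements.append(_SYMBOLS[z - 1])
        ge = edges[edge_off : edge_off + ne]  # directed arc list
        gf = efeat[edge_off : edge_off + ne]
        # keep one direction of each symmetric arc pair
        seen: dict[tuple[int, int], np.ndarray] = {}
        for (a, b), e in zip(ge, gf):
            key = (min(a, b), max(a, b))
            if key not in seen:
                seen[key] = e
        und = np.array(sorted(seen), dtype=int).reshape(-1, 2)
        und_feat = (
            np.array([seen[tuple(k)] for k in und])
            if len(und)
            else np.zeros((0, gf.shape[1]))
        )
        graphs.append(
            MolecularGraph(
                node_elements=elements,
                node_labels=feats[:, 1:],
                edges=und,
                edge_labels=und_feat,
                targets=targets[gi],
                graph_id=f"ogb-{gi}",
            )
        )
        node_off += nn
        edge_off += ne
    return graphs


@dataclass
class Dataset:
    """A named dataset with train/valid/test splits and task metadata."""

    name: str
    task_type: str  # binary-multitask | regression
    n_tasks: int
    metric: str  # AUROC | AP | RMSE
    splits: dict[str, list[MolecularGraph]] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    @property
    def train(self):
        return self.splits["train"]

    @property
    def valid(self):
        return self.splits["valid"]

    @property
    def test(self):
        return self.splits["test"]


def write_dataset(ds: Dataset, outdir) -> None:
    os.makedirs(outdir, exist_ok=True)
    meta = {
        "name": ds.name,
        "task_type": ds.task_type,
        "n_tasks": ds.n_tasks,
        "metric": ds.metric,
        "provenance": ds.provenance,
    }
    with open(os.path.join(outdir, "meta.json"), "w") as fh:
        json.dump(meta, fh, indent=1)
    for split, graphs in ds.splits.items():
        write_graphs(graphs, os.path.join(outdir, f"{split}.json"))


def load_dataset(path) -> Dataset:
    with open(os.path.join(path, "meta.json")) as fh:
        meta = json.load(fh)
    splits = {}
    for split in ("train", "valid", "test"):
        p = os.path.join(path, f"{split}.json")
        if os.path.exists(p):
            splits[split] = read_graphs(p)
    return Dataset(
        name=meta["name"],
        task_type=meta["task_type"],
        n_tasks=meta["n_tasks"],
        metric=meta["metric"],
        splits=splits,
        provenance=meta.get("provenance", {}),
    )
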