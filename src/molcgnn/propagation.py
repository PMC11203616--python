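"""Recurrent message passing for standard and composite graph networks.

Every node n carries a state vector x_n of dimension d_x, initialized from
a seeded zero-centered uniform distribution.  For K iterations all states
are updated synchronously; the standard model applies one weight-shared
state-updating network f_w,

    x_n^t = f_w( x_n^{t-1}, l_n, sum_{m in Ne(n)} (x_m^{t-1}, l_m, e_mn) ),

while the composite model dispatches node n of type i = T(n) to a dedicated
network f_{w,i} whose message omits the neighbor label (the neighbor's type
is what its own updater encodes),

    x_n^t = f_{w,i}( x_n^{t-1}, l_n, sum_{m in Ne(n)} (x_m^{t-1}, e_mn) ).

Aggregation is the vector sum of the concatenated message components (the
empty sum is the zero vector), so the per-node aggregate decomposes into
``adjacency @ states``, ``adjacency @ labels`` and a constant edge-label
sum.  After K iterations, a single output network g_w maps each node's
(state, label) to a per-node output and the graph output is the mean over
all nodes:

    y_G = (1 / |N|) * sum_n g_w(x_n^K, l_n),

which makes y_G invariant under node relabeling.  All state-updating
networks of a composite model share the output dimension d_x so typed nodes
can exchange messages.

Training-time gradients are computed by exact backpropagation through the
unrolled K-step recurrence (see :func:`backward_graph_outputs`); the state
initialization is treated as a constant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .graphs import GraphBatch
from .nets import (
    MLPSpec,
    NetworkWeights,
    build_mlp,
    mlp_backward,
    mlp_forward_cache,
)

__all__ = [
    "NodeStateMatrix",
    "PropagationConfig",
    "GnnModel",
    "CompositeGnnModel",
    "init_states",
    "gnn_step",
    "cgnn_step",
    "propagate",
    "graph_output",
    "make_gnn",
    "make_cgnn",
    "save_model",
    "load_model",
]


@dataclass
class NodeStateMatrix:
    """Per-node state vectors at a given iteration t in 0..K."""

    states: np.ndarray  # (total_nodes, d_x)
    iteration: int = 0


@dataclass(frozen=True)
class PropagationConfig:
    """Message-passing hyperparameters.

    ``iterations`` (K) is 6 in all reference experiments; ``aggregation``
    is the sum; ``state_dim`` is d_x; initial states are uniform on
    [-init_scale, +init_scale] per coordinate, drawn with ``seed``.
    """

    iterations: int = 6
    state_dim: int = 5
    aggregation: str = "sum"
    init_scale: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations < 0:
            raise ValueError(f"iteration count K must be >= 0, got {self.iterations}")
        if self.state_dim < 1:
            raise ValueError(f"state_dim must be >= 1, got {self.state_dim}")
        if self.aggregation != "sum":
            raise ValueError(f"unsupported aggregation {self.aggregation!r}")
        if self.init_scale < 0:
            raise ValueError("init_scale must be >= 0")


@dataclass
class GnnModel:
    """Standard recurrent model: one shared f_w, one g_w."""

    state_spec: MLPSpec
    state_net: NetworkWeights
    output_spec: MLPSpec
    output_net: NetworkWeights
    propagation: PropagationConfig
    include_neighbor_label: bool = True

    def __post_init__(self) -> None:
        if self.state_spec.output_dim != self.propagation.state_dim:
            raise ValueError(
                "state-updating network output_dim must equal state_dim"
            )

    def parameters(self) -> list[np.ndarray]:
        return self.state_net.arrays() + self.output_net.arrays()

    @property
    def kind(self) -> str:
        return "gnn"


@dataclass
class CompositeGnnModel:
    """Composite model: one f_{w,i} per node type, a single shared g_w."""

    state_specs: dict[int, MLPSpec]
    state_nets: dict[int, NetworkWeights]
    output_spec: MLPSpec
    output_net: NetworkWeights
    propagation: PropagationConfig
    include_neighbor_label: bool = False

    def __post_init__(self) -> None:
        if set(self.state_specs) != set(self.state_nets):
            raise ValueError("state_specs and state_nets must share type keys")
        for t, spec in self.state_specs.items():
            if spec.output_dim != self.propagation.state_dim:
                raise ValueError(
                    f"updater for type {t}: output_dim must equal state_dim "
                    "(all types share d_x)"
                )

    @property
    def type_keys(self) -> list[int]:
        return sorted(self.state_specs)

    def parameters(self) -> list[np.ndarray]:
        params: list[np.ndarray] = []
        for t in self.type_keys:
            params += self.state_nets[t].arrays()
        return params + self.output_net.arrays()

    @property
    def kind(self) -> str:
        return "cgnn"


def init_states(node_count: int, cfg: PropagationConfig) -> NodeStateMatrix:
    """Seeded i.i.d. uniform[-init_scale, init_scale] initial states."""
    if node_count < 1:
        raise ValueError(f"node_count must be >= 1, got {node_count}")
    rng = np.random.default_rng(cfg.seed)
    states = rng.uniform(
        -cfg.init_scale, cfg.init_scale, size=(node_count, cfg.state_dim)
    )
    return NodeStateMatrix(states=states, iteration=0)


def _message_input(batch: GraphBatch, states: np.ndarray, include_neighbor_label: bool):
    """Concatenated per-node update input (x_n, l_n, aggregated message)."""
    neighbor_state_sum = batch.adjacency @ states
    parts = [states, batch.node_labels, neighbor_state_sum]
    if include_neighbor_label:
        parts.append(batch.neighbor_label_sums)
    parts.append(batch.edge_label_sums)
    return np.hstack(parts)


def _check_input_dim(spec: MLPSpec, z: np.ndarray, what: str) -> None:
    if z.shape[1] != spec.input_dim:
        raise ValueError(
            f"{what}: update input has dimension {z.shape[1]} but the "
            f"network expects {spec.input_dim} "
            "(state_dim + label dims + message dim must match)"
        )


def gnn_step(
    batch: GraphBatch, states: NodeStateMatrix, model: GnnModel
) -> NodeStateMatrix:
    """One synchronous state update of the standard model."""
    new, _ = _gnn_step_cache(batch, states.states, model)
    return NodeStateMatrix(states=new, iteration=states.iteration + 1)


def _gnn_step_cache(batch: GraphBatch, states: np.ndarray, model: GnnModel):
    z = _message_input(batch, states, model.include_neighbor_label)
    _check_input_dim(model.state_spec, z, "state-updating network")
    new, cache = mlp_forward_cache(model.state_net, model.state_spec, z)
    return new, cache


def cgnn_step(
    batch: GraphBatch, states: NodeStateMatrix, model: CompositeGnnModel
) -> NodeStateMatrix:
    """One synchronous state update dispatching each node to f_{w,T(n)}."""
    new, _ = _cgnn_step_cache(batch, states.states, model)
    return NodeStateMatrix(states=new, iteration=states.iteration + 1)


def _cgnn_step_cache(batch: GraphBatch, states: np.ndarray, model: CompositeGnnModel):
    if batch.node_types is None:
        raise ValueError("composite model requires a batch of composite graphs")
    z = _message_input(batch, states, model.include_neighbor_label)
    new = np.empty((batch.total_nodes, model.propagation.state_dim))
    caches = {}
    for t in np.unique(batch.node_types):
        t = int(t)
        if t not in model.state_nets:
            raise ValueError(
                f"no state-updating network registered for node type {t}"
            )
        idx = np.flatnonzero(batch.node_types == t)
        spec = model.state_specs[t]
        _check_input_dim(spec, z, f"state-updating network for type {t}")
        out, cache = mlp_forward_cache(model.state_nets[t], spec, z[idx])
        new[idx] = out
        caches[t] = (idx, cache)
    return new, caches


def propagate(batch: GraphBatch, model) -> NodeStateMatrix:
    """Run exactly K update steps from the seeded initial states."""
    states = init_states(batch.total_nodes, model.propagation)
    step = gnn_step if isinstance(model, GnnModel) else cgnn_step
    for _ in range(model.propagation.iterations):
        states = step(batch, states, model)
    return states


def graph_output(
    batch: GraphBatch, final_states: NodeStateMatrix, model
) -> np.ndarray:
    """Mean-over-nodes graph readout: one output vector per graph."""
    y, _ = _graph_output_cache(batch, final_states.states, model)
    return y


def _graph_output_cache(batch: GraphBatch, states: np.ndarray, model):
    z = np.hstack([states, batch.node_labels])
    _check_input_dim(model.output_spec, z, "output network")
    per_node, cache = mlp_forward_cache(model.output_net, model.output_spec, z)
    y = np.zeros((batch.n_graphs, per_node.shape[1]))
    np.add.at(y, batch.graph_membership, per_node)
    y /= batch.node_counts[:, None]
    return y, cache


# ---------------------------------------------------------------------------
# forward/backward engine used by the training loop


def forward_graph_outputs(batch: GraphBatch, model, with_cache: bool = False):
    """Full forward pass: K propagation steps plus the graph readout.

    With ``with_cache=True`` also returns the per-step caches required by
    :func:`backward_graph_outputs`.
    """
    states = init_states(batch.total_nodes, model.propagation).states
    is_composite_model = isinstance(model, CompositeGnnModel)
    step = _cgnn_step_cache if is_composite_model else _gnn_step_cache
    step_caches = []
    for _ in range(model.propagation.iterations):
        states, cache = step(batch, states, model)
        step_caches.append(cache)
    y, out_cache = _graph_output_cache(batch, states, model)
    if not with_cache:
        return y
    return y, (step_caches, out_cache)


def backward_graph_outputs(batch: GraphBatch, model, caches, d_y: np.ndarray):
    """Backpropagate d(loss)/d(y_G) through readout and K unrolled steps.

    Returns gradients as a flat list aligned with ``model.parameters()``.
    """
    step_caches, out_cache = caches
    d_x = model.propagation.state_dim
    ldim = batch.label_dim
    col0 = d_x + ldim  # first column of the aggregated neighbor-state block

    d_per_node = (d_y / batch.node_counts[:, None])[batch.graph_membership]
    dz_out, out_grads = mlp_backward(
        model.output_net, model.output_spec, out_cache, d_per_node
    )
    d_states = dz_out[:, :d_x]

    if isinstance(model, CompositeGnnModel):
        f_grads = {
            t: [np.zeros_like(a) for a in model.state_nets[t].arrays()]
            for t in model.type_keys
        }
        for cache in reversed(step_caches):
            dz_full = None
            new_d_states = np.zeros_like(d_states)
            for t, (idx, mlp_cache) in cache.items():
                dz_t, grads_t = mlp_backward(
                    model.state_nets[t], model.state_specs[t], mlp_cache,
                    d_states[idx],
                )
                for acc, g in zip(f_grads[t], grads_t):
                    acc += g
                if dz_full is None:
                    dz_full = np.zeros((batch.total_nodes, dz_t.shape[1]))
                dz_full[idx] = dz_t
            new_d_states = dz_full[:, :d_x] + batch.adjacency.T @ dz_full[
                :, col0 : col0 + d_x
            ]
            d_states = new_d_states
        flat: list[np.ndarray] = []
        for t in model.type_keys:
            flat += f_grads[t]
        return flat + out_grads

    f_grads = [np.zeros_like(a) for a in model.state_net.arrays()]
    for cache in reversed(step_caches):
        dz, grads = mlp_backward(
            model.state_net, model.state_spec, cache, d_states
        )
        for acc, g in zip(f_grads, grads):
            acc += g
        d_states = dz[:, :d_x] + batch.adjacency.T @ dz[:, col0 : col0 + d_x]
    return f_grads + out_grads


# ---------------------------------------------------------------------------
# model factories and checkpoints


def _state_input_dim(
    d_x: int, label_dim: int, edge_label_dim: int, include_neighbor_label: bool
) -> int:
    dim = d_x + label_dim + d_x + edge_label_dim
    if include_neighbor_label:
        dim += label_dim
    return dim


def make_gnn(
    *,
    label_dim: int,
    edge_label_dim: int,
    n_tasks: int,
    state_dim: int,
    hidden_state: int,
    hidden_output: int,
    activation: str,
    iterations: int = 6,
    init_scale: float = 0.1,
    seed: int = 0,
    include_neighbor_label: bool = True,
) -> GnnModel:
    """Build a standard model with seeded weights for the given data shape."""
    prop = PropagationConfig(
        iterations=iterations, state_dim=state_dim, init_scale=init_scale, seed=seed
    )
    sspec = MLPSpec(
        input_dim=_state_input_dim(
            state_dim, label_dim, edge_label_dim, include_neighbor_label
        ),
        hidden_units=hidden_state,
        output_dim=state_dim,
        hidden_activation=activation,
    )
    ospec = MLPSpec(
        input_dim=state_dim + label_dim,
        hidden_units=hidden_output,
        output_dim=n_tasks,
        hidden_activation=activation,
        output_activation="sigmoid",
    )
    return GnnModel(
        state_spec=sspec,
        state_net=build_mlp(sspec, seed),
        output_spec=ospec,
        output_net=build_mlp(ospec, seed + 1),
        propagation=prop,
        include_neighbor_label=include_neighbor_label,
    )


def make_cgnn(
    *,
    label_dim: int,
    edge_label_dim: int,
    n_tasks: int,
    state_dim: int,
    hidden_state: int,
    hidden_output: int,
    activation: str,
    types: list[int] | None = None,
    iterations: int = 6,
    init_scale: float = 0.1,
    seed: int = 0,
) -> CompositeGnnModel:
    """Build a composite model with one state updater per node type.

    By default updaters are registered for all 8 element groups so unseen
    (but supported) types in held-out data dispatch correctly.
    """
    types = sorted(types) if types is not None else list(range(1, 9))
    prop = PropagationConfig(
        iterations=iterations, state_dim=state_dim, init_scale=init_scale, seed=seed
    )
    sspec = MLPSpec(
        input_dim=_state_input_dim(state_dim, label_dim, edge_label_dim, False),
        hidden_units=hidden_state,
        output_dim=state_dim,
        hidden_activation=activation,
    )
    ospec = MLPSpec(
        input_dim=state_dim + label_dim,
        hidden_units=hidden_output,
        output_dim=n_tasks,
        hidden_activation=activation,
        output_activation="sigmoid",
    )
    return CompositeGnnModel(
        state_specs={t: sspec for t in types},
        state_nets={t: build_mlp(sspec, seed * 101 + t) for t in types},
        output_spec=ospec,
        output_net=build_mlp(ospec, seed * 101),
        propagation=prop,
    )


def _spec_to_jsonable(spec: MLPSpec) -> dict:
    return {
        "input_dim": spec.input_dim,
        "hidden_units": spec.hidden_units,
        "output_dim": spec.output_dim,
        "hidden_activation": spec.hidden_activation,
        "output_activation": spec.output_activation,
    }


def save_model(model, path, extra: dict | None = None) -> None:
    """Write a JSON checkpoint (specs, weights, propagation config)."""
    prop = model.propagation
    payload = {
        "kind": model.kind,
        "propagation": {
            "iterations": prop.iterations,
            "state_dim": prop.state_dim,
            "aggregation": prop.aggregation,
            "init_scale": prop.init_scale,
            "seed": prop.seed,
        },
        "output_spec": _spec_to_jsonable(model.output_spec),
        "output_net": model.output_net.to_jsonable(),
        "include_neighbor_label": model.include_neighbor_label,
        "extra": extra or {},
    }
    if isinstance(model, CompositeGnnModel):
        payload["state_specs"] = {
            str(t): _spec_to_jsonable(s) for t, s in model.state_specs.items()
        }
        payload["state_nets"] = {
            str(t): w.to_jsonable() for t, w in model.state_nets.items()
        }
    else:
        payload["state_spec"] = _spec_to_jsonable(model.state_spec)
        payload["state_net"] = model.state_net.to_jsonable()
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path):
    """Load a checkpoint written by :func:`save_model`.

    Returns ``(model, extra)`` where ``extra`` is the caller-supplied
    metadata dict (task type, normalizer bounds, ...).
    """
    with open(path) as fh:
        payload = json.load(fh)
    prop = PropagationConfig(**payload["propagation"])
    ospec = MLPSpec(**payload["output_spec"])
    onet = NetworkWeights.from_jsonable(payload["output_net"])
    if payload["kind"] == "cgnn":
        model = CompositeGnnModel(
            state_specs={int(t): MLPSpec(**s) for t, s in payload["state_specs"].items()},
            state_nets={
                int(t): NetworkWeights.from_jsonable(w)
                for t, w in payload["state_nets"].items()
            },
            output_spec=ospec,
            output_net=onet,
            propagation=prop,
            include_neighbor_label=payload["include_neighbor_label"],
        )
    else:
        model = GnnModel(
            state_spec=MLPSpec(**payload["state_spec"]),
            state_net=NetworkWeights.from_jsonable(payload["state_net"]),
            output_spec=ospec,
            output_net=onet,
            propagation=prop,
            include_neighbor_label=payload["include_neighbor_label"],
        )
    return model, payload.get("extra", {})
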