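"""Independent naive per-node implementation of the message-passing model.

Deliberately written with explicit Python loops and scalar arithmetic,
sharing no propagation code with the package: it re-derives the state
update, the per-type dispatch and the averaged graph readout directly from
their definitions, and serves as the oracle the vectorized implementation
is checked against.
"""

import numpy as np

SELU_ALPHA = 1.6732632423543772848170429916717
SELU_SCALE = 1.0507009873554804934193349852946


def act(name, v):
    out = np.empty_like(v, dtype=float)
    for i, x in enumerate(np.ravel(v)):
        if name == "relu":
            y = x if x > 0 else 0.0
        elif name == "tanh":
            y = np.tanh(x)
        elif name == "selu":
            y = SELU_SCALE * (x if x > 0 else SELU_ALPHA * (np.exp(x) - 1.0))
        elif name == "sigmoid":
            y = 1.0 / (1.0 + np.exp(-x))
        else:
            raise AssertionError(name)
        out.ravel()[i] = y
    return out


def mlp(weights, hidden_act, out_act, x):
    h = act(hidden_act, x @ weights.W1 + weights.b1)
    return act(out_act, h @ weights.W2 + weights.b2)


def neighbors(g):
    """adjacency lists with edge labels: node -> [(m, e_mn), ...]"""
    adj = {n: [] for n in range(g.node_count)}
    for (a, b), e in zip(g.edges, g.edge_labels):
        adj[int(a)].append((int(b), e))
        adj[int(b)].append((int(a), e))
    return adj


def gnn_step_naive(g, states, weights, activation, include_neighbor_label):
    """One synchronous update, node by node, message by message."""
    adj = neighbors(g)
    labels = g.node_labels
    new = np.zeros_like(states)
    for n in range(g.node_count):
        msg_dim = states.shape[1] + (labels.shape[1] if include_neighbor_label else 0) \
            + g.edge_labels.shape[1]
        agg = np.zeros(msg_dim)  # empty sum convention
        for m, e in adj[n]:
            parts = [states[m]]
            if include_neighbor_label:
                parts.append(labels[m])
            parts.append(e)
            agg = agg + np.concatenate(parts)
        z = np.concatenate([states[n], labels[n], agg])
        new[n] = mlp(weights, activation, activation, z[None, :])[0]
    return new


def cgnn_step_naive(g, node_types, states, weights_by_type, activation):
    """Per-type dispatch; the message omits the neighbor label."""
    adj = neighbors(g)
    labels = g.node_labels
    new = np.zeros_like(states)
    for n in range(g.node_count):
        agg = np.zeros(states.shape[1] + g.edge_labels.shape[1])
        for m, e in adj[n]:
            agg = agg + np.concatenate([states[m], e])
        z = np.concatenate([states[n], labels[n], agg])
        w = weights_by_type[int(node_types[n])]
        new[n] = mlp(w, activation, activation, z[None, :])[0]
    return new


def graph_output_naive(g, final_states, weights, activation):
    """Mean over nodes of the sigmoid-headed output network."""
    total = None
    for n in range(g.node_count):
        z = np.concatenate([final_states[n], g.node_labels[n]])
        o = mlp(weights, activation, "sigmoid", z[None, :])[0]
        total = o if total is None else total + o
    return total / g.node_count
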