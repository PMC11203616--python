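"""Single-hidden-layer MLPs used as state-updating and output networks.

All networks in the model family have exactly one hidden layer.  The hidden
layer and the output layer of a state-updating network share one activation
(relu, tanh or selu, a searched hyperparameter); the output network's final
layer uses the logistic sigmoid so graph outputs land in (0, 1) for both
classification and (normalized) regression.

Weights are initialized with seeded Glorot-uniform (fan-scaled) sampling so
that identical (spec, seed) pairs give bit-identical networks; deeper or
fancier architectures are deliberately out of scope.  Forward passes cache
pre-activations so the training module can run exact reverse-mode
differentiation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "ACTIVATIONS",
    "MLPSpec",
    "NetworkWeights",
    "build_mlp",
    "mlp_forward",
]

_SELU_ALPHA = 1.6732632423543772848170429916717
_SELU_SCALE = 1.0507009873554804934193349852946


def _relu(x):
    return np.maximum(x, 0.0)


def _drelu(x):
    return (x > 0).astype(float)


def _tanh(x):
    return np.tanh(x)


def _dtanh(x):
    t = np.tanh(x)
    return 1.0 - t * t


def _selu(x):
    neg = np.minimum(x, 0.0)  # keep exp argument bounded
    return _SELU_SCALE * np.where(x > 0, x, _SELU_ALPHA * np.expm1(neg))


def _dselu(x):
    neg = np.minimum(x, 0.0)
    return _SELU_SCALE * np.where(x > 0, 1.0, _SELU_ALPHA * np.exp(neg))


def _sigmoid(x):
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _dsigmoid(x):
    s = _sigmoid(x)
    return s * (1.0 - s)


#: activation name -> (function, derivative w.r.t. pre-activation)
ACTIVATIONS: dict[str, tuple[Callable, Callable]] = {
    "relu": (_relu, _drelu),
    "tanh": (_tanh, _dtanh),
    "selu": (_selu, _dselu),
    "sigmoid": (_sigmoid, _dsigmoid),
}

HIDDEN_ACTIVATIONS = ("relu", "tanh", "selu")


@dataclass(frozen=True)
class MLPSpec:
    """Shape and activations of a single-hidden-layer MLP.

    ``output_activation`` is either ``"same-as-hidden"`` (state-updating
    networks) or ``"sigmoid"`` (the output network's logistic head).
    """

    input_dim: int
    hidden_units: int
    output_dim: int
    hidden_activation: str = "tanh"
    output_activation: str = "same-as-hidden"

    def __post_init__(self) -> None:
        for name, v in (
            ("input_dim", self.input_dim),
            ("hidden_units", self.hidden_units),
            ("output_dim", self.output_dim),
        ):
            if int(v) < 1:
                raise ValueError(f"{name} must be a positive integer, got {v}")
        if self.hidden_activation not in HIDDEN_ACTIVATIONS:
            raise ValueError(
                f"hidden_activation must be one of {HIDDEN_ACTIVATIONS}, "
                f"got {self.hidden_activation!r}"
            )
        if self.output_activation not in ("same-as-hidden", "sigmoid"):
            raise ValueError(
                f"output_activation must be 'same-as-hidden' or 'sigmoid', "
                f"got {self.output_activation!r}"
            )

    @property
    def resolved_output_activation(self) -> str:
        if self.output_activation == "same-as-hidden":
            return self.hidden_activation
        return self.output_activation


@dataclass
class NetworkWeights:
    """Dense parameters of one MLP plus the seed they were drawn from."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    seed: int = 0

    def arrays(self) -> list[np.ndarray]:
        return [self.W1, self.b1, self.W2, self.b2]

    def copy(self) -> "NetworkWeights":
        return NetworkWeights(
            self.W1.copy(), self.b1.copy(), self.W2.copy(), self.b2.copy(), self.seed
        )

    def to_jsonable(self) -> dict:
        return {
            "W1": self.W1.tolist(),
            "b1": self.b1.tolist(),
            "W2": self.W2.tolist(),
            "b2": self.b2.tolist(),
            "seed": int(self.seed),
        }

    @classmethod
    def from_jsonable(cls, d: dict) -> "NetworkWeights":
        return cls(
            W1=np.asarray(d["W1"], dtype=float),
            b1=np.asarray(d["b1"], dtype=float),
            W2=np.asarray(d["W2"], dtype=float),
            b2=np.asarray(d["b2"], dtype=float),
            seed=int(d.get("seed", 0)),
        )


def build_mlp(spec: MLPSpec, seed: int) -> NetworkWeights:
    """Glorot-uniform initialization, fully determined by (spec, seed)."""
    rng = np.random.default_rng(seed)

    def glorot(fan_in: int, fan_out: int) -> np.ndarray:
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=(fan_in, fan_out))

    return NetworkWeights(
        W1=glorot(spec.input_dim, spec.hidden_units),
        b1=np.zeros(spec.hidden_units),
        W2=glorot(spec.hidden_units, spec.output_dim),
        b2=np.zeros(spec.output_dim),
        seed=int(seed),
    )


def mlp_forward(
    weights: NetworkWeights, spec: MLPSpec, x: np.ndarray
) -> np.ndarray:
    """Evaluate the MLP on a ``(batch, input_dim)`` array."""
    out, _ = mlp_forward_cache(weights, spec, x)
    return out


def mlp_forward_cache(weights: NetworkWeights, spec: MLPSpec, x: np.ndarray):
    """Forward pass returning the cache needed for the backward pass."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[1] != spec.input_dim:
        raise ValueError(
            f"input dimension {x.shape[1]} does not match spec.input_dim "
            f"{spec.input_dim}"
        )
    act_h, _ = ACTIVATIONS[spec.hidden_activation]
    act_o, _ = ACTIVATIONS[spec.resolved_output_activation]
    p1 = x @ weights.W1 + weights.b1
    h = act_h(p1)
    p2 = h @ weights.W2 + weights.b2
    out = act_o(p2)
    return out, (x, p1, h, p2)


def mlp_backward(weights: NetworkWeights, spec: MLPSpec, cache, d_out: np.ndarray):
    """Reverse-mode pass.

    Given the gradient of the loss w.r.t. the MLP output, returns
    ``(d_input, [dW1, db1, dW2, db2])``.
    """
    x, p1, h, p2 = cache
    _, dact_h = ACTIVATIONS[spec.hidden_activation]
    _, dact_o = ACTIVATIONS[spec.resolved_output_activation]
    dp2 = d_out * dact_o(p2)
    dW2 = h.T @ dp2
    db2 = dp2.sum(axis=0)
    dh = dp2 @ weights.W2.T
    dp1 = dh * dact_h(p1)
    dW1 = x.T @ dp1
    db1 = dp1.sum(axis=0)
    dx = dp1 @ weights.W1.T
    return dx, [dW1, db1, dW2, db2]
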