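"""Supervised training: masked losses, Adam, early stopping.

Binary / multi-task binary targets use mean binary cross-entropy over the
observed (non-missing) entries only — multi-task molecular benchmarks leave
many task labels unset and those entries must contribute neither value nor
gradient.  Regression targets are min-max normalized to [0, 1] on the
training split (the sigmoid output head covers exactly that range); the
error metric is later evaluated on the original scale after inverse
transformation.

Training runs Adam (textbook beta/epsilon constants; only the initial
learning rate is searched) for at most ``max_epochs`` epochs, evaluating
the validation loss after every epoch.  When validation loss fails to
strictly improve for ``patience`` consecutive epochs, training stops and
the weights of the best-validation epoch are restored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graphs import GraphBatch
from .propagation import backward_graph_outputs, forward_graph_outputs

__all__ = [
    "TrainConfig",
    "TargetNormalizer",
    "TrainRecord",
    "EarlyStopper",
    "TrainingDivergedError",
    "masked_loss",
    "masked_loss_grad",
    "normalize_targets",
    "fit",
]

_EPS = 1e-7  # probability clip for BCE

TASK_TYPES = ("binary-multitask", "regression")


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass(frozen=True)
class TrainConfig:
    initial_learning_rate: float = 1e-3
    max_epochs: int = 300
    patience: int = 10
    seed: int = 0
    task_type: str = "binary-multitask"
    batch_size: int | None = None  # None = full batch

    def __post_init__(self) -> None:
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.task_type not in TASK_TYPES:
            raise ValueError(
                f"task_type must be one of {TASK_TYPES}, got {self.task_type!r}"
            )
        if self.initial_learning_rate <= 0:
            raise ValueError("initial_learning_rate must be positive")


@dataclass
class TargetNormalizer:
    """Per-task affine map sending train-split min/max to 0/1."""

    minimum: np.ndarray
    maximum: np.ndarray

    def transform(self, y: np.ndarray) -> np.ndarray:
        return (y - self.minimum) / (self.maximum - self.minimum)

    def inverse(self, y: np.ndarray) -> np.ndarray:
        return y * (self.maximum - self.minimum) + self.minimum

    def to_jsonable(self) -> dict:
        return {"minimum": self.minimum.tolist(), "maximum": self.maximum.tolist()}

    @classmethod
    def from_jsonable(cls, d: dict) -> "TargetNormalizer":
        return cls(
            minimum=np.asarray(d["minimum"], dtype=float),
            maximum=np.asarray(d["maximum"], dtype=float),
        )


def normalize_targets(train_targets: np.ndarray) -> TargetNormalizer:
    """Fit the min-max normalizer on a (n_graphs, n_tasks) target matrix.

    Missing entries (NaN) are ignored; a constant target column is an error
    (nothing to regress onto, and the affine map would be degenerate).
    """
    t = np.asarray(train_targets, dtype=float)
    if t.ndim == 1:
        t = t[:, None]
    mn = np.nanmin(t, axis=0)
    mx = np.nanmax(t, axis=0)
    if np.any(~np.isfinite(mn)) or np.any(~np.isfinite(mx)):
        raise ValueError("a target column has no observed values")
    if np.any(mx <= mn):
        bad = int(np.flatnonzero(mx <= mn)[0])
        raise ValueError(
            f"target column {bad} is constant on the training split; "
            "at least two distinct values are required"
        )
    return TargetNormalizer(minimum=mn, maximum=mx)


def _observed_mask(targets: np.ndarray) -> np.ndarray:
    mask = ~np.isnan(targets)
    if not mask.any():
        raise ValueError("degenerate batch: every target entry is missing")
    return mask


def masked_loss(
    predictions: np.ndarray, targets: np.ndarray, task_type: str
) -> float:
    """Mean BCE (binary) or MSE (regression) over observed entries only."""
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(targets, dtype=float)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: predictions {p.shape} vs targets {y.shape}")
    mask = _observed_mask(y)
    if task_type == "binary-multitask":
        pc = np.clip(p[mask], _EPS, 1.0 - _EPS)
        yy = y[mask]
        return float(-np.mean(yy * np.log(pc) + (1.0 - yy) * np.log1p(-pc)))
    if task_type == "regression":
        return float(np.mean((p[mask] - y[mask]) ** 2))
    raise ValueError(f"unknown task_type {task_type!r}")


def masked_loss_grad(
    predictions: np.ndarray, targets: np.ndarray, task_type: str
) -> np.ndarray:
    """d(masked_loss)/d(predictions); zero at missing entries."""
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(targets, dtype=float)
    mask = _observed_mask(y)
    m = mask.sum()
    grad = np.zeros_like(p)
    if task_type == "binary-multitask":
        pc = np.clip(p[mask], _EPS, 1.0 - _EPS)
        grad[mask] = (pc - y[mask]) / (pc * (1.0 - pc)) / m
    elif task_type == "regression":
        grad[mask] = 2.0 * (p[mask] - y[mask]) / m
    else:
        raise ValueError(f"unknown task_type {task_type!r}")
    return grad


class Adam:
    """Adam over a list of parameter arrays, updated in place."""

    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class EarlyStopper:
    """Patience-based stopping on strict validation-loss decrease.

    Ties count as non-improvement. ``update`` returns True when the run
    should stop (``patience`` consecutive epochs without improvement).
    """

    def __init__(self, patience: int):
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.best = np.inf
        self.best_epoch = 0
        self.since_improvement = 0

    def update(self, epoch: int, val_loss: float) -> bool:
        if val_loss < self.best:
            self.best = val_loss
            self.best_epoch = epoch
            self.since_improvement = 0
            return False
        self.since_improvement += 1
        return self.since_improvement >= self.patience


@dataclass
class TrainRecord:
    train_losses: list[float] = field(default_factory=list)
    valid_losses: list[float] = field(default_factory=list)
    best_epoch: int = 0
    stopped_epoch: int = 0
    restored: bool = False
    normalizer: TargetNormalizer | None = None

    def to_jsonable(self) -> dict:
        return {
            "train_losses": self.train_losses,
            "valid_losses": self.valid_losses,
            "best_epoch": self.best_epoch,
            "stopped_epoch": self.stopped_epoch,
            "restored": self.restored,
            "normalizer": self.normalizer.to_jsonable() if self.normalizer else None,
        }


def _loss_and_grads(model, batch: GraphBatch, targets: np.ndarray, task_type: str):
    y, caches = forward_graph_outputs(batch, model, with_cache=True)
    loss = masked_loss(y, targets, task_type)
    d_y = masked_loss_grad(y, targets, task_type)
    grads = backward_graph_outputs(batch, model, caches, d_y)
    return loss, grads


def predict(model, batch: GraphBatch, normalizer: TargetNormalizer | None = None):
    """Graph outputs; denormalized to the original scale when a normalizer
    is given (regression)."""
    y = forward_graph_outputs(batch, model)
    if normalizer is not None:
        y = normalizer.inverse(y)
    return y


def fit(
    model,
    train: GraphBatch,
    valid: GraphBatch,
    cfg: TrainConfig,
    normalizer: TargetNormalizer | None = None,
):
    """Train in place; returns ``(model, TrainRecord)``.

    For regression the targets are normalized with ``normalizer`` (fitted on
    the training split when not supplied); classification targets are used
    as-is.  Fully determined by (data, config, seed).
    """
    if train.targets.shape[1] != valid.targets.shape[1]:
        raise ValueError("train and valid batches disagree on task count")
    if cfg.task_type == "regression" and normalizer is None:
        normalizer = normalize_targets(train.targets)
    train_targets = (
        normalizer.transform(train.targets) if normalizer is not None else train.targets
    )
    valid_targets = (
        normalizer.transform(valid.targets) if normalizer is not None else valid.targets
    )

    params = model.parameters()
    opt = Adam(params, lr=cfg.initial_learning_rate)
    stopper = EarlyStopper(cfg.patience)
    record = TrainRecord(normalizer=normalizer)
    best_weights = [p.copy() for p in params]
    rng = np.random.default_rng(cfg.seed)

    if cfg.batch_size is not None:
        from .graphs import batch_graphs  # minibatches re-batched per epoch

        graphs = train.graphs

    for epoch in range(1, cfg.max_epochs + 1):
        if cfg.batch_size is None:
            loss, grads = _loss_and_grads(model, train, train_targets, cfg.task_type)
            opt.step(grads)
            epoch_loss = loss
        else:
            order = rng.permutation(len(graphs))
            total, seen = 0.0, 0
            for start in range(0, len(order), cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                mb = batch_graphs([graphs[i] for i in idx])
                mb_targets = (
                    normalizer.transform(mb.targets)
                    if normalizer is not None
                    else mb.targets
                )
                loss, grads = _loss_and_grads(model, mb, mb_targets, cfg.task_type)
                opt.step(grads)
                total += loss * len(idx)
                seen += len(idx)
            epoch_loss = total / seen
        if not np.isfinite(epoch_loss):
            raise TrainingDivergedError(
                f"non-finite training loss at epoch {epoch} "
                f"(lr={cfg.initial_learning_rate})"
            )
        val_loss = masked_loss(
            forward_graph_outputs(valid, model), valid_targets, cfg.task_type
        )
        record.train_losses.append(float(epoch_loss))
        record.valid_losses.append(float(val_loss))
        improved_before = stopper.best
        stop = stopper.update(epoch, float(val_loss))
        if val_loss < improved_before:
            best_weights = [p.copy() for p in params]
        record.stopped_epoch = epoch
        if stop:
            break

    record.best_epoch = stopper.best_epoch
    for p, w in zip(params, best_weights):
        p[:] = w
    record.restored = True
    return model, record
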