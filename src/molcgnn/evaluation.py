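"""Benchmark-compatible evaluation metrics: AUROC, AP, RMSE.

The metric for each molecular benchmark is fixed by the benchmark itself:
ROC-AUC for the (possibly multi-task) classification sets, average
precision for the heavily imbalanced MUV screens, RMSE (on the original
target scale) for FreeSolv hydration free energies.  Multi-task scores are
the unweighted mean of the per-task scores over the tasks that are
evaluable in the split (both classes present for AUROC, at least one
positive for AP); missing labels are excluded per task.

AUROC uses the rank (Mann-Whitney) formulation — the probability that a
random positive outranks a random negative, ties counted half — via
scikit-learn; AP is precision averaged at each positive's rank.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "EvaluationReport",
    "auroc",
    "average_precision",
    "rmse",
    "metric_for_dataset",
    "evaluate_predictions",
]

logger = logging.getLogger(__name__)


@dataclass
class EvaluationReport:
    metric_name: str  # AUROC | AP | RMSE
    value: float
    per_task_values: list[float]
    n_examples: int

    def to_jsonable(self) -> dict:
        return {
            "metric_name": self.metric_name,
            "value": self.value,
            "per_task_values": self.per_task_values,
            "n_examples": self.n_examples,
        }


def _as_matrix(a) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    return a[:, None] if a.ndim == 1 else a


def auroc(scores, labels) -> float:
    """Area under the ROC curve; multi-task inputs are averaged per task.

    Equals the probability that a uniformly random positive receives a
    higher score than a uniformly random negative (ties count half).  A
    single-column input with only one class raises; in the multi-task mean,
    single-class tasks are dropped with a warning.
    """
    s, y = _as_matrix(scores), _as_matrix(labels)
    if s.shape != y.shape:
        raise ValueError(f"shape mismatch: scores {s.shape} vs labels {y.shape}")
    per_task = []
    for k in range(y.shape[1]):
        obs = ~np.isnan(y[:, k])
        yk, sk = y[obs, k], s[obs, k]
        if len(np.unique(yk)) < 2:
            if y.shape[1] == 1:
                raise ValueError(
                    "AUROC is undefined: only one class present among labels"
                )
            logger.warning("AUROC: task %d has a single class; dropped", k)
            continue
        per_task.append(float(roc_auc_score(yk, sk)))
    if not per_task:
        raise ValueError("AUROC is undefined: no task has both classes")
    return float(np.mean(per_task))


def average_precision(scores, labels) -> float:
    """Mean per-task average precision (precision at each positive's rank)."""
    s, y = _as_matrix(scores), _as_matrix(labels)
    if s.shape != y.shape:
        raise ValueError(f"shape mismatch: scores {s.shape} vs labels {y.shape}")
    per_task = []
    for k in range(y.shape[1]):
        obs = ~np.isnan(y[:, k])
        yk, sk = y[obs, k], s[obs, k]
        if yk.sum() < 1:
            logger.warning("AP: task %d has no positives; dropped", k)
            continue
        per_task.append(float(average_precision_score(yk, sk)))
    if not per_task:
        raise ValueError("AP is undefined: no positives in any task")
    return float(np.mean(per_task))


def rmse(predictions, targets) -> float:
    """Root mean squared error on the raw target scale."""
    p = np.asarray(predictions, dtype=float).reshape(-1)
    t = np.asarray(targets, dtype=float).reshape(-1)
    if p.shape != t.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {t.shape}")
    if p.size < 1:
        raise ValueError("RMSE requires at least one pair")
    obs = ~np.isnan(t)
    return float(np.sqrt(np.mean((p[obs] - t[obs]) ** 2)))


_DATASET_METRICS = {
    "hiv": "AUROC",
    "tox21": "AUROC",
    "tox-21": "AUROC",
    "bace": "AUROC",
    "bbbp": "AUROC",
    "clintox": "AUROC",
    "sider": "AUROC",
    "freesolv": "RMSE",
    "muv": "AP",
}


def metric_for_dataset(dataset_name: str) -> str:
    """The benchmark-defined metric (AUROC | AP | RMSE) for a dataset name.

    Accepts plain names ("FreeSolv") and the ``ogbg-mol*`` spellings.
    """
    key = dataset_name.lower().strip()
    if key.startswith("ogbg-mol"):
        key = key[len("ogbg-mol"):]
    if key not in _DATASET_METRICS:
        raise ValueError(f"unknown dataset {dataset_name!r}")
    return _DATASET_METRICS[key]


def metric_direction(metric_name: str) -> int:
    """+1 if larger is better (AUROC/AP), -1 if smaller is better (RMSE)."""
    if metric_name in ("AUROC", "AP"):
        return 1
    if metric_name == "RMSE":
        return -1
    raise ValueError(f"unknown metric {metric_name!r}")


def evaluate_predictions(predictions, targets, metric_name: str) -> EvaluationReport:
    """Score predictions against targets with the named metric."""
    p, t = _as_matrix(predictions), _as_matrix(targets)
    if metric_name == "AUROC":
        per_task = []
        for k in range(t.shape[1]):
            obs = ~np.isnan(t[:, k])
            if len(np.unique(t[obs, k])) < 2:
                continue
            per_task.append(float(roc_auc_score(t[obs, k], p[obs, k])))
        value = auroc(p, t)
    elif metric_name == "AP":
        per_task = []
        for k in range(t.shape[1]):
            obs = ~np.isnan(t[:, k])
            if t[obs, k].sum() < 1:
                continue
            per_task.append(float(average_precision_score(t[obs, k], p[obs, k])))
        value = average_precision(p, t)
    elif metric_name == "RMSE":
        per_task = [rmse(p[:, k], t[:, k]) for k in range(t.shape[1])]
        value = float(np.mean(per_task))
    else:
        raise ValueError(f"unknown metric {metric_name!r}")
    return EvaluationReport(
        metric_name=metric_name,
        value=value,
        per_task_values=per_task,
        n_examples=int(t.shape[0]),
    )
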