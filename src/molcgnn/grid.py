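"""Hyperparameter grid enumeration and sweep execution.

The reference search grid spans the initial learning rate (ILR), the hidden
units of the state-updating network (HS) and of the output network (HO),
the state dimension (SD = d_x) and the shared activation (AF):

    ILR in {1e-2, 1e-3, 1e-4, 1e-5}
    HS  in {10, 20, 30, 50}
    HO  in {20, 40, 70, 100}
    SD  in {3, 5, 10, 15, 30}
    AF  in {relu, tanh, selu}

i.e. 4*4*4*5*3 = 960 configurations per model kind.  Every configuration
is trained with early stopping, scored with the dataset's benchmark metric
on the validation split, and the grid optimum (max for AUROC/AP, min for
RMSE; ties broken by enumeration order) is finally evaluated on the test
split.  Per-config seeds derive from a base seed plus the enumeration
index so sweeps parallelize and resume reproducibly.
"""

from __future__ import annotations

import itertools
import json
import logging
import os
from dataclasses import dataclass, field, asdict

from .evaluation import evaluate_predictions, metric_direction
from .graphs import batch_graphs, heterogenize, homogenize
from .io import Dataset
from .propagation import make_cgnn, make_gnn
from .training import TrainConfig, TrainingDivergedError, fit, predict

__all__ = ["GRID_VALUES", "ModelConfig", "SweepResult", "enumerate_grid", "run_sweep"]

logger = logging.getLogger(__name__)

#: the reference grid axes, in enumeration order
GRID_VALUES = {
    "ilr": (1e-2, 1e-3, 1e-4, 1e-5),
    "hs": (10, 20, 30, 50),
    "ho": (20, 40, 70, 100),
    "sd": (3, 5, 10, 15, 30),
    "af": ("relu", "tanh", "selu"),
}


@dataclass(frozen=True)
class ModelConfig:
    """One point of the search grid for one model kind."""

    ilr: float
    hs: int
    ho: int
    sd: int
    af: str
    model_kind: str = "gnn"

    def __post_init__(self) -> None:
        if self.model_kind not in ("gnn", "cgnn"):
            raise ValueError(f"model_kind must be gnn or cgnn, got {self.model_kind!r}")
        if self.af not in ("relu", "tanh", "selu"):
            raise ValueError(f"unknown activation {self.af!r}")


def enumerate_grid(
    value_lists: dict | None = None, model_kind: str = "gnn"
) -> list[ModelConfig]:
    """Cartesian product of the hyperparameter value lists, fixed order."""
    values = dict(GRID_VALUES)
    if value_lists:
        values.update(value_lists)
    for key, vals in values.items():
        if len(tuple(vals)) == 0:
            raise ValueError(f"empty value list for hyperparameter {key!r}")
    axes = [values[k] for k in ("ilr", "hs", "ho", "sd", "af")]
    return [
        ModelConfig(ilr=i, hs=h, ho=o, sd=s, af=a, model_kind=model_kind)
        for i, h, o, s, a in itertools.product(*axes)
    ]


@dataclass
class SweepResult:
    dataset: str
    metric: str
    records: list[dict] = field(default_factory=list)  # per-config outcomes
    best_index: int = -1
    best_config: ModelConfig | None = None
    best_valid_metric: float = float("nan")
    test_metric: float = float("nan")
    selection_rule: str = ""

    def to_jsonable(self) -> dict:
        d = {
            "dataset": self.dataset,
            "metric": self.metric,
            "records": self.records,
            "best_index": self.best_index,
            "best_config": asdict(self.best_config) if self.best_config else None,
            "best_valid_metric": self.best_valid_metric,
            "test_metric": self.test_metric,
            "selection_rule": self.selection_rule,
        }
        return d


def build_model_for_dataset(
    config: ModelConfig,
    ds: Dataset,
    seed: int,
    iterations: int = 6,
):
    """Instantiate a model sized for the dataset and convert its splits.

    Returns ``(model, {split: GraphBatch})`` — homogenized (species one-hot)
    graphs for the standard model, heterogenized (typed) graphs for the
    composite one.
    """
    convert = homogenize if config.model_kind == "gnn" else heterogenize
    batches = {
        split: batch_graphs([convert(g) for g in graphs])
        for split, graphs in ds.splits.items()
    }
    any_batch = batches["train"]
    kwargs = dict(
        label_dim=any_batch.label_dim,
        edge_label_dim=any_batch.edge_label_dim,
        n_tasks=ds.n_tasks,
        state_dim=config.sd,
        hidden_state=config.hs,
        hidden_output=config.ho,
        activation=config.af,
        iterations=iterations,
        seed=seed,
    )
    model = make_gnn(**kwargs) if config.model_kind == "gnn" else make_cgnn(**kwargs)
    return model, batches


def _train_and_score(config: ModelConfig, ds: Dataset, train_cfg: TrainConfig, seed: int):
    model, batches = build_model_for_dataset(config, ds, seed)
    cfg = TrainConfig(
        initial_learning_rate=config.ilr,
        max_epochs=train_cfg.max_epochs,
        patience=train_cfg.patience,
        seed=seed,
        task_type=ds.task_type if ds.task_type == "regression" else "binary-multitask",
        batch_size=train_cfg.batch_size,
    )
    model, record = fit(model, batches["train"], batches["valid"], cfg)
    norm = record.normalizer
    valid_pred = predict(model, batches["valid"], norm)
    valid_report = evaluate_predictions(valid_pred, batches["valid"].targets, ds.metric)
    test_pred = predict(model, batches["test"], norm)
    test_report = evaluate_predictions(test_pred, batches["test"].targets, ds.metric)
    return model, record, valid_report, test_report


def run_sweep(
    ds: Dataset,
    grid: list[ModelConfig],
    train_cfg: TrainConfig,
    out_dir: str | None = None,
) -> SweepResult:
    """Train every configuration, select by validation metric, test the best.

    Configurations whose training aborts (non-finite loss, undefined
    metric) are recorded as failed and excluded from selection.  With
    ``out_dir`` set, per-config records are written as JSON and completed
    configs are skipped on re-runs (resumable sweeps).
    """
    direction = metric_direction(ds.metric)
    result = SweepResult(
        dataset=ds.name,
        metric=ds.metric,
        selection_rule=(
            f"{'max' if direction > 0 else 'min'} validation {ds.metric}; "
            "ties broken by enumeration order"
        ),
    )
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)

    for i, config in enumerate(grid):
        rec_path = os.path.join(out_dir, f"config-{i:04d}.json") if out_dir else None
        if rec_path and os.path.exists(rec_path):
            with open(rec_path) as fh:
                rec = json.load(fh)
            result.records.append(rec)
            continue
        seed = (train_cfg.seed + i) % (2**31)
        rec = {"index": i, "config": asdict(config), "seed": seed}
        try:
            _, record, valid_report, test_report = _train_and_score(
                config, ds, train_cfg, seed
            )
            rec.update(
                status="ok",
                valid_metric=valid_report.value,
                test_metric=test_report.value,
                best_epoch=record.best_epoch,
                stopped_epoch=record.stopped_epoch,
            )
        except (TrainingDivergedError, ValueError) as exc:
            logger.warning("config %d failed: %s", i, exc)
            rec.update(status="failed", error=str(exc))
        result.records.append(rec)
        if rec_path:
            with open(rec_path, "w") as fh:
                json.dump(rec, fh)

    best_i, best_v = -1, None
    for rec in result.records:
        if rec.get("status") != "ok":
            continue
        v = rec["valid_metric"]
        if best_v is None or direction * v > direction * best_v:
            best_i, best_v = rec["index"], v
    if best_i < 0:
        raise RuntimeError("sweep failed: no configuration trained successfully")
    result.best_index = best_i
    result.best_config = grid[best_i]
    result.best_valid_metric = float(best_v)
    result.test_metric = float(result.records[best_i]["test_metric"])
    if out_dir:
        with open(os.path.join(out_dir, "sweep.json"), "w") as fh:
            json.dump(result.to_jsonable(), fh, indent=1)
    return result
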