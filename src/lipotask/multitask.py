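"""Task bookkeeping, masked multitask loss, helper tasks and training.

A model is trained jointly on several regression endpoints; molecules
missing a label for a task simply contribute nothing to that task's loss
(masked mean squared error). Tasks carry a role: *primary* tasks are what
the model reports at prediction time; *helper* tasks (other datasets'
measurements, or another predictor's outputs) enter only the training loss,
acting as regularizers, and are never part of the prediction output —
which is why slow or licensed helper predictors are tolerable: they are
not needed once the model is trained.
"""

from __future__ import annotations

import json
import logging
from collections.abc import Callable, Sequence
from dataclasses import dataclass, field

import numpy as np

from . import dmpnn
from .chem_graph import (
    FEATURIZATION_VERSION,
    DirectedMolGraph,
    MoleculeRecord,
    build_directed_graph,
    canonical_smiles,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TaskSpec:
    name: str
    role: str = "primary"  # "primary" | "helper"
    source: str = ""  # provenance label, e.g. "opera", "chembl", "external_predictor"

    def __post_init__(self) -> None:
        if self.role not in ("primary", "helper"):
            raise ValueError(f"unknown task role {self.role!r}")


def check_task_specs(specs: Sequence[TaskSpec]) -> None:
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("task names must be unique")
    if not any(s.role == "primary" for s in specs):
        raise ValueError("at least one primary task is required")


@dataclass
class TargetMatrix:
    """Per-molecule, per-task observations with a missing-value mask."""

    values: np.ndarray  # (n_molecules, n_tasks), NaN where unobserved
    mask: np.ndarray  # same shape, bool

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if not np.array_equal(self.mask, np.isfinite(self.values)):
            raise ValueError("mask must be true exactly where values are finite")
        if self.values.shape[0] and not self.mask.any(axis=1).all():
            raise ValueError("every molecule needs at least one observed task")


def build_target_matrix(
    records: Sequence[MoleculeRecord], specs: Sequence[TaskSpec]
) -> TargetMatrix:
    vals = np.full((len(records), len(specs)), np.nan)
    for i, rec in enumerate(records):
        for j, spec in enumerate(specs):
            v = rec.values.get(spec.name, np.nan)
            if v is not None and np.isfinite(v):
                vals[i, j] = float(v)
    return TargetMatrix(values=vals, mask=np.isfinite(vals))


def assemble_tasks(
    datasets: Sequence[tuple[str, Sequence[MoleculeRecord]]],
    mode: str = "separate",
    merged_name: str = "merged",
) -> tuple[list[MoleculeRecord], list[TaskSpec], TargetMatrix]:
    """Combine single-property datasets into one multitask table.

    ``separate`` emits one task column per dataset (same physical property
    measured by two sources stays two tasks); ``merged`` pools everything
    into a single column. Molecules appearing in several datasets collapse
    into one row with several observed entries. Duplicate measurements for
    a molecule within one column are resolved by the median (count logged).
    """
    if mode not in ("separate", "merged"):
        raise ValueError(f"unknown mode {mode!r}")
    if any(len(recs) == 0 for _, recs in datasets):
        raise ValueError("every dataset must be non-empty")

    task_names = (
        [name for name, _ in datasets] if mode == "separate" else [merged_name]
    )
    pooled: dict[str, dict[str, list[float]]] = {}
    ids: dict[str, str | None] = {}
    order: list[str] = []
    for d_idx, (name, recs) in enumerate(datasets):
        col = name if mode == "separate" else merged_name
        for rec in recs:
            smi = canonical_smiles(rec.smiles)
            if smi not in pooled:
                pooled[smi] = {}
                ids[smi] = rec.id
                order.append(smi)
            obs = [v for v in rec.values.values() if np.isfinite(v)]
            pooled[smi].setdefault(col, []).extend(obs)

    n_dups = sum(
        1 for cols in pooled.values() for vs in cols.values() if len(vs) > 1
    )
    if n_dups:
        logger.info("resolved %d duplicate molecule/task measurements by median", n_dups)

    records = [
        MoleculeRecord(
            smiles=smi,
            id=ids[smi],
            values={c: float(np.median(vs)) for c, vs in pooled[smi].items()},
        )
        for smi in order
    ]
    specs = [TaskSpec(name=t, role="primary", source=t) for t in task_names]
    return records, specs, build_target_matrix(records, specs)


HelperProvider = Callable[[str], dict[str, float]]


def attach_helper_tasks(
    records: Sequence[MoleculeRecord],
    provider: HelperProvider | None,
    source: str = "external_predictor",
) -> tuple[list[MoleculeRecord], list[TaskSpec]]:
    """Add helper-task columns computed by ``provider`` (smiles -> values).

    The provider may be another model's predictions (the novel trick: feed
    a slower predictor's logP/logD estimates as extra loss tasks). Provider
    failures on individual molecules leave those entries masked and are
    logged. With ``provider=None`` records pass through unchanged
    (singletask path).
    """
    if provider is None:
        return list(records), []
    out: list[MoleculeRecord] = []
    helper_names: list[str] = []
    n_fail = 0
    for rec in records:
        vals = dict(rec.values)
        try:
            extra = provider(rec.smiles)
        except Exception as exc:  # provider failure -> masked entries
            n_fail += 1
            logger.warning("helper provider failed on %s: %s", rec.smiles, exc)
            extra = {}
        for k, v in extra.items():
            if k not in helper_names:
                helper_names.append(k)
            if np.isfinite(v):
                vals[k] = float(v)
        out.append(MoleculeRecord(smiles=rec.smiles, id=rec.id, values=vals))
    if n_fail:
        logger.info("helper provider failed on %d/%d molecules", n_fail, len(records))
    specs = [TaskSpec(name=n, role="helper", source=source) for n in helper_names]
    return out, specs


def masked_loss(pred: np.ndarray, targets: TargetMatrix) -> float:
    """Mean squared error over observed entries only."""
    mask = targets.mask
    n_obs = int(mask.sum())
    if n_obs == 0:
        raise ValueError("no observed entries: cannot compute a loss")
    diff = np.where(mask, pred - np.nan_to_num(targets.values), 0.0)
    return float(np.sum(diff**2) / n_obs)


def masked_loss_grad(pred: np.ndarray, targets: TargetMatrix) -> tuple[float, np.ndarray]:
    """Loss and its gradient w.r.t. predictions; exactly 0 on masked cells."""
    mask = targets.mask
    n_obs = int(mask.sum())
    if n_obs == 0:
        raise ValueError("no observed entries: cannot compute a loss")
    diff = np.where(mask, pred - np.nan_to_num(targets.values), 0.0)
    return float(np.sum(diff**2) / n_obs), 2.0 * diff / n_obs


@dataclass
class TrainedModel:
    """Weights + task list + per-task normalization scalers."""

    params: dmpnn.ModelParams
    weights: dmpnn.Weights
    tasks: list[TaskSpec]
    scaler_mean: np.ndarray  # (n_tasks,)
    scaler_sd: np.ndarray  # (n_tasks,)
    featurization_version: str = FEATURIZATION_VERSION
    history: dict = field(default_factory=dict)

    @property
    def primary_tasks(self) -> list[TaskSpec]:
        return [t for t in self.tasks if t.role == "primary"]

    def save(self, path: str) -> None:
        """Single-file checkpoint: numpy archive + JSON metadata entry."""
        meta = {
            "params": self.params.to_dict(),
            "tasks": [{"name": t.name, "role": t.role, "source": t.source} for t in self.tasks],
            "featurization_version": self.featurization_version,
            "history": self.history,
        }
        np.savez(
            path,
            __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            scaler_mean=self.scaler_mean,
            scaler_sd=self.scaler_sd,
            **self.weights,
        )

    @classmethod
    def load(cls, path: str) -> "TrainedModel":
        with np.load(path) as npz:
            meta = json.loads(bytes(npz["__meta__"]).decode())
            weights = {
                k: npz[k]
                for k in npz.files
                if k not in ("__meta__", "scaler_mean", "scaler_sd")
            }
            scaler_mean = npz["scaler_mean"]
            scaler_sd = npz["scaler_sd"]
        return cls(
            params=dmpnn.ModelParams(**meta["params"]),
            weights=weights,
            tasks=[TaskSpec(**t) for t in meta["tasks"]],
            scaler_mean=scaler_mean,
            scaler_sd=scaler_sd,
            featurization_version=meta["featurization_version"],
            history=meta.get("history", {}),
        )


class _Adam:
    def __init__(self, weights: dmpnn.Weights, beta1=0.9, beta2=0.999, eps=1e-8):
        self.m = {k: np.zeros_like(v) for k, v in weights.items()}
        self.v = {k: np.zeros_like(v) for k, v in weights.items()}
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, weights: dmpnn.Weights, grads: dmpnn.Weights, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k in weights:
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            weights[k] -= lr * mhat / (np.sqrt(vhat) + self.eps)


def _noam_lr(
    step: int,
    steps_per_epoch: int,
    epochs: int,
    warmup_epochs: float = 2.0,
    init_lr: float = 1e-4,
    max_lr: float = 1e-3,
    final_lr: float = 1e-4,
) -> float:
    """Linear warmup to max_lr, then exponential decay to final_lr."""
    warmup = max(1, int(warmup_epochs * steps_per_epoch))
    total = max(warmup + 1, epochs * steps_per_epoch)
    if step < warmup:
        return init_lr + (max_lr - init_lr) * step / warmup
    frac = (step - warmup) / (total - warmup)
    return max_lr * (final_lr / max_lr) ** min(frac, 1.0)


def _fit_scaler(targets: TargetMatrix, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-task z-score parameters from training-set observed values only."""
    vals, mask = targets.values[idx], targets.mask[idx]
    n_tasks = vals.shape[1]
    mean = np.zeros(n_tasks)
    sd = np.ones(n_tasks)
    for j in range(n_tasks):
        col = vals[mask[:, j], j]
        if col.size < 2:
            raise ValueError(f"task {j} has fewer than 2 observed training molecules")
        mean[j] = col.mean()
        s = col.std(ddof=0)
        sd[j] = s if s > 1e-12 else 1.0
    return mean, sd


def train(
    records: Sequence[MoleculeRecord],
    task_specs: Sequence[TaskSpec],
    params: dmpnn.ModelParams | None = None,
    seed: int = 0,
    epochs: int = 30,
    batch_size: int = 50,
    split: tuple[np.ndarray, np.ndarray] | None = None,
    split_sizes: tuple[float, float] = (0.9, 0.1),
    descriptors: np.ndarray | None = None,
    warmup_epochs: float = 2.0,
    init_lr: float = 1e-4,
    max_lr: float = 1e-3,
    final_lr: float = 1e-4,
    grad_clip: float | None = 10.0,
    graphs: Sequence[DirectedMolGraph] | None = None,
) -> TrainedModel:
    """Train a multitask D-MPNN; deterministic given ``seed``.

    The validation selection metric is the masked loss on *primary* tasks
    only (helpers regularize training but should not drive early stopping);
    the best-validation checkpoint is returned, with the loss history in
    ``model.history``. ``epochs=0`` returns the freshly initialized model.
    """
    task_specs = list(task_specs)
    check_task_specs(task_specs)
    targets = build_target_matrix(records, task_specs)
    n = len(records)
    n_tasks = len(task_specs)
    if params is None:
        params = dmpnn.ModelParams(n_tasks=n_tasks)
    if params.n_tasks != n_tasks:
        raise ValueError("params.n_tasks does not match the task list")

    if graphs is None:
        graphs = [build_directed_graph(r.smiles) for r in records]
    graphs = list(graphs)

    if split is None:
        rng = np.random.default_rng(seed + 7919)
        perm = rng.permutation(n)
        n_train = int(round(split_sizes[0] * n))
        train_idx, val_idx = perm[:n_train], perm[n_train:]
    else:
        train_idx, val_idx = (np.asarray(s, dtype=np.intp) for s in split)

    for j in range(n_tasks):
        if targets.mask[train_idx, j].sum() < 2:
            raise ValueError(
                f"task {task_specs[j].name!r} has fewer than 2 observed training molecules"
            )

    mean, sd = _fit_scaler(targets, train_idx)
    norm_vals = (targets.values - mean) / sd

    weights = dmpnn.init_weights(params, seed)
    primary_cols = np.array([t.role == "primary" for t in task_specs])

    def _masked_mse(idx: np.ndarray, cols: np.ndarray) -> float:
        if idx.size == 0:
            return np.nan
        preds = dmpnn.forward(
            dmpnn.batch_graphs([graphs[i] for i in idx]),
            weights,
            params,
            descriptors=descriptors[idx] if descriptors is not None else None,
        )
        mask = targets.mask[idx][:, cols]
        if mask.sum() == 0:
            return np.nan
        diff = np.where(mask, preds[:, cols] - np.nan_to_num(norm_vals[idx][:, cols]), 0.0)
        return float(np.sum(diff**2) / mask.sum())

    model = TrainedModel(
        params=params,
        weights=weights,
        tasks=task_specs,
        scaler_mean=mean,
        scaler_sd=sd,
        history={"train_loss": [], "val_loss": [], "seed": seed},
    )
    if epochs == 0:
        return model

    opt = _Adam(weights)
    shuffle_rng = np.random.default_rng(seed + 104729)
    dropout_rng = np.random.default_rng(seed + 1299709)
    steps_per_epoch = max(1, int(np.ceil(train_idx.size / batch_size)))
    step = 0
    best_val = np.inf
    best_weights = {k: v.copy() for k, v in weights.items()}

    for epoch in range(epochs):
        order = shuffle_rng.permutation(train_idx)
        epoch_loss, epoch_obs = 0.0, 0
        for start in range(0, order.size, batch_size):
            idx = order[start : start + batch_size]
            batch = dmpnn.batch_graphs([graphs[i] for i in idx])
            desc = descriptors[idx] if descriptors is not None else None
            preds, cache = dmpnn.forward(
                batch, weights, params, descriptors=desc,
                training=True, dropout_rng=dropout_rng, want_cache=True,
            )
            mask = targets.mask[idx]
            n_obs = int(mask.sum())
            diff = np.where(mask, preds - np.nan_to_num(norm_vals[idx]), 0.0)
            loss = float(np.sum(diff**2) / n_obs)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, step {step}: {loss}"
                )
            grads = dmpnn.backward(2.0 * diff / n_obs, batch, weights, params, cache)
            if grad_clip is not None:
                gnorm = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
                if gnorm > grad_clip:
                    grads = {k: g * (grad_clip / gnorm) for k, g in grads.items()}
            opt.step(weights, grads, _noam_lr(
                step, steps_per_epoch, epochs, warmup_epochs, init_lr, max_lr, final_lr
            ))
            step += 1
            epoch_loss += loss * n_obs
            epoch_obs += n_obs
        model.history["train_loss"].append(epoch_loss / max(epoch_obs, 1))

        val = _masked_mse(val_idx, primary_cols)
        model.history["val_loss"].append(None if np.isnan(val) else val)
        score = val if np.isfinite(val) else model.history["train_loss"][-1]
        if score < best_val:
            best_val = score
            best_weights = {k: v.copy() for k, v in weights.items()}

    model.weights = best_weights
    return model


def predict_primary(
    model: TrainedModel,
    smiles: Sequence[str],
    descriptors: np.ndarray | None = None,
) -> tuple[np.ndarray, dict[int, str]]:
    """Predict primary-task values in original units.

    Helper outputs are computed internally but dropped: the returned matrix
    has one column per primary task, in spec order. Unfeaturizable
    molecules yield NaN rows and an entry in the failure dict; other rows
    are unaffected. No helper provider is needed at prediction time.
    """
    graphs: list[DirectedMolGraph | None] = []
    failures: dict[int, str] = {}
    for i, smi in enumerate(smiles):
        try:
            graphs.append(build_directed_graph(smi))
        except Exception as exc:
            failures[i] = str(exc)
            graphs.append(None)
    ok = [i for i, g in enumerate(graphs) if g is not None]
    primary_cols = [i for i, t in enumerate(model.tasks) if t.role == "primary"]
    out = np.full((len(smiles), len(primary_cols)), np.nan)
    if ok:
        desc = descriptors[ok] if descriptors is not None else None
        preds = dmpnn.forward_graphs(
            [graphs[i] for i in ok],
            model.weights,
            model.params,
            descriptors=desc,
            scaler=(model.scaler_mean, model.scaler_sd),
        )
        out[ok] = preds[:, primary_cols]
    return out, failures
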