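"""Ensembles of independently seeded models with SEM uncertainty.

The production recipe trains N models (default 10) on the same data with
different seeds; the reported prediction is the member mean and its
uncertainty the standard error of the mean (sample sd over members with
the n-1 denominator, divided by sqrt(N)). A singleton ensemble degenerates
to the underlying model with SEM 0.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import multitask
from .chem_graph import MoleculeRecord
from .dmpnn import ModelParams


@dataclass
class Ensemble:
    members: list[multitask.TrainedModel]
    seeds: list[int]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble needs at least one member")
        names = [[t.name for t in m.tasks] for m in self.members]
        if any(nm != names[0] for nm in names):
            raise ValueError("members must share task ordering")
        vers = {m.featurization_version for m in self.members}
        if len(vers) > 1:
            raise ValueError("members must share featurization version")

    @property
    def primary_task_names(self) -> list[str]:
        return [t.name for t in self.members[0].primary_tasks]


@dataclass
class EnsemblePrediction:
    """mean/sem per molecule and primary task; member values kept for audit."""

    task_names: list[str]
    mean: np.ndarray  # (n_molecules, n_primary)
    sem: np.ndarray  # same shape
    member_values: np.ndarray  # (n_members, n_molecules, n_primary)
    failures: dict[int, str]

    def to_frame(self, smiles: Sequence[str], ids: Sequence[str] | None = None) -> pd.DataFrame:
        """Submission-shaped table: id, smiles, pred_<task>, sem_<task>."""
        data: dict = {
            "id": list(ids) if ids is not None else [f"mol{i}" for i in range(len(smiles))],
            "smiles": list(smiles),
        }
        for j, name in enumerate(self.task_names):
            data[f"pred_{name}"] = self.mean[:, j]
            data[f"sem_{name}"] = self.sem[:, j]
        return pd.DataFrame(data)


def train_ensemble(
    records: Sequence[MoleculeRecord],
    task_specs: Sequence[multitask.TaskSpec],
    params: ModelParams | None = None,
    n_members: int = 10,
    base_seed: int = 0,
    **train_kwargs,
) -> Ensemble:
    """Train ``n_members`` independent models with seeds base_seed + i."""
    if n_members < 1:
        raise ValueError("n_members must be >= 1")
    members, seeds = [], []
    for i in range(n_members):
        seed = base_seed + i
        try:
            members.append(
                multitask.train(records, task_specs, params=params, seed=seed, **train_kwargs)
            )
        except Exception as exc:
            raise RuntimeError(f"ensemble member {i} (seed {seed}) failed: {exc}") from exc
        seeds.append(seed)
    return Ensemble(members=members, seeds=seeds)


def predict_with_sem(ensemble: Ensemble, smiles: Sequence[str]) -> EnsemblePrediction:
    """Member-mean predictions with per-compound SEM.

    SEM = sample sd (ddof=1) of member predictions / sqrt(n_members);
    defined as 0 for a singleton ensemble. Featurization failures are
    isolated per molecule (NaN rows).
    """
    member_preds = []
    failures: dict[int, str] = {}
    for m in ensemble.members:
        preds, fails = multitask.predict_primary(m, smiles)
        member_preds.append(preds)
        failures.update(fails)
    arr = np.stack(member_preds)  # (n_members, n_mols, n_primary)
    mean = arr.mean(axis=0)
    if arr.shape[0] > 1:
        sem = arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0])
    else:
        sem = np.zeros_like(mean)
    return EnsemblePrediction(
        task_names=ensemble.primary_task_names,
        mean=mean,
        sem=sem,
        member_values=arr,
        failures=failures,
    )
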