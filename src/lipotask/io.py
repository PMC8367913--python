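"""Reading and writing molecule/property tables and run configurations.

CSV layout: a ``smiles`` column (or the first column) holds structures,
every other numeric column is a task, and empty cells mean "not
measured" (not "NA" strings). SDF (V2000) structures carry task values
as numeric tag fields.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict
from rdkit import Chem

from .chem_graph import InvalidSmilesError, MoleculeRecord, parse_smiles

logger = logging.getLogger(__name__)


def read_table(path: str | Path, format: str | None = None) -> tuple[list[MoleculeRecord], list[str]]:
    """Read molecules + task columns from CSV or SDF.

    Returns (records, task column names), preserving row order. Rows with
    unreadable structures are logged with their line/record number and
    skipped; a file with no readable rows is an error.
    """
    path = Path(path)
    if format is None:
        format = "sdf" if path.suffix.lower() == ".sdf" else "csv"
    if format == "csv":
        return _read_csv(path)
    if format == "sdf":
        return _read_sdf(path)
    raise ValueError(f"unknown format {format!r}")


def _read_csv(path: Path) -> tuple[list[MoleculeRecord], list[str]]:
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: no rows")
    smiles_col = next((c for c in df.columns if c.lower() == "smiles"), df.columns[0])
    id_col = next((c for c in df.columns if c.lower() in ("id", "name")), None)
    task_cols = [
        c
        for c in df.columns
        if c not in (smiles_col, id_col)
        and pd.api.types.is_numeric_dtype(pd.to_numeric(df[c], errors="coerce"))
        and pd.to_numeric(df[c], errors="coerce").notna().any()
    ]
    records = []
    for line, (_, row) in enumerate(df.iterrows(), start=2):
        smi = row[smiles_col]
        try:
            parse_smiles(str(smi))
        except InvalidSmilesError as exc:
            logger.warning("%s line %d: %s", path, line, exc)
            continue
        vals = {}
        for c in task_cols:
            v = pd.to_numeric(pd.Series([row[c]]), errors="coerce").iloc[0]
            if pd.notna(v):
                vals[c] = float(v)
        records.append(
            MoleculeRecord(
                smiles=str(smi),
                id=str(row[id_col]) if id_col and pd.notna(row[id_col]) else None,
                values=vals,
            )
        )
    if not records:
        raise ValueError(f"{path}: no rows with a parsable SMILES column")
    return records, task_cols


def _read_sdf(path: Path) -> tuple[list[MoleculeRecord], list[str]]:
    supplier = Chem.SDMolSupplier(str(path))
    records, task_cols = [], []
    for i, mol in enumerate(supplier):
        if mol is None:
            logger.warning("%s record %d: unreadable structure", path, i + 1)
            continue
        vals = {}
        for prop in mol.GetPropNames():
            try:
                vals[prop] = float(mol.GetProp(prop))
            except ValueError:
                continue
            if prop not in task_cols:
                task_cols.append(prop)
        name = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else None
        records.append(MoleculeRecord(smiles=Chem.MolToSmiles(mol), id=name, values=vals))
    if not records:
        raise ValueError(f"{path}: no readable molecules")
    return records, task_cols


def write_table(records: list[MoleculeRecord], task_cols: list[str], path: str | Path) -> None:
    """Write records as a molecule/task CSV (missing values = empty cells)."""
    rows = []
    for rec in records:
        row: dict = {"smiles": rec.smiles}
        if rec.id is not None:
            row["id"] = rec.id
        for c in task_cols:
            v = rec.values.get(c, np.nan)
            row[c] = v if np.isfinite(v) else np.nan
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


class RunConfig(BaseModel):
    """Full training-run configuration; round-trips losslessly via YAML.

    Field names mirror the underlying network/split options (depth,
    dropout, ffn_num_layers, hidden_size, split_sizes, split_type,
    ensemble_size, seed, epochs) so configs read like the tool's flags.
    """

    model_config = ConfigDict(extra="forbid")

    depth: int = 3
    hidden_size: int = 300
    ffn_num_layers: int = 2
    dropout: float = 0.0
    aggregation: str = "mean"
    split_type: str = "random"  # "random" | "scaffold_balanced"
    split_sizes: tuple[float, float, float] = (0.9, 0.1, 0.0)
    test_similarity_threshold: float = 0.25
    train_similarity_threshold: float = 0.4
    primary_tasks: list[str] = []
    helper_tasks: list[str] = []
    ensemble_size: int = 1
    seed: int = 0
    epochs: int = 30
    batch_size: int = 50
    n_boot: int = 1000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=False)
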