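import numpy as np
import pytest

from lipotask import MoleculeRecord, TaskSpec
from lipotask.dmpnn import ModelParams


SMALL_SMILES = [
    "C", "CC", "CCO", "c1ccccc1", "Cc1ccccc1", "CC(C)CN", "CCOC(=O)C",
    "c1ccncc1", "ClCCCl", "CC(=O)Nc1ccccc1", "OCCO", "CCCCCC",
    "C1CCCCC1", "CC#N", "BrCC(=O)O", "FC(F)(F)c1ccccc1", "CN(C)C=O",
    "c1ccc2ccccc2c1", "OC(=O)c1ccccc1O", "CSC",
]


@pytest.fixture(scope="session")
def small_smiles():
    return list(SMALL_SMILES)


@pytest.fixture(scope="session")
def tiny_params():
    return ModelParams(depth=3, hidden_size=6, ffn_num_layers=2, n_tasks=2)


def make_records(smiles, values_per_task):
    """Build records given {task: list-of-values (NaN = missing)}."""
    tasks = list(values_per_task)
    recs = []
    for i, smi in enumerate(smiles):
        vals = {
            t: float(values_per_task[t][i])
            for t in tasks
            if np.isfinite(values_per_task[t][i])
        }
        recs.append(MoleculeRecord(smiles=smi, id=f"m{i}", values=vals))
    return recs


@pytest.fixture(scope="session")
def linear_logp_records():
    """50 molecules with a simple structure-driven target for fast training."""
    rng = np.random.default_rng(42)
    from rdkit import Chem

    smiles = (SMALL_SMILES * 3)[:50]
    y = []
    for smi in smiles:
        mol = Chem.MolFromSmiles(smi)
        y.append(0.3 * mol.GetNumAtoms() + rng.normal(0, 0.1))
    return make_records(smiles, {"logp": y}), [TaskSpec("logp", "primary")]
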