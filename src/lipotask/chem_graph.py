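"""Molecular graphs, fingerprints and scaffolds.

This module turns SMILES/RDKit molecules into the directed edge graph the
message-passing network consumes, and provides the circular fingerprints
(ECFP_6 convention: Morgan radius 3), Tanimoto similarity and Bemis-Murcko
scaffolds used for dataset curation and splitting.

Hydrogens are implicit: they appear as an atom feature (attached H count),
never as graph nodes. Salts and mixtures are reduced to the largest organic
fragment before featurization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from rdkit.Chem.Scaffolds import MurckoScaffold

logger = logging.getLogger(__name__)

#: version tag stored in model checkpoints; bump on any feature change
FEATURIZATION_VERSION = "lipotask-feat-1"

_ELEMENTS = ["C", "N", "O", "F", "P", "S", "Cl", "Br", "I", "B", "Si"]
_DEGREES = [0, 1, 2, 3, 4, 5]
_FORMAL_CHARGES = [-2, -1, 0, 1, 2]
_CHIRAL_TAGS = [
    Chem.ChiralType.CHI_UNSPECIFIED,
    Chem.ChiralType.CHI_TETRAHEDRAL_CW,
    Chem.ChiralType.CHI_TETRAHEDRAL_CCW,
]
_NUM_HS = [0, 1, 2, 3, 4]
_HYBRIDIZATIONS = [
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
    Chem.HybridizationType.SP3D,
    Chem.HybridizationType.SP3D2,
]

# one extra slot per block for "other"
ATOM_FDIM = (
    (len(_ELEMENTS) + 1)
    + (len(_DEGREES) + 1)
    + (len(_FORMAL_CHARGES) + 1)
    + (len(_CHIRAL_TAGS) + 1)
    + (len(_NUM_HS) + 1)
    + (len(_HYBRIDIZATIONS) + 1)
    + 1  # aromatic
    + 1  # scaled mass
)
BOND_FDIM = 4 + 1 + 1  # order one-hot, conjugated, in-ring


class InvalidSmilesError(ValueError):
    """Raised when a SMILES string cannot be parsed into a valid molecule."""

    def __init__(self, smiles: str, reason: str = "could not be parsed"):
        self.smiles = smiles
        super().__init__(f"invalid SMILES {smiles!r}: {reason}")


@dataclass
class MoleculeRecord:
    """One molecule with per-task observations.

    ``values`` and ``observed`` share task ordering; unobserved values are
    ignored by every loss and metric computation downstream.
    """

    smiles: str
    id: str | None = None
    values: dict[str, float] = field(default_factory=dict)

    def observed_tasks(self) -> list[str]:
        return [k for k, v in self.values.items() if np.isfinite(v)]


def parse_smiles(smiles: str, keep_largest_fragment: bool = True) -> Chem.Mol:
    """Parse a SMILES string into a sanitized RDKit molecule.

    Aromaticity is perceived; for salts/mixtures the largest organic fragment
    (most heavy atoms, carbon-containing preferred) is kept and the action is
    logged. Raises :class:`InvalidSmilesError` on unparsable input or
    molecules without heavy atoms, carrying the offending string so curation
    can drop-and-log.
    """
    if not smiles or not isinstance(smiles, str):
        raise InvalidSmilesError(str(smiles), "empty input")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSmilesError(smiles)
    if mol.GetNumAtoms() == 0:
        raise InvalidSmilesError(smiles, "no heavy atoms")
    if keep_largest_fragment:
        frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
        if len(frags) > 1:
            def _key(m: Chem.Mol) -> tuple[int, int]:
                has_c = any(a.GetSymbol() == "C" for a in m.GetAtoms())
                return (int(has_c), m.GetNumAtoms())

            mol = max(frags, key=_key)
            logger.info(
                "kept largest fragment of %r -> %s", smiles, Chem.MolToSmiles(mol)
            )
    return mol


def canonical_smiles(smiles: str) -> str:
    return Chem.MolToSmiles(parse_smiles(smiles))


def _one_hot(value, choices: list) -> list[float]:
    vec = [0.0] * (len(choices) + 1)
    try:
        vec[choices.index(value)] = 1.0
    except ValueError:
        vec[-1] = 1.0
    return vec


def atom_features(atom: Chem.Atom) -> np.ndarray:
    feats = (
        _one_hot(atom.GetSymbol(), _ELEMENTS)
        + _one_hot(atom.GetTotalDegree(), _DEGREES)
        + _one_hot(atom.GetFormalCharge(), _FORMAL_CHARGES)
        + _one_hot(atom.GetChiralTag(), _CHIRAL_TAGS)
        + _one_hot(atom.GetTotalNumHs(), _NUM_HS)
        + _one_hot(atom.GetHybridization(), _HYBRIDIZATIONS)
        + [1.0 if atom.GetIsAromatic() else 0.0]
        + [atom.GetMass() * 0.01]
    )
    return np.asarray(feats, dtype=np.float64)


def bond_features(bond: Chem.Bond) -> np.ndarray:
    bt = bond.GetBondType()
    feats = [
        1.0 if bt == Chem.BondType.SINGLE else 0.0,
        1.0 if bt == Chem.BondType.DOUBLE else 0.0,
        1.0 if bt == Chem.BondType.TRIPLE else 0.0,
        1.0 if bt == Chem.BondType.AROMATIC else 0.0,
        1.0 if bond.GetIsConjugated() else 0.0,
        1.0 if bond.IsInRing() else 0.0,
    ]
    return np.asarray(feats, dtype=np.float64)


@dataclass
class DirectedMolGraph:
    """Directed-edge representation of one molecule.

    Every bond yields two opposite directed edges with identical bond
    features. ``reverse_edge`` is an involution pairing them; the network's
    message update uses it to exclude the reverse edge from incoming sums.
    """

    n_atoms: int
    n_directed_edges: int
    atom_feats: np.ndarray  # (n_atoms, ATOM_FDIM)
    edge_feats: np.ndarray  # (n_directed_edges, BOND_FDIM)
    edge_source: np.ndarray  # (E,) int
    edge_target: np.ndarray  # (E,) int
    reverse_edge: np.ndarray  # (E,) int

    def incoming_edges(self, atom: int) -> list[int]:
        """Directed edge indices pointing into ``atom``."""
        return [e for e in range(self.n_directed_edges) if self.edge_target[e] == atom]

    def validate(self) -> None:
        E = self.n_directed_edges
        assert E % 2 == 0
        rev = self.reverse_edge
        if E:
            assert np.all(rev[rev] == np.arange(E)), "reverse_edge not an involution"
            assert np.all(rev != np.arange(E))
            assert np.all(self.edge_source[rev] == self.edge_target)


def build_directed_graph(mol: Chem.Mol | str) -> DirectedMolGraph:
    """Build the directed molecular graph with atom/bond feature matrices."""
    if isinstance(mol, str):
        mol = parse_smiles(mol)
    n = mol.GetNumAtoms()
    afeat = (
        np.stack([atom_features(a) for a in mol.GetAtoms()])
        if n
        else np.zeros((0, ATOM_FDIM))
    )
    src, tgt, rev, efeat = [], [], [], []
    for bond in mol.GetBonds():
        u, v = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        f = bond_features(bond)
        e = len(src)
        src += [u, v]
        tgt += [v, u]
        rev += [e + 1, e]
        efeat += [f, f]
    E = len(src)
    g = DirectedMolGraph(
        n_atoms=n,
        n_directed_edges=E,
        atom_feats=afeat,
        edge_feats=np.stack(efeat) if E else np.zeros((0, BOND_FDIM)),
        edge_source=np.asarray(src, dtype=np.intp),
        edge_target=np.asarray(tgt, dtype=np.intp),
        reverse_edge=np.asarray(rev, dtype=np.intp),
    )
    g.validate()
    return g


_fp_generators: dict[tuple[int, int], object] = {}


def fingerprint(mol: Chem.Mol | str, radius: int = 3, n_bits: int = 2048) -> np.ndarray:
    """Circular substructure fingerprint (radius 3 = ECFP_6 convention).

    Returns a uint8 0/1 vector of length ``n_bits``. Deterministic: identical
    canonical molecules give identical bit sets.
    """
    if isinstance(mol, str):
        mol = parse_smiles(mol)
    key = (radius, n_bits)
    if key not in _fp_generators:
        _fp_generators[key] = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=n_bits
        )
    fp = _fp_generators[key].GetFingerprintAsNumPy(mol)
    return fp.astype(np.uint8)


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto coefficient |a∩b| / |a∪b| of two equal-length bit vectors.

    Two all-zero fingerprints give 0.0 by convention (cannot occur for a
    valid molecule, avoids 0/0).
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = int(np.sum(a | b))
    if union == 0:
        return 0.0
    return int(np.sum(a & b)) / union


def murcko_scaffold(mol: Chem.Mol | str) -> str:
    """Bemis-Murcko framework SMILES; acyclic molecules map to ''."""
    if isinstance(mol, str):
        mol = parse_smiles(mol)
    return MurckoScaffold.MurckoScaffoldSmiles(mol=mol)
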