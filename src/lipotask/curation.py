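"""Similarity-biased test selection, leakage filtering, and splits.

The curation recipe mimics a blind-challenge setting: pick as the test set
the pool molecules whose maximum Tanimoto similarity to a small reference
set (e.g. the 22 SAMPL7 challenge molecules) exceeds 0.25, then remove
from the remaining training pool every molecule with similarity > 0.4 to
any test molecule, so the split is simultaneously realistic and hard
(no near-duplicates leak across it).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .chem_graph import fingerprint, murcko_scaffold, tanimoto

logger = logging.getLogger(__name__)


@dataclass
class SplitResult:
    train: list[int]
    validation: list[int]
    test: list[int]
    provenance: dict = field(default_factory=dict)

    def validate(self, n: int) -> None:
        all_idx = self.train + self.validation + self.test
        if sorted(all_idx) != list(range(n)):
            raise ValueError("split does not partition the input indices")


def _fps(smiles_list, radius=3, n_bits=2048) -> np.ndarray:
    return np.stack([fingerprint(s, radius=radius, n_bits=n_bits) for s in smiles_list])


def max_similarity(
    pool_fps: np.ndarray, ref_fps: np.ndarray
) -> np.ndarray:
    """Per pool molecule, max Tanimoto over the reference set (vectorized)."""
    a = pool_fps.astype(bool)
    b = ref_fps.astype(bool)
    inter = a.astype(np.int32) @ b.T.astype(np.int32)
    pa = a.sum(axis=1, keepdims=True)
    pb = b.sum(axis=1, keepdims=True).T
    union = pa + pb - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / union, 0.0)
    return sim.max(axis=1) if sim.size else np.zeros(a.shape[0])


def select_biased_test(
    pool_smiles: list[str],
    reference_smiles: list[str],
    threshold: float = 0.25,
    radius: int = 3,
    n_bits: int = 2048,
) -> list[int]:
    """Indices whose max similarity to any reference is strictly > threshold."""
    if not pool_smiles or not reference_smiles:
        raise ValueError("pool and references must be non-empty")
    sims = max_similarity(
        _fps(pool_smiles, radius, n_bits), _fps(reference_smiles, radius, n_bits)
    )
    selected = [i for i in range(len(pool_smiles)) if sims[i] > threshold]
    logger.info(
        "biased test selection: %d/%d molecules with max TC > %g",
        len(selected), len(pool_smiles), threshold,
    )
    return selected


def filter_training(
    candidate_smiles: list[str],
    test_smiles: list[str],
    threshold: float = 0.4,
    radius: int = 3,
    n_bits: int = 2048,
) -> list[int]:
    """Keep candidates whose max similarity to every test molecule is <= threshold."""
    if not test_smiles:
        raise ValueError("test set must be non-empty")
    if not candidate_smiles:
        return []
    sims = max_similarity(
        _fps(candidate_smiles, radius, n_bits), _fps(test_smiles, radius, n_bits)
    )
    kept = [i for i in range(len(candidate_smiles)) if sims[i] <= threshold]
    logger.info(
        "training filter: removed %d/%d molecules with max TC > %g to the test set",
        len(candidate_smiles) - len(kept), len(candidate_smiles), threshold,
    )
    return kept


def curate(
    pool_smiles: list[str],
    reference_smiles: list[str],
    test_threshold: float = 0.25,
    train_threshold: float = 0.4,
) -> tuple[list[int], list[int], dict]:
    """Full recipe: biased test selection then training-leakage filter.

    Returns (train indices, test indices, provenance) over the pool.
    """
    test_idx = select_biased_test(pool_smiles, reference_smiles, test_threshold)
    test_set = set(test_idx)
    remainder = [i for i in range(len(pool_smiles)) if i not in test_set]
    kept_local = filter_training(
        [pool_smiles[i] for i in remainder], [pool_smiles[i] for i in test_idx],
        train_threshold,
    )
    train_idx = [remainder[i] for i in kept_local]
    prov = {
        "test_threshold": test_threshold,
        "train_threshold": train_threshold,
        "n_pool": len(pool_smiles),
        "n_test": len(test_idx),
        "n_removed": len(remainder) - len(train_idx),
        "n_train": len(train_idx),
    }
    return train_idx, test_idx, prov


def _target_counts(n: int, fractions: tuple[float, float, float]) -> list[int]:
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    raw = [f * n for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    # largest-remainder rounding
    rem = sorted(range(3), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in rem[: n - sum(counts)]:
        counts[i] += 1
    return counts


def random_split(
    n: int,
    fractions: tuple[float, float, float] = (0.9, 0.1, 0.0),
    seed: int = 0,
) -> SplitResult:
    """Seeded shuffle then contiguous slicing into train/validation/test."""
    counts = _target_counts(n, fractions)
    perm = np.random.default_rng(seed).permutation(n)
    train = perm[: counts[0]]
    val = perm[counts[0] : counts[0] + counts[1]]
    test = perm[counts[0] + counts[1] :]
    res = SplitResult(
        train=[int(i) for i in train],
        validation=[int(i) for i in val],
        test=[int(i) for i in test],
        provenance={"type": "random", "fractions": list(fractions), "seed": seed},
    )
    res.validate(n)
    return res


def scaffold_balanced_split(
    smiles_list: list[str],
    fractions: tuple[float, float, float] = (0.9, 0.1, 0.0),
    seed: int = 0,
) -> SplitResult:
    """Partition molecules by Bemis-Murcko scaffold.

    Whole scaffold groups are assigned to a partition, so no scaffold spans
    two partitions. Groups larger than half the validation target are
    placed in train first; the remaining groups are shuffled by seed and
    each is assigned to the partition with the largest remaining deficit
    (ties favor train, then validation). A single scaffold exceeding the
    train fraction triggers a warning but still lands in train.
    """
    n = len(smiles_list)
    counts = _target_counts(n, fractions)
    groups: dict[str, list[int]] = {}
    for i, smi in enumerate(smiles_list):
        groups.setdefault(murcko_scaffold(smi), []).append(i)

    big_cutoff = max(counts[1], counts[2]) / 2 if (counts[1] or counts[2]) else 0
    big, small = [], []
    for scaffold, idxs in groups.items():
        if len(idxs) > counts[0]:
            logger.warning(
                "scaffold %r (%d molecules) exceeds the train target %d; assigned to train",
                scaffold, len(idxs), counts[0],
            )
        (big if big_cutoff and len(idxs) > big_cutoff else small).append(idxs)
    big.sort(key=len, reverse=True)
    if not big_cutoff:  # no val/test requested: everything is "small"
        big, small = sorted(groups.values(), key=len, reverse=True), []

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(small))
    parts: list[list[int]] = [[], [], []]
    for idxs in big:
        parts[0].extend(idxs)
    for gi in order:
        idxs = small[gi]
        deficits = [counts[k] - len(parts[k]) for k in range(3)]
        k = int(np.argmax(deficits))
        parts[k].extend(idxs)

    res = SplitResult(
        train=parts[0],
        validation=parts[1],
        test=parts[2],
        provenance={
            "type": "scaffold_balanced",
            "fractions": list(fractions),
            "seed": seed,
            "n_scaffolds": len(groups),
        },
    )
    res.validate(n)
    return res
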