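"""Similarity-biased curation and scaffold-balanced splitting.

Mimics building a blind-challenge test set: select pool molecules with
Tanimoto similarity > 0.25 to a reference set, then drop training
molecules with similarity > 0.4 to the chosen test set so nothing leaks.
"""

from lipotask import curate, scaffold_balanced_split
from lipotask.synthetic import fixture_split_pool

pool, references, tc = fixture_split_pool(seed=0)
train_idx, test_idx, prov = curate(pool, references,
                                   test_threshold=0.25, train_threshold=0.4)
print(f"pool {prov['n_pool']} molecules, {len(references)} references")
print(f"selected {prov['n_test']} test molecules (max TC to a reference > 0.25)")
print(f"removed {prov['n_removed']} near-test molecules from training (TC > 0.4)")
print(f"final training pool: {prov['n_train']}")

res = scaffold_balanced_split([pool[i] for i in train_idx],
                              fractions=(0.8, 0.2, 0.0), seed=1)
print(f"\nscaffold-balanced 80/20 split of the training pool: "
      f"{len(res.train)}/{len(res.validation)} "
      f"({res.provenance['n_scaffolds']} scaffolds, none spanning partitions)")
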