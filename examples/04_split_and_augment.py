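"""Stratified splitting and balanced augmentation arithmetic.

Applies the pipeline's split and augmentation rules to the reference
per-class specimen counts (1934 manually annotated elements over 13
classes): an 80% stratified training split with largest-remainder
rounding, then x37 label-preserving augmentation capped at 3034 elements
per class.
"""

import numpy as np

from benthoscan.classifiers import knn_k
from benthoscan.dataset import (
    REFERENCE_SPECIMEN_COUNTS,
    balance_augment,
    stratified_allocation,
)
from benthoscan.synth import generate_crop_bank

total = sum(REFERENCE_SPECIMEN_COUNTS.values())
alloc = stratified_allocation(REFERENCE_SPECIMEN_COUNTS, 0.8)
n_train = sum(alloc.values())
print(f"reference collection: {total} elements over 13 classes")
print(f"80% stratified training split: {n_train} elements")
print(f"square-root rule neighbour count: k = {knn_k(n_train)}")

augmented = {c: min(37 * n, 3034) for c, n in alloc.items()}
print(f"after x37 augmentation capped at 3034: {sum(augmented.values())} elements")
at_cap = sum(1 for v in augmented.values() if v == 3034)
print(f"  {at_cap} classes at the cap; below cap: "
      + ", ".join(f"{c}={v}" for c, v in augmented.items() if v < 3034))

# the same rule on actual crops, at a desk scale
bank = generate_crop_bank(per_class=4, seed=3, classes=("crab", "squid"))
grown = balance_augment(bank, per_original=5, class_cap=18,
                        rng=np.random.default_rng(0))
print(f"\ndemo on real crops: {len(bank)} originals -> {len(grown)} elements "
      f"(caps respected, originals kept, labels preserved)")
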