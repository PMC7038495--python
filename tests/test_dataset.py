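"""Class schema, stratified splitting and balanced augmentation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from benthoscan.dataset import (
    CLASSES,
    REFERENCE_SPECIMEN_COUNTS,
    AnnotatedElement,
    augment_element,
    balance_augment,
    flip_horizontal,
    load_elements,
    save_elements,
    scale_brightness,
    split_train_test,
    stratified_allocation,
    zoom_crop,
)

#: per-class training-set sizes implied by the 80% stratified split of the
#: reference collection (largest-remainder rounding), and the class totals
#: after x37 augmentation capped at 3034
EXPECTED_TRAIN = {
    "rockfish": 164, "king crab": 136, "squid": 77, "starfish": 135,
    "hermit crab": 147, "anemone": 78, "shrimp": 123, "sea urchin": 110,
    "eel like fish": 159, "crab": 82, "coral": 114, "turbidity": 141,
    "shadow": 81,
}
EXPECTED_AUGMENTED = {
    "rockfish": 3034, "king crab": 3034, "squid": 2849, "starfish": 3034,
    "hermit crab": 3034, "anemone": 2886, "shrimp": 3034, "sea urchin": 3034,
    "eel like fish": 3034, "crab": 3034, "coral": 3034, "turbidity": 3034,
    "shadow": 2997,
}


def _elem(label, idx, size=6):
    rng = np.random.default_rng(idx)
    return AnnotatedElement(
        element_id=f"{label}-{idx}",
        crop=rng.integers(0, 256, (size, size, 3), dtype=np.uint8),
        label=label,
    )


class TestSchema:
    def test_thirteen_unique_classes(self):
        assert len(CLASSES) == 13
        assert len(set(CLASSES)) == 13

    def test_reference_counts_total(self):
        assert sum(REFERENCE_SPECIMEN_COUNTS.values()) == 1934

    def test_label_outside_schema_rejected(self):
        with pytest.raises(ValueError):
            AnnotatedElement("x", np.zeros((2, 2), np.uint8), "octopus")


class TestStratifiedSplit:
    def test_global_size_is_floor_of_fraction(self):
        alloc = stratified_allocation(REFERENCE_SPECIMEN_COUNTS, 0.8)
        assert sum(alloc.values()) == 1547 == math.floor(0.8 * 1934)

    def test_per_class_allocation_matches_largest_remainder_arithmetic(self):
        alloc = stratified_allocation(REFERENCE_SPECIMEN_COUNTS, 0.8)
        assert alloc == EXPECTED_TRAIN

    def test_fraction_one_puts_everything_in_train(self):
        elements = [_elem("crab", i) for i in range(7)]
        sd = split_train_test(elements, 1.0, seed=0)
        assert len(sd.train) == 7 and sd.test == []

    @given(
        counts=st.lists(st.integers(1, 30), min_size=2, max_size=6),
        fraction=st.floats(0.1, 0.9),
        seed=st.integers(0, 100),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_split_disjoint_and_sized(self, counts, fraction, seed):
        elements = []
        for c, n in zip(CLASSES, counts):
            elements.extend(_elem(c, i, size=2) for i in range(n))
        sd = split_train_test(elements, fraction, seed=seed)
        train_ids = {e.element_id for e in sd.train}
        test_ids = {e.element_id for e in sd.test}
        assert not train_ids & test_ids
        assert len(train_ids) + len(test_ids) == len(elements)
        assert len(sd.train) == math.floor(fraction * len(elements))

    def test_deterministic_given_seed(self):
        elements = [_elem(c, i) for c in CLASSES[:3] for i in range(9)]
        a = split_train_test(elements, 0.8, seed=5)
        b = split_train_test(elements, 0.8, seed=5)
        assert [e.element_id for e in a.train] == [e.element_id for e in b.train]


class TestAugmentPrimitives:
    def test_horizontal_flip_is_involution(self):
        crop = _elem("squid", 1).crop
        assert np.array_equal(flip_horizontal(flip_horizontal(crop)), crop)

    def test_brightness_scale_on_constant_crop(self):
        crop = np.full((4, 4, 3), 100, np.uint8)
        assert np.all(scale_brightness(crop, 1.3) == 130)
        assert np.all(scale_brightness(crop, 3.0) == 255)  # clipped

    def test_zoom_preserves_shape(self):
        crop = _elem("squid", 2, size=11).crop
        for f in (0.8, 1.2):
            assert zoom_crop(crop, f).shape == crop.shape

    def test_augmented_copy_keeps_label_and_parent(self):
        rng = np.random.default_rng(0)
        e = _elem("shrimp", 3)
        a = augment_element(e, rng)
        assert a.label == "shrimp"
        assert a.origin == "augmented"
        assert a.parent_id == e.element_id


class TestBalanceAugment:
    def test_per_original_one_is_identity(self):
        train = [_elem("coral", i) for i in range(5)]
        out = balance_augment(train, per_original=1, class_cap=100)
        assert out == train

    def test_capped_multiplier_reproduces_reference_totals(self):
        # stratified 80% split of the reference counts, then x37 capped at
        # 3034: ten classes hit the cap, three stay below, total 39,072
        totals = {
            c: min(37 * n, 3034) for c, n in EXPECTED_TRAIN.items()
        }
        assert totals == EXPECTED_AUGMENTED
        assert sum(totals.values()) == 39072

    def test_augmented_counts_and_caps_on_small_data(self):
        rng = np.random.default_rng(1)
        train = [_elem("rockfish", i) for i in range(4)]
        train += [_elem("squid", i) for i in range(2)]
        out = balance_augment(train, per_original=5, class_cap=12, rng=rng)
        by_class = {}
        for e in out:
            by_class[e.label] = by_class.get(e.label, 0) + 1
        assert by_class == {"rockfish": 12, "squid": 10}  # capped / 5 * n_c
        originals = [e for e in out if e.origin == "manual"]
        assert len(originals) == 6  # originals never dropped
        assert all(e.label in ("rockfish", "squid") for e in out)

    def test_labels_preserved_and_parents_recorded(self):
        rng = np.random.default_rng(2)
        train = [_elem("shadow", i) for i in range(3)]
        out = balance_augment(train, per_original=3, class_cap=100, rng=rng)
        for e in out:
            if e.origin == "augmented":
                assert e.label == "shadow"
                assert e.parent_id in {t.element_id for t in train}


def test_elements_roundtrip_on_disk(tmp_path):
    elems = [_elem("anemone", i) for i in range(3)]
    save_elements(tmp_path, elems, {elems[0].element_id: "train"})
    loaded, splits = load_elements(tmp_path)
    assert [e.element_id for e in loaded] == [e.element_id for e in elems]
    assert np.array_equal(loaded[1].crop, elems[1].crop)
    assert splits == {elems[0].element_id: "train"}
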