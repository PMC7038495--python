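"""Metrics, cross-validation contracts and detection time series."""

from datetime import date

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from benthoscan.classifiers import build_config
from benthoscan.dataset import CLASSES
from benthoscan.evaluation import (
    DetectionTimeSeries,
    accuracy,
    compare_series,
    confusion_matrix,
    cross_entropy_loss,
    cross_validate,
    detection_time_series,
    macro_auc,
    per_class_recall,
    tpr_fpr,
)
from benthoscan.synth import generate_crop_bank


def pairwise_auc(pos, neg):
    """Concordant-pair oracle: P(score+ > score-) with half credit for ties."""
    wins = ties = 0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        y = list(CLASSES)
        cm = confusion_matrix(y, y)
        assert np.trace(cm.counts) == 13
        assert cm.counts.sum() == 13

    def test_hand_tally(self):
        cm = confusion_matrix(["a", "a", "b", "b"], ["a", "b", "b", "b"],
                              classes=("a", "b"))
        assert cm.counts.tolist() == [[1, 1], [0, 2]]
        assert accuracy(cm) == pytest.approx(3 / 4)

    def test_empty_input_all_zero(self):
        cm = confusion_matrix([], [])
        assert cm.counts.sum() == 0
        with pytest.raises(ValueError):
            accuracy(cm)

    def test_label_outside_schema_fatal(self):
        with pytest.raises(ValueError):
            confusion_matrix(["kraken"], ["rockfish"])


class TestRates:
    def test_binary_accuracy_from_tp_tn(self):
        # TP=8, TN=7, FP=3, FN=2 -> (8+7)/20
        cm = confusion_matrix(
            ["p"] * 10 + ["n"] * 10,
            ["p"] * 8 + ["n"] * 2 + ["p"] * 3 + ["n"] * 7,
            classes=("p", "n"),
        )
        assert accuracy(cm) == pytest.approx(0.75)

    def test_tpr_and_fpr_direct_substitution(self):
        cm = confusion_matrix(
            ["p"] * 10 + ["n"] * 10,
            ["p"] * 8 + ["n"] * 2 + ["p"] * 3 + ["n"] * 7,
            classes=("p", "n"),
        )
        tpr, fpr = tpr_fpr(cm, 0)
        assert tpr == pytest.approx(8 / 10)
        assert fpr == pytest.approx(3 / 10)

    def test_no_false_positives_gives_zero_fpr(self):
        cm = confusion_matrix(["p", "p", "n"], ["p", "p", "n"], classes=("p", "n"))
        assert tpr_fpr(cm, 0)[1] == 0.0

    def test_accuracy_one_iff_diagonal(self):
        cm = confusion_matrix(["a", "b"], ["a", "b"], classes=("a", "b"))
        assert accuracy(cm) == 1.0
        assert per_class_recall(cm) == {"a": 1.0, "b": 1.0}


class TestMacroAuc:
    def test_perfect_separation_is_one(self):
        truth = ["a"] * 3 + ["b"] * 3
        scores = np.array([[0.9, 0.1]] * 3 + [[0.1, 0.9]] * 3)
        assert macro_auc(scores, truth, ("a", "b")) == pytest.approx(1.0)

    def test_worked_single_class_example(self):
        # positives scored {0.9, 0.4}, negatives {0.8, 0.3}:
        # concordant pairs 3 of 4 -> AUC 3/4 (both one-vs-rest directions)
        truth = ["a", "a", "b", "b"]
        s_a = [0.9, 0.4, 0.8, 0.3]
        scores = np.stack([s_a, 1 - np.asarray(s_a)], axis=1)
        assert macro_auc(scores, truth, ("a", "b")) == pytest.approx(3 / 4)

    def test_identical_scores_give_half(self):
        truth = ["a", "a", "b", "b"]
        scores = np.full((4, 2), 0.5)
        assert macro_auc(scores, truth, ("a", "b")) == pytest.approx(0.5)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        truth = rng.choice(["a", "b", "c"], 30).tolist()
        scores = rng.random((30, 3))
        base = macro_auc(scores, truth, ("a", "b", "c"))
        transformed = np.exp(5 * scores)  # strictly monotone
        assert macro_auc(transformed, truth, ("a", "b", "c")) == pytest.approx(base)

    def test_absent_class_excluded_with_warning(self):
        truth = ["a", "a", "b", "b"]
        scores = np.random.default_rng(1).random((4, 3))
        with pytest.warns(UserWarning, match="absent"):
            macro_auc(scores, truth, ("a", "b", "c"))

    @given(data=st.data())
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_agrees_with_concordant_pair_oracle(self, data):
        n = data.draw(st.integers(4, 20))
        k = data.draw(st.integers(2, 4))
        classes = tuple("abcd"[:k])
        truth = data.draw(
            st.lists(st.sampled_from(classes), min_size=n, max_size=n)
        )
        if len(set(truth)) < 2:
            return
        scores = np.asarray(
            data.draw(
                st.lists(
                    st.lists(st.integers(0, 5), min_size=k, max_size=k),
                    min_size=n, max_size=n,
                )
            ),
            dtype=float,
        )
        expected = []
        t = np.asarray(truth)
        for j, c in enumerate(classes):
            if c not in set(truth):
                continue
            pos = scores[t == c, j]
            neg = scores[t != c, j]
            expected.append(pairwise_auc(pos, neg))
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            got = macro_auc(scores, truth, classes)
        assert got == pytest.approx(np.mean(expected), abs=1e-9)


def test_loss_penalizes_low_true_class_score():
    truth = ["a", "b"]
    good = np.array([[0.9, 0.1], [0.1, 0.9]])
    bad = np.array([[0.1, 0.9], [0.9, 0.1]])
    assert cross_entropy_loss(good, truth, ("a", "b")) < cross_entropy_loss(
        bad, truth, ("a", "b")
    )
    zero = np.array([[0.0, 1.0]])
    assert np.isfinite(cross_entropy_loss(zero, ["a"], ("a", "b")))


def test_chance_level_metrics_on_random_scores():
    rng = np.random.default_rng(7)
    n_per = 60
    truth = [c for c in CLASSES for _ in range(n_per)]
    scores = rng.random((13 * n_per, 13))
    pred = [CLASSES[i] for i in scores.argmax(axis=1)]
    acc = accuracy(confusion_matrix(truth, pred))
    n = len(truth)
    sd_acc = np.sqrt((1 / 13) * (12 / 13) / n)
    assert abs(acc - 1 / 13) <= 3 * sd_acc
    assert abs(macro_auc(scores, truth) - 0.5) <= 0.05


@pytest.fixture(scope="module")
def elements():
    return generate_crop_bank(per_class=6, seed=31, classes=CLASSES[:4])


class TestCrossValidate:

    def test_validation_folds_partition_elements(self, elements):
        rep = cross_validate(build_config("DT1"), elements, folds=3, seed=0)
        seen = np.concatenate(rep.fold_indices)
        assert sorted(seen) == list(range(len(elements)))

    def test_stratified_fold_sizes_differ_by_at_most_one(self, elements):
        rep = cross_validate(build_config("DT1"), elements, folds=3, seed=0)
        labels = np.asarray([e.label for e in elements])
        for c in set(labels):
            per_fold = [int((labels[idx] == c).sum()) for idx in rep.fold_indices]
            assert max(per_fold) - min(per_fold) <= 1

    def test_class_smaller_than_folds_fatal(self, elements):
        with pytest.raises(ValueError, match="smaller"):
            cross_validate(build_config("DT1"), elements, folds=7, seed=0)

    def test_report_shapes_and_ranges(self, elements):
        rep = cross_validate(build_config("RF1"), elements, folds=3, seed=1)
        assert len(rep.fold_accuracy) == 3
        assert len(rep.fold_auc) == 3
        assert 0.0 <= rep.accuracy <= 1.0
        assert 0.0 <= rep.macro_auc <= 1.0
        assert rep.confusion.total == len(elements)

    def test_augmentation_inside_training_folds_only(self, elements):
        # with augmentation on, the validation counts per fold are unchanged:
        # augmented copies exist only transiently inside each training fold
        rep = cross_validate(
            build_config("DT1"), elements, folds=3, seed=0,
            augment_params={"per_original": 3, "class_cap": 50},
        )
        assert rep.confusion.total == len(elements)
        seen = np.concatenate(rep.fold_indices)
        assert sorted(seen) == list(range(len(elements)))


class TestTimeSeries:
    def test_no_detections_gives_zero_series(self):
        series = detection_time_series(
            [], "rockfish", date_range=(date(2024, 1, 1), date(2024, 1, 3))
        )
        assert [c for _, c in series.points] == [0, 0, 0]
        assert series.images_with_detection == 0

    def test_counts_by_date_with_gap(self):
        records = [
            ("i1", date(2024, 1, 1), "rockfish"),
            ("i2", date(2024, 1, 1), "rockfish"),
            ("i3", date(2024, 1, 3), "rockfish"),
            ("i3", date(2024, 1, 3), "rockfish"),
            ("i4", date(2024, 1, 3), "rockfish"),
            ("i9", date(2024, 1, 2), "squid"),
        ]
        series = detection_time_series(records, "rockfish")
        assert [c for _, c in series.points] == [2, 0, 3]
        assert series.total == 5
        assert series.images_with_detection == 4  # i1, i2, i3 (dedup), i4

    def test_compare_identical_series_zero_difference(self):
        pts = [(date(2024, 1, 1), 2), (date(2024, 1, 2), 1)]
        a = DetectionTimeSeries("crab", pts, "automatic", 2)
        m = DetectionTimeSeries("crab", pts, "manual", 2)
        df = compare_series(a, m)
        assert df["difference"].tolist() == [0, 0]

    def test_compare_totals_and_differences(self):
        a = DetectionTimeSeries(
            "crab", [(date(2024, 1, 1), 3), (date(2024, 1, 2), 1)], "automatic", 3
        )
        m = DetectionTimeSeries(
            "crab", [(date(2024, 1, 1), 2), (date(2024, 1, 2), 1)], "manual", 2
        )
        df = compare_series(a, m)
        assert df["difference"].tolist() == [1, 0]
        assert df.attrs["auto_total"] == 4
        assert df.attrs["manual_total"] == 3

    def test_date_mismatch_fatal(self):
        a = DetectionTimeSeries("crab", [(date(2024, 1, 1), 1)], "automatic")
        m = DetectionTimeSeries("crab", [(date(2024, 1, 2), 1)], "manual")
        with pytest.raises(ValueError, match="date"):
            compare_series(a, m)

    def test_empty_range_empty_summary(self):
        a = DetectionTimeSeries("crab", [], "automatic")
        m = DetectionTimeSeries("crab", [], "manual")
        assert len(compare_series(a, m)) == 0

    def test_strictly_increasing_dates_enforced(self):
        with pytest.raises(ValueError):
            DetectionTimeSeries(
                "crab", [(date(2024, 1, 2), 1), (date(2024, 1, 1), 1)]
            )
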