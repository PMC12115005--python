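import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import surgloc as sl
from surgloc.errors import ConfigurationError, DataError, UndefinedAPError
from surgloc.evaluation import ConfusionCounts, match_dataset
from surgloc.localization import Detection
from surgloc.synthetic import GroundTruthBox
from oracles import brute_force_ap


class TestPrecisionRecallF1:
    def test_perfect_counts(self):
        assert sl.precision_recall(ConfusionCounts(tp=5)) == (1.0, 1.0)

    def test_hand_counts(self):
        p, r = sl.precision_recall(ConfusionCounts(tp=3, fp=1, fn=2))
        assert (p, r) == (0.75, 0.6)

    def test_degenerate_counts_are_zero(self):
        assert sl.precision_recall(ConfusionCounts()) == (0.0, 0.0)

    def test_f1_fixed_point_and_examples(self):
        assert sl.f1_score(0.9, 0.9) == pytest.approx(0.9)
        assert sl.f1_score(1.0, 0.5) == pytest.approx(2 / 3)
        assert sl.f1_score(0.0, 1.0) == 0.0
        assert sl.f1_score(0.0, 0.0) == 0.0


class TestAveragePrecision:
    def test_perfect_ranking(self):
        assert sl.average_precision([0.9, 0.8, 0.1], [1, 1, 0]) == 1.0

    def test_hand_example(self):
        ap = sl.average_precision([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0])
        assert ap == pytest.approx(1 * 0.5 + (2 / 3) * 0.5)

    def test_no_positives_is_undefined(self):
        with pytest.raises(UndefinedAPError):
            sl.average_precision([0.5, 0.4], [0, 0])

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(300):
            n = rng.integers(2, 40)
            scores = rng.random(n)
            labels = rng.integers(0, 2, size=n)
            if labels.sum() == 0:
                labels[0] = 1
            ours = sl.average_precision(scores, labels)
            assert ours == pytest.approx(brute_force_ap(scores, labels), abs=1e-12)

    def test_matches_sklearn(self):
        """Independent cross-check: scikit-learn uses the same rank-sum form."""
        from sklearn.metrics import average_precision_score

        rng = np.random.default_rng(23)
        for _ in range(30):
            n = rng.integers(3, 60)
            scores = rng.random(n)  # continuous scores: no tie-convention differences
            labels = rng.integers(0, 2, size=n)
            if labels.sum() == 0:
                labels[0] = 1
            assert sl.average_precision(scores, labels) == pytest.approx(
                average_precision_score(labels, scores), abs=1e-10
            )

    def test_mean_ap(self):
        assert sl.mean_ap([1.0, 1.0]) == 1.0
        assert sl.mean_ap([0.8, 0.6]) == pytest.approx(0.7)


class TestClassificationReport:
    def test_perfect_predictions(self):
        labels = np.array([[1, 0], [0, 1], [1, 1], [0, 0]])
        report = sl.classification_report(labels.astype(float), labels, ("a", "b"))
        for cls in report.per_class.values():
            assert cls["recall"] == 100.0 and cls["f1"] == 100.0 and cls["ap"] == 100.0
        assert report.mean_ap == 100.0

    def test_single_class_hand_counts(self):
        probs = np.array([[0.9], [0.8], [0.7], [0.6]])
        labels = np.array([[1], [0], [1], [0]])
        report = sl.classification_report(probs, labels, ("tool",))
        entry = report.per_class["tool"]
        assert entry["recall"] == pytest.approx(100.0)
        assert entry["f1"] == pytest.approx(100 * 2 / 3)

    def test_misaligned_inputs(self):
        with pytest.raises(DataError):
            sl.classification_report(np.zeros((3, 2)), np.zeros((4, 2)), ("a", "b"))

    def test_means_are_unweighted_class_averages(self):
        rng = np.random.default_rng(29)
        probs = rng.random((50, 3))
        labels = rng.integers(0, 2, size=(50, 3))
        labels[0] = 1  # every class has a positive
        report = sl.classification_report(probs, labels, ("a", "b", "c"))
        assert report.mean_ap == pytest.approx(
            np.mean([report.per_class[c]["ap"] for c in ("a", "b", "c")])
        )
        assert report.mean_f1 == pytest.approx(
            np.mean([report.per_class[c]["f1"] for c in ("a", "b", "c")])
        )

    @given(st.integers(min_value=1, max_value=200))
    @settings(max_examples=30, deadline=None)
    def test_binary_probabilities_reduce_to_set_arithmetic(self, seed):
        rng = np.random.default_rng(seed)
        probs = rng.integers(0, 2, size=(30, 2)).astype(float)
        labels = rng.integers(0, 2, size=(30, 2))
        labels[:3] = 1
        report = sl.classification_report(probs, labels, ("a", "b"))
        for k, name in enumerate(("a", "b")):
            tp = np.sum((probs[:, k] == 1) & (labels[:, k] == 1))
            fn = np.sum((probs[:, k] == 0) & (labels[:, k] == 1))
            expected_recall = 100.0 * tp / (tp + fn) if tp + fn else 0.0
            assert report.per_class[name]["recall"] == pytest.approx(expected_recall)


def det(cid, box, conf):
    return Detection(cid, box, conf)


def gt(cid, box):
    return GroundTruthBox(cid, box)


class TestMatchDetections:
    BOX = (0, 0, 10, 10)
    SHIFTED = (8, 0, 18, 10)  # IoU = 2/18 < 0.5 with BOX

    def test_confident_and_overlapping_is_tp_both_modes(self):
        for mode in ("paper", "standard"):
            counts = sl.match_detections([det(0, self.BOX, 0.9)], [gt(0, self.BOX)], mode=mode)
            assert (counts[0].tp, counts[0].fp, counts[0].fn) == (1, 0, 0)

    def test_confident_poorly_localized(self):
        """Paper convention: a confident miss is a false negative, not a false positive."""
        paper = sl.match_detections([det(0, self.SHIFTED, 0.9)], [gt(0, self.BOX)], mode="paper")
        assert (paper[0].tp, paper[0].fp, paper[0].fn) == (0, 0, 2)  # det + missed truth
        std = sl.match_detections([det(0, self.SHIFTED, 0.9)], [gt(0, self.BOX)], mode="standard")
        assert (std[0].tp, std[0].fp, std[0].fn) == (0, 1, 1)

    def test_low_confidence_detection(self):
        paper = sl.match_detections([det(0, self.BOX, 0.3)], [gt(0, self.BOX)], mode="paper")
        assert paper[0].tp == 0 and paper[0].fn >= 1  # counted as a miss despite overlap
        std = sl.match_detections([det(0, self.BOX, 0.3)], [gt(0, self.BOX)], mode="standard")
        assert (std[0].tp, std[0].fp, std[0].fn) == (0, 0, 1)  # ignored detection, missed truth

    def test_missed_truth(self):
        counts = sl.match_detections([], [gt(2, self.BOX)])
        assert (counts[2].tp, counts[2].fp, counts[2].fn) == (0, 0, 1)

    def test_one_to_one_matching(self):
        """Two detections cannot both claim a single ground-truth box."""
        counts = sl.match_detections(
            [det(0, self.BOX, 0.9), det(0, self.BOX, 0.8)], [gt(0, self.BOX)], mode="standard"
        )
        assert (counts[0].tp, counts[0].fp, counts[0].fn) == (1, 1, 0)

    def test_classes_never_cross_match(self):
        counts = sl.match_detections([det(1, self.BOX, 0.9)], [gt(0, self.BOX)], mode="standard")
        assert counts[0].fn == 1 and counts[1].fp == 1

    def test_standard_mode_accounts_for_every_truth(self):
        rng = np.random.default_rng(31)
        for _ in range(30):
            dets, gts = [], []
            for _ in range(rng.integers(0, 6)):
                x, y = rng.integers(0, 30, size=2)
                dets.append(det(0, (int(x), int(y), int(x + 10), int(y + 10)), float(rng.random())))
            for _ in range(rng.integers(0, 6)):
                x, y = rng.integers(0, 30, size=2)
                gts.append(gt(0, (int(x), int(y), int(x + 10), int(y + 10))))
            counts = sl.match_detections(dets, gts, mode="standard")
            if gts:
                assert counts[0].tp + counts[0].fn >= len(gts)

    def test_bad_thresholds_rejected(self):
        with pytest.raises(ConfigurationError):
            sl.match_detections([], [], conf_threshold=1.5)


class TestLocalizationReport:
    def test_perfect_detections(self):
        frames = [
            ([det(0, (0, 0, 10, 10), 1.0)], [gt(0, (0, 0, 10, 10))]),
            ([det(1, (5, 5, 20, 20), 1.0)], [gt(1, (5, 5, 20, 20))]),
        ]
        report = sl.localization_report(frames, ("a", "b"))
        assert report.localization_per_class == {"a": 100.0, "b": 100.0}
        assert report.localization_mean_f1 == 100.0

    def test_dropped_boxes_follow_closed_form(self):
        """Drop 1 of 10 truths: recall 0.9, precision 1 -> F1 = 2*0.9/1.9."""
        frames = []
        for i in range(10):
            truth = gt(0, (0, i, 10, i + 10))
            dets = [] if i == 0 else [det(0, truth.box, 0.95)]
            frames.append((dets, [truth]))
        report = sl.localization_report(frames, ("tool",), mode="paper")
        assert report.localization_per_class["tool"] == pytest.approx(100 * 2 * 0.9 / 1.9)

    def test_absent_class_omitted(self):
        frames = [([det(0, (0, 0, 5, 5), 0.9)], [gt(0, (0, 0, 5, 5))])]
        report = sl.localization_report(frames, ("a", "b"))
        assert "b" not in report.localization_per_class

    def test_accumulation_over_frames(self):
        frames = [
            ([det(0, (0, 0, 10, 10), 0.9)], [gt(0, (0, 0, 10, 10))]),
            ([], [gt(0, (0, 0, 10, 10))]),
        ]
        counts = match_dataset(frames)
        assert (counts[0].tp, counts[0].fn) == (1, 1)


class TestSplits:
    def test_threefold_eighty_videos(self):
        plan = sl.make_splits(range(80), "kfold", 3, seed=4)
        test_sizes = sorted(len(te) for _, te in plan.folds)
        assert test_sizes == [26, 27, 27]
        all_test = [v for _, te in plan.folds for v in te]
        assert sorted(all_test) == list(range(80))  # disjoint and covering
        for tr, te in plan.folds:
            assert set(tr) & set(te) == set()
            assert sorted(set(tr) | set(te)) == list(range(80))

    def test_fixed_fraction_half(self):
        plan = sl.make_splits(range(80), "fixed_fraction", 0.5, seed=4)
        (train, test), = plan.folds
        assert len(train) == 40 and len(test) == 40
        assert set(train) & set(test) == set()

    def test_seed_determinism(self):
        a = sl.make_splits(range(20), "kfold", 4, seed=9)
        b = sl.make_splits(range(20), "kfold", 4, seed=9)
        assert a == b

    def test_invalid_k(self):
        with pytest.raises(ConfigurationError):
            sl.make_splits(range(5), "kfold", 7)
        with pytest.raises(ConfigurationError):
            sl.make_splits([1], "fixed_fraction", 0.5)


def test_report_serialization(tmp_path):
    report = sl.classification_report(
        np.array([[0.9, 0.2], [0.1, 0.8]]), np.array([[1, 0], [0, 1]]), ("a", "b")
    )
    report.write_json(tmp_path / "r.json")
    report.write_csv(tmp_path / "r.csv")
    import json

    data = json.loads((tmp_path / "r.json").read_text())
    assert data["means"]["mAP"] == 100.0
    lines = (tmp_path / "r.csv").read_text().strip().splitlines()
    assert lines[0].startswith("tool,recall_pct")
    assert lines[-1].startswith("mean,")
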