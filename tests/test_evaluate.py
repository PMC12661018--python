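import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thighacc import annotations_to_epochs, bland_altman, class_metrics, confusion, interrater
from thighacc.classify import EpochLabelSeries
from thighacc.evaluate import (
    AnnotationTrack,
    Interval,
    agreement_from_confusion,
    balanced_accuracy_from,
    f1_from_precision_recall,
    overall_balanced_accuracy,
    pool_confusions,
    round_half_away,
)


class TestAnnotationAlignment:
    def test_single_interval(self):
        track = AnnotationTrack([Interval(0.0, 60.0, "walk")])
        out = annotations_to_epochs(track, 0.0, 60)
        assert out.labels == ["walk"] * 60

    def test_majority_rule_at_transition(self):
        track = AnnotationTrack([Interval(0.0, 10.4, "walk"), Interval(10.4, 20.0, "stairs")])
        out = annotations_to_epochs(track, 0.0, 20)
        assert out.labels[10] == "stairs"  # 0.4 s walk vs 0.6 s stairs

    def test_uncertain_becomes_excluded(self):
        track = AnnotationTrack([Interval(0.0, 30.0, "uncertain"), Interval(30.0, 60.0, "walk")])
        out = annotations_to_epochs(track, 0.0, 60)
        assert out.labels[:30] == ["excluded"] * 30
        assert out.labels[30:] == ["walk"] * 30

    def test_gap_becomes_excluded(self):
        track = AnnotationTrack([Interval(0.0, 10.0, "walk"), Interval(20.0, 30.0, "stand")])
        out = annotations_to_epochs(track, 0.0, 30)
        assert out.labels[12] == "excluded"

    def test_overlap_within_rater_rejected(self):
        track = AnnotationTrack([Interval(0.0, 15.0, "walk"), Interval(10.0, 20.0, "stand")])
        with pytest.raises(ValueError, match="overlap"):
            annotations_to_epochs(track, 0.0, 20)

    def test_csv_round_trip(self, tmp_path):
        track = AnnotationTrack(
            [Interval(0.0, 10.5, "walk", "r1"), Interval(10.5, 20.0, "uncertain", "r1")]
        )
        p = tmp_path / "ann.csv"
        track.to_csv(p)
        back = AnnotationTrack.from_csv(p)
        assert back.to_frame().equals(track.to_frame())


class TestConfusion:
    def test_perfect_agreement(self):
        series = EpochLabelSeries(["walk"] * 50 + ["stand"] * 50, 0.0)
        cm = confusion(series, series)
        assert cm.accuracy == 1.0
        assert np.trace(cm.counts.to_numpy()) == 100

    def test_known_corruption_rate(self):
        rng = np.random.default_rng(0)
        true = ["walk"] * 4000
        pred = [("stairs" if rng.random() < 0.05 else "walk") for _ in true]
        cm = confusion(EpochLabelSeries(true, 0.0), EpochLabelSeries(pred, 0.0))
        pct = cm.row_percent().loc["walk", "stairs"]
        assert pct == pytest.approx(5.0, abs=1.0)

    def test_pairwise_exclusion(self):
        true = EpochLabelSeries(["walk", "excluded", "walk", "stand"], 0.0)
        pred = EpochLabelSeries(["walk", "walk", "excluded", "stand"], 0.0)
        cm = confusion(true, pred)
        assert cm.total == 2

    def test_all_excluded_rejected(self):
        true = EpochLabelSeries(["excluded"] * 5, 0.0)
        pred = EpochLabelSeries(["walk"] * 5, 0.0)
        with pytest.raises(ValueError, match="no comparable"):
            confusion(true, pred)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            confusion(EpochLabelSeries(["walk"], 0.0), EpochLabelSeries(["walk"] * 2, 0.0))

    def test_pooling_sums_counts(self):
        a = confusion(EpochLabelSeries(["walk"] * 10, 0.0), EpochLabelSeries(["walk"] * 10, 0.0))
        b = confusion(
            EpochLabelSeries(["walk"] * 5 + ["run"] * 5, 0.0),
            EpochLabelSeries(["walk"] * 4 + ["run"] * 6, 0.0),
        )
        pooled = pool_confusions([a, b])
        assert pooled.total == 20
        assert pooled.counts.loc["walk", "walk"] == 14


class TestMetrics:
    def test_f1_worked_example(self):
        # precision 0.98, recall 0.89 -> 0.9328, printed as 0.93
        f1 = f1_from_precision_recall(0.98, 0.89)
        assert f1 == pytest.approx(0.9328, abs=5e-4)
        assert round_half_away(f1, 2) == 0.93

    def test_balanced_accuracy_worked_example(self):
        assert balanced_accuracy_from(0.94, 0.98) == pytest.approx(0.96)

    def test_overall_balanced_accuracy_worked_example(self):
        recalls = (0.89, 0.97, 0.94, 1.00, 0.91, 0.94)
        assert round_half_away(overall_balanced_accuracy(recalls), 2) == 0.94

    def test_perfect_classifier_all_ones(self):
        series = EpochLabelSeries(["walk"] * 30 + ["stand"] * 30 + ["run"] * 30, 0.0)
        report = class_metrics(confusion(series, series))
        assert (report.per_class[["precision", "recall", "specificity", "f1"]] == 1.0).all().all()
        assert report.overall_balanced_accuracy == 1.0

    def test_absent_class_omitted(self):
        true = EpochLabelSeries(["walk"] * 10 + ["stand"] * 10, 0.0)
        pred = EpochLabelSeries(["walk"] * 8 + ["run"] * 2 + ["stand"] * 10, 0.0)
        report = class_metrics(confusion(true, pred))
        assert "run" not in report.per_class.index  # zero true instances

    def test_matches_sklearn_on_random_labels(self):
        """Independent cross-check of the one-vs-all metric computation."""
        from sklearn.metrics import precision_recall_fscore_support, recall_score

        rng = np.random.default_rng(42)
        classes = ["sedentary", "stand", "walk", "run"]
        true = list(rng.choice(classes, 500))
        pred = list(rng.choice(classes, 500))
        report = class_metrics(
            confusion(EpochLabelSeries(true, 0.0), EpochLabelSeries(pred, 0.0))
        )
        p, r, f, _ = precision_recall_fscore_support(
            true, pred, labels=list(report.per_class.index), zero_division=0
        )
        np.testing.assert_allclose(report.per_class["precision"], p, atol=1e-12)
        np.testing.assert_allclose(report.per_class["recall"], r, atol=1e-12)
        np.testing.assert_allclose(report.per_class["f1"], f, atol=1e-12)
        assert report.overall_balanced_accuracy == pytest.approx(
            recall_score(true, pred, average="macro", zero_division=0)
        )

    def test_f1_between_precision_and_recall(self):
        rng = np.random.default_rng(7)
        true = list(rng.choice(["walk", "stand"], 200, p=[0.7, 0.3]))
        pred = list(rng.choice(["walk", "stand"], 200))
        report = class_metrics(confusion(EpochLabelSeries(true, 0.0), EpochLabelSeries(pred, 0.0)))
        for _, row in report.per_class.iterrows():
            lo, hi = sorted([row["precision"], row["recall"]])
            assert lo - 1e-12 <= row["f1"] <= hi + 1e-12


class TestInterrater:
    def test_toy_table_formula(self):
        p_o, kappa = agreement_from_confusion(np.array([[45, 5], [5, 45]]))
        assert p_o == pytest.approx(0.90)
        assert kappa == pytest.approx(0.80)

    def test_identical_tracks(self):
        track = AnnotationTrack([Interval(0.0, 50.0, "walk"), Interval(50.0, 100.0, "stand")])
        pct, kappa = interrater(track, track, 0.0, 100)
        assert (pct, kappa) == (1.0, 1.0)

    def test_constant_rater_gives_zero_kappa(self):
        a = AnnotationTrack([Interval(0.0, 50.0, "walk", "a"), Interval(50.0, 100.0, "stand", "a")])
        b = AnnotationTrack([Interval(0.0, 100.0, "walk", "b")])
        pct, kappa = interrater(a, b, 0.0, 100)
        assert pct == pytest.approx(0.5)
        assert kappa == pytest.approx(0.0, abs=1e-12)

    def test_matches_sklearn_kappa(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(3)
        labels = ["walk", "stand", "sedentary"]
        la = list(rng.choice(labels, 300))
        lb = [x if rng.random() < 0.8 else str(rng.choice(labels)) for x in la]
        a = AnnotationTrack([Interval(float(i), float(i + 1), x, "a") for i, x in enumerate(la)])
        b = AnnotationTrack([Interval(float(i), float(i + 1), x, "b") for i, x in enumerate(lb)])
        _, kappa = interrater(a, b, 0.0, 300)
        assert kappa == pytest.approx(cohen_kappa_score(la, lb), abs=1e-12)


class TestBlandAltman:
    def test_identical_lists_zero_bias(self):
        res = bland_altman([10.0, 20.0, 30.0], [10.0, 20.0, 30.0])
        assert res.mean_bias == 0.0
        assert (res.loa_low, res.loa_high) == (0.0, 0.0)

    def test_hand_computed_sd(self):
        ref = [10.0, 10.0, 10.0, 10.0, 10.0]
        test = [11.0, 9.0, 10.0, 12.0, 8.0]  # diffs 1, -1, 0, 2, -2
        res = bland_altman(test, ref)
        assert res.mean_bias == pytest.approx(0.0)
        assert res.sd_diff == pytest.approx(1.5811, abs=1e-4)
        assert res.loa_high == pytest.approx(3.099, abs=1e-3)
        assert res.loa_low == pytest.approx(-3.099, abs=1e-3)

    def test_relative_bias_display(self):
        # bias -0.5 min against reference mean 29.2 min -> -1.71%, prints -2%
        ref = np.full(10, 29.2)
        test = ref - 0.5
        res = bland_altman(test, ref)
        assert res.relative_bias_pct == pytest.approx(-1.712, abs=1e-2)
        assert res.display_relative_pct() == -2.0

    def test_zero_reference_mean_flagged(self):
        res = bland_altman([1.0, -1.0], [0.5, -0.5])
        assert res.relative_bias_pct is None
        assert res.display_relative_pct() is None

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [1.0])

    @given(st.floats(min_value=-50, max_value=50))
    @settings(derandomize=True, max_examples=30)
    def test_shift_invariance(self, c):
        test = [12.0, 15.0, 9.0, 20.0]
        ref = [10.0, 14.0, 11.0, 18.0]
        base = bland_altman(test, ref)
        shifted = bland_altman([x + c for x in test], ref)
        assert shifted.mean_bias == pytest.approx(base.mean_bias + c, abs=1e-9)
        assert shifted.sd_diff == pytest.approx(base.sd_diff, abs=1e-9)


class TestRounding:
    @pytest.mark.parametrize(
        "x, nd, expected",
        [(0.935, 2, 0.94), (-0.935, 2, -0.94), (9.5, 0, 10.0), (-1.5, 0, -2.0), (0.9328, 2, 0.93)],
    )
    def test_half_away_from_zero(self, x, nd, expected):
        assert round_half_away(x, nd) == expected
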