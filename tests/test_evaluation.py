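"""Detection matching, segmentation overlap, classification and CA9 cross-tab."""

import itertools

import numpy as np
import pytest

from dcispatial import (
    ca9_bin_crosstab,
    classification_metrics,
    f1_from_pr,
    mask_metrics,
    match_detections,
    metrics_from_counts,
)
from dcispatial.cells import CellClass
from dcispatial.evaluation import round_half_away


def brute_force_tp(pred, truth, radius):
    """Max number of one-to-one matches within radius, by enumeration."""
    pred, truth = np.asarray(pred, float), np.asarray(truth, float)
    n, m = len(pred), len(truth)
    best = 0
    for subset in itertools.permutations(range(m), min(n, m)):
        tp = sum(
            np.linalg.norm(pred[i] - truth[j]) <= radius
            for i, j in zip(range(n), subset)
        )
        best = max(best, tp)
    # permutations over pred order too, for n > m
    for subset in itertools.permutations(range(n), min(n, m)):
        tp = sum(
            np.linalg.norm(pred[i] - truth[j]) <= radius
            for j, i in zip(range(m), subset)
        )
        best = max(best, tp)
    return best


class TestDetection:
    def test_identical_points_perfect(self):
        pts = np.array([[0, 0], [5, 5], [9, 1]], float)
        ev = match_detections(pts, pts, match_radius=2.0)
        assert (ev.precision, ev.recall, ev.f1) == (1.0, 1.0, 1.0)

    def test_adopted_detector_counts_round_to_published_metrics(self):
        ev = metrics_from_counts(3591, 1200, 564)
        assert round_half_away(ev.recall, 2) == 0.86
        assert round_half_away(ev.f1, 2) == 0.80
        # recomputed precision is 3591/4791 = 0.7495 (rounds to 0.75)
        assert ev.precision == pytest.approx(3591 / 4791)

    def test_dropped_and_spurious_counts(self):
        rng = np.random.default_rng(0)
        truth = rng.uniform(0, 100, size=(10, 2))
        pred = np.vstack([truth[:8], [[500.0, 500.0]]])  # 2 dropped, 1 far spurious
        ev = match_detections(pred, truth, match_radius=10.0)
        assert (ev.TP, ev.FP, ev.FN) == (8, 1, 2)

    def test_matches_brute_force_on_small_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            pred = rng.uniform(0, 30, size=(rng.integers(1, 6), 2))
            truth = rng.uniform(0, 30, size=(rng.integers(1, 6), 2))
            ev = match_detections(pred, truth, match_radius=8.0)
            assert ev.TP == brute_force_tp(pred, truth, 8.0)

    def test_empty_inputs_degenerate_perfect(self):
        ev = match_detections(np.zeros((0, 2)), np.zeros((0, 2)))
        assert ev.degenerate and ev.f1 == 1.0

    @pytest.mark.parametrize(
        "tp,fp,fn,expect",
        [((1), 0, 0, 1.0), (0, 5, 5, 0.0)],
    )
    def test_counts_edge_cases(self, tp, fp, fn, expect):
        ev = metrics_from_counts(tp, fp, fn)
        assert ev.precision == ev.recall == ev.f1 == expect

    def test_counts_agree_with_matching_when_unambiguous(self):
        # pairwise distances all << or >> radius
        truth = np.array([[0, 0], [100, 0], [0, 100]], float)
        pred = np.array([[1, 0], [100, 1], [300, 300]], float)
        ev_match = match_detections(pred, truth, match_radius=10.0)
        ev_counts = metrics_from_counts(2, 1, 1)
        assert (ev_match.precision, ev_match.recall, ev_match.f1) == (
            ev_counts.precision,
            ev_counts.recall,
            ev_counts.f1,
        )


class TestF1:
    def test_published_pr_rounds_to_067(self):
        assert round_half_away(f1_from_pr(0.73, 0.62), 2) == 0.67

    @pytest.mark.parametrize("p,r,expect", [(1, 1, 1.0), (0.5, 0.5, 0.5)])
    def test_harmonic_mean_fixed_points(self, p, r, expect):
        assert f1_from_pr(p, r) == pytest.approx(expect)

    def test_f1_between_min_and_max(self):
        rng = np.random.default_rng(2)
        for p, r in rng.uniform(0.01, 1.0, size=(50, 2)):
            f1 = f1_from_pr(p, r)
            assert min(p, r) - 1e-12 <= f1 <= max(p, r) + 1e-12


class TestMaskMetrics:
    def test_identical_masks(self):
        m = np.zeros((20, 20), bool)
        m[5:15, 5:15] = True
        ev = mask_metrics(m, m)
        assert ev.dice == 1.0 and ev.specificity == 1.0

    def test_disjoint_equal_masks(self):
        a = np.zeros((20, 20), bool)
        b = np.zeros((20, 20), bool)
        a[:5], b[10:15] = True, True
        assert mask_metrics(a, b).dice == 0.0

    def test_half_overlap_dice(self):
        a = np.zeros((10, 20), bool)
        b = np.zeros((10, 20), bool)
        a[:, :10], b[:, 5:15] = True, True
        assert mask_metrics(a, b).dice == pytest.approx(0.5)

    def test_symmetry_and_translation_invariance(self):
        rng = np.random.default_rng(3)
        a = rng.random((30, 30)) > 0.6
        b = rng.random((30, 30)) > 0.6
        assert mask_metrics(a, b).dice == mask_metrics(b, a).dice
        assert (
            mask_metrics(np.roll(a, 4, axis=1), np.roll(b, 4, axis=1)).dice
            == mask_metrics(a, b).dice
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mask_metrics(np.zeros((3, 3), bool), np.zeros((4, 4), bool))


class TestClassification:
    def test_perfect_prediction(self):
        labels = [c.value for c in CellClass] * 20
        ev = classification_metrics(labels, labels)
        assert ev.accuracy_pct == 100.0
        assert (ev.per_predicted_pct == 100.0).all()

    def test_per_predicted_percentage_is_column_summary(self):
        true = ["stroma"] * 9 + ["CA9_pos_epithelial"]
        pred = ["stroma"] * 10  # 9 of 10 predicted-stroma are truly stroma
        ev = classification_metrics(true, pred)
        assert ev.per_predicted_pct["stroma"] == pytest.approx(90.0)

    def test_random_labels_match_analytic_accuracy(self):
        rng = np.random.default_rng(4)
        p = np.array([0.072, 0.041, 0.340, 0.430, 0.117])
        classes = [c.value for c in CellClass]
        n = 5000
        true = rng.choice(classes, size=n, p=p)
        pred = rng.choice(classes, size=n, p=p)
        expected = float(np.sum(p**2)) * 100
        ev = classification_metrics(true, pred)
        se = 100 * np.sqrt(expected / 100 * (1 - expected / 100) / n)
        assert abs(ev.accuracy_pct - expected) < 2.58 * se

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics(["stroma"], ["tumour"])


class TestCa9Crosstab:
    def test_published_row_percentage(self):
        # 11 sections in the 1-5% bin, 5 pathologist-positive -> 45%
        abundances = [0.02] * 11 + [0.005] * 3
        groups = ["Positive"] * 5 + ["Negative"] * 6 + ["Negative"] * 3
        tab = ca9_bin_crosstab(abundances, groups)
        assert tab.loc["1-5%", "n"] == 11
        assert tab.loc["1-5%", "Positive_pct"] == 45

    def test_all_negative_zero_abundance(self):
        tab = ca9_bin_crosstab([0.0] * 4, ["Negative"] * 4)
        assert tab.loc["0-1%", "n"] == 4
        assert tab.loc["0-1%", "Negative_pct"] == 100

    def test_bin_boundaries_half_open_upward(self):
        tab = ca9_bin_crosstab([0.005, 0.03, 0.2], ["Positive"] * 3)
        assert (tab["n"] == 1).all()
        # boundary values stay in the lower bin
        tab2 = ca9_bin_crosstab([0.01, 0.05], ["Negative"] * 2)
        assert tab2.loc["0-1%", "n"] == 1 and tab2.loc["1-5%", "n"] == 1

    def test_row_percentages_recompute_from_counts(self):
        rng = np.random.default_rng(5)
        a = rng.uniform(0, 0.2, size=40)
        g = rng.choice(["Positive", "Negative"], size=40)
        tab = ca9_bin_crosstab(a, g)
        for b in tab.index:
            n = tab.loc[b, "n"]
            if n:
                assert tab.loc[b, "Positive_pct"] == int(
                    round_half_away(100 * tab.loc[b, "Positive"] / n)
                )

    def test_out_of_range_abundance_rejected(self):
        with pytest.raises(ValueError):
            ca9_bin_crosstab([1.2], ["Positive"])
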