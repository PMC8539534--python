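import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hsablate import evaluation as ev
from hsablate.io import EXCLUDED, NO_DAMAGE, RING, THERMO


def _rand_mask(rng, shape=(12, 12), p=0.4):
    return rng.random(shape) < p


class TestDice:
    def test_identical_nonempty_masks(self, rng):
        m = _rand_mask(rng)
        m[0, 0] = True
        assert ev.dice(m, m) == 1.0

    def test_nonempty_truth_empty_prediction_is_zero(self):
        truth = np.zeros((8, 8), dtype=bool)
        truth[3, 3] = truth[3, 4] = True  # a 2-px region
        assert ev.dice(truth, np.zeros_like(truth)) == 0.0

    def test_both_empty_convention_is_one(self):
        z = np.zeros((5, 5), dtype=bool)
        assert ev.dice(z, z) == 1.0

    def test_matches_set_arithmetic_oracle(self, rng):
        for _ in range(10):
            a, b = _rand_mask(rng), _rand_mask(rng)
            inter = sum(
                1 for i in range(12) for j in range(12) if a[i, j] and b[i, j]
            )
            oracle = 2 * inter / (a.sum() + b.sum())
            assert ev.dice(a, b) == pytest.approx(oracle, abs=1e-12)

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        a, b = _rand_mask(rng), _rand_mask(rng)
        assert ev.dice(a, b) == ev.dice(b, a)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            ev.dice(np.zeros((3, 3), bool), np.zeros((4, 4), bool))


class TestPerClassAccuracy:
    def test_perfect_prediction_scores_one_per_class(self, rng):
        truth = rng.integers(0, 3, (10, 10))
        for cls in (0, 1, 2):
            assert ev.per_class_accuracy(truth, truth, cls) == 1.0

    def test_complemented_binary_map_scores_zero(self):
        truth = np.zeros((6, 6), dtype=int)
        truth[:3] = 1
        pred = 1 - truth
        assert ev.per_class_accuracy(pred, truth, 1) == 0.0

    def test_matches_confusion_matrix_oracle(self, rng):
        pred = rng.integers(0, 3, (9, 9))
        truth = rng.integers(0, 3, (9, 9))
        for cls in (0, 1, 2):
            tp = np.sum((pred == cls) & (truth == cls))
            tn = np.sum((pred != cls) & (truth != cls))
            oracle = (tp + tn) / pred.size
            assert ev.per_class_accuracy(pred, truth, cls) == pytest.approx(oracle)

    def test_excluded_pixels_dropped_from_both(self):
        truth = np.full((4, 4), NO_DAMAGE)
        pred = truth.copy()
        pred[0, 0] = EXCLUDED
        truth[1, 1] = EXCLUDED
        assert ev.per_class_accuracy(pred, truth, NO_DAMAGE) == 1.0

    def test_no_evaluated_pixels_rejected(self):
        e = np.full((3, 3), EXCLUDED)
        with pytest.raises(ValueError, match="no evaluated"):
            ev.per_class_accuracy(e, e, 0)


class TestRelativeError:
    def test_exact_prediction_gives_zero_map(self, rng):
        actual = rng.uniform(40, 110, (7, 7))
        np.testing.assert_allclose(ev.relative_error_map(actual, actual), 0.0)

    def test_known_signed_value(self):
        pred = np.full((2, 2), 55.0)
        actual = np.full((2, 2), 50.0)
        np.testing.assert_allclose(ev.relative_error_map(pred, actual), 10.0)
        np.testing.assert_allclose(ev.relative_error_map(actual, pred), -5.0 / 55 * 100)

    def test_matches_loop_oracle(self, rng):
        pred = rng.uniform(40, 120, (6, 5))
        actual = rng.uniform(40, 120, (6, 5))
        out = ev.relative_error_map(pred, actual)
        for i in range(6):
            for j in range(5):
                assert out[i, j] == pytest.approx(
                    (pred[i, j] - actual[i, j]) / actual[i, j] * 100, rel=1e-12
                )

    def test_mre_uses_absolute_values(self):
        rel = np.array([[10.0, -10.0]])
        assert ev.mre(rel) == pytest.approx(10.0)

    def test_mre_of_zero_map_is_zero(self):
        assert ev.mre(np.zeros((4, 4))) == 0.0

    def test_empty_region_reports_missing(self):
        rel = np.full((3, 3), np.nan)
        assert ev.mre(rel) is None

    def test_mre_matches_oracle_on_random_region(self, rng):
        rel = rng.normal(0, 20, (8, 8))
        region = _rand_mask(rng, (8, 8))
        oracle = np.mean([abs(rel[i, j]) for i in range(8) for j in range(8) if region[i, j]])
        assert ev.mre(rel, region) == pytest.approx(oracle, rel=1e-12)

    def test_aggregation_sd_only_for_three_plus(self):
        mean, sd = ev.aggregate([10.0, 12.0])
        assert mean == 11.0 and sd is None
        mean, sd = ev.aggregate([10.0, 12.0, 14.0])
        assert sd == pytest.approx(2.0)


class TestMargins:
    def test_uniform_baseline_map_gives_empty_margin(self):
        assert not ev.margin_from_peakmap(np.full((6, 6), 36.0), 50.6).any()

    def test_uniform_hot_map_fills_roi(self):
        roi = np.zeros((6, 6), dtype=bool)
        roi[2:5, 2:5] = True
        mask = ev.margin_from_peakmap(np.full((6, 6), 60.0), 50.6, roi_mask=roi)
        np.testing.assert_array_equal(mask, roi)

    def test_generator_threshold_reproduces_ground_truth_margin(self, ablation):
        final = ablation.steps[-1]
        mask = ev.margin_from_peakmap(final.gt_peak, ablation.params.damage_threshold)
        np.testing.assert_array_equal(mask, ev.margin_from_labels(final.gt_labels))

    def test_margin_size_monotone_in_threshold(self, ablation):
        peak = ablation.steps[-1].gt_peak
        sizes = [
            ev.margin_from_peakmap(peak, t).sum() for t in np.linspace(40, 110, 15)
        ]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_margin_from_labels_counts(self):
        labels = np.full((4, 4), NO_DAMAGE)
        labels[0, :3] = RING
        labels[1, :2] = THERMO
        assert ev.margin_from_labels(labels).sum() == 5

    def test_compare_margins_identical_and_disjoint(self):
        roi = np.ones((10, 10), dtype=bool)
        a = np.zeros_like(roi)
        a[:5] = True
        assert ev.compare_margins(a, a, roi) == (1.0, 1.0)
        d, acc = ev.compare_margins(a, ~a, roi)
        assert d == 0.0 and acc == 0.0

    def test_compare_margins_matches_oracles(self, rng):
        a, b = _rand_mask(rng), _rand_mask(rng)
        d, acc = ev.compare_margins(a, b)
        assert d == pytest.approx(ev.dice(a, b))
        assert acc == pytest.approx(np.mean(a == b))

    def test_symmetry_of_margin_comparison(self, rng):
        a, b = _rand_mask(rng), _rand_mask(rng)
        assert ev.compare_margins(a, b) == ev.compare_margins(b, a)


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        r, r2, p = ev.pearson_correlation(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)
        assert p < 1e-10

    def test_perfect_anticorrelation(self):
        x = np.arange(8.0)
        r, _, _ = ev.pearson_correlation(x, -x)
        assert r == pytest.approx(-1.0)

    def test_matches_covariance_formula_oracle(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        r, r2, _ = ev.pearson_correlation(x, y)
        oracle = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert r == pytest.approx(oracle, abs=1e-10)
        assert r2 == pytest.approx(oracle**2, abs=1e-10)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ev.pearson_correlation(np.ones(5), np.arange(5.0))

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            ev.pearson_correlation([1.0, 2.0], [3.0, 4.0])


class TestHistologyCorrelation:
    def test_classwise_peak_temperature_correlates_with_severity(self, study):
        """The class-wise measured peak temperature correlates strongly with
        the Glisson histology severity score across procedures."""
        temps, scores = [], []
        for abl in study:
            final = abl.steps[-1]
            roi = abl.roi.mask(abl.params.shape)
            g = abl.histology[abl.histology["compartment"] == "glisson"]
            for cls, name in ((NO_DAMAGE, "no_damage"), (RING, "ring"), (THERMO, "thermo")):
                sel = (final.gt_labels == cls) & roi
                if not sel.any():
                    continue
                temps.append(float(final.gt_peak[sel].mean()))
                scores.append(float(g.loc[g["class"] == name, "score"].iloc[0]))
        r, r2, p = ev.pearson_correlation(temps, scores)
        assert r > 0.8
        assert p < 0.001


class TestInterAnnotator:
    def test_identical_annotations_score_one(self, rng):
        ann = rng.integers(0, 3, (10, 10))
        out = ev.inter_annotator_agreement(ann, ann)
        for d, acc in out.values():
            assert d == 1.0 and acc == 1.0

    def test_missing_small_thermo_region_zeroes_its_dice(self):
        """A 2-px thermo region annotated by A but missed by B gives thermo
        DICE 0 while barely moving the other classes."""
        a = np.full((20, 20), NO_DAMAGE)
        a[5:10, 5:10] = RING
        a[7, 7] = a[7, 8] = THERMO
        b = a.copy()
        b[7, 7] = b[7, 8] = RING
        out = ev.inter_annotator_agreement(a, b)
        assert out["thermo"][0] == 0.0
        assert out["ring"][0] > 0.9
        assert out["no_damage"][0] == 1.0

    def test_matches_underlying_metric_oracles(self, rng):
        a = rng.integers(0, 3, (9, 9))
        b = rng.integers(0, 3, (9, 9))
        out = ev.inter_annotator_agreement(a, b)
        assert out["ring"][0] == pytest.approx(ev.dice(a == RING, b == RING))
        assert out["ring"][1] == pytest.approx(ev.per_class_accuracy(b, a, RING))
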