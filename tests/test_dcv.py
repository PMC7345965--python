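"""Metrics (NMC, AUROC, DQ2) and the double cross-validation engine."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aastone import (
    DCVConfig,
    double_cross_validate,
    generate_cohort,
    default_cohort_spec,
    metric_auroc,
    metric_dq2,
    metric_nmc,
    metric_q2,
)
from aastone.dcv import stratified_folds


class TestNMC:
    def test_hand_counts(self):
        assert metric_nmc(np.array([1, 1, 0, 0]), np.array([1, 0, 0, 1])) == 2
        assert metric_nmc(np.zeros(5, int), np.zeros(5, int)) == 0
        y = np.tile([0, 1], 14)[:27]
        assert metric_nmc(y, 1 - y) == 27

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            metric_nmc(np.array([0, 1]), np.array([0]))


def _auroc_bruteforce(true, scores):
    """Exhaustive pair counting: concordant=1, tie=0.5 over all pos x neg."""
    pos = scores[true == 1]
    neg = scores[true == 0]
    total = 0.0
    for sp, sn in itertools.product(pos, neg):
        total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))


class TestAUROC:
    def test_known_values(self):
        assert metric_auroc(np.array([0, 0, 1, 1]), np.array([0.1, 0.2, 0.8, 0.9])) == 1.0
        assert metric_auroc(np.array([0, 1, 0, 1]), np.ones(4)) == 0.5
        # 3 pos x 1 neg: pairs (0.9,0.4),(0.8,0.4) concordant, (0.3,0.4) not
        assert metric_auroc(
            np.array([1, 1, 0, 1]), np.array([0.9, 0.8, 0.4, 0.3])
        ) == pytest.approx(2 / 3)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            metric_auroc(np.ones(3, int), np.arange(3.0))

    @given(
        labels=st.lists(st.integers(0, 1), min_size=2, max_size=8),
        raw=st.lists(st.integers(-3, 3), min_size=8, max_size=8),
    )
    @settings(max_examples=300, deadline=None)
    def test_matches_exhaustive_pair_counting(self, labels, raw):
        """Rank formulation == brute-force pair counting, ties included."""
        true = np.array(labels)
        if true.min() == true.max():
            return
        scores = np.array(raw[: len(true)], dtype=float)
        assert metric_auroc(true, scores) == pytest.approx(
            _auroc_bruteforce(true, scores)
        )


class TestDQ2:
    def test_perfect_prediction(self):
        y = np.array([0, 0, 1, 1])
        assert metric_dq2(y, y.astype(float)) == 1.0

    def test_overshoot_residuals_truncated_to_perfect(self):
        y = np.array([0, 0, 1, 1])
        scores = np.array([-0.2, -0.2, 1.5, 1.5])
        assert metric_dq2(y, scores) == 1.0
        assert metric_q2(y, scores) < 1.0

    def test_constant_mean_prediction_is_zero(self):
        y = np.array([0, 1, 0, 1])
        assert metric_dq2(y, np.full(4, y.mean())) == pytest.approx(0.0)

    def test_constant_labels_rejected(self):
        with pytest.raises(ValueError, match="sum of squares"):
            metric_dq2(np.ones(4, int), np.ones(4))

    @given(
        labels=st.lists(st.integers(0, 1), min_size=3, max_size=10),
        raw=st.lists(st.floats(-2, 3, allow_nan=False), min_size=10, max_size=10),
    )
    @settings(max_examples=200, deadline=None)
    def test_dq2_never_below_q2(self, labels, raw):
        """Truncation can only shrink squared residuals."""
        true = np.array(labels)
        if true.min() == true.max():
            return
        scores = np.array(raw[: len(true)])
        assert metric_dq2(true, scores) >= metric_q2(true, scores) - 1e-12


class TestStratifiedFolds:
    def test_folds_partition_samples_with_both_classes(self, rng):
        y = np.array([0] * 12 + [1] * 15)
        folds = stratified_folds(y, 5, rng)
        assert len(folds) == 5
        all_idx = np.sort(np.concatenate(folds))
        np.testing.assert_array_equal(all_idx, np.arange(27))
        for f in folds:
            assert {0, 1} <= set(y[f])

    def test_fold_count_reduced_when_class_too_small(self, rng):
        y = np.array([0] * 3 + [1] * 10)
        with pytest.warns(UserWarning, match="reducing folds"):
            folds = stratified_folds(y, 5, rng)
        assert len(folds) == 3

    def test_tiny_class_rejected_by_name(self, rng):
        y = np.array([0] + [1] * 10)
        with pytest.raises(ValueError, match="CNT"):
            stratified_folds(y, 5, rng)


class TestDoubleCrossValidation:
    def test_every_sample_predicted_once_per_repetition(self, default_dcv_result):
        res = default_dcv_result
        assert res.outer_scores.shape == (20, 27)
        assert np.isfinite(res.outer_scores).all()

    def test_strong_cohort_classified_well_with_few_lvs(self, default_dcv_result):
        res = default_dcv_result
        assert res.summary["outer_accuracy_mean"] >= 75.7
        assert res.summary["inner_accuracy_mean"] >= 84.2
        # strong separation should need few latent variables
        frac_small = (res.chosen_lv <= 3).mean()
        assert frac_small >= 0.9

    def test_rates_bounded(self, default_dcv_result):
        for vals in (
            default_dcv_result.outer_accuracy,
            default_dcv_result.inner_accuracy,
            default_dcv_result.outer_accuracy_sf,
            default_dcv_result.outer_accuracy_cnt,
        ):
            assert (0 <= vals).all() and (vals <= 100).all()

    def test_determinism_same_seed(self, default_table):
        cfg = DCVConfig(n_repetitions=3, seed=11)
        r1 = double_cross_validate(default_table, cfg)
        r2 = double_cross_validate(default_table, cfg)
        np.testing.assert_array_equal(r1.outer_scores, r2.outer_scores)
        np.testing.assert_array_equal(r1.chosen_lv, r2.chosen_lv)
        np.testing.assert_array_equal(r1.final_model.B, r2.final_model.B)

    def test_permuted_labels_give_chance_accuracy(self, default_table):
        rng = np.random.default_rng(0)
        shuffled = default_table.with_labels(rng.permutation(default_table.y))
        res = double_cross_validate(shuffled, DCVConfig(n_repetitions=20, seed=5))
        assert 35.0 <= res.summary["outer_accuracy_mean"] <= 65.0
        # mean outer AUROC near 0.5 as well
        aurocs = [
            metric_auroc(shuffled.y, res.outer_scores[r]) for r in range(20)
        ]
        assert 0.35 <= np.mean(aurocs) <= 0.65

    def test_submodel_coefficients_collected(self, default_dcv_result):
        assert default_dcv_result.outer_coefficients.shape == (20 * 5, 35)
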