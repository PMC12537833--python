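"""Split arithmetic, stratified metrics vs brute-force oracles, CV contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cravemap import (
    SyntheticConfig,
    classification_metrics,
    extract_extremes,
    generate_cohort,
    make_split,
    pearson_metric,
    repeat_cv,
    run_cv,
    stratified_metric,
)
from cravemap.evaluation import SplitPlan


class TestMakeSplit:
    def test_51_subjects_give_11_holdout_40_fitting(self):
        subjects = [f"s{i}" for i in range(51)]
        plan = make_split(subjects, holdout_fraction=0.2, k=5, seed=0)
        assert len(plan.holdout_subjects) == 11
        assert len(plan.fitting_subjects) == 40

    def test_40_fitting_subjects_make_five_folds_of_eight(self):
        plan = make_split([f"s{i}" for i in range(51)], 0.2, k=5, seed=3)
        assert sorted(len(f) for f in plan.folds) == [8] * 5

    def test_fold_sizes_differ_by_at_most_one(self):
        plan = make_split([f"s{i}" for i in range(23)], 0.2, k=5, seed=1)
        sizes = [len(f) for f in plan.folds]
        assert max(sizes) - min(sizes) <= 1

    def test_zero_fraction_folds_everyone(self):
        plan = make_split(list("abcdefgh"), holdout_fraction=0.0, k=4, seed=0)
        assert plan.holdout_subjects == ()
        assert sorted(plan.fitting_subjects) == sorted("abcdefgh")

    def test_partition_is_disjoint_and_complete(self):
        subjects = [f"s{i}" for i in range(17)]
        plan = make_split(subjects, 0.25, k=3, seed=9)
        everyone = list(plan.holdout_subjects) + list(plan.fitting_subjects)
        assert sorted(everyone) == sorted(subjects)

    def test_deterministic_per_seed_and_seed_sensitive(self):
        subjects = [f"s{i}" for i in range(30)]
        assert make_split(subjects, 0.2, 5, seed=4) == make_split(subjects, 0.2, 5, seed=4)
        assert (
            make_split(subjects, 0.2, 5, seed=4).holdout_subjects
            != make_split(subjects, 0.2, 5, seed=5).holdout_subjects
        )

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError, match="folds"):
            make_split(list("abcde"), 0.2, k=5, seed=0)


class TestStratifiedMetrics:
    def test_hand_computed_example(self):
        mv = stratified_metric([1, 1, 2, 2], [1, 2, 2, 2], "rmse")
        assert mv.value == pytest.approx(np.sqrt(0.5) / 2)  # (sqrt(1/2)+0)/2
        assert mv.stratified and mv.n == 4

    def test_perfect_predictions_zero(self):
        assert stratified_metric([1, 2, 3], [1, 2, 3], "mae").value == 0.0

    def test_single_level_collapses_to_plain_metric(self, rng):
        yhat = rng.normal(2, 1, 50)
        y = np.full(50, 2.0)
        plain = float(np.sqrt(np.mean((yhat - y) ** 2)))
        assert stratified_metric(y, yhat, "rmse").value == pytest.approx(plain)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_groupby_oracle(self, seed):
        r = np.random.default_rng(seed)
        y = r.integers(1, 5, 40).astype(float)
        yhat = r.normal(2.5, 1.0, 40)
        for metric, fn in (
            ("rmse", lambda a, b: np.sqrt(np.mean((a - b) ** 2))),
            ("mae", lambda a, b: np.mean(np.abs(a - b))),
        ):
            oracle = np.mean(
                [fn(yhat[y == lv], y[y == lv]) for lv in np.unique(y)]
            )
            assert abs(stratified_metric(y, yhat, metric).value - oracle) <= 1e-12

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            stratified_metric([], [], "rmse")


class TestPearson:
    def test_identity_and_negation(self):
        y = np.array([1.0, 2, 3, 4])
        assert pearson_metric(y, y).value == pytest.approx(1.0)
        assert pearson_metric(y, -y).value == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        assert pearson_metric([1, 2, 3, 4], [2, 1, 4, 3]).value == pytest.approx(0.6)

    def test_constant_vector_reported_undefined(self):
        assert np.isnan(pearson_metric([1, 1, 1], [1, 2, 3]).value)


class TestClassificationMetrics:
    def test_auc_from_pair_counting_example(self):
        m = classification_metrics([0, 0, 1, 1], [0.1, 0.4, 0.35, 0.8])
        assert m["auc_roc"].value == pytest.approx(0.75)  # 3 of 4 pairs concordant

    def test_perfect_separation(self):
        m = classification_metrics([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert m["auc_roc"].value == 1.0

    def test_tied_scores_give_half(self):
        m = classification_metrics([0, 1, 0, 1], [0.3, 0.3, 0.3, 0.3])
        assert m["auc_roc"].value == pytest.approx(0.5)

    def test_boundary_score_counts_positive(self):
        m = classification_metrics([1], [0.5], threshold=0.5)
        assert m["accuracy"].value == 1.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_auc_equals_mann_whitney_u(self, seed):
        from scipy.stats import mannwhitneyu

        r = np.random.default_rng(seed)
        labels = np.array([0] * 10 + [1] * 8)
        scores = np.round(r.normal(size=18), 1)  # coarse grid forces ties
        auc = classification_metrics(labels, scores)["auc_roc"].value
        u = mannwhitneyu(scores[labels == 1], scores[labels == 0]).statistic
        assert abs(auc - u / (10 * 8)) <= 1e-12

    def test_single_class_auc_undefined(self):
        m = classification_metrics([1, 1], [0.2, 0.9])
        assert np.isnan(m["auc_roc"].value) and np.isnan(m["auc_pr"].value)


class TestExtractExtremes:
    def test_first_occurrence_rule(self):
        pair = extract_extremes([2, 1, 3, 1, 4, 4], block_indices=range(6))
        assert (pair.min_index, pair.max_index) == (1, 4)
        assert not pair.degenerate

    def test_block_order_not_list_order(self):
        # same ratings presented with blocks out of order
        pair = extract_extremes([4, 1, 4], block_indices=[5, 3, 1])
        assert pair.min_index == 1  # rating 1 at block 3
        assert pair.max_index == 2  # first max in block order is block 1

    def test_constant_ratings_degenerate(self):
        pair = extract_extremes([2, 2, 2], block_indices=range(3))
        assert pair.degenerate and pair.min_index == 0 and pair.max_index == 0

    def test_single_sample_degenerate(self):
        pair = extract_extremes([3])
        assert pair.degenerate and (pair.min_index, pair.max_index) == (0, 0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            extract_extremes([])


class TestRunCV:
    def test_no_subject_spans_train_and_test(self, small_cohort):
        plan = make_split(small_cohort.subjects, 0.2, k=3, seed=0)
        res = run_cv(small_cohort, {"method": "pca", "n_components": 5}, plan=plan)
        # hold-out rows must never receive out-of-fold predictions
        hold_rows = np.isin(small_cohort.subject_ids, plan.holdout_subjects)
        assert np.all(np.isnan(res.oof_pred[hold_rows]))
        assert not np.any(np.isnan(res.oof_pred[~hold_rows]))

    def test_planted_duplicate_subject_trips_leakage_assertion(self, small_cohort):
        subjects = small_cohort.subjects
        leaky = SplitPlan(
            holdout_subjects=(),
            folds=(tuple(subjects[:4]), tuple(subjects[3:])),  # subjects[3] twice
            k=2,
            seed=0,
        )
        with pytest.raises(AssertionError, match="leakage"):
            run_cv(small_cohort, {"method": "pca", "n_components": 5}, plan=leaky)

    def test_noiseless_cohort_predicts_out_of_fold_exactly(self):
        cfg = SyntheticConfig(n_subjects=10, n_excluded=0, n_voxels=512,
                              signature_support=16, noise_sd=0.0,
                              subject_sd=0.0, seed=5)
        cohort, _ = generate_cohort(cfg)
        plan = make_split(cohort.subjects, 0.0, k=5, seed=0)
        res = run_cv(cohort, {"method": "pca", "n_components": 2}, plan=plan)
        assert res.pooled["rmse_stratified"].value <= 1e-6

    def test_permuted_labels_give_near_zero_pooled_r(self):
        cfg = SyntheticConfig(n_subjects=40, n_excluded=0, n_voxels=512,
                              signature_support=32, seed=6)
        cohort, _ = generate_cohort(cfg)
        rng = np.random.default_rng(0)
        meta = cohort.meta.copy()
        meta["rating"] = rng.permutation(meta["rating"].to_numpy())
        shuffled = type(cohort)(cohort.X, meta, cohort.stack)
        plan = make_split(shuffled.subjects, 0.0, k=5, seed=0)
        res = run_cv(shuffled, {"method": "pca", "n_components": 20}, plan=plan)
        assert abs(res.pooled["pearson_r"].value) <= 0.2

    def test_repeat_cv_deterministic_and_varies_over_repetitions(self, small_cohort):
        df1 = repeat_cv(small_cohort, {"method": "pca", "n_components": 5},
                        n_repetitions=4, k=3, seed=2)
        df2 = repeat_cv(small_cohort, {"method": "pca", "n_components": 5},
                        n_repetitions=4, k=3, seed=2)
        assert df1.equals(df2)
        assert df1["rmse"].nunique() > 1  # fresh fold assignments change metrics
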