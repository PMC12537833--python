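"""Back-projection identity, display normalization, atlas summarization."""

import numpy as np
import pytest

from cravemap import (
    RegressorSpec,
    back_project,
    fit_pipeline,
    normalize_for_display,
    summarize_by_atlas,
    synthetic_parcellation,
)
from cravemap.dataio import ParcellationVolume, VolumeStack


RED = {"method": "pca", "n_components": 6}


class TestBackProjection:
    @pytest.mark.parametrize("family,hp", [
        ("ols", {}),
        ("ridge", {"alpha": 0.5}),
        ("lasso", {"alpha": 0.01}),
        ("elastic_net", {"alpha": 0.01, "l1_ratio": 0.5}),
    ])
    @pytest.mark.parametrize("seed", [0, 1])
    def test_voxel_dot_product_reproduces_predictions(self, small_cohort,
                                                      family, hp, seed):
        rng = np.random.default_rng(seed)
        idx = rng.permutation(len(small_cohort))[:60]
        data = small_cohort.select(idx)
        pipe = fit_pipeline(data.X, data.ratings, dict(RED),
                            spec=RegressorSpec(family, hp), seed=seed)
        sig = back_project(pipe)
        direct = data.X @ sig.vb_raw + sig.b0_adj
        assert np.max(np.abs(pipe.predict(data.X) - direct)) <= 1e-8

    def test_all_zero_off_mask_sample_predicts_adjusted_intercept(self, small_cohort):
        pipe = fit_pipeline(small_cohort.X, small_cohort.ratings, dict(RED))
        sig = back_project(pipe)
        zero = np.zeros((1, small_cohort.stack.n_voxels))
        assert pipe.predict(zero)[0] == pytest.approx(sig.b0_adj, abs=1e-8)

    def test_zero_coefficients_give_zero_map(self, small_cohort):
        # huge ridge penalty drives B to 0, hence an (almost exactly) zero map
        pipe = fit_pipeline(small_cohort.X, small_cohort.ratings, dict(RED),
                            spec=RegressorSpec("ridge", {"alpha": 1e14}))
        sig = back_project(pipe)
        assert np.max(np.abs(sig.vb)) <= 1e-8

    def test_single_component_map_is_first_eigenvector(self, small_cohort):
        pipe = fit_pipeline(small_cohort.X, small_cohort.ratings,
                            {"method": "pca", "n_components": 1})
        sig = back_project(pipe)
        red = pipe.reducer
        expected = np.zeros_like(sig.vb)
        expected[red.kept_columns_] = red.components_[0] * pipe.B[0]
        np.testing.assert_allclose(sig.vb, expected, atol=1e-12)

    def test_map_zero_outside_kept_columns(self, small_cohort):
        pipe = fit_pipeline(small_cohort.X, small_cohort.ratings, dict(RED))
        sig = back_project(pipe)
        off = np.setdiff1d(np.arange(sig.vb.size), pipe.reducer.kept_columns_)
        assert np.all(sig.vb[off] == 0) and np.all(sig.vb_raw[off] == 0)

    def test_two_fits_on_identical_data_give_identical_maps(self, small_cohort):
        a = back_project(fit_pipeline(small_cohort.X, small_cohort.ratings, dict(RED)))
        b = back_project(fit_pipeline(small_cohort.X, small_cohort.ratings, dict(RED)))
        assert np.array_equal(a.vb, b.vb) and np.array_equal(a.vb_raw, b.vb_raw)

    def test_tree_family_rejected(self, small_cohort):
        pipe = fit_pipeline(small_cohort.X, small_cohort.ratings, dict(RED),
                            spec=RegressorSpec("random_forest",
                                               {"n_estimators": 5}))
        with pytest.raises(ValueError, match="linear"):
            back_project(pipe)

    def test_anova_reducer_rejected(self, small_cohort):
        pipe = fit_pipeline(small_cohort.X, small_cohort.ratings,
                            {"method": "anova", "n_components": 6})
        with pytest.raises(ValueError, match="PCA"):
            back_project(pipe)


class TestNormalizeForDisplay:
    @pytest.fixture()
    def sig(self, small_cohort):
        return back_project(
            fit_pipeline(small_cohort.X, small_cohort.ratings, dict(RED))
        )

    def test_self_reference_scale_one(self, sig):
        out = normalize_for_display(sig, sig.vb_raw)
        assert out.norm_factor == pytest.approx(1.0)

    def test_norm_matches_reference(self, sig, small_cohort):
        ref = small_cohort.mean_beta_map()
        out = normalize_for_display(sig, ref)
        assert np.linalg.norm(out.vb_raw) == pytest.approx(
            np.linalg.norm(ref), abs=1e-10
        )

    def test_homogeneity_and_sign_preserved(self, sig, small_cohort):
        ref = small_cohort.mean_beta_map()
        out1 = normalize_for_display(sig, ref)
        out2 = normalize_for_display(sig, 2 * ref)
        assert np.linalg.norm(out2.vb_raw) == pytest.approx(
            2 * np.linalg.norm(out1.vb_raw)
        )
        assert np.array_equal(np.sign(out1.vb), np.sign(sig.vb))

    def test_zero_reference_rejected(self, sig):
        with pytest.raises(ValueError, match="zero"):
            normalize_for_display(sig, np.zeros_like(sig.vb_raw))


class TestAtlasSummary:
    def _tiny_setup(self):
        mask = np.ones((3, 1, 1), dtype=bool)
        stack = VolumeStack((3, 1, 1), np.eye(4), mask)
        labels = np.array([1, 1, 2]).reshape(3, 1, 1)
        parc = ParcellationVolume(labels=labels)
        return stack, parc

    def test_hand_computed_region_means(self):
        from cravemap.signature import SignatureMap

        stack, parc = self._tiny_setup()
        sig = SignatureMap(vb=np.array([1.0, 3.0, 2.0]),
                           vb_raw=np.array([1.0, 3.0, 2.0]), b0_adj=0.0)
        df = summarize_by_atlas(sig, parc, stack)
        means = dict(zip(df.region_id, df.mean_vb))
        assert means == {1: 2.0, 2: 2.0}

    def test_uniform_map_gives_uniform_means(self):
        from cravemap.signature import SignatureMap

        stack, parc = self._tiny_setup()
        sig = SignatureMap(vb=np.full(3, 0.7), vb_raw=np.full(3, 0.7), b0_adj=0.0)
        df = summarize_by_atlas(sig, parc, stack)
        assert np.allclose(df.mean_vb, 0.7)

    def test_matches_per_region_loop_oracle(self, small_cohort):
        pipe = fit_pipeline(small_cohort.X, small_cohort.ratings, dict(RED))
        sig = back_project(pipe)
        parc = synthetic_parcellation(small_cohort.stack, n_regions=12, seed=1)
        df = summarize_by_atlas(sig, parc, small_cohort.stack)
        vol = small_cohort.stack.unflatten(sig.vb)
        for _, row in df.iterrows():
            sel = (parc.labels == row.region_id) & small_cohort.stack.mask
            assert abs(vol[sel].mean() - row.mean_vb) <= 1e-12

    def test_ranking_descends(self, small_cohort):
        pipe = fit_pipeline(small_cohort.X, small_cohort.ratings, dict(RED))
        sig = back_project(pipe)
        parc = synthetic_parcellation(small_cohort.stack, n_regions=8, seed=2)
        df = summarize_by_atlas(sig, parc, small_cohort.stack)
        assert np.all(np.diff(df.mean_vb) <= 0)
        assert df["rank"].tolist() == list(range(1, len(df) + 1))

    def test_246_region_parcellation_yields_246_rows(self):
        from cravemap import SyntheticConfig, generate_cohort
        from cravemap.signature import SignatureMap

        cohort, _ = generate_cohort(
            SyntheticConfig(n_subjects=2, n_excluded=0, seed=0)
        )  # default 16^3 grid, ~2458 in-mask voxels
        stack = cohort.stack
        parc = synthetic_parcellation(stack, n_regions=246, seed=0)
        sig = SignatureMap(
            vb=np.arange(stack.n_voxels, dtype=float),
            vb_raw=np.arange(stack.n_voxels, dtype=float),
            b0_adj=0.0,
        )
        df = summarize_by_atlas(sig, parc, stack)
        assert len(df) == 246

    def test_empty_region_missing_not_zero(self):
        from cravemap.signature import SignatureMap

        stack, _ = self._tiny_setup()
        labels = np.array([1, 1, 0]).reshape(3, 1, 1)  # region 2 never appears
        parc = ParcellationVolume(labels=labels)
        sig = SignatureMap(vb=np.ones(3), vb_raw=np.ones(3), b0_adj=0.0)
        df = summarize_by_atlas(sig, parc, stack)
        assert df.region_id.tolist() == [1]

    def test_disjoint_parcellation_rejected(self):
        from cravemap.signature import SignatureMap

        stack, _ = self._tiny_setup()
        parc = ParcellationVolume(labels=np.zeros((3, 1, 1), dtype=int))
        sig = SignatureMap(vb=np.ones(3), vb_raw=np.ones(3), b0_adj=0.0)
        with pytest.raises(ValueError, match="overlap"):
            summarize_by_atlas(sig, parc, stack)
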