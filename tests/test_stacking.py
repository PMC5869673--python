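"""Stacker, bias corrector, and end-to-end pipeline behaviour."""

import numpy as np
import pytest

from mozzage import (
    CVConfig,
    SplineConfig,
    SplitSpec,
    SyntheticSpec,
    fit_bias_correction,
    fit_pipeline,
    fit_stacker,
    fit_standard_pipeline,
    generate_study,
    predict_age,
    rmse,
    split_train_val_test,
)
from mozzage.errors import GridError, SizeError
from mozzage.spectra_io import SpectraDataset, WavelengthGrid

from conftest import COARSE_GRID


class TestStacker:
    def test_perfect_base_predictor_recovered(self):
        rng = np.random.default_rng(0)
        truth = rng.uniform(1, 20, 200)
        stack = fit_stacker(truth[:, None], truth)
        out = stack.predict(truth[:, None])
        assert np.max(np.abs(out - truth)) < 0.05

    def test_perfect_plus_noise_predictor(self):
        # One informative and one useless base model: the stacker should
        # track the informative one closely (linear-stacking oracle).
        rng = np.random.default_rng(1)
        truth = rng.uniform(1, 20, 400)
        base = np.column_stack([truth, rng.normal(10, 5, 400)])
        stack = fit_stacker(base, truth)
        test_truth = rng.uniform(1, 20, 400)
        test_base = np.column_stack([test_truth, rng.normal(10, 5, 400)])
        err = rmse(stack.predict(test_base), test_truth)
        assert err < 0.1 * np.std(test_truth) + 0.3

    def test_four_smooth_terms_for_anopheles_layout(self, study_ds, study_split):
        pipe = fit_pipeline(
            study_ds, split=SplitSpec(seed=7), precomputed_split=study_split
        )
        assert pipe.stacker.n_inputs == 4  # 3 interval models + wide model

    def test_too_few_rows_raise(self):
        rng = np.random.default_rng(2)
        with pytest.raises(SizeError):
            fit_stacker(rng.normal(size=(10, 2)), rng.uniform(1, 9, 10))


class TestBiasCorrection:
    def test_identity_when_already_unbiased(self):
        rng = np.random.default_rng(3)
        truth = rng.uniform(1, 20, 300)
        corr = fit_bias_correction(truth, truth)
        assert np.max(np.abs(corr(truth) - truth)) < 0.2

    def test_affine_distortion_inverted(self):
        rng = np.random.default_rng(4)
        truth = rng.uniform(1, 20, 300)
        raw = 0.5 * truth + 2.5
        corr = fit_bias_correction(raw, truth)
        assert rmse(corr(raw), truth) < 0.3

    def test_monotone_nondecreasing(self):
        rng = np.random.default_rng(5)
        truth = rng.uniform(1, 20, 300)
        raw = truth + rng.normal(0, 2, 300)
        corr = fit_bias_correction(raw, truth)
        grid = np.linspace(raw.min() - 2, raw.max() + 2, 500)
        assert np.all(np.diff(corr(grid)) >= -1e-9)

    def test_decile_mean_residuals_near_zero(self):
        rng = np.random.default_rng(6)
        truth = rng.uniform(1, 20, 600)
        # moderate noise: at high noise, conditional-mean calibration
        # cannot be unbiased per *true*-age decile (regression to the mean)
        raw = 0.7 * truth + 3 + rng.normal(0, 0.4, 600)
        corr = fit_bias_correction(raw, truth)
        corrected = corr(raw)
        deciles = np.quantile(truth, np.linspace(0, 1, 11))
        for lo, hi in zip(deciles[:-1], deciles[1:]):
            m = (truth >= lo) & (truth <= hi)
            assert abs(np.mean(corrected[m] - truth[m])) < 0.5

    def test_constant_raw_falls_back_to_identity(self):
        with pytest.warns(UserWarning, match="identity"):
            corr = fit_bias_correction(np.full(100, 4.0), np.linspace(1, 9, 100))
        np.testing.assert_allclose(corr(np.array([-1.0, 3.0])), [0.0, 3.0])

    def test_monotone_distortion_recovered_noiselessly(self):
        # property: any smooth monotone distortion of a noiseless predictor
        # is inverted to within half a day
        rng = np.random.default_rng(7)
        truth = np.sort(rng.uniform(0.5, 20, 500))
        for g in (lambda t: 1.8 * np.sqrt(t) + 1, lambda t: 0.05 * t**2 + 0.5 * t):
            raw = g(truth)
            corr = fit_bias_correction(raw, truth)
            assert rmse(corr(raw), truth) < 0.5


class TestPipeline:
    def test_same_seed_identical_test_predictions(self, study_ds):
        preds = []
        for _ in range(2):
            parts = split_train_val_test(study_ds, SplitSpec(seed=5))
            pipe = fit_pipeline(
                study_ds, split=SplitSpec(seed=5), precomputed_split=parts
            )
            preds.append(pipe.predict(parts.test))
        np.testing.assert_array_equal(preds[0], preds[1])

    def test_predictions_finite_nonnegative_in_range(self, study_ds, study_split):
        pipe = fit_pipeline(
            study_ds, split=SplitSpec(seed=7), precomputed_split=study_split
        )
        preds = predict_age(pipe, study_split.test)
        assert np.all(np.isfinite(preds)) and np.all(preds >= 0)
        # the training-mean spectrum maps into the observed age range
        mean_ds = SpectraDataset(
            study_ds.grid,
            study_ds.absorbance.mean(axis=0, keepdims=True),
            study_ds.meta.iloc[[0]],
        )
        assert 0 <= pipe.predict(mean_ds)[0] <= study_ds.ages.max()

    def test_batch_equals_row_by_row(self, study_ds, study_split):
        pipe = fit_pipeline(
            study_ds, split=SplitSpec(seed=7), precomputed_split=study_split
        )
        sub = study_split.test.subset(np.arange(5))
        batch = pipe.predict(sub)
        single = np.concatenate(
            [pipe.predict(sub.subset(np.array([i]))) for i in range(5)]
        )
        np.testing.assert_allclose(batch, single)

    def test_leakage_guard_test_rows_never_used(self, study_ds):
        # corrupting the test-partition spectra must not change the fit
        parts = split_train_val_test(study_ds, SplitSpec(seed=9))
        pipe_a = fit_pipeline(
            study_ds, split=SplitSpec(seed=9), precomputed_split=parts
        )
        corrupted = study_ds.absorbance.copy()
        corrupted[parts.test_idx] = 0.0
        ds_b = SpectraDataset(study_ds.grid, corrupted, study_ds.meta)
        parts_b = split_train_val_test(ds_b, SplitSpec(seed=9))
        np.testing.assert_array_equal(parts.test_idx, parts_b.test_idx)
        pipe_b = fit_pipeline(
            ds_b, split=SplitSpec(seed=9), precomputed_split=parts_b
        )
        probe = parts.val
        np.testing.assert_allclose(pipe_a.predict(probe), pipe_b.predict(probe))

    def test_bias_corrected_flattens_error_slope(self, study_ds, study_split):
        naive = fit_pipeline(
            study_ds, split=SplitSpec(seed=7),
            precomputed_split=study_split, bias_correct=False,
        )
        corrected = fit_pipeline(
            study_ds, split=SplitSpec(seed=7), precomputed_split=study_split
        )
        truth = study_split.test.ages
        slope_naive = np.polyfit(truth, naive.predict(study_split.test) - truth, 1)[0]
        slope_corr = np.polyfit(truth, corrected.predict(study_split.test) - truth, 1)[0]
        assert abs(slope_corr) <= abs(slope_naive) + 0.02

    def test_grid_mismatch_raises(self, study_ds, study_split):
        pipe = fit_pipeline(
            study_ds, split=SplitSpec(seed=7), precomputed_split=study_split
        )
        other = generate_study(
            SyntheticSpec(
                n_mosquitoes=60,
                grid=WavelengthGrid(350, 2500, 50.0),
                age_mean=6.0,
                age_bin_counts=None,
                seed=1,
            )
        )
        with pytest.raises(GridError):
            pipe.predict(other)

    def test_ipls_beats_standard_over_seeds(self):
        # paired Monte-Carlo: corrected iPLS should usually beat the
        # full-spectrum baseline on data whose signal sits in the intervals
        wins = 0
        n_seeds = 5
        for seed in range(n_seeds):
            ds = generate_study(
                SyntheticSpec(n_mosquitoes=400, grid=COARSE_GRID,
                              age_mean=None, age_bin_counts=None,
                              ages=tuple(np.random.default_rng(seed).uniform(1, 25, 400)),
                              seed=100 + seed)
            )
            split = SplitSpec(seed=seed)
            parts = split_train_val_test(ds, split)
            cv = CVConfig(n_bootstrap=10, seed=seed)
            ipls = fit_pipeline(ds, split=split, cv=cv, precomputed_split=parts,
                                spline_config=SplineConfig(df=5))
            std = fit_standard_pipeline(ds, split=split, cv=cv,
                                        precomputed_split=parts)
            truth = parts.test.ages
            if rmse(ipls.predict(parts.test), truth) < rmse(std.predict(parts.test), truth):
                wins += 1
        assert wins >= 3
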