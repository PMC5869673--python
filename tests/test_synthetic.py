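"""Generator determinism, signal recoverability, and study structure."""

import numpy as np
import pytest

from mozzage import (
    ConfigurationError,
    CVConfig,
    GridError,
    SplitSpec,
    SyntheticSpec,
    SplineConfig,
    age_group_counts,
    fit_pipeline,
    fit_pls,
    generate_multistudy,
    generate_reference_dataset,
    generate_study,
    predict_pls,
    rmse,
    split_train_val_test,
)
from mozzage.synthetic import REFERENCE_STUDY_TABLE

from conftest import COARSE_GRID


def _quiet_spec(**kw):
    base = dict(
        grid=COARSE_GRID, n_mosquitoes=100, age_mean=6.0, age_bin_counts=None
    )
    base.update(kw)
    return SyntheticSpec(**base)


class TestGenerateStudy:
    def test_deterministic_per_seed(self):
        a = generate_study(_quiet_spec(seed=5))
        b = generate_study(_quiet_spec(seed=5))
        assert a.equals(b)
        c = generate_study(_quiet_spec(seed=6))
        assert not np.array_equal(a.absorbance, c.absorbance)

    def test_zero_effect_zero_noise_identical_rows(self):
        ds = generate_study(
            _quiet_spec(
                signal_bands=(), age_jitter_sd=0.0, n_artifacts=0,
                artifact_sd=0.0, noise_sd=0.0, seed=1,
            )
        )
        np.testing.assert_allclose(
            ds.absorbance,
            np.broadcast_to(ds.absorbance[0], ds.absorbance.shape),
        )

    def test_noiseless_single_band_recoverable_by_one_component(self):
        ds = generate_study(
            _quiet_spec(
                n_mosquitoes=60,
                signal_bands=((709.0, 1066.0, 0.002),),
                age_jitter_sd=0.0, n_artifacts=0, artifact_sd=0.0,
                noise_sd=0.0, seed=2,
            )
        )
        cols = ds.grid.indices_between(709, 1066)
        m = fit_pls(ds.absorbance[:, cols], ds.ages, CVConfig(n_bootstrap=5, seed=0))
        assert m.n_components == 1
        assert rmse(predict_pls(m, ds.absorbance[:, cols]), ds.ages) < 1e-6

    def test_noise_dial_degrades_accuracy(self):
        # more per-mosquito noise => strictly worse pipeline error
        errs = []
        for noise_scale in (0.5, 3.0):
            vals = []
            for seed in range(3):
                ds = generate_study(
                    SyntheticSpec(
                        grid=COARSE_GRID, n_mosquitoes=400,
                        age_mean=None, age_bin_counts=None,
                        ages=tuple(np.random.default_rng(seed).uniform(1, 25, 400)),
                        artifact_sd=0.02 * noise_scale,
                        noise_sd=0.01 * noise_scale,
                        seed=50 + seed,
                    )
                )
                split = SplitSpec(seed=seed)
                parts = split_train_val_test(ds, split)
                pipe = fit_pipeline(
                    ds, split=split, cv=CVConfig(n_bootstrap=5, seed=seed),
                    precomputed_split=parts, spline_config=SplineConfig(df=5),
                )
                vals.append(rmse(pipe.predict(parts.test), parts.test.ages))
            errs.append(np.median(vals))
        assert errs[1] > errs[0]

    def test_band_outside_grid_raises(self):
        with pytest.raises(GridError):
            _quiet_spec(signal_bands=((3000.0, 3100.0, 0.001),))

    def test_bin_counts_must_sum_to_n(self):
        with pytest.raises(ConfigurationError):
            generate_study(
                SyntheticSpec(grid=COARSE_GRID, n_mosquitoes=10,
                              age_bin_counts=(5, 5, 5, 0, 0))
            )


class TestScaledBinCounts:
    @pytest.mark.parametrize("n", [1, 7, 300, 871, 1000])
    def test_sum_and_proportions(self, n):
        from mozzage import scaled_bin_counts

        counts = scaled_bin_counts(n)
        assert sum(counts) == n
        if n >= 300:
            # young-heavy imbalance preserved
            assert counts[0] + counts[1] > counts[2] + counts[3] + counts[4]

    def test_study_a_exact(self):
        from mozzage import scaled_bin_counts

        assert scaled_bin_counts(871) == (196, 302, 100, 101, 172)


class TestMultistudy:
    def test_row_count_conserved(self):
        specs = [
            _quiet_spec(n_mosquitoes=30 + 10 * i, study=s, seed=i)
            for i, s in enumerate("ABC")
        ]
        ds = generate_multistudy(specs)
        assert ds.n_samples == 30 + 40 + 50
        assert ds.studies == ["A", "B", "C"]

    def test_grid_mismatch_raises(self):
        from mozzage import WavelengthGrid

        other = WavelengthGrid(350, 2500, 50.0)
        with pytest.raises(GridError):
            generate_multistudy(
                [_quiet_spec(seed=0), _quiet_spec(grid=other, seed=1)]
            )

    def test_cross_study_transfer_fails(self):
        # train on study 1, test on study 2 with different offsets/artifacts:
        # between-study error should exceed within-study error
        ages = tuple(np.random.default_rng(0).uniform(1, 25, 500))
        mk = lambda off, gain, seed, study: SyntheticSpec(
            grid=COARSE_GRID, n_mosquitoes=500, age_mean=None,
            age_bin_counts=None, ages=ages, study=study,
            study_offset=off, study_gain=gain, seed=seed,
        )
        ds1 = generate_study(mk(0.0, 1.0, 1, "A"))
        ds2 = generate_study(mk(0.3, 1.2, 2, "B"))
        split = SplitSpec(seed=0)
        parts = split_train_val_test(ds1, split)
        pipe = fit_pipeline(ds1, split=split, cv=CVConfig(n_bootstrap=8, seed=0),
                            precomputed_split=parts)
        within = rmse(pipe.predict(parts.test), parts.test.ages)
        between = rmse(pipe.predict(ds2), ds2.ages)
        assert between > within


class TestReferenceDataset:
    def test_reference_composition_reproduced(self):
        ds = generate_reference_dataset(seed=0, grid=COARSE_GRID)
        assert ds.n_samples == 4549
        table = age_group_counts(ds)
        assert table.loc["A"].tolist() == [196, 302, 100, 101, 172]
        assert int(table.loc["A"].sum()) == 871
        ref = REFERENCE_STUDY_TABLE.set_index("study")
        for study in ref.index:
            np.testing.assert_array_equal(
                table.loc[study].to_numpy(),
                ref.loc[study, ["n_le5", "n_5_10", "n_10_15", "n_15_20", "n_gt20"]]
                .to_numpy(dtype=int),
            )
        assert int(table.to_numpy().sum()) == 4549

    def test_age_imbalance_drives_underprediction_of_old(self):
        # more young than old in calibration => naive pipeline
        # under-predicts the oldest mosquitoes before correction
        ds = generate_reference_dataset(seed=3, grid=COARSE_GRID).for_study("A")
        split = SplitSpec(seed=1)
        parts = split_train_val_test(ds, split)
        pipe = fit_pipeline(ds, split=split, cv=CVConfig(n_bootstrap=8, seed=1),
                            precomputed_split=parts, bias_correct=False)
        preds = pipe.predict(parts.test)
        truth = parts.test.ages
        old = truth > 15
        assert np.mean(preds[old] - truth[old]) < 0.0
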