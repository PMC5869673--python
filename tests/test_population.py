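"""Population simulation, mean-age inference, decomposition and power."""

import numpy as np
import pytest

from mozzage import (
    ConfigurationError,
    PopulationSpec,
    SizeError,
    SurrogateModel,
    decompose_uncertainty,
    estimate_mean_age,
    min_sample_size_to_distinguish,
    proportion_old,
    sample_population,
)


class TestSamplePopulation:
    def test_large_sample_mean_close(self):
        ages = sample_population(PopulationSpec(5.0, 1_000_000, seed=1))
        assert ages.mean() == pytest.approx(5.0, abs=0.02)
        assert ages.min() >= 0

    def test_single_draw_nonnegative(self):
        assert sample_population(PopulationSpec(3.0, 1, seed=2))[0] >= 0

    def test_seed_determinism(self):
        a = sample_population(PopulationSpec(7.0, 100, seed=3))
        b = sample_population(PopulationSpec(7.0, 100, seed=3))
        np.testing.assert_array_equal(a, b)


class TestEstimateMeanAge:
    def test_constant_observations_zero_width(self):
        est = estimate_mean_age(np.full(50, 5.0), seed=0)
        assert est.mean == 5.0
        assert est.width == pytest.approx(0.0, abs=1e-12)

    def test_noisy_exponential_recovery(self):
        rng = np.random.default_rng(4)
        obs = rng.exponential(7.0, 10_000) + rng.normal(0, 2.0, 10_000)
        se = np.sqrt((7.0**2 + 2.0**2) / 10_000)
        est = estimate_mean_age(obs, seed=1)
        assert est.mean == pytest.approx(7.0, abs=3 * se)
        assert est.lower < est.mean < est.upper

    def test_interval_width_shrinks_with_n(self):
        rng = np.random.default_rng(5)
        widths = []
        for n in (50, 200, 800):
            est = estimate_mean_age(rng.exponential(5.0, n), seed=2,
                                    replicates=4000)
            widths.append(est.width)
        assert widths[0] > widths[1] > widths[2]

    def test_unbiased_across_means_and_sizes(self):
        # sample mean of (exponential + mean-zero noise) is unbiased:
        # grand mean over replicates within 3 Monte-Carlo SEs of truth
        rng = np.random.default_rng(6)
        reps = 2000
        for mean_age in (3.0, 5.0, 7.0):
            for n in (50, 100, 300):
                true = rng.exponential(mean_age, (reps, n))
                noisy = true + rng.normal(0, 2.0, (reps, n))
                ests = noisy.mean(axis=1)
                se = np.sqrt((mean_age**2 + 4.0) / n / reps)
                assert abs(ests.mean() - mean_age) < 3 * se, (mean_age, n)

    def test_empty_input_raises(self):
        with pytest.raises(SizeError):
            estimate_mean_age([])

    def test_parametric_interval_with_surrogate(self):
        rng = np.random.default_rng(7)
        obs = rng.exponential(5.0, 200)
        noiseless = estimate_mean_age(obs, seed=3, method="parametric")
        noisy = estimate_mean_age(
            obs, seed=3, method="parametric",
            model=SurrogateModel(0.0, 1.0, 2.0),
        )
        assert noisy.width > noiseless.width


class TestDecomposeUncertainty:
    def test_zero_noise_share_exactly_zero(self):
        m = SurrogateModel(alpha=0.0, beta=1.0, sigma0=0.0, sigma1=0.0)
        d = decompose_uncertainty(5.0, 100, m, replicates=2000, seed=0)
        assert d.nirs_share == 0.0
        assert d.total_width == d.sampling_width

    def test_matches_brute_force_oracle(self):
        # independent two-arm Monte-Carlo with plain numpy
        m = SurrogateModel(alpha=0.0, beta=1.0, sigma0=2.0)
        d = decompose_uncertainty(5.0, 100, m, replicates=100_000, seed=1)
        rng = np.random.default_rng(99)
        reps = 100_000
        true = rng.exponential(5.0, (reps, 100))
        noisy = true + rng.normal(0, 2.0, (reps, 100))
        w = lambda x: np.diff(np.quantile(x.mean(axis=1), [0.025, 0.975]))[0]
        w_s, w_t = w(true), w(noisy)
        oracle_share = (w_t - w_s) / w_t
        assert d.nirs_share == pytest.approx(oracle_share, abs=0.01)

    def test_share_shrinks_with_training_size_and_mean_age(self):
        from mozzage import study_a_power_law, surrogate_from_training_size

        fit = study_a_power_law()
        shares_by_ntrain = [
            decompose_uncertainty(
                5.0, 100, surrogate_from_training_size(fit, n), 20_000, seed=2
            ).nirs_share
            for n in (100, 500, 100_000)
        ]
        assert shares_by_ntrain[0] > shares_by_ntrain[1] > shares_by_ntrain[2]
        m = surrogate_from_training_size(fit, 500)
        share_young = decompose_uncertainty(3.0, 100, m, 20_000, seed=3).nirs_share
        share_old = decompose_uncertainty(7.0, 100, m, 20_000, seed=3).nirs_share
        assert share_young > share_old

    def test_variance_method_in_unit_interval(self):
        m = SurrogateModel(0.0, 1.0, 2.0)
        d = decompose_uncertainty(5.0, 100, m, 20_000, seed=4, method="variance")
        assert 0.0 < d.nirs_share < 1.0


class TestMinSampleSize:
    def test_identical_means_sentinel(self):
        m = SurrogateModel(0.0, 1.0, 2.0)
        assert min_sample_size_to_distinguish(5.0, 5.0, m) is None

    def test_monotone_in_mean_separation(self):
        m = SurrogateModel(0.0, 1.0, 2.1)
        grid = np.arange(10, 401, 10)
        n_wide = min_sample_size_to_distinguish(
            3.0, 7.0, m, replicates=2000, seed=5, n_grid=grid
        )
        n_narrow = min_sample_size_to_distinguish(
            5.0, 7.0, m, replicates=2000, seed=5, n_grid=grid
        )
        assert n_wide is not None and n_narrow is not None
        assert n_wide < n_narrow

    def test_monotone_in_surrogate_precision(self):
        grid = np.arange(10, 501, 10)
        n_noisy = min_sample_size_to_distinguish(
            5.0, 7.0, SurrogateModel(0.0, 1.0, 3.0), replicates=2000,
            seed=6, n_grid=grid,
        )
        n_clean = min_sample_size_to_distinguish(
            5.0, 7.0, SurrogateModel(0.0, 1.0, 0.5), replicates=2000,
            seed=6, n_grid=grid,
        )
        assert n_clean <= n_noisy

    def test_ztest_criterion_runs(self):
        m = SurrogateModel(0.0, 1.0, 2.0)
        n = min_sample_size_to_distinguish(
            5.0, 7.0, m, criterion="ztest", replicates=1500, seed=7
        )
        assert n is not None


class TestProportionOld:
    def test_all_young(self):
        assert proportion_old(np.full(10, 3.0)) == 0.0

    def test_closed_form_exponential(self):
        rng = np.random.default_rng(8)
        ages = rng.exponential(5.0, 1_000_000)
        assert proportion_old(ages, 7.0) == pytest.approx(
            np.exp(-7.0 / 5.0), abs=0.002
        )

    def test_bias_grows_with_noise_while_mean_stays_unbiased(self):
        rng = np.random.default_rng(9)
        true = rng.exponential(5.0, 200_000)
        p_true = proportion_old(true)
        biases, mean_errs = [], []
        for sd in (1.0, 3.0):
            noisy = true + rng.normal(0, sd, true.size)
            biases.append(abs(proportion_old(noisy) - p_true))
            mean_errs.append(abs(noisy.mean() - true.mean()))
        assert biases[1] > biases[0]
        assert max(mean_errs) < 0.05
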