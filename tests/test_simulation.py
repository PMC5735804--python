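"""Monte Carlo data-generating process and study driver."""

import numpy as np
import pytest

from tweediecost.simulation import (
    CostDataset,
    SimulationConfig,
    apply_high_corr_zeros,
    apply_low_corr_zeros,
    gen_betas,
    gen_positive_costs,
    gen_user_covariates,
    run_monte_carlo_study,
    simulate_dataset,
)


class TestCovariateAndCoefficientDraws:
    def test_user_covariates_respect_their_uniform_supports(self):
        X = gen_user_covariates(100_000, np.random.default_rng(0))
        assert X[:, 0].min() >= 2 and X[:, 0].max() <= 8
        assert X[:, 1].min() >= -10 and X[:, 1].max() <= 1
        assert X[:, 2].min() >= -2 and X[:, 2].max() <= 0

    def test_covariate_means_match_interval_midpoints(self):
        n = 100_000
        X = gen_user_covariates(n, np.random.default_rng(1))
        for j, (lo, hi) in enumerate([(2, 8), (-10, 1), (-2, 0)]):
            mid = (lo + hi) / 2
            se = (hi - lo) / np.sqrt(12 * n)
            assert abs(X[:, j].mean() - mid) < 3 * se

    def test_betas_lie_in_their_support_and_mean(self):
        rng = np.random.default_rng(2)
        draws = np.array([gen_betas(rng) for _ in range(30_000)])
        assert draws.min() >= -2 and draws.max() <= 1
        assert draws.mean() == pytest.approx(-0.5, abs=3 * np.sqrt(0.75) / np.sqrt(draws.size))

    def test_draws_are_seed_deterministic(self):
        a = gen_user_covariates(100, np.random.default_rng(3))
        b = gen_user_covariates(100, np.random.default_rng(3))
        assert np.array_equal(a, b)


class TestPositiveCostGeneration:
    def test_conditional_mean_and_variance_track_the_gamma_design(self):
        rng = np.random.default_rng(4)
        n = 200_000
        X = np.column_stack([rng.uniform(1.0, 2.0, n), np.zeros(n), np.zeros(n)])
        beta = np.array([2.0, 0.0, 0.0])  # eta in [2, 4]
        y = gen_positive_costs(X, beta, 30.0, rng)
        eta = X @ beta
        for lo in np.arange(2.0, 4.0, 0.25):
            band = (eta >= lo) & (eta < lo + 0.25)
            mu_band = np.exp(eta[band])
            assert y[band].mean() == pytest.approx(mu_band.mean(), rel=0.02)
            # within-band variance = design constant + spread of band means
            assert y[band].var() == pytest.approx(30.0 + mu_band.var(), rel=0.05)

    def test_all_costs_strictly_positive(self):
        rng = np.random.default_rng(5)
        X = gen_user_covariates(5000, rng)
        y = gen_positive_costs(X, np.array([0.8, 0.0, -0.1]), 30.0, rng)
        assert np.all(y > 0)

    def test_overflowing_linear_predictor_suggests_redraw(self):
        X = np.array([[8.0, 1.0, 0.0]])
        with pytest.raises(ValueError, match="redraw"):
            gen_positive_costs(X, np.array([3.0, 0.0, 0.0]), 30.0, np.random.default_rng(0))

    def test_underflowing_gamma_shape_suggests_redraw(self):
        X = np.array([[2.0, -10.0, -2.0], [8.0, 1.0, 0.0]])
        with pytest.raises(ValueError, match="redraw"):
            gen_positive_costs(X, np.array([0.5, 0.5, 0.5]), 30.0, np.random.default_rng(0))


@pytest.fixture()
def base_dataset():
    rng = np.random.default_rng(6)
    X = gen_user_covariates(2000, rng)
    y = gen_positive_costs(X, np.array([0.8, 0.01, -0.1]), 30.0, rng)
    return CostDataset(X=X, y=y)


class TestZeroInjection:
    def test_low_corr_zero_fraction_is_exact(self, base_dataset):
        out = apply_low_corr_zeros(base_dataset, 0.3, np.random.default_rng(7))
        assert int(out.is_zero.sum()) == round(2000 * 0.3)

    def test_low_corr_nonusers_lie_in_their_boxes(self, base_dataset):
        out = apply_low_corr_zeros(base_dataset, 0.2, np.random.default_rng(8))
        Z = out.X[out.is_zero]
        assert Z[:, 0].min() >= 3 and Z[:, 0].max() <= 6
        assert Z[:, 1].min() >= -2 and Z[:, 1].max() <= 3
        assert Z[:, 2].min() >= -1 and Z[:, 2].max() <= 1

    def test_low_corr_leaves_users_bitwise_unchanged(self, base_dataset):
        out = apply_low_corr_zeros(base_dataset, 0.2, np.random.default_rng(9))
        keep = ~out.is_zero  # replacement happens in place, rows keep indices
        assert np.array_equal(out.y[keep], base_dataset.y[keep])
        assert np.array_equal(out.X[keep], base_dataset.X[keep])

    def test_high_corr_zeroes_exactly_the_lowest_costs(self, base_dataset):
        out = apply_high_corr_zeros(base_dataset, 0.25)
        n0 = round(2000 * 0.25)
        assert int(out.is_zero.sum()) == n0
        zeroed_original = np.sort(base_dataset.y)[:n0]
        assert out.y[out.y > 0].min() >= zeroed_original.max()

    def test_high_corr_covariates_untouched(self, base_dataset):
        out = apply_high_corr_zeros(base_dataset, 0.25)
        assert np.array_equal(out.X, base_dataset.X)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.5])
    def test_zero_proportion_out_of_range_raises(self, base_dataset, bad):
        with pytest.raises(ValueError):
            apply_high_corr_zeros(base_dataset, bad)


class TestConfigAndDataset:
    def test_defaults_are_the_reference_design(self):
        cfg = SimulationConfig(scenario="high_corr", zero_prop=0.1)
        assert (cfg.n, cfg.n_replicates, cfg.theta_rate) == (5000, 100, 30.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"scenario": "medium", "zero_prop": 0.1},
            {"scenario": "low_corr", "zero_prop": 0.0},
            {"scenario": "low_corr", "zero_prop": 1.0},
            {"scenario": "low_corr", "zero_prop": 0.1, "n": 0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)

    def test_dataset_rejects_negative_costs(self):
        with pytest.raises(ValueError):
            CostDataset(X=np.ones((3, 3)), y=np.array([1.0, -1.0, 2.0]))

    def test_is_zero_tracks_exact_zeros(self, base_dataset):
        out = apply_high_corr_zeros(base_dataset, 0.1)
        assert np.array_equal(out.is_zero, out.y == 0)


class TestStudyDriver:
    def test_simulated_replicate_has_requested_zero_fraction(self):
        cfg = SimulationConfig(scenario="high_corr", zero_prop=0.15, n=1000,
                               n_replicates=1, seed=1)
        data, info = simulate_dataset(cfg, np.random.default_rng(10))
        assert int(data.is_zero.sum()) == round(1000 * 0.15)
        assert info["beta"].shape == (3,)

    def test_study_is_reproducible_and_ranks_are_permutations(self):
        cfg = SimulationConfig(scenario="low_corr", zero_prop=0.2, n=500,
                               n_replicates=2, seed=5)
        rep1 = run_monte_carlo_study(cfg)
        rep2 = run_monte_carlo_study(cfg)
        assert rep1.to_dict() == rep2.to_dict()
        recs = rep1.records_frame()
        for (_, _), grp in recs.groupby(["replicate", "zero_prop"]):
            assert sorted(grp["rank_aic"]) == [1, 2, 3, 4, 5]
            assert sorted(grp["rank_rmse"]) == [1, 2, 3, 4, 5]
        assert all(
            rep1.n_replicates <= s <= 5 * rep1.n_replicates
            for s in rep1.rank_sums_aic.values()
        )
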