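"""Distributional model: design-matrix coding, the Gibbs sampler against
known-truth simulations, slope arithmetic, diagnostics, and predictive-density
model comparison."""

import numpy as np
import pandas as pd
import pytest

import assemblage as A
from assemblage import ValidationError
from assemblage.model import (MCMCConfig, ModelSpec, compare_models,
                              derive_group_slopes, fit_distributional_model,
                              group_slopes_from_dataframe, prepare_model_data,
                              sample_prior_predictive,
                              simulate_similarity_records)


class TestPrepareModelData:
    def test_design_matrix_coding(self, recovery_records, recovery_spec):
        data = prepare_model_data(recovery_records, period=1, spec=recovery_spec)
        assert data.x_names == ["Intercept", "centered_day", "disturbance",
                               "centered_day:disturbance"]
        # disturbance dummy: 1 for D rows, 0 for U rows (treatment coding)
        d_col = data.X[:, 2]
        assert set(np.unique(d_col)) == {0.0, 1.0}
        # interaction column is the elementwise product
        np.testing.assert_allclose(data.X[:, 3], data.X[:, 1] * data.X[:, 2])

    def test_centered_day_mean_zero(self, recovery_records, recovery_spec):
        data = prepare_model_data(recovery_records, period=1, spec=recovery_spec)
        assert abs(data.X[:, 1].mean()) < 1e-10

    def test_period_filter(self):
        rec = simulate_similarity_records(
            beta={"Intercept": 0.5}, gamma={"Intercept": -3.0}, seed=0)
        rec2 = rec.copy()
        rec2["period"] = 2
        rec2["day"] += 28
        both = pd.concat([rec, rec2], ignore_index=True)
        spec = ModelSpec(mean_terms=("centered_day", "disturbance",
                                     "centered_day:disturbance"),
                         sigma_terms=("centered_day",))
        data = prepare_model_data(both, period=1, spec=spec)
        assert data.n_obs == len(rec)

    def test_single_level_factor_is_named_in_error(self):
        rec = simulate_similarity_records(
            beta={"Intercept": 0.5}, gamma={"Intercept": -3.0},
            disturbances=("U",), capacities=("L", "H"), seed=0)
        with pytest.raises(ValidationError, match="disturbance"):
            prepare_model_data(rec, period=1)

    def test_mixed_indices_rejected(self, recovery_records):
        mixed = recovery_records.copy()
        mixed.loc[mixed.index[:5], "index"] = "sorensen"
        with pytest.raises(ValidationError, match="indices"):
            prepare_model_data(mixed, period=1)


class TestMCMCConfig:
    def test_default_retains_8000_draws(self):
        assert MCMCConfig().retained_draws == 8000

    def test_invalid_configs(self):
        with pytest.raises(ValidationError):
            MCMCConfig(chains=1)
        with pytest.raises(ValidationError):
            MCMCConfig(warmup=5000, iterations_per_chain=4000)


class TestFit:
    def test_default_fit_retains_8000_draws(self, default_fit):
        assert default_fit.n_retained == 8000
        df = default_fit.to_dataframe()
        assert len(df) == 8000
        assert df["chain"].nunique() == 4

    def test_default_fit_converges(self, default_fit):
        assert default_fit.diagnostics["rhat"].max() <= 1.01
        assert default_fit.n_divergences == 0

    def test_recovers_known_slopes(self, default_fit):
        # data simulated with beta_t = 0.01 and gamma_t = -0.05
        bt = default_fit.coef("b_centered_day")
        gt = default_fit.coef("sigma_centered_day")
        assert abs(bt.mean() - 0.01) < 3 * bt.std()
        assert abs(gt.mean() - (-0.05)) < 3 * gt.std()

    def test_null_recovery(self, quick_config):
        # zero slopes, homoscedastic: every slope posterior is centred near 0
        rec = simulate_similarity_records(
            beta={"Intercept": 0.6}, gamma={"Intercept": np.log(0.04)},
            tau=0.02, n_pairs=3, days=np.arange(2, 30, 2), seed=99)
        spec = ModelSpec(mean_terms=("centered_day", "disturbance",
                                     "centered_day:disturbance"),
                         sigma_terms=("centered_day",))
        fit = fit_distributional_model(
            prepare_model_data(rec, period=1, spec=spec), config=quick_config)
        for name in ("b_centered_day", "b_centered_day:disturbance",
                     "sigma_centered_day"):
            draws = fit.coef(name)
            assert abs(draws.mean()) < 2 * draws.std()

    def test_rhat_failure_raises(self, recovery_records, recovery_spec):
        # two 3-iteration chains cannot pass split-Rhat
        data = prepare_model_data(recovery_records, period=1, spec=recovery_spec)
        cfg = MCMCConfig(chains=2, iterations_per_chain=6, warmup=2, seed=0)
        with pytest.raises(A.ConvergenceError):
            fit_distributional_model(data, config=cfg)

    def test_prior_predictive_is_finite(self, recovery_records, recovery_spec):
        data = prepare_model_data(recovery_records, period=1, spec=recovery_spec)
        draws = sample_prior_predictive(data, n_draws=200, seed=0)
        assert np.isfinite(draws["y"]).all()
        assert (draws["sigma"] > 0).all()


class TestGroupSlopes:
    def test_reference_group_equals_time_coefficient(self, default_fit):
        slopes = derive_group_slopes(default_fit)
        np.testing.assert_array_equal(slopes.mu_slopes["U"],
                                      default_fit.coef("b_centered_day"))

    def test_slope_difference_is_the_interaction(self, default_fit):
        slopes = derive_group_slopes(default_fit)
        np.testing.assert_allclose(
            slopes.mu_slopes["D"] - slopes.mu_slopes["U"],
            default_fit.coef("b_centered_day:disturbance"))

    def test_full_design_group_sum(self, quick_config):
        rec = simulate_similarity_records(
            beta={"Intercept": 0.6, "centered_day": 0.004},
            gamma={"Intercept": np.log(0.05)}, capacities=("L", "H"), seed=7)
        fit = fit_distributional_model(prepare_model_data(rec, period=1),
                                       config=quick_config, rhat_action="warn")
        slopes = derive_group_slopes(fit)
        expected = (fit.coef("b_centered_day")
                    + fit.coef("b_centered_day:disturbance")
                    + fit.coef("b_centered_day:capacity")
                    + fit.coef("b_centered_day:disturbance:capacity"))
        np.testing.assert_allclose(slopes.mu_slopes["DH"], expected)
        assert set(slopes.mu_slopes) == {"UL", "UH", "DL", "DH"}
        assert set(slopes.sigma_slopes) == {"U", "D"}

    def test_summary_cis_are_ordered(self, default_fit):
        summ = derive_group_slopes(default_fit).summary()
        assert (summ["ci95_lo"] <= summ["ci80_lo"]).all()
        assert (summ["ci80_lo"] <= summ["ci50_lo"]).all()
        assert (summ["ci50_hi"] <= summ["ci80_hi"]).all()
        assert (summ["ci80_hi"] <= summ["ci95_hi"]).all()

    def test_round_trip_through_dataframe(self, default_fit):
        df = default_fit.to_dataframe()
        direct = derive_group_slopes(default_fit)
        rebuilt = group_slopes_from_dataframe(df, period=1, index="bray_curtis")
        for g in direct.mu_slopes:
            np.testing.assert_allclose(rebuilt.mu_slopes[g], direct.mu_slopes[g])

    def test_recovery_of_distinct_group_slopes(self, quick_config):
        # distinct known slopes per disturbance group
        rec = simulate_similarity_records(
            beta={"Intercept": 0.6, "centered_day": -0.008,
                  "centered_day:disturbance": 0.02},
            gamma={"Intercept": np.log(0.04)}, tau=0.01, seed=12)
        spec = ModelSpec(mean_terms=("centered_day", "disturbance",
                                     "centered_day:disturbance"),
                         sigma_terms=("centered_day",))
        fit = fit_distributional_model(prepare_model_data(rec, period=1, spec=spec),
                                       config=quick_config, rhat_action="warn")
        slopes = derive_group_slopes(fit)
        for group, truth in (("U", -0.008), ("D", 0.012)):
            d = slopes.mu_slopes[group]
            assert abs(d.mean() - truth) < 2 * d.std()


class TestCompareModels:
    @staticmethod
    def _fit(rec, sigma_terms, config):
        spec = ModelSpec(mean_terms=("centered_day", "disturbance",
                                     "centered_day:disturbance"),
                         sigma_terms=sigma_terms)
        return fit_distributional_model(prepare_model_data(rec, 1, spec),
                                        config=config, rhat_action="warn")

    def test_self_comparison_is_a_tie(self, default_fit):
        out = compare_models([default_fit, default_fit], names=["a", "b"])
        assert out["delta_elpd"].abs().max() == pytest.approx(0.0, abs=1e-9)

    def test_heteroscedastic_model_wins_on_heteroscedastic_data(self, quick_config):
        wins = 0
        n_sims = 10
        for k in range(n_sims):
            rec = simulate_similarity_records(
                beta={"Intercept": 0.6, "centered_day": 0.005},
                gamma={"Intercept": np.log(0.05), "centered_day": -0.08},
                tau=0.01, seed=500 + k)
            het = self._fit(rec, ("centered_day",), quick_config)
            hom = self._fit(rec, (), quick_config)
            out = compare_models([het, hom], names=["het", "hom"])
            wins += out.loc[0, "model"] == "het"
        assert wins >= 8

    def test_mismatched_observations_rejected(self, default_fit, quick_config):
        other = simulate_similarity_records(
            beta={"Intercept": 0.5}, gamma={"Intercept": -3.0},
            days=np.arange(2, 20, 2), seed=1)
        fit2 = self._fit(other, ("centered_day",), quick_config)
        with pytest.raises(ValidationError, match="observation set"):
            compare_models([default_fit, fit2])
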