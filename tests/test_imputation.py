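"""Imputation engines: design construction, FCS, MVNI, posterior draws."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

import ccmi
from ccmi.imputation import (
    STRATEGIES,
    CompletedDataset,
    FitError,
    GlmFit,
    ImputationConfig,
    ImputationStrategy,
    InvalidStrategyError,
    _da_chain,
    _logit_fit,
    build_imputation_design,
    fcs_impute,
    impute,
    mvni_impute,
    posterior_draw_glm,
)

FAST = ImputationConfig(m=3, fcs_cycles=3, mvni_burnin=20)


class TestStrategies:
    def test_registry_has_the_seven_approaches(self):
        assert set(STRATEGIES) == {"FCS-WO", "FCS-WX", "FCS-SS", "FCS-WM",
                                   "MVNI-WO", "MVNI-WX", "MVNI-SS"}

    def test_weighted_model_requires_fcs(self):
        with pytest.raises(InvalidStrategyError):
            ImputationStrategy("MVNI", "weighted_model", "MVNI-WM")

    def test_engine_rejects_wrong_framework(self, masked_sample):
        sample, _ = masked_sample
        with pytest.raises(InvalidStrategyError):
            fcs_impute(sample, STRATEGIES["MVNI-WO"], FAST, np.random.default_rng(0))
        with pytest.raises(InvalidStrategyError):
            mvni_impute(sample, STRATEGIES["FCS-WO"], FAST, np.random.default_rng(0))


class TestImputationDesign:
    def test_weight_only_base_predictors(self, masked_sample):
        sample, _ = masked_sample
        design = build_imputation_design(sample, STRATEGIES["FCS-WO"])
        assert design["petown"]["predictors"] == [
            "foodallergy", "vdi", "cauc", "hxfamall", "nsib1", "nsib2",
            "antevd", "mage", "seifa1", "seifa2"]
        assert not design["petown"]["stratify_by_outcome"]
        assert not design["petown"]["weighted"]

    def test_interactions_exclude_the_target_itself(self, masked_sample):
        sample, _ = masked_sample
        design = build_imputation_design(sample, STRATEGIES["FCS-WX"])
        preds = design["petown"]["predictors"]
        assert "foodallergy:vdi" in preds and "foodallergy:antevd" in preds
        assert "foodallergy:petown" not in preds
        assert "foodallergy:mage" not in preds  # auxiliaries not interacted

    def test_stratum_specific_drops_outcome(self, masked_sample):
        sample, _ = masked_sample
        design = build_imputation_design(sample, STRATEGIES["FCS-SS"])
        assert "foodallergy" not in design["antevd"]["predictors"]
        assert design["antevd"]["stratify_by_outcome"]

    def test_weighted_model_flag(self, masked_sample):
        sample, _ = masked_sample
        design = build_imputation_design(sample, STRATEGIES["FCS-WM"])
        assert design["petown"]["weighted"]


class TestEngineContracts:
    def test_no_missing_data_returns_copies(self, observed_registry):
        params, spec = observed_registry
        rng = np.random.default_rng(21)
        cohort = ccmi.generate_cohort(params, spec, 400, rng)
        sample = ccmi.select_subcohort(cohort, 0.5, rng)
        for label in ("FCS-WO", "MVNI-WO"):
            out = impute(sample, STRATEGIES[label], FAST, np.random.default_rng(1))
            assert len(out) == FAST.m
            for c in out:
                assert c.converged
                pd.testing.assert_frame_equal(c.data, sample.records)

    @pytest.mark.parametrize("label", list(STRATEGIES))
    def test_observed_cells_immutable_and_missing_filled(self, masked_sample, label):
        sample, _ = masked_sample
        out = impute(sample, STRATEGIES[label], FAST, np.random.default_rng(2))
        pet_obs = sample.records["petown"].notna().to_numpy()
        ant_obs = sample.records["antevd"].notna().to_numpy()
        for c in out:
            assert c.converged
            # observed cells bit-identical, all gaps filled
            for var, obs in (("petown", pet_obs), ("antevd", ant_obs)):
                before = sample.records[var].to_numpy(dtype=float)
                after = c.data[var].to_numpy(dtype=float)
                assert np.array_equal(before[obs], after[obs])
                assert np.isfinite(after).all()
            others = [col for col in sample.records.columns
                      if col not in ("petown", "antevd")]
            pd.testing.assert_frame_equal(c.data[others], sample.records[others])

    def test_fcs_imputes_binary_mvni_unrounded(self, masked_sample):
        sample, _ = masked_sample
        miss = sample.records["petown"].isna().to_numpy()
        fcs = fcs_impute(sample, STRATEGIES["FCS-WO"], FAST, np.random.default_rng(3))
        vals = fcs[0].data["petown"].to_numpy()[miss]
        assert set(np.unique(vals)) <= {0.0, 1.0}
        mvni = mvni_impute(sample, STRATEGIES["MVNI-WO"], FAST, np.random.default_rng(4))
        vals = mvni[0].data["petown"].to_numpy()[miss]
        assert np.any((vals != 0.0) & (vals != 1.0))

    def test_between_imputation_variability(self, masked_sample):
        sample, _ = masked_sample
        out = fcs_impute(sample, STRATEGIES["FCS-WO"], FAST, np.random.default_rng(5))
        means = [c.data["petown"].mean() for c in out]
        assert np.std(means) > 0

    def test_stacked_csv_export(self, masked_sample, tmp_path):
        from ccmi.imputation import completed_to_csv
        sample, _ = masked_sample
        out = fcs_impute(sample, STRATEGIES["FCS-WO"], FAST, np.random.default_rng(13))
        path = tmp_path / "completed.csv"
        completed_to_csv(out, path)
        back = pd.read_csv(path)
        assert len(back) == FAST.m * len(sample.records)
        assert sorted(back["imputation"].unique()) == [1, 2, 3]
        assert back["petown"].notna().all()


class TestPosteriorDraw:
    def test_zero_covariance_returns_point_estimate(self):
        fit = GlmFit(np.array([1.0, -2.0]), np.zeros((2, 2)))
        draw = posterior_draw_glm(fit, np.random.default_rng(0))
        assert np.array_equal(draw, fit.params)

    def test_draw_covariance_matches(self):
        cov = np.array([[0.04, 0.01], [0.01, 0.09]])
        fit = GlmFit(np.array([0.5, -0.5]), cov)
        rng = np.random.default_rng(1)
        draws = np.array([posterior_draw_glm(fit, rng) for _ in range(10_000)])
        assert np.allclose(np.cov(draws.T), cov, rtol=0.12, atol=0.004)
        assert np.allclose(draws.mean(axis=0), fit.params, atol=0.01)

    def test_seeded_reproducibility(self):
        fit = GlmFit(np.array([0.0]), np.array([[1.0]]))
        a = posterior_draw_glm(fit, np.random.default_rng(42))
        b = posterior_draw_glm(fit, np.random.default_rng(42))
        assert np.array_equal(a, b)

    def test_non_positive_definite_rejected(self):
        fit = GlmFit(np.array([0.0, 0.0]), np.array([[1.0, 2.0], [2.0, 1.0]]))
        with pytest.raises(FitError):
            posterior_draw_glm(fit, np.random.default_rng(2))


class TestStatisticalBehaviour:
    def test_single_missing_value_follows_posterior_predictive(self):
        """Long-run FCS imputation frequency matches an independently
        computed posterior-predictive probability (statsmodels route)."""
        rng = np.random.default_rng(6)
        n = 400
        params, spec = ccmi.make_scenario_params()
        cohort = ccmi.generate_cohort(params, spec, n, rng)
        cohort.loc[cohort.index[0], "petown"] = np.nan
        sample = ccmi.select_subcohort(cohort, 1.0, rng)

        # oracle: observed-data logistic fit + normal posterior draws
        from ccmi.imputation import _expand, build_imputation_design, _design_matrix
        base = _expand(sample.records)
        arrays = {c: base[c].to_numpy(dtype=float) for c in base.columns}
        design = build_imputation_design(sample, STRATEGIES["FCS-WO"])
        obs = ~np.isnan(arrays["petown"])
        X = _design_matrix(arrays, design["petown"]["predictors"], obs)
        res = sm.Logit(arrays["petown"][obs], X).fit(disp=0)
        x0 = _design_matrix(arrays, design["petown"]["predictors"], ~obs)
        beta_draws = np.random.default_rng(7).multivariate_normal(
            res.params, res.cov_params(), size=5000)
        oracle_p = float(np.mean(expit(beta_draws @ x0[0])))

        config = ImputationConfig(m=300, fcs_cycles=2, augment=False)
        out = fcs_impute(sample, STRATEGIES["FCS-WO"], config,
                         np.random.default_rng(8))
        freq = np.mean([c.data["petown"].iloc[0] for c in out])
        se = np.sqrt(oracle_p * (1 - oracle_p) / 300)
        assert freq == pytest.approx(oracle_p, abs=4 * se + 0.02)

    def test_mcar_marginal_preservation(self, masked_sample):
        """Pooled post-imputation prevalence matches the pre-masking value
        under a completely-at-random mechanism."""
        sample, cohort = masked_sample
        config = ImputationConfig(m=30, fcs_cycles=5)
        out = fcs_impute(sample, STRATEGIES["FCS-WO"], config,
                         np.random.default_rng(9))
        pooled = np.mean([c.data["antevd"].mean() for c in out])
        truth = cohort.loc[sample.records.index, "antevd"].mean()
        assert pooled == pytest.approx(truth, abs=0.035)

    def test_da_chain_tracks_conditional_normal(self):
        """Sampler recovers the conditional-normal law on a bivariate toy."""
        rng = np.random.default_rng(10)
        n = 2000
        y1 = rng.standard_normal(n)
        y2 = 1.0 + 2.0 * y1 + rng.normal(0, 1.0, n)
        Y = np.column_stack([y1, y2])
        miss = np.zeros_like(Y, dtype=bool)
        miss[: n // 2, 1] = True
        Y_masked = Y.copy()
        Y_masked[miss] = np.nan
        imputed = []
        for rep in range(30):
            work = Y_masked.copy()
            done, ok = _da_chain(work, miss, 30, np.random.default_rng(100 + rep))
            assert ok
            imputed.append(done[: n // 2, 1])
        imp = np.vstack(imputed)
        # regression of imputed on observed y1 reproduces slope and noise
        slope = np.polyfit(np.tile(y1[: n // 2], 30), imp.ravel(), 1)[0]
        assert slope == pytest.approx(2.0, abs=0.1)
        resid_sd = (imp - (1.0 + 2.0 * y1[: n // 2])).std()
        assert resid_sd == pytest.approx(1.0, abs=0.1)

    def test_weight_accommodations_agree_when_weights_are_null(self):
        """With pi = 1 (all weights 1) and MCAR gaps, WO, SS and WM target
        the same conditional model and give close pooled prevalences."""
        params, spec = ccmi.make_scenario_params()
        rng = np.random.default_rng(11)
        cohort = ccmi.generate_cohort(params, spec, 3000, rng)
        masked = ccmi.induce_independent(cohort, 30.0, rng)
        sample = ccmi.select_subcohort(masked, 1.0, rng)
        config = ImputationConfig(m=10, fcs_cycles=5)
        pooled = {}
        for label in ("FCS-WO", "FCS-SS", "FCS-WM"):
            out = fcs_impute(sample, STRATEGIES[label], config,
                             np.random.default_rng(12))
            pooled[label] = np.mean([c.data["petown"].mean() for c in out])
        vals = list(pooled.values())
        assert max(vals) - min(vals) < 0.02
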