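"""GLMM fitting, LRT, Nakagawa R2 and residual checks.

The Gaussian and Poisson fitters are checked two independent ways:
against frozen reference values from R lme4 (lmer/glmer, ML, computed
on the identical seeded dataset), and against statsmodels MixedLM at
run time for the Gaussian family.
"""

import numpy as np
import pandas as pd
import pytest

from gullmig.popstats import (ModelSpec, PopulationFit, compare_populations,
                              fit_glmm, lrt, r2_nakagawa, residual_check,
                              simulate_response_dataset)


@pytest.fixture(scope="module")
def gauss_data():
    rng = np.random.default_rng(42)
    df = simulate_response_dataset(
        {"A": 100.0, "B": 115.0, "C": 95.0, "D": 108.0}, [8, 12, 17, 11],
        "gaussian", rng, sd_between=8.0, sd_resid=12.0)
    return df.rename(columns={"value": "resp"})


@pytest.fixture(scope="module")
def pois_data():
    rng = np.random.default_rng(43)
    df = simulate_response_dataset(
        {"A": 30.0, "B": 22.0, "C": 18.0, "D": 25.0}, [8, 12, 17, 11],
        "poisson", rng, sd_between=0.25)
    return df.rename(columns={"value": "resp"})


class TestAgainstLme4:
    # reference: R lme4 on the same seeded CSVs, ML estimation
    LMER_BETA = [99.83803, 15.69522, -4.590389, 8.074997]
    LMER_LL_FULL, LMER_LL_NULL = -178.5533, -189.1967
    LMER_TAU2, LMER_S2 = 22.63982, 78.53262
    GLMER_BETA = [3.461358, -0.6210737, -0.4047693, -0.1340973]
    GLMER_CHI2 = 2 * (-37.85039 + 47.72809)
    GLMER_TAU2 = 0.02974463
    GLMER_SE = [0.09583555, 0.1340394, 0.1205506, 0.127907]

    def test_gaussian_matches_lmer(self, gauss_data):
        fit = fit_glmm(gauss_data, ModelSpec("resp", "gaussian",
                                             reference_level="A"))
        assert fit.beta == pytest.approx(self.LMER_BETA, rel=1e-4)
        assert fit.loglik == pytest.approx(self.LMER_LL_FULL, abs=1e-3)
        assert fit.random_intercept_var == pytest.approx(self.LMER_TAU2,
                                                         rel=1e-2)
        assert fit.resid_var == pytest.approx(self.LMER_S2, rel=1e-2)

    def test_gaussian_lrt_matches_lmer(self, gauss_data):
        fit = compare_populations(gauss_data,
                                  ModelSpec("resp", "gaussian",
                                            reference_level="A"))
        expect = 2 * (self.LMER_LL_FULL - self.LMER_LL_NULL)
        assert fit.lrt_chi2 == pytest.approx(expect, abs=2e-2)
        assert fit.lrt_df == 3

    def test_poisson_matches_glmer(self, pois_data):
        fit = compare_populations(pois_data,
                                  ModelSpec("resp", "poisson",
                                            reference_level="A"))
        assert fit.beta == pytest.approx(self.GLMER_BETA, abs=2e-3)
        assert fit.random_intercept_var == pytest.approx(self.GLMER_TAU2,
                                                         abs=2e-3)
        assert fit.se == pytest.approx(self.GLMER_SE, rel=2e-2)
        assert fit.lrt_chi2 == pytest.approx(self.GLMER_CHI2, abs=5e-2)

    def test_gaussian_matches_statsmodels_mixedlm(self, gauss_data):
        sm = pytest.importorskip("statsmodels.regression.mixed_linear_model")
        X = pd.get_dummies(gauss_data["population"], drop_first=True,
                           dtype=float)
        X.insert(0, "Intercept", 1.0)
        m = sm.MixedLM(gauss_data["resp"], X,
                       groups=gauss_data["individual"]).fit(reml=False)
        fit = fit_glmm(gauss_data, ModelSpec("resp", "gaussian",
                                             reference_level="A"))
        assert fit.beta == pytest.approx(np.asarray(m.fe_params), rel=1e-4)


class TestSingularHandling:
    def test_zero_variance_triggers_refit(self):
        rng = np.random.default_rng(0)
        df = simulate_response_dataset({"A": 10.0, "B": 12.0}, [15, 15],
                                       "gaussian", rng, sd_between=0.0,
                                       sd_resid=3.0).rename(
                                           columns={"value": "resp"})
        fit = fit_glmm(df, ModelSpec("resp", "gaussian"))
        if fit.singular:
            # fixed effects must agree with plain OLS
            ols = np.linalg.lstsq(fit.X, fit.y, rcond=None)[0]
            assert fit.beta == pytest.approx(ols, rel=1e-8)
            assert not fit.has_random

    def test_one_track_per_individual_inestimable(self):
        rng = np.random.default_rng(1)
        rows = [{"population": p, "individual": f"{p}{i}",
                 "resp": rng.normal(10.0 + 3 * (p == "B"), 2.0)}
                for p in "AB" for i in range(12)]
        df = pd.DataFrame(rows)
        fit = fit_glmm(df, ModelSpec("resp", "gaussian"))
        # variance split is unidentifiable; the fit must not crash and a
        # singular resolution must fall back to OLS coefficients
        assert np.all(np.isfinite(fit.beta))


class TestLRT:
    def test_identical_likelihoods_give_zero_and_p_one(self, gauss_data):
        """If the fixed effect explains nothing (likelihoods equal) the
        statistic is 0 and p = 1; with four populations df = 3."""
        full = fit_glmm(gauss_data, ModelSpec("resp", "gaussian"))
        null = fit_glmm(gauss_data, ModelSpec("resp", "gaussian"),
                        _with_population=False,
                        _force_no_random=not full.has_random)
        null_equal = PopulationFit(**{**null.__dict__, "loglik": full.loglik})
        chi2, df, p = lrt(full, null_equal)
        assert chi2 == 0.0
        assert p == 1.0
        assert df == 3  # four populations -> 3 contrast parameters

    def test_reference_level_invariance(self, gauss_data):
        stats = []
        for ref in ["A", "C"]:
            fit = compare_populations(gauss_data,
                                      ModelSpec("resp", "gaussian",
                                                reference_level=ref))
            stats.append(fit.lrt_chi2)
        assert stats[0] == pytest.approx(stats[1], abs=1e-6)

    def test_non_nested_rejected(self, gauss_data, pois_data):
        g = fit_glmm(gauss_data, ModelSpec("resp", "gaussian"))
        with pytest.raises(ValueError):
            lrt(g, g)  # same size: not nested
        p = fit_glmm(pois_data, ModelSpec("resp", "poisson"))
        with pytest.raises(ValueError):
            lrt(g, p)

    def test_strong_effect_power(self):
        """3-SD group separation at n=12/group rejects essentially always."""
        rng = np.random.default_rng(5)
        rejections = 0
        for _ in range(60):
            df = simulate_response_dataset(
                {"A": 0.0, "B": 3.0, "C": 0.0, "D": 3.0}, [12, 12, 12, 12],
                "gaussian", rng, sd_between=0.3,
                sd_resid=1.0).rename(columns={"value": "resp"})
            fit = compare_populations(df, ModelSpec("resp", "gaussian"))
            rejections += fit.lrt_p < 0.05
        assert rejections >= 57  # > 0.95 power


class TestNakagawaR2:
    def test_zero_fixed_zero_random(self):
        fit = PopulationFit(
            family="gaussian", terms=["Intercept"], beta=np.array([5.0]),
            se=np.array([1.0]), ci_low=np.array([3.0]), ci_high=np.array([7.0]),
            random_intercept_var=0.0, resid_var=4.0, loglik=0.0, n_obs=10,
            n_fixed=1, singular=False, has_random=False,
            X=np.ones((10, 1)), y=np.full(10, 5.0), groups=np.arange(10))
        assert r2_nakagawa(fit) == (0.0, 0.0)

    def test_random_only_conditional_exceeds_marginal(self):
        fit = PopulationFit(
            family="gaussian", terms=["Intercept"], beta=np.array([5.0]),
            se=np.array([1.0]), ci_low=np.array([3.0]), ci_high=np.array([7.0]),
            random_intercept_var=2.0, resid_var=4.0, loglik=0.0, n_obs=10,
            n_fixed=1, singular=False, has_random=True,
            X=np.ones((10, 1)), y=np.full(10, 5.0), groups=np.arange(10))
        r2m, r2c = r2_nakagawa(fit)
        assert r2m == 0.0 and r2c == pytest.approx(2.0 / 6.0)

    def test_constructed_variance_shares(self):
        """Fixed 50%, random 30%, residual 20% at n=2000 recovers
        (~0.5, ~0.8)."""
        rng = np.random.default_rng(7)
        rows = []
        for g in range(250):
            mean = [-1.0, 1.0][g % 2] * np.sqrt(0.5)  # var(fixed) = 0.5
            u = rng.normal(0.0, np.sqrt(0.3))
            for r in range(8):
                rows.append({"population": "AB"[g % 2],
                             "individual": f"i{g}",
                             "resp": mean + u + rng.normal(0, np.sqrt(0.2))})
        df = pd.DataFrame(rows)
        fit = fit_glmm(df, ModelSpec("resp", "gaussian"))
        r2m, r2c = r2_nakagawa(fit)
        assert r2m == pytest.approx(0.5, abs=0.05)
        assert r2c == pytest.approx(0.8, abs=0.05)

    def test_ordering_invariant(self, gauss_data, pois_data):
        for df, fam in [(gauss_data, "gaussian"), (pois_data, "poisson")]:
            fit = fit_glmm(df, ModelSpec("resp", fam))
            r2m, r2c = r2_nakagawa(fit)
            assert 0.0 <= r2m <= r2c <= 1.0


class TestResidualCheck:
    def test_well_specified_mostly_clean(self):
        rng = np.random.default_rng(11)
        flags = 0
        for s in range(30):
            df = simulate_response_dataset(
                {"A": 10.0, "B": 14.0}, [20, 20], "gaussian", rng,
                sd_between=1.0, sd_resid=2.0).rename(columns={"value": "resp"})
            fit = fit_glmm(df, ModelSpec("resp", "gaussian"))
            flags += residual_check(fit, seed=s).flagged
        assert flags <= 6  # non-significant in >= 80% here (alpha 0.05)

    def test_poisson_data_with_gaussian_family_flagged(self):
        """Counts spanning two orders of magnitude violate the constant-
        variance Gaussian assumption and must be flagged."""
        rng = np.random.default_rng(12)
        df = simulate_response_dataset(
            {"A": 3.0, "B": 200.0}, [60, 60], "poisson", rng,
            sd_between=0.0).rename(columns={"value": "resp"})
        fit = fit_glmm(df, ModelSpec("resp", "gaussian",
                                     random_intercept=False))
        assert residual_check(fit, seed=0).flagged

    def test_empty_model_rejected(self):
        fit = PopulationFit(
            family="gaussian", terms=[], beta=np.array([]), se=np.array([]),
            ci_low=np.array([]), ci_high=np.array([]),
            random_intercept_var=0.0, resid_var=1.0, loglik=0.0, n_obs=0,
            n_fixed=0, singular=False, has_random=False,
            X=None, y=np.array([]), groups=np.array([]))
        with pytest.raises(ValueError):
            residual_check(fit)


class TestValidation:
    def test_single_population_rejected(self):
        df = pd.DataFrame({"population": ["A"] * 6,
                           "individual": list("abcdef"),
                           "resp": np.arange(6.0)})
        with pytest.raises(ValueError):
            fit_glmm(df, ModelSpec("resp", "gaussian"))

    def test_non_integer_poisson_rejected(self, gauss_data):
        with pytest.raises(ValueError):
            fit_glmm(gauss_data, ModelSpec("resp", "poisson"))

    def test_family_mapping(self):
        assert ModelSpec("migration_distance_km").resolved_family() == "gaussian"
        assert ModelSpec("duration_days").resolved_family() == "poisson"
        assert ModelSpec("stopover_length").resolved_family() == "poisson"
        with pytest.raises(ValueError):
            ModelSpec("unknown_thing").resolved_family()
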