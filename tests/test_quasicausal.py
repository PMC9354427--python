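"""Quasi-causal bivariate model: moments, fits, Wald tests, conversions."""

import numpy as np
import pytest

from twinpillars.ace import pair_loglik_continuous, pair_loglik_ordinal
from twinpillars.pillars import code_dataset
from twinpillars.quasicausal import (
    QuasiCausalSpec,
    StructuralParams,
    fit_model,
    implied_pair_moments,
    liability_predictor_loglik,
    multiplicative_factor,
    percent_change_per_pillar,
    wald_equal,
    wald_test,
)
from twinpillars.synth import GeneratorConfig, OutcomeModel, generate_registry

PARAMS = StructuralParams(
    mu_x=3.0, p_xa=0.6, p_xc=0.45, p_xe=0.5, b_p=-0.08, b_a=-0.05, b_c=0.03,
    mu_y=1.2, p_ua=0.35, p_uc=0.2, p_ue=0.4,
)


def _simulate_structural(params, zygosity, n, rng):
    """Direct simulation of the structural equations (independent of the
    moment algebra under test)."""
    rbar = {"MZ": 1.0, "DZ": 0.5}[zygosity]
    shared = rng.standard_normal((n, 1))
    a_x = np.sqrt(rbar) * shared + np.sqrt(1 - rbar) * rng.standard_normal((n, 2))
    c_x = rng.standard_normal((n, 1))
    e_x = rng.standard_normal((n, 2))
    x = params.mu_x + params.p_xa * a_x + params.p_xc * c_x + params.p_xe * e_x
    shared_u = rng.standard_normal((n, 1))
    a_u = np.sqrt(rbar) * shared_u + np.sqrt(1 - rbar) * rng.standard_normal((n, 2))
    c_u = rng.standard_normal((n, 1))
    e_u = rng.standard_normal((n, 2))
    y = (
        params.mu_y
        + params.b_p * (x - params.mu_x)
        + params.b_a * a_x
        + params.b_c * c_x
        + params.p_ua * a_u
        + params.p_uc * c_u
        + params.p_ue * e_u
    )
    return x, y


class TestImpliedMoments:
    @pytest.mark.parametrize("zygosity", ["MZ", "DZ"])
    def test_against_monte_carlo(self, zygosity):
        rng = np.random.default_rng(0)
        n = 1_000_000
        x, y = _simulate_structural(PARAMS, zygosity, n, rng)
        emp = np.cov(
            np.column_stack([x[:, 0], y[:, 0], x[:, 1], y[:, 1]]).T
        )
        mu, sigma = implied_pair_moments(PARAMS, zygosity)
        assert np.allclose(mu, [PARAMS.mu_x, PARAMS.mu_y] * 2)
        scale = np.sqrt(np.outer(np.diag(sigma), np.diag(sigma)))
        assert np.max(np.abs(emp - sigma) / scale) < 0.01

    def test_no_confound_paths(self):
        p = StructuralParams(
            mu_x=0, p_xa=0.6, p_xc=0.4, p_xe=0.5, b_p=-0.1, b_a=0.0, b_c=0.0,
            mu_y=0, p_ua=0.3, p_uc=0.3, p_ue=0.3,
        )
        _, sigma = implied_pair_moments(p, "MZ")
        var_x = 0.6**2 + 0.4**2 + 0.5**2
        assert sigma[0, 1] == pytest.approx(-0.1 * var_x, abs=1e-12)

    def test_zygosity_difference_only_through_a_terms(self):
        _, s_mz = implied_pair_moments(PARAMS, "MZ")
        _, s_dz = implied_pair_moments(PARAMS, "DZ")
        # within-person blocks identical across zygosity
        assert np.allclose(s_mz[:2, :2], s_dz[:2, :2])
        # cross-twin X covariance differs by exactly 0.5 * a_x^2
        assert s_mz[0, 2] - s_dz[0, 2] == pytest.approx(0.5 * PARAMS.p_xa**2)
        # cross-twin X1,Y2 differs by 0.5 * (b_p a_x^2 + b_a a_x)
        expected = 0.5 * (PARAMS.b_p * PARAMS.p_xa**2 + PARAMS.b_a * PARAMS.p_xa)
        assert s_mz[0, 3] - s_dz[0, 3] == pytest.approx(expected)


def _coded(b_p, b_a, b_c, n_pairs, seed, prop_female=1.0):
    cfg = GeneratorConfig(
        n_mz_pairs=n_pairs, n_dz_pairs=n_pairs, prop_female=prop_female, seed=seed,
        outcomes={
            "log_bmi": OutcomeModel(
                mean=3.25, resid_sd=0.19, resid_ace=(0.6, 0.1, 0.3),
                b_p=b_p, b_a=b_a, b_c=b_c,
            ),
            "sqrt_phq": OutcomeModel(mean=0.62, resid_sd=0.6,
                                     resid_ace=(0.35, 0.05, 0.6)),
        },
        missing_rates={}, round_raw=False,
    )
    return code_dataset(generate_registry(cfg))


SPEC_OBS = dict(outcome="log_bmi", pillars="all",
                predictor_mode="observed_count", groups=None)


class TestFitModel:
    def test_slope_recovery(self):
        """Model 2 recovers the generating within-person slope."""
        coded = _coded(b_p=-0.10, b_a=0.0, b_c=0.0, n_pairs=2000, seed=3)
        fit = fit_model(QuasiCausalSpec(model_level=2, **SPEC_OBS), coded)
        # generator slope is per population-SD of the count; the observed-
        # count fit is per count unit
        prev = np.asarray(GeneratorConfig().pillar_prevalences)
        sd = np.sqrt((prev * (1 - prev)).sum())
        assert fit.converged
        assert fit["b_p"] == pytest.approx(-0.10 / sd, abs=2 * fit.se["b_p"])

    def test_attenuation_under_confounding(self):
        """Pure between-family confounding: the phenotypic model (1) is
        biased away from zero, the quasi-causal model (2) is not."""
        coded = _coded(b_p=0.0, b_a=-0.05, b_c=-0.05, n_pairs=2000, seed=4)
        f1 = fit_model(QuasiCausalSpec(model_level=1, **SPEC_OBS), coded)
        f2 = fit_model(QuasiCausalSpec(model_level=2, **SPEC_OBS), coded)
        z1, p1 = f1.z_and_p("b_p")
        assert p1 < 0.01 and f1["b_p"] < 0
        assert abs(f2["b_p"]) < 2 * f2.se["b_p"]
        assert abs(f2["b_p"]) < abs(f1["b_p"])

    def test_nesting_minus2ll(self):
        """Model 2 nests Model 1 (b_f = 0) and Model 3 (b_p equated)."""
        coded = _coded(b_p=-0.05, b_a=-0.04, b_c=-0.04, n_pairs=600, seed=5,
                       prop_female=0.5)
        by_sex = dict(outcome="log_bmi", pillars="all",
                      predictor_mode="observed_count")
        f1 = fit_model(QuasiCausalSpec(model_level=1, **by_sex), coded,
                       compute_vcov=False)
        f2 = fit_model(QuasiCausalSpec(model_level=2, **by_sex), coded,
                       compute_vcov=False)
        f3 = fit_model(QuasiCausalSpec(model_level=3, **by_sex), coded,
                       compute_vcov=False)
        assert f1.minus2ll >= f2.minus2ll - 1e-6
        assert f3.minus2ll >= f2.minus2ll - 1e-6

    def test_covariate_recovery(self):
        cfg = GeneratorConfig(
            n_mz_pairs=1500, n_dz_pairs=1500, prop_female=1.0, seed=6,
            outcomes={
                "log_bmi": OutcomeModel(
                    mean=3.25, resid_sd=0.19, resid_ace=(0.6, 0.1, 0.3),
                    b_p=-0.05, covariate_effects={"age": 0.03},
                ),
                "sqrt_phq": OutcomeModel(mean=0.62, resid_sd=0.6,
                                         resid_ace=(0.35, 0.05, 0.6)),
            },
            missing_rates={}, round_raw=False,
        )
        coded = code_dataset(generate_registry(cfg))
        spec = QuasiCausalSpec(model_level=2, covariates=("age",), **SPEC_OBS)
        fit = fit_model(spec, coded)
        # generator slope is per z-scored age (SD 18 years); the fit is per year
        assert fit["beta_age"] == pytest.approx(
            0.03 / 18.0, abs=2 * fit.se["beta_age"]
        )

    def test_pillar_subset_and_presets(self):
        coded = _coded(b_p=-0.05, b_a=0.0, b_c=0.0, n_pairs=500, seed=7)
        spec = QuasiCausalSpec(
            outcome="log_bmi", pillars="bmi_top2", model_level=1,
            predictor_mode="observed_count", groups=None,
        )
        fit = fit_model(spec, coded, compute_vcov=False)
        assert fit.converged
        spec2 = QuasiCausalSpec(
            outcome="log_bmi", pillars=("sedentary", "nonsmoking"),
            model_level=1, predictor_mode="observed_count", groups=None,
        )
        assert fit_model(spec2, coded, compute_vcov=False).converged


class TestWald:
    def test_zero_when_constraint_holds(self):
        coded = _coded(b_p=-0.05, b_a=0.0, b_c=0.0, n_pairs=300, seed=8)
        fit = fit_model(QuasiCausalSpec(model_level=2, **SPEC_OBS), coded)
        est = fit["b_p"]
        R = np.zeros((1, len(fit.param_names)))
        R[0, fit.param_names.index("b_p")] = 1.0
        stat, df, p = wald_test(fit, R, r=[est])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_z_squared_identity(self):
        coded = _coded(b_p=-0.05, b_a=0.0, b_c=0.0, n_pairs=300, seed=9)
        fit = fit_model(QuasiCausalSpec(model_level=2, **SPEC_OBS), coded)
        stat, df, _ = wald_test(fit, ["b_p"])
        z, _ = fit.z_and_p("b_p")
        assert df == 1
        assert stat == pytest.approx(z**2, abs=1e-10)


class TestPercentChange:
    @pytest.mark.parametrize(
        "b_p,pct,factor",
        [(-0.026, 2.6, 0.97), (-0.052, 5.1, 0.95), (0.0, 0.0, 1.0),
         (-0.006, 0.6, 0.99)],
    )
    def test_printed_conversions(self, b_p, pct, factor):
        assert round(percent_change_per_pillar(b_p), 1) == pct
        assert round(multiplicative_factor(b_p), 2) == factor


class TestLiabilityMode:
    def test_factorizes_when_paths_zero(self):
        """With b_p = b_a = b_c = 0 the mixed likelihood is the ordinal
        pair likelihood plus the continuous pair likelihood."""
        rng = np.random.default_rng(10)
        tau = np.array([-1.0, -0.2, 0.5, 1.1, 1.8])
        shares = np.sqrt([0.4, 0.2, 0.4])
        params = StructuralParams(
            mu_x=0.0, p_xa=shares[0], p_xc=shares[1], p_xe=shares[2],
            b_p=0.0, b_a=0.0, b_c=0.0,
            mu_y=1.0, p_ua=0.3, p_uc=0.25, p_ue=0.35,
        )
        n = 60
        counts = rng.integers(0, 6, (n, 2)).astype(float)
        y = rng.normal(1.0, 0.5, (n, 2))
        counts[0, 1] = np.nan
        y[1, 0] = np.nan
        counts[2, :] = np.nan
        y[3, :] = np.nan
        for zyg in ("MZ", "DZ"):
            mixed = liability_predictor_loglik(counts, y, zyg, params, tau)
            var_u = 0.3**2 + 0.25**2 + 0.35**2
            ll_ord = pair_loglik_ordinal(counts, zyg, tau, 0.4, 0.2)
            ll_con = pair_loglik_continuous(
                y, zyg, 1.0, var_u, 0.3**2 / var_u, 0.25**2 / var_u
            )
            assert np.allclose(mixed, ll_ord + ll_con, atol=1e-8)

    def test_cross_mode_consistency(self):
        """Observed-count and liability fits agree on sign and overlap in
        confidence intervals on well-populated data."""
        coded = _coded(b_p=-0.12, b_a=0.0, b_c=0.0, n_pairs=500, seed=11)
        f_obs = fit_model(QuasiCausalSpec(model_level=2, **SPEC_OBS), coded)
        spec_l = QuasiCausalSpec(
            outcome="log_bmi", pillars="all", model_level=2,
            predictor_mode="liability_ordinal", groups=None,
        )
        f_liab = fit_model(spec_l, coded)
        assert np.sign(f_obs["b_p"]) == np.sign(f_liab["b_p"]) == -1
        lo_o = f_obs["b_p"] - 1.96 * f_obs.se["b_p"]
        hi_o = f_obs["b_p"] + 1.96 * f_obs.se["b_p"]
        lo_l = f_liab["b_p"] - 1.96 * f_liab.se["b_p"]
        hi_l = f_liab["b_p"] + 1.96 * f_liab.se["b_p"]
        assert max(lo_o, lo_l) <= min(hi_o, hi_l)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(12)
        tau = np.array([-0.5, 0.5])
        params = StructuralParams(
            mu_x=0.0, p_xa=0.5, p_xc=0.4, p_xe=0.77, b_p=-0.2, b_a=-0.1,
            b_c=-0.05, mu_y=0.5, p_ua=0.3, p_uc=0.2, p_ue=0.4,
        )
        counts = rng.integers(0, 3, (40, 2)).astype(float)
        y = rng.normal(0.5, 0.6, (40, 2))
        a = liability_predictor_loglik(counts, y, "DZ", params, tau)
        b = liability_predictor_loglik(
            counts[:, ::-1], y[:, ::-1], "DZ", params, tau
        )
        assert np.allclose(a, b, atol=1e-10)
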