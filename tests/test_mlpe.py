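import numpy as np
import pytest

from ibrkit import (
    PairwiseModelData,
    PairwiseSimParams,
    aicc,
    dic,
    fit_mlpe_mcmc,
    fit_mlpe_reml,
    r2_beta,
    r2_m,
    simulate_pairwise_response,
    standardize_columns,
)
from ibrkit.errors import ParameterError
from ibrkit.experiments import _reference_resistance
from ibrkit.mlpe import MLPEFit, _ess, wald_f


@pytest.fixture(scope="module")
def resist():
    return _reference_resistance(20, seed=5)


def make_data(resist, beta=(0.5,), sigma_u=0.2, sigma_e=0.1, seed=6, beta0=0.0):
    y = simulate_pairwise_response(
        resist,
        PairwiseSimParams(beta0=beta0, beta=beta, sigma_u=sigma_u,
                          sigma_e=sigma_e, seed=seed),
    )
    return PairwiseModelData.from_matrices(y, {"resist": resist})


class TestStandardize:
    def test_two_sd_convention(self):
        z, centers, scales = standardize_columns(np.array([1.0, 2.0, 3.0]))
        assert z.mean() == pytest.approx(0.0, abs=1e-15)
        assert z.std(ddof=1) == pytest.approx(0.5, abs=1e-12)
        assert centers[0] == 2.0 and scales[0] == pytest.approx(2.0)

    def test_idempotent_up_to_scale(self):
        x = np.array([1.0, 4.0, 2.0, 8.0])
        z1, _, _ = standardize_columns(x)
        z2, _, s2 = standardize_columns(z1.ravel())
        np.testing.assert_allclose(z1.ravel(), z2.ravel() * s2[0], atol=1e-12)

    def test_constant_column_rejected(self):
        with pytest.raises(ParameterError, match="constant"):
            standardize_columns(np.ones(5))

    def test_slope_backtransform_matches_raw_ols(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=60)
        y = 3.0 + 1.7 * x + rng.normal(0, 0.1, size=60)
        z, _, scales = standardize_columns(x)
        b_std = np.polyfit(z.ravel(), y, 1)[0]
        b_raw = np.polyfit(x, y, 1)[0]
        assert b_std / scales[0] == pytest.approx(b_raw, rel=1e-10)


class TestREML:
    def test_matches_independent_mixedlm_oracle(self, resist):
        statsmodels = pytest.importorskip("statsmodels")
        from statsmodels.regression.mixed_linear_model import MixedLM

        data = make_data(resist)
        fit = fit_mlpe_reml(data)
        x, _ = data.design(None)
        with np.errstate(all="ignore"):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = MixedLM(
                    data.response, x, groups=np.ones(data.n_rows),
                    exog_vc={"u": {1.0: data.z_matrix()}},
                ).fit(reml=True)
        np.testing.assert_allclose(fit.beta, res.fe_params, atol=1e-5)
        assert fit.sigma_u2 == pytest.approx(float(res.vcomp[0]), abs=1e-4)
        assert fit.sigma_e2 == pytest.approx(res.scale, abs=1e-5)
        assert fit.reml_loglik == pytest.approx(res.llf, abs=1e-5)

    def test_fixed_zero_gamma_reproduces_ols_exactly(self, resist):
        data = make_data(resist, sigma_u=0.0, seed=11)
        fit = fit_mlpe_reml(data, fix_gamma=0.0)
        x, _ = data.design(None)
        beta_ols, *_ = np.linalg.lstsq(x, data.response, rcond=None)
        np.testing.assert_allclose(fit.beta, beta_ols, atol=1e-10)
        resid = data.response - x @ beta_ols
        s2 = float(resid @ resid) / (data.n_rows - x.shape[1])
        assert fit.sigma_e2 == pytest.approx(s2, rel=1e-12)

    def test_row_permutation_invariance(self, resist):
        data = make_data(resist)
        rng = np.random.default_rng(3)
        perm = rng.permutation(data.n_rows)
        permuted = PairwiseModelData(
            response=data.response[perm],
            predictors=data.predictors[perm],
            predictor_names=data.predictor_names,
            membership=data.membership[perm],
            n_groups=data.n_groups,
        )
        f1 = fit_mlpe_reml(data)
        f2 = fit_mlpe_reml(permuted)
        np.testing.assert_allclose(f1.beta, f2.beta, atol=1e-9)
        # the variance profile is flat to machine precision near its optimum,
        # so the ratio search can stop within its bracketing tolerance
        assert f1.sigma_u2 == pytest.approx(f2.sigma_u2, rel=1e-5)

    def test_slope_recovered_within_interval(self, resist):
        data = make_data(resist, beta=(0.5,), seed=21)
        fit = fit_mlpe_reml(data)
        assert abs(fit.beta[1] - 0.5) < 3 * fit.beta_se[1]
        assert fit.converged

    def test_intercept_only_fit(self, resist):
        data = make_data(resist)
        fit = fit_mlpe_reml(data, predictors=[])
        assert fit.n_fixed == 1
        assert fit.sigma_u2 >= 0


class TestMCMC:
    def test_posterior_mean_matches_reml(self, resist):
        data = make_data(resist, seed=31)
        reml = fit_mlpe_reml(data)
        mcmc = fit_mlpe_mcmc(data, iterations=4000, burnin=1000, seed=1)
        assert abs(mcmc.posterior_mean_beta()[1] - reml.beta[1]) < 0.05

    def test_two_chains_agree_within_mc_error(self, resist):
        data = make_data(resist, seed=32)
        mcmc = fit_mlpe_mcmc(data, iterations=4000, burnin=1000, seed=2)
        means = np.array([c["beta"].mean(axis=0) for c in mcmc.chains])
        mcse2 = np.array([
            [c["beta"][:, j].std(ddof=1) ** 2 / _ess(c["beta"][:, j])
             for j in range(means.shape[1])]
            for c in mcmc.chains
        ])
        z = np.abs(means[0] - means[1]) / np.sqrt(mcse2.sum(axis=0))
        assert np.all(z < 3.0)
        assert mcmc.convergence_ok

    def test_zero_group_variance_shrinks_posterior(self, resist):
        data = make_data(resist, sigma_u=0.0, sigma_e=0.1, seed=33)
        mcmc = fit_mlpe_mcmc(data, iterations=4000, burnin=1000, seed=3)
        su2 = np.median(mcmc.pooled("sigma_u2"))
        se2 = np.median(mcmc.pooled("sigma_e2"))
        assert su2 < se2 / 10

    def test_requires_two_chains(self, resist):
        with pytest.raises(ParameterError):
            fit_mlpe_mcmc(make_data(resist), chains=1)

    def test_credible_interval_shapes(self, resist):
        mcmc = fit_mlpe_mcmc(make_data(resist), iterations=2000, burnin=500,
                             seed=4)
        for method in ("quantile", "hpd"):
            ci = mcmc.credible_interval(0.95, method=method)
            assert ci.shape == (2, 2)
            assert np.all(ci[:, 0] < ci[:, 1])


class TestCriteria:
    def test_aicc_formula(self):
        fit = MLPEFit(
            beta=np.zeros(1), beta_se=np.ones(1), beta_names=["(intercept)"],
            sigma_u2=0.1, sigma_e2=0.1, reml_loglik=-100.0, converged=True,
            n_obs=435, n_groups=30, data=None,
        )
        assert aicc(fit, n_obs=435, k=3) == pytest.approx(206 + 24 / 431, abs=1e-10)

    def test_aicc_exceeds_aic(self, resist):
        fit = fit_mlpe_reml(make_data(resist))
        aic = -2 * fit.reml_loglik + 2 * (fit.n_fixed + 2)
        assert aicc(fit) > aic

    def test_aicc_undefined_for_tiny_n(self):
        fit = MLPEFit(
            beta=np.zeros(1), beta_se=np.ones(1), beta_names=["(intercept)"],
            sigma_u2=0.1, sigma_e2=0.1, reml_loglik=-10.0, converged=True,
            n_obs=4, n_groups=3, data=None,
        )
        with pytest.raises(ParameterError):
            aicc(fit, n_obs=4, k=3)

    def test_noise_predictor_usually_increases_aicc(self):
        resist = _reference_resistance(15, seed=40)
        rng = np.random.default_rng(41)
        worse = 0
        n_reps = 40
        for rep in range(n_reps):
            y = simulate_pairwise_response(
                resist,
                PairwiseSimParams(beta=(0.5,), sigma_u=0.1, sigma_e=0.1,
                                  seed=500 + rep),
            )
            noise_vals = rng.normal(size=y.size)
            data = PairwiseModelData(
                response=y,
                predictors=np.column_stack([
                    standardize_columns(resist.condensed())[0],
                    standardize_columns(noise_vals)[0],
                ]),
                predictor_names=["resist", "noise"],
                membership=resist.pair_members(),
                n_groups=resist.n_groups,
            )
            base = aicc(fit_mlpe_reml(data, ["resist"]))
            full = aicc(fit_mlpe_reml(data, ["resist", "noise"]))
            worse += full > base
        assert worse >= 0.8 * n_reps

    def test_dic_prefers_true_predictor(self, resist):
        hits = 0
        for rep in range(10):
            data = make_data(resist, beta=(1.0,), sigma_u=0.1, sigma_e=0.1,
                             seed=600 + rep)
            with_pred = dic(fit_mlpe_mcmc(data, iterations=1500, burnin=500,
                                          seed=rep))
            without = dic(fit_mlpe_mcmc(data, predictors=[], iterations=1500,
                                        burnin=500, seed=rep))
            hits += with_pred < without
        assert hits >= 9

    def test_r2_beta_zero_without_fixed_effects(self, resist):
        fit = fit_mlpe_reml(make_data(resist), predictors=[])
        assert r2_beta(fit) == 0.0

    def test_r2_beta_equals_ols_r2_at_zero_gamma(self, resist):
        data = make_data(resist, sigma_u=0.0, seed=51)
        fit = fit_mlpe_reml(data, fix_gamma=0.0)
        x, _ = data.design(None)
        y = data.response
        beta_ols, *_ = np.linalg.lstsq(x, y, rcond=None)
        ss_res = float(((y - x @ beta_ols) ** 2).sum())
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2_ols = 1 - ss_res / ss_tot
        for method in ("satterthwaite", "residual"):
            assert r2_beta(fit, ddf_method=method) == pytest.approx(r2_ols, abs=1e-6)

    def test_r2_beta_monotone_in_f(self, resist):
        fit = fit_mlpe_reml(make_data(resist))
        nu = fit.n_obs - fit.n_fixed
        f = wald_f(fit)
        lo = (1 / nu) * (f / 2) / (1 + (1 / nu) * (f / 2))
        assert r2_beta(fit, ddf_method="residual") > lo

    def test_kenward_roger_clearly_signposted(self, resist):
        fit = fit_mlpe_reml(make_data(resist))
        with pytest.raises(NotImplementedError, match="satterthwaite"):
            r2_beta(fit, ddf_method="kenward-roger")

    def test_r2_m_zero_for_intercept_only(self, resist):
        fit = fit_mlpe_reml(make_data(resist), predictors=[])
        assert r2_m(fit) == 0.0

    def test_r2_m_approaches_one_in_noise_free_limit(self, resist):
        data = make_data(resist, beta=(1.0,), sigma_u=0.0, sigma_e=1e-5,
                         seed=52)
        fit = fit_mlpe_reml(data)
        assert r2_m(fit) > 0.999

    def test_r2_m_close_to_ols_r2_when_no_group_variance(self, resist):
        data = make_data(resist, sigma_u=0.0, seed=53)
        fit = fit_mlpe_reml(data)
        x, _ = data.design(None)
        y = data.response
        beta_ols, *_ = np.linalg.lstsq(x, y, rcond=None)
        r2_ols = 1 - float(((y - x @ beta_ols) ** 2).sum()) / float(
            ((y - y.mean()) ** 2).sum()
        )
        assert r2_m(fit) == pytest.approx(r2_ols, abs=0.02)
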