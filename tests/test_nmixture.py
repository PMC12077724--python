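"""N-mixture model: marginal likelihood, closed-form limits, fitting
behaviour, derived quantities."""

import numpy as np
import pytest
from scipy.stats import poisson

from camuse import FitConfig, NmixParams, fit_nmixture, nmix_site_loglik
from camuse.mcmc import calibration_priors
from camuse.nmixture import derive_detection_prob_nmix, derive_expected_count

from _oracles import nmix_loglik_enumeration, random_nmix_instance


class TestSiteLoglik:
    def test_poisson_thinning_limit(self):
        # J=1, sigma=0: y ~ Poisson(lambda * rho) exactly
        for lam, rho_logit, y in [(1.0, 0.0, 0), (2.5, -1.0, 3), (0.7, 1.5, 1)]:
            params = NmixParams(alpha=[[np.log(lam)]], beta=[[rho_logit]])
            ll = nmix_site_loglik([[y]], [1], params, [1.0], trunc=150)
            rho = 1 / (1 + np.exp(-rho_logit))
            assert ll == pytest.approx(poisson.logpmf(y, lam * rho), rel=1e-12)

    def test_worked_value_half_nat(self):
        params = NmixParams(alpha=[[0.0]], beta=[[0.0]])
        ll = nmix_site_loglik([[0]], [1], params, [1.0], trunc=100)
        assert ll == pytest.approx(-0.5, abs=1e-12)

    def test_no_detection_limit_probability_one(self):
        params = NmixParams(alpha=[[0.0]], beta=[[-40.0]])
        ll = nmix_site_loglik([[0], [0], [0]], [1, 1, 1], params, [1.0], trunc=60)
        assert ll == pytest.approx(0.0, abs=1e-10)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(60):
            y, rep, alpha, beta, sigma, x = random_nmix_instance(rng)
            a = nmix_site_loglik(y, rep, NmixParams(alpha=alpha, beta=beta,
                                                    sigma=sigma), x, trunc=120)
            b = nmix_loglik_enumeration(y, rep, alpha, beta, sigma, x, n_max=120)
            worst = max(worst, abs(a - b))
        assert worst < 1e-10

    def test_overdispersion_quadrature_vs_adaptive_integration(self):
        # validates the Gauss-Hermite rule itself against scipy.quad
        from scipy.integrate import quad
        from scipy.stats import binom, norm

        lam, b, sigma, y = 1.5, -0.8, 0.9, 2
        params = NmixParams(alpha=[[np.log(lam)]], beta=[[b]], sigma=sigma)
        ll = nmix_site_loglik([[y]], [1], params, [1.0], trunc=200)
        total = 0.0
        for n in range(0, 200):
            f = lambda e: binom.pmf(y, n, 1 / (1 + np.exp(-(b + e)))) * \
                norm.pdf(e, 0, sigma)
            total += poisson.pmf(n, lam) * quad(f, -8 * sigma, 8 * sigma,
                                                limit=200)[0]
        assert ll == pytest.approx(np.log(total), abs=1e-6)

    def test_truncation_stability(self):
        rng = np.random.default_rng(7)
        y, rep, alpha, beta, sigma, x = random_nmix_instance(rng)
        params = NmixParams(alpha=alpha, beta=beta, sigma=sigma)
        base = nmix_site_loglik(y, rep, params, x, trunc=90)
        bigger = nmix_site_loglik(y, rep, params, x, trunc=240)
        assert abs(base - bigger) < 1e-12

    def test_trunc_below_max_count_rejected(self):
        params = NmixParams(alpha=[[0.0]], beta=[[0.0]])
        with pytest.raises(ValueError, match="trunc"):
            nmix_site_loglik([[9]], [1], params, [1.0], trunc=5)

    def test_label_invariance(self):
        rng = np.random.default_rng(9)
        y = rng.integers(0, 4, size=(3, 3))
        rep = np.array([1, 2, 1])
        alpha = rng.normal(0, 0.5, (3, 2))
        beta = rng.normal(-1, 0.5, (2, 3))
        x = np.array([1.0, 0.3])
        perm = [2, 0, 1]
        a = nmix_site_loglik(y, rep, NmixParams(alpha=alpha, beta=beta,
                                                sigma=0.4), x, trunc=80)
        b = nmix_site_loglik(y[:, perm], rep,
                             NmixParams(alpha=alpha[perm], beta=beta[:, perm],
                                        sigma=0.4), x, trunc=80)
        assert a == pytest.approx(b, rel=1e-12)


class TestFit:
    def test_binary_data_rejected(self, small_study, short_fit_config):
        with pytest.raises(ValueError, match="count histories"):
            fit_nmixture(small_study["data"].binarize(), small_study["cov"],
                         short_fit_config)

    def test_unstandardized_covariates_warn(self, small_study, short_fit_config):
        from camuse.covariates import SiteCovariateTable
        from dataclasses import replace

        raw = small_study["cov"].raw * 3.0 + 5.0
        tab = SiteCovariateTable(raw=raw, standardized=raw,
                                 scaler=small_study["cov"].scaler)
        cfg = replace(short_fit_config, n_iter=60, n_burnin=20)
        with pytest.warns(UserWarning, match="standardized"):
            fit_nmixture(small_study["data"], tab, cfg)

    def test_same_seed_identical_draws(self, small_study, short_fit_config):
        from dataclasses import replace

        cfg = replace(short_fit_config, n_iter=300, n_burnin=100)
        a = fit_nmixture(small_study["data"], small_study["cov"], cfg)
        b = fit_nmixture(small_study["data"], small_study["cov"], cfg)
        assert np.array_equal(a.get("alpha"), b.get("alpha"))
        assert np.array_equal(a.get("sigma"), b.get("sigma"))

    def test_sigma_zero_truth_recovered_near_zero(self):
        # generated without overdispersion: the posterior for sigma should
        # concentrate near 0
        from camuse.covariates import standardize
        from camuse.synthetic import (HyperConfig, default_design,
                                      gen_community_truth,
                                      gen_detection_histories,
                                      gen_site_covariates)

        cfg = HyperConfig(
            state_hyper_mean=[0.6, 0.2], state_hyper_sd=[0.2, 0.1],
            detect_hyper_mean=[-1.5] * 4, detect_hyper_sd=0.2,
            overdispersion_sd=0.0,
        )
        design = default_design(120, 14, seed=20)
        cov = standardize(gen_site_covariates(120, np.eye(1), seed=21,
                                              names=["x"]))
        truth = gen_community_truth(cfg, 3, 4, seed=22)
        data, _ = gen_detection_histories(truth, cov, design, "nmixture",
                                          seed=23)
        fit_cfg = FitConfig(n_chains=2, n_iter=2200, n_burnin=1000, seed=24,
                            priors=calibration_priors(2), n_quad=9)
        draws = fit_nmixture(data, cov, fit_cfg)
        upper = np.percentile(draws.stacked("sigma"), 97.5)
        assert upper < 0.5


class TestDerivedQuantities:
    @staticmethod
    def _draws_with(alpha0):
        """Posterior store with a single controlled alpha intercept path."""
        import xarray as xr
        from camuse.mcmc import FitConfig, PosteriorDraws

        alpha0 = np.asarray(alpha0, dtype=float)  # (draws,)
        alpha = alpha0[None, :, None, None] * np.ones((1, len(alpha0), 1, 1))
        beta = np.zeros((1, len(alpha0), 1, 1))
        ds = xr.Dataset(
            {
                "alpha": (("chain", "draw", "species", "covariate"), alpha),
                "beta": (("chain", "draw", "replicate", "species"), beta),
                "hyper_mean": (("chain", "draw", "covariate"),
                               alpha[:, :, 0, :]),
                "hyper_sd": (("chain", "draw", "covariate"),
                             np.ones((1, len(alpha0), 1))),
                "sigma": (("chain", "draw"), np.zeros((1, len(alpha0)))),
            },
            coords={"species": ["sp0"], "covariate": ["intercept"],
                    "replicate": [1]},
        )
        return PosteriorDraws(ds, "nmixture", ["sp0"], ["intercept"],
                              FitConfig(n_chains=1, n_iter=2, n_burnin=0))

    def test_degenerate_posterior(self):
        d = self._draws_with([np.log(2.0)] * 8)
        out = derive_expected_count(d)
        assert out.loc["sp0", "mean"] == pytest.approx(2.0)
        assert out.loc["sp0", "ci_lo"] == pytest.approx(2.0)
        assert out.loc["sp0", "ci_hi"] == pytest.approx(2.0)

    def test_two_draw_mean(self):
        d = self._draws_with([0.0, np.log(4.0)])
        out = derive_expected_count(d)
        assert out.loc["sp0", "mean"] == pytest.approx(2.5)

    def test_detection_backtransform(self):
        d = self._draws_with([0.0, 0.0])
        det = derive_detection_prob_nmix(d)
        assert det["mean"].iloc[0] == pytest.approx(0.5)

    def test_detection_one_percent_logit(self):
        d = self._draws_with([0.0, 0.0])
        d.ds["beta"][:] = -4.59512
        det = derive_detection_prob_nmix(d)
        assert det["mean"].iloc[0] == pytest.approx(0.01, abs=1e-5)

    def test_detection_monotone_in_beta(self):
        lo = self._draws_with([0.0] * 4)
        hi = self._draws_with([0.0] * 4)
        lo.ds["beta"][:] = -1.0
        hi.ds["beta"][:] = 0.5
        assert (derive_detection_prob_nmix(hi)["mean"].iloc[0]
                > derive_detection_prob_nmix(lo)["mean"].iloc[0])

    def test_table_schema(self):
        out = derive_expected_count(self._draws_with([0.1, 0.2]))
        assert {"mean", "ci_lo", "ci_hi"} <= set(out.columns)
        assert out.index.name == "species"
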