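import numpy as np
import pytest
from scipy import integrate, stats

from ednaq.domain_model import (CovariateSet, CTObservation, LatentState,
                                ModelParameters, StandardsSet, SurveyDataset,
                                SurveyDesign)
from ednaq.likelihood import (CONST_VAR, FULL, NO_MIXTURE, PriorSpec,
                              availability_loglik, collection_loglik,
                              ct_mean, ct_variance, hierarchy_loglik,
                              joint_log_posterior, log_prior,
                              replicate_component_loglik,
                              replicate_marginal_loglik)

CT_MAX = 40.0
SIGMA_C = 40.0


class TestCTMean:

    def test_w1(self):
        assert ct_mean(1.0, 44.0, -1.7) == pytest.approx(44.0)

    def test_high_concentration(self):
        # 44 - 1.7 ln(3e7), natural log
        assert ct_mean(3e7, 44.0, -1.7) == pytest.approx(
            44.0 - 1.7 * np.log(3e7), abs=1e-12)
        assert ct_mean(3e7, 44.0, -1.7) == pytest.approx(14.731, abs=1e-3)

    def test_tenfold_identity(self):
        for w in (0.3, 7.0, 1e5):
            assert ct_mean(10 * w, 44.0, -1.7) - ct_mean(w, 44.0, -1.7) \
                == pytest.approx(-1.7 * np.log(10), abs=1e-10)

    def test_nonpositive_w_raises(self):
        with pytest.raises(ValueError):
            ct_mean(0.0, 44.0, -1.7)


class TestCTVariance:

    def test_w1(self):
        assert ct_variance(1.0, 0.2, -0.25) == pytest.approx(np.exp(0.2))
        assert ct_variance(1.0, 0.2, -0.25) == pytest.approx(1.2214,
                                                             abs=1e-4)

    def test_a2_zero_constant(self):
        vals = [ct_variance(w, 0.2, 0.0) for w in (0.1, 1.0, 1e6)]
        assert np.ptp(vals) == pytest.approx(0.0, abs=1e-12)

    def test_high_concentration(self):
        assert ct_variance(3e7, 0.2, -0.25) == pytest.approx(
            np.exp(0.2) * (3e7) ** (-0.25), rel=1e-10)
        assert ct_variance(3e7, 0.2, -0.25) == pytest.approx(0.0165,
                                                             abs=2e-4)

    def test_decreasing_in_w_when_a2_negative(self):
        ws = np.logspace(-2, 8, 30)
        vals = ct_variance(ws, 0.2, -0.25)
        assert (np.diff(vals) < 0).all()


class TestComponentLoglik:

    def test_censored_clean_at_boundary_mean(self):
        # mu = ct_max: exactly half the normal mass is censored
        w = np.exp((44.0 - CT_MAX) / 1.7)   # mu(w) = ct_max
        ll = replicate_component_loglik(None, w, 0, 44.0, -1.7, 0.2, -0.25,
                                        SIGMA_C, CT_MAX)
        assert ll == pytest.approx(np.log(0.5), abs=1e-9)

    def test_censored_inhibited_at_boundary_mean_is_certain(self):
        w = np.exp((44.0 - CT_MAX) / 1.7)
        ll = replicate_component_loglik(None, w, 2, 44.0, -1.7, 0.2, -0.25,
                                        SIGMA_C, CT_MAX)
        assert ll == pytest.approx(0.0, abs=1e-12)

    def test_contaminated_matches_independent_truncnorm(self):
        # oracle: quadrature-normalised truncated normal density
        w, ct = 200.0, 20.0
        mu = 44.0 - 1.7 * np.log(w)
        Z, _ = integrate.quad(
            lambda x: stats.norm.pdf(x, mu, SIGMA_C), 0.0, mu)
        oracle = np.log(stats.norm.pdf(ct, mu, SIGMA_C) / Z)
        ll = replicate_component_loglik(ct, w, 1, 44.0, -1.7, 0.2, -0.25,
                                        SIGMA_C, CT_MAX)
        assert ll == pytest.approx(oracle, abs=1e-10)

    def test_contaminated_scipy_truncnorm_oracle(self):
        w, ct = 50.0, 10.0
        mu = 44.0 - 1.7 * np.log(w)
        a, b = (0.0 - mu) / SIGMA_C, (mu - mu) / SIGMA_C
        oracle = stats.truncnorm.logpdf(ct, a, b, loc=mu, scale=SIGMA_C)
        ll = replicate_component_loglik(ct, w, 1, 44.0, -1.7, 0.2, -0.25,
                                        SIGMA_C, CT_MAX)
        assert ll == pytest.approx(oracle, abs=1e-10)

    def test_contaminated_empty_support(self):
        # mu <= 0 at very large w
        w = np.exp(44.0 / 1.7 + 1.0)
        ll = replicate_component_loglik(10.0, w, 1, 44.0, -1.7, 0.2, -0.25,
                                        SIGMA_C, CT_MAX)
        assert ll == -np.inf

    def test_inhibited_matches_scipy(self):
        w, ct = 3e4, 30.0
        mu = 44.0 - 1.7 * np.log(w)
        oracle = stats.truncnorm.logpdf(ct, 0.0, np.inf, loc=mu,
                                        scale=SIGMA_C)
        ll = replicate_component_loglik(ct, w, 2, 44.0, -1.7, 0.2, -0.25,
                                        SIGMA_C, CT_MAX)
        assert ll == pytest.approx(oracle, abs=1e-10)

    def test_observed_ct_above_ct_max_rejected(self):
        with pytest.raises(ValueError):
            replicate_component_loglik(41.0, 100.0, 0, 44.0, -1.7, 0.2,
                                       -0.25, SIGMA_C, CT_MAX)


class TestMarginal:

    def test_zero_probabilities_reduce_to_clean(self):
        for ct in (12.0, 35.0, None):
            m = replicate_marginal_loglik(ct, 500.0, 0.0, 0.0, 44.0, -1.7,
                                          0.2, -0.25, SIGMA_C, CT_MAX)
            c = replicate_component_loglik(ct, 500.0, 0, 44.0, -1.7, 0.2,
                                           -0.25, SIGMA_C, CT_MAX)
            assert m == pytest.approx(c, abs=1e-12)

    def test_lower_bound_by_weighted_component(self):
        ct, w = 5.0, 30.0
        m = replicate_marginal_loglik(ct, w, 0.05, 0.1, 44.0, -1.7, 0.2,
                                      -0.25, SIGMA_C, CT_MAX)
        c1 = replicate_component_loglik(ct, w, 1, 44.0, -1.7, 0.2, -0.25,
                                        SIGMA_C, CT_MAX)
        assert m >= np.log(0.05) + c1 - 1e-12

    def test_constraint_enforced(self):
        with pytest.raises(ValueError):
            replicate_marginal_loglik(10.0, 100.0, 0.3, 0.25, 44.0, -1.7,
                                      0.2, -0.25, SIGMA_C, CT_MAX)

    @pytest.mark.parametrize("w", [1.0, 30.0, 3e3, 3e7])
    def test_normalisation_quadrature(self, w):
        """Mixture density over (-inf, ct_max) plus censored mass = 1."""
        p_c, p_h = 0.05, 0.1

        def dens(ct):
            return np.exp(replicate_marginal_loglik(
                ct, w, p_c, p_h, 44.0, -1.7, 0.2, -0.25, SIGMA_C, CT_MAX))

        mass, _ = integrate.quad(dens, -300.0, CT_MAX, limit=400)
        cens = np.exp(replicate_marginal_loglik(
            None, w, p_c, p_h, 44.0, -1.7, 0.2, -0.25, SIGMA_C, CT_MAX))
        assert mass + cens == pytest.approx(1.0, abs=1e-6)


class TestGaussianStages:

    def test_availability_at_conditional_means(self, rng):
        n, T = 4, 5
        X = rng.normal(size=(n, T, 2))
        beta_b = np.array([0.3, -0.6])
        rho = rng.normal(1.0, 0.1, size=n)
        d = X @ beta_b
        l = np.empty((n, T))
        l[:, 0] = 2.0 + d[:, 0]
        for t in range(1, T):
            l[:, t] = rho * (l[:, t - 1] - d[:, t - 1]) + d[:, t]
        ll = availability_loglik(l, X, 2.0, beta_b, rho, 1.0, 1.0)
        assert ll == pytest.approx(-(n * T / 2) * np.log(2 * np.pi),
                                   abs=1e-10)

    def test_availability_T1_reduces_to_first_term(self, rng):
        X = rng.normal(size=(3, 1, 1))
        l = rng.normal(size=(3, 1))
        ll = availability_loglik(l, X, 0.5, [1.0], [0.9, 0.9, 0.9], 1.0,
                                 2.0)
        oracle = sum(stats.norm.logpdf(l[i, 0], 0.5 + X[i, 0, 0],
                                       np.sqrt(2.0)) for i in range(3))
        assert ll == pytest.approx(oracle, abs=1e-12)

    def test_availability_flat_loop_oracle(self, rng):
        n, T = 2, 3
        X = rng.normal(size=(n, T, 2))
        l = rng.normal(size=(n, T))
        beta_b0, beta_b = 1.3, np.array([0.5, -0.2])
        rho = np.array([0.8, 1.1])
        tau2, tau2_1 = 0.7, 1.9
        oracle = 0.0
        for i in range(n):
            oracle += stats.norm.logpdf(
                l[i, 0], beta_b0 + X[i, 0] @ beta_b, np.sqrt(tau2_1))
            for t in range(1, T):
                mean = rho[i] * (l[i, t - 1] - X[i, t - 1] @ beta_b) \
                    + X[i, t] @ beta_b
                oracle += stats.norm.logpdf(l[i, t], mean, np.sqrt(tau2))
        ll = availability_loglik(l, X, beta_b0, beta_b, rho, tau2, tau2_1)
        assert ll == pytest.approx(oracle, abs=1e-12)

    def test_collection_at_conditional_means(self, rng):
        n, T, M = 2, 3, 4
        l = rng.normal(size=(n, T))
        X = rng.normal(size=(n, T, M, 1))
        v = l[:, :, None] + X[..., 0] * 0.4
        ll = collection_loglik(v, l, X, [0.4], 1.0)
        assert ll == pytest.approx(-(n * T * M / 2) * np.log(2 * np.pi),
                                   abs=1e-10)

    def test_collection_beta_zero_ignores_covariates(self, rng):
        l = rng.normal(size=(2, 2))
        v = rng.normal(size=(2, 2, 3))
        X1 = rng.normal(size=(2, 2, 3, 1))
        X2 = rng.normal(size=(2, 2, 3, 1))
        assert collection_loglik(v, l, X1, [0.0], 1.5) == \
            collection_loglik(v, l, X2, [0.0], 1.5)

    def test_collection_flat_loop_oracle(self, rng):
        n, T, M = 2, 2, 3
        l = rng.normal(size=(n, T))
        X = rng.normal(size=(n, T, M, 2))
        v = rng.normal(size=(n, T, M))
        beta_w = np.array([1.0, -0.5])
        oracle = 0.0
        for i in range(n):
            for t in range(T):
                for m in range(M):
                    oracle += stats.norm.logpdf(
                        v[i, t, m], l[i, t] + X[i, t, m] @ beta_w,
                        np.sqrt(0.8))
        assert collection_loglik(v, l, X, beta_w, 0.8) == \
            pytest.approx(oracle, abs=1e-12)

    def test_hierarchy_zero_scores(self):
        ll = hierarchy_loglik([1.0, 1.0], 1.0, 2.0, [44.0], [-1.7], 44.0,
                              -1.7, 0.5)
        oracle = 2 * stats.norm.logpdf(0.0, 0.0, np.sqrt(2.0)) \
            + 2 * stats.norm.logpdf(0.0, 0.0, np.sqrt(0.5))
        assert ll == pytest.approx(oracle, abs=1e-12)

    def test_hierarchy_hand_computation(self, rng):
        rho, rho0, s2r = [0.7], 1.0, 0.3
        a1, a2, a10, a20, s2a = [43.0], [-1.6], 44.0, -1.7, 0.2
        oracle = (stats.norm.logpdf(0.7, 1.0, np.sqrt(0.3))
                  + stats.norm.logpdf(43.0, 44.0, np.sqrt(0.2))
                  + stats.norm.logpdf(-1.6, -1.7, np.sqrt(0.2)))
        assert hierarchy_loglik(rho, rho0, s2r, a1, a2, a10, a20, s2a) == \
            pytest.approx(oracle, abs=1e-12)

    def test_nonpositive_variance_raises(self):
        with pytest.raises(ValueError):
            hierarchy_loglik([1.0], 1.0, 0.0, [44.0], [-1.7], 44.0, -1.7,
                             0.1)


class TestVariants:

    def test_const_var_matches_full_at_reference_w(self):
        # homoscedastic limit: a2 = 0 and sigma2_P = exp(a1)
        w0, ct = 123.0, 25.0
        full = replicate_marginal_loglik(ct, w0, 0.05, 0.1, 44.0, -1.7,
                                         0.3, 0.0, SIGMA_C, CT_MAX,
                                         variant=FULL)
        const = replicate_marginal_loglik(ct, w0, 0.05, 0.1, 44.0, -1.7,
                                          0.0, 0.0, SIGMA_C, CT_MAX,
                                          variant=CONST_VAR,
                                          sigma2_P=np.exp(0.3))
        assert const == pytest.approx(full, abs=1e-12)

    def test_no_mixture_equals_full_with_zero_probs(self):
        for ct in (18.0, None):
            nm = replicate_marginal_loglik(ct, 80.0, 0.0, 0.0, 44.0, -1.7,
                                           0.2, -0.25, SIGMA_C, CT_MAX,
                                           variant=NO_MIXTURE)
            fu = replicate_marginal_loglik(ct, 80.0, 0.0, 0.0, 44.0, -1.7,
                                           0.2, -0.25, SIGMA_C, CT_MAX,
                                           variant=FULL)
            assert nm == pytest.approx(fu, abs=1e-12)

    def test_no_mixture_rejects_nonzero_gamma(self):
        with pytest.raises(ValueError):
            replicate_component_loglik(10.0, 100.0, 1, 44.0, -1.7, 0.2,
                                       -0.25, SIGMA_C, CT_MAX,
                                       variant=NO_MIXTURE)


def _tiny_dataset(rng):
    """n=1, T=1, M=1, K=1 plus one standard."""
    design = SurveyDesign.rectangular(1, 1, 1, 1, ct_max=CT_MAX)
    cov = CovariateSet(rng.normal(size=(1, 1, 1)),
                       rng.normal(size=(1, 1, 1, 1)))
    obs = [CTObservation(0, 0, 0, 0, 0, ct=28.0)]
    std = StandardsSet(plate=[0], concentration=[3e3], ct=[30.5],
                       censored=[False])
    return SurveyDataset(design, cov, obs, std)


class TestJointLogPosterior:

    def _params(self, **over):
        base = dict(beta_b0=6.0, beta_b=[1.0], beta_w=[-1.0], rho=[1.0],
                    rho0=1.0, sigma2_rho=0.1, tau2=1.0, tau2_1=1.0,
                    sigma2=1.0, alpha1=[44.0], alpha2=[-1.7],
                    alpha1_0=44.0, alpha2_0=-1.7, sigma2_alpha=0.1,
                    a1=0.2, a2=-0.25, p_c=0.05, p_h=0.1, sigma_c=SIGMA_C,
                    ct_max=CT_MAX)
        base.update(over)
        return ModelParameters(**base)

    def test_constraint_violation_gives_neg_inf(self, rng):
        ds = _tiny_dataset(rng)
        latent = LatentState(np.zeros((1, 1)), np.full((1, 1, 1), 2.0),
                             np.zeros((1, 1, 1, 1), dtype=int))
        lp = joint_log_posterior(self._params(p_c=0.3, p_h=0.3), latent,
                                 ds, PriorSpec())
        assert lp == -np.inf

    def test_tiny_instance_matches_enumerated_oracle(self, rng):
        ds = _tiny_dataset(rng)
        params = self._params()
        latent = LatentState(np.array([[5.0]]), np.full((1, 1, 1), 4.5),
                             np.zeros((1, 1, 1, 1), dtype=int))
        priors = PriorSpec()

        # independent oracle: sum each named density by hand
        Xb = ds.covariates.site
        Xw = ds.covariates.sample
        oracle = log_prior(params, priors)
        oracle += stats.norm.logpdf(
            5.0, 6.0 + Xb[0, 0, 0] * 1.0, 1.0)          # availability t=1
        oracle += stats.norm.logpdf(
            4.5, 5.0 + Xw[0, 0, 0, 0] * -1.0, 1.0)      # collection
        oracle += stats.norm.logpdf(1.0, 1.0, np.sqrt(0.1))     # rho_i
        oracle += stats.norm.logpdf(44.0, 44.0, np.sqrt(0.1))   # alpha1_p
        oracle += stats.norm.logpdf(-1.7, -1.7, np.sqrt(0.1))   # alpha2_p
        for ct, w in ((28.0, np.exp(4.5)), (30.5, 3e3)):
            mu = 44.0 - 1.7 * np.log(w)
            sy = np.sqrt(np.exp(0.2 - 0.25 * np.log(w)))
            clean = stats.norm.pdf(ct, mu, sy)
            Zc, _ = integrate.quad(
                lambda x: stats.norm.pdf(x, mu, SIGMA_C), 0, mu)
            contam = stats.norm.pdf(ct, mu, SIGMA_C) / Zc \
                if 0 < ct < mu else 0.0
            inhib = stats.norm.pdf(ct, mu, SIGMA_C) / 0.5 if ct >= mu \
                else 0.0
            oracle += np.log(0.85 * clean + 0.05 * contam + 0.1 * inhib)

        lp = joint_log_posterior(params, latent, ds, priors)
        assert lp == pytest.approx(oracle, abs=1e-10)

    def test_standards_add_terms(self, rng):
        ds = _tiny_dataset(rng)
        params = self._params()
        latent = LatentState(np.array([[5.0]]), np.full((1, 1, 1), 4.5),
                             np.zeros((1, 1, 1, 1), dtype=int))
        lp_with = joint_log_posterior(params, latent, ds, PriorSpec())
        ds_no_std = SurveyDataset(
            ds.design, ds.covariates, ds.observations,
            StandardsSet(plate=np.empty(0, int), concentration=np.empty(0),
                         ct=np.empty(0), censored=np.empty(0, bool)))
        lp_without = joint_log_posterior(params, latent, ds_no_std,
                                         PriorSpec())
        assert lp_with != lp_without


class TestPriors:

    def test_yaml_round_trip(self, tmp_path):
        spec = PriorSpec(coef_sd=3.0, sd_scale=2.5)
        path = tmp_path / "priors.yaml"
        spec.to_yaml(path)
        assert PriorSpec.from_yaml(path) == spec

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "priors.yaml"
        path.write_text("bogus: 1\n")
        with pytest.raises(ValueError, match="unknown prior keys"):
            PriorSpec.from_yaml(path)
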