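"""Densities of the hierarchical CT model.

The observation model for a replicate with sample concentration ``w``:

* clean (``gamma = 0``): ``CT ~ N(mu(w), sigma2_y(w))`` with
  ``mu(w) = alpha1_p + alpha2_p * log(w)`` and
  ``log sigma2_y(w) = a1 + a2 * log(w)`` (log-linear variance);
* contaminated (``gamma = 1``): ``CT ~ TN_(0, mu)(mu, sigma_c^2)`` —
  a normal truncated to lie below its own mean (faster amplification);
* inhibited (``gamma = 2``): ``CT ~ TN_(mu, inf)(mu, sigma_c^2)``.

CT values at or above ``ct_max`` are right-censored; censored cells
contribute the (renormalised) mass each component places on
``[ct_max, inf)``.  All logs are natural.  Everything here is vectorised
over replicates and computed in log space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml
from scipy.special import log_ndtr, logsumexp, ndtr

from .domain_model import (LatentState, ModelParameters, SurveyDataset)

__all__ = [
    "FULL", "CONST_VAR", "NO_MIXTURE", "ModelVariant", "PriorSpec",
    "ct_mean", "ct_variance", "component_logliks", "loglik_clean",
    "loglik_contaminated", "loglik_inhibited",
    "replicate_component_loglik", "replicate_marginal_loglik",
    "availability_loglik", "collection_loglik", "hierarchy_loglik",
    "log_prior", "joint_log_posterior",
]

_LOG_2PI = float(np.log(2.0 * np.pi))
_NEG_INF = -np.inf


@dataclass(frozen=True)
class ModelVariant:
    """Which observation model to fit.

    ``FULL`` is the complete model; ``CONST_VAR`` replaces the log-linear
    CT variance by a single constant ``sigma2_P``; ``NO_MIXTURE`` fixes
    ``p_c = p_h = 0`` (no contamination/inhibition components).
    """

    tag: str = "full"

    def __post_init__(self) -> None:
        if self.tag not in ("full", "const_var", "no_mixture"):
            raise ValueError(f"unknown model variant {self.tag!r}")

    @property
    def constant_ct_variance(self) -> bool:
        return self.tag == "const_var"

    @property
    def mixture(self) -> bool:
        return self.tag != "no_mixture"


FULL = ModelVariant("full")
CONST_VAR = ModelVariant("const_var")
NO_MIXTURE = ModelVariant("no_mixture")


def ct_mean(w, alpha1_p, alpha2_p):
    """Expected CT at concentration ``w``: ``alpha1_p + alpha2_p * ln(w)``."""
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ValueError("concentration w must be > 0")
    return alpha1_p + alpha2_p * np.log(w)


def ct_variance(w, a1, a2):
    """CT variance at concentration ``w``: ``exp(a1 + a2 * ln(w))``."""
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ValueError("concentration w must be > 0")
    return np.exp(a1 + a2 * np.log(w))


def _norm_logpdf(x, mu, sd):
    z = (x - mu) / sd
    return -0.5 * z * z - np.log(sd) - 0.5 * _LOG_2PI


def _log_diff_ndtr(hi, lo):
    """log(Phi(hi) - Phi(lo)) for hi > lo, elementwise, guarded."""
    val = ndtr(hi) - ndtr(lo)
    with np.errstate(divide="ignore"):
        return np.log(np.maximum(val, 0.0))


def _prepare(ct, censored, w, ct_max):
    ct = np.asarray(ct, dtype=float)
    censored = np.asarray(censored, dtype=bool)
    w = np.asarray(w, dtype=float)
    obs = ~censored
    ct_safe = np.where(obs, ct, 0.0)
    if np.any(obs & (ct_safe >= ct_max)):
        raise ValueError("observed CT must be < ct_max (else CENSORED)")
    return ct_safe, obs, w


def loglik_clean(ct, censored, w, alpha1_p, alpha2_p, a1, a2, ct_max,
                 sigma2_P=None):
    """Clean-component (gamma = 0) log-likelihood: plain normal with the
    log-linear variance (or the constant ``sigma2_P``); censored cells
    contribute the upper-tail mass beyond ``ct_max``."""
    ct_safe, obs, w = _prepare(ct, censored, w, ct_max)
    mu = ct_mean(w, alpha1_p, alpha2_p)
    if sigma2_P is not None:
        sd_y = np.broadcast_to(np.sqrt(sigma2_P), mu.shape)
    else:
        sd_y = np.exp(0.5 * (a1 + a2 * np.log(w)))
    z = (ct_safe - mu) / sd_y
    return np.where(obs,
                    -0.5 * z * z - np.log(sd_y) - 0.5 * _LOG_2PI,
                    log_ndtr(-(ct_max - mu) / sd_y))


def loglik_contaminated(ct, censored, w, alpha1_p, alpha2_p, sigma_c,
                        ct_max):
    """Contaminated-component (gamma = 1) log-likelihood:
    ``TN_(0, mu)(mu, sigma_c^2)``; empty support (-inf) if ``mu <= 0``."""
    ct_safe, obs, w = _prepare(ct, censored, w, ct_max)
    mu = ct_mean(w, alpha1_p, alpha2_p)
    with np.errstate(invalid="ignore"):   # mu <= 0 rows are masked below
        logZ1 = _log_diff_ndtr(np.zeros_like(mu), -mu / sigma_c)
        in_support = (ct_safe > 0) & (ct_safe < mu)
        L_obs = np.where(in_support,
                         _norm_logpdf(ct_safe, mu, sigma_c) - logZ1,
                         _NEG_INF)
        # censored: mass of (ct_max, mu) when mu > ct_max, else zero mass
        L_cens = np.where(
            mu > ct_max,
            _log_diff_ndtr(np.zeros_like(mu), (ct_max - mu) / sigma_c)
            - logZ1,
            _NEG_INF)
    out = np.where(obs, L_obs, L_cens)
    return np.where(mu > 0, out, _NEG_INF)


def loglik_inhibited(ct, censored, w, alpha1_p, alpha2_p, sigma_c, ct_max):
    """Inhibited-component (gamma = 2) log-likelihood:
    ``TN_(mu, inf)(mu, sigma_c^2)`` (normaliser 1/2)."""
    ct_safe, obs, w = _prepare(ct, censored, w, ct_max)
    mu = ct_mean(w, alpha1_p, alpha2_p)
    L_obs = np.where(ct_safe >= mu,
                     _norm_logpdf(ct_safe, mu, sigma_c) + np.log(2.0),
                     _NEG_INF)
    # censored: the whole support lies beyond ct_max when mu >= ct_max
    L_cens = np.where(mu >= ct_max, 0.0,
                      log_ndtr(-(ct_max - mu) / sigma_c) + np.log(2.0))
    return np.where(obs, L_obs, L_cens)


def component_logliks(ct, censored, w, alpha1_p, alpha2_p, a1, a2,
                      sigma_c, ct_max, sigma2_P=None):
    """Log-likelihood of each mixture component, vectorised.

    Parameters are broadcastable arrays over replicates; ``ct`` may hold
    NaN where ``censored`` is True.  Returns ``(L0, L1, L2)`` — the
    log-density (or log censoring mass) under the clean, contaminated and
    inhibited components.  Support violations yield ``-inf``.
    """
    L0 = loglik_clean(ct, censored, w, alpha1_p, alpha2_p, a1, a2, ct_max,
                      sigma2_P=sigma2_P)
    L1 = loglik_contaminated(ct, censored, w, alpha1_p, alpha2_p, sigma_c,
                             ct_max)
    L2 = loglik_inhibited(ct, censored, w, alpha1_p, alpha2_p, sigma_c,
                          ct_max)
    return L0, L1, L2


def replicate_component_loglik(ct, w, gamma, alpha1_p, alpha2_p, a1, a2,
                               sigma_c, ct_max,
                               variant: ModelVariant = FULL,
                               sigma2_P: Optional[float] = None) -> float:
    """Scalar log-density of one replicate under a fixed ``gamma``.

    ``ct is None`` denotes a censored replicate, in which case the log of
    the component's renormalised mass on ``[ct_max, inf)`` is returned.
    """
    if not variant.mixture and gamma != 0:
        raise ValueError("no_mixture variant only permits gamma = 0")
    censored = ct is None
    ct_val = np.nan if censored else float(ct)
    s2P = sigma2_P if variant.constant_ct_variance else None
    L0, L1, L2 = component_logliks(
        np.array([ct_val]), np.array([censored]), np.array([float(w)]),
        alpha1_p, alpha2_p, a1, a2, sigma_c, ct_max, sigma2_P=s2P)
    return float((L0, L1, L2)[gamma][0])


def replicate_marginal_loglik(ct, w, p_c, p_h, alpha1_p, alpha2_p, a1, a2,
                              sigma_c, ct_max,
                              variant: ModelVariant = FULL,
                              sigma2_P: Optional[float] = None) -> float:
    """Scalar log-density of one replicate with ``gamma`` marginalised out."""
    if p_c < 0 or p_h < 0 or p_c + p_h >= 0.5:
        raise ValueError("require p_c, p_h >= 0 and p_c + p_h < 0.5")
    censored = ct is None
    ct_val = np.nan if censored else float(ct)
    s2P = sigma2_P if variant.constant_ct_variance else None
    L0, L1, L2 = component_logliks(
        np.array([ct_val]), np.array([censored]), np.array([float(w)]),
        alpha1_p, alpha2_p, a1, a2, sigma_c, ct_max, sigma2_P=s2P)
    if not variant.mixture:
        return float(L0[0])
    return float(mixture_marginal(L0, L1, L2, p_c, p_h)[0])


def mixture_marginal(L0, L1, L2, p_c, p_h):
    """Stable log of ``(1-p_c-p_h) e^L0 + p_c e^L1 + p_h e^L2``."""
    with np.errstate(divide="ignore"):
        logw = np.log(np.array([1.0 - p_c - p_h, p_c, p_h]))
    stacked = np.stack([L0 + logw[0], L1 + logw[1], L2 + logw[2]])
    return logsumexp(stacked, axis=0)


def availability_loglik(l, X_b, beta_b0, beta_b, rho, tau2, tau2_1) -> float:
    """Log-density of the site availability process.

    ``l[i, 0] ~ N(beta_b0 + X_b[i, 0] @ beta_b, tau2_1)`` and for ``t > 0``
    ``l[i, t] ~ N(rho_i (l[i, t-1] - X_b[i, t-1] @ beta_b)
    + X_b[i, t] @ beta_b, tau2)``.
    """
    if tau2 <= 0 or tau2_1 <= 0:
        raise ValueError("tau2 and tau2_1 must be > 0")
    l = np.asarray(l, dtype=float)
    X_b = np.asarray(X_b, dtype=float)
    rho = np.atleast_1d(np.asarray(rho, dtype=float))
    d = X_b @ np.atleast_1d(beta_b)            # (n, T) covariate effect
    out = float(np.sum(_norm_logpdf(l[:, 0], beta_b0 + d[:, 0],
                                    np.sqrt(tau2_1))))
    if l.shape[1] > 1:
        mean = rho[:, None] * (l[:, :-1] - d[:, :-1]) + d[:, 1:]
        out += float(np.sum(_norm_logpdf(l[:, 1:], mean, np.sqrt(tau2))))
    return out


def collection_loglik(v, l, X_w, beta_w, sigma2,
                      sample_mask=None) -> float:
    """Log-density of sample log-DNA: ``v ~ N(l + X_w @ beta_w, sigma2)``.

    ``v`` has shape ``(n, T, max_M)``; ``sample_mask`` selects the cells
    that correspond to real samples (all, if omitted).
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    v = np.asarray(v, dtype=float)
    mean = np.asarray(l, dtype=float)[:, :, None] \
        + np.asarray(X_w, dtype=float) @ np.atleast_1d(beta_w)
    ll = _norm_logpdf(v, mean, np.sqrt(sigma2))
    if sample_mask is not None:
        ll = ll[np.asarray(sample_mask, dtype=bool)]
    return float(np.sum(ll))


def hierarchy_loglik(rho, rho0, sigma2_rho, alpha1, alpha2,
                     alpha1_0, alpha2_0, sigma2_alpha) -> float:
    """Log-density of the site-AR and plate-coefficient hierarchies.

    Intercepts and slopes share the single variance ``sigma2_alpha``.
    """
    if sigma2_rho <= 0 or sigma2_alpha <= 0:
        raise ValueError("hierarchy variances must be > 0")
    out = float(np.sum(_norm_logpdf(np.asarray(rho, dtype=float), rho0,
                                    np.sqrt(sigma2_rho))))
    sd_a = np.sqrt(sigma2_alpha)
    out += float(np.sum(_norm_logpdf(np.asarray(alpha1, dtype=float),
                                     alpha1_0, sd_a)))
    out += float(np.sum(_norm_logpdf(np.asarray(alpha2, dtype=float),
                                     alpha2_0, sd_a)))
    return out


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------

@dataclass
class PriorSpec:
    """Weakly-informative default priors; every field user-overridable.

    Regression coefficients and ``beta_b0`` get N(0, coef_sd^2); the plate
    hierarchy means get the stated normals; every standard deviation
    (tau, tau_1, sigma, sigma_rho, sigma_alpha, sigma_P) gets
    half-N(0, sd_scale^2); (p_c, p_h) is uniform on the constrained
    simplex ``{p_c, p_h >= 0, p_c + p_h < 0.5}``.
    """

    coef_sd: float = 10.0
    beta_b0_sd: float = 10.0
    rho0_sd: float = 10.0
    alpha1_0_mean: float = 40.0
    alpha1_0_sd: float = 10.0
    alpha2_0_mean: float = 0.0
    alpha2_0_sd: float = 10.0
    a_sd: float = 10.0
    sd_scale: float = 5.0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh)

    @staticmethod
    def from_yaml(path) -> "PriorSpec":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(PriorSpec().__dict__)
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown prior keys: {sorted(bad)}")
        return PriorSpec(**data)


def _half_normal_logpdf(sd, scale):
    if sd <= 0:
        return _NEG_INF
    return (0.5 * np.log(2.0 / np.pi) - np.log(scale)
            - 0.5 * (sd / scale) ** 2)


def log_prior(params: ModelParameters, priors: PriorSpec,
              variant: ModelVariant = FULL) -> float:
    """Joint log-prior over the top-level parameters.

    Returns ``-inf`` outside the support (including the p_c + p_h
    constraint).
    """
    if not params.probability_constraint_ok():
        return _NEG_INF
    p = params
    out = 0.0
    out += _norm_logpdf(p.beta_b0, 0.0, priors.beta_b0_sd)
    out += float(np.sum(_norm_logpdf(p.beta_b, 0.0, priors.coef_sd)))
    out += float(np.sum(_norm_logpdf(p.beta_w, 0.0, priors.coef_sd)))
    out += _norm_logpdf(p.rho0, 0.0, priors.rho0_sd)
    out += _norm_logpdf(p.alpha1_0, priors.alpha1_0_mean, priors.alpha1_0_sd)
    out += _norm_logpdf(p.alpha2_0, priors.alpha2_0_mean, priors.alpha2_0_sd)
    for s2 in (p.sigma2_rho, p.tau2, p.tau2_1, p.sigma2, p.sigma2_alpha):
        out += _half_normal_logpdf(np.sqrt(s2), priors.sd_scale)
    if variant.constant_ct_variance:
        if p.sigma2_P is None:
            return _NEG_INF
        out += _half_normal_logpdf(np.sqrt(p.sigma2_P), priors.sd_scale)
    else:
        out += _norm_logpdf(p.a1, 0.0, priors.a_sd)
        out += _norm_logpdf(p.a2, 0.0, priors.a_sd)
    # (p_c, p_h) uniform on the constrained simplex: constant, omitted.
    return float(out)


def joint_log_posterior(params: ModelParameters, latent: LatentState,
                        dataset: SurveyDataset, priors: PriorSpec,
                        variant: ModelVariant = FULL,
                        marginalize_gamma: bool = True) -> float:
    """Unnormalised log-posterior of the full model on a dataset.

    Sums availability, collection and hierarchy log-densities, the CT
    likelihood of every environmental replicate and every standard
    (standards use their known concentration), and the log-prior.  With
    ``marginalize_gamma`` the replicate mixture is marginalised; otherwise
    the likelihood conditions on ``latent.gamma`` and adds the categorical
    prior mass of each indicator.
    """
    lp = log_prior(params, priors, variant)
    if not np.isfinite(lp):
        return _NEG_INF
    p = params
    d = dataset.design
    cov = dataset.covariates

    out = lp
    out += availability_loglik(latent.l, cov.site, p.beta_b0, p.beta_b,
                               p.rho, p.tau2, p.tau2_1)
    mask = np.zeros((d.n_sites, d.n_times, d.max_samples), dtype=bool)
    for i in range(d.n_sites):
        for t in range(d.n_times):
            mask[i, t, :d.samples_per_occasion[i, t]] = True
    out += collection_loglik(latent.v, latent.l, cov.sample, p.beta_w,
                             p.sigma2, sample_mask=mask)
    out += hierarchy_loglik(p.rho, p.rho0, p.sigma2_rho, p.alpha1, p.alpha2,
                            p.alpha1_0, p.alpha2_0, p.sigma2_alpha)

    s2P = p.sigma2_P if variant.constant_ct_variance else None
    # environmental replicates
    ct_list, cens_list, w_list, a1p, a2p, g_list = [], [], [], [], [], []
    for o in dataset.observations:
        ct_list.append(np.nan if o.is_censored else o.ct)
        cens_list.append(o.is_censored)
        w_list.append(np.exp(latent.v[o.site, o.time, o.sample]))
        a1p.append(p.alpha1[o.plate])
        a2p.append(p.alpha2[o.plate])
        g_list.append(latent.gamma[o.site, o.time, o.sample, o.replicate])
    # standards: known concentration
    s = dataset.standards
    ct_all = np.concatenate([np.asarray(ct_list, dtype=float), s.ct])
    cens_all = np.concatenate([np.asarray(cens_list, dtype=bool),
                               s.censored])
    w_all = np.concatenate([np.asarray(w_list, dtype=float),
                            s.concentration])
    a1p_all = np.concatenate([np.asarray(a1p), p.alpha1[s.plate]])
    a2p_all = np.concatenate([np.asarray(a2p), p.alpha2[s.plate]])

    L0, L1, L2 = component_logliks(ct_all, cens_all, w_all, a1p_all,
                                   a2p_all, p.a1, p.a2, p.sigma_c,
                                   p.ct_max, sigma2_P=s2P)
    if not variant.mixture:
        out += float(np.sum(L0))
    elif marginalize_gamma:
        out += float(np.sum(mixture_marginal(L0, L1, L2, p.p_c, p.p_h)))
    else:
        # condition on the environmental indicators; standards (whose
        # indicators are not part of LatentState) stay marginalised
        n_env = len(g_list)
        g_env = np.asarray(g_list, dtype=int)
        comp = np.stack([L0[:n_env], L1[:n_env], L2[:n_env]])
        with np.errstate(divide="ignore"):
            logw = np.log(np.array([1.0 - p.p_c - p.p_h, p.p_c, p.p_h]))
        idx = np.arange(n_env)
        out += float(np.sum(comp[g_env, idx] + logw[g_env]))
        out += float(np.sum(mixture_marginal(L0[n_env:], L1[n_env:],
                                             L2[n_env:], p.p_c, p.p_h)))
    return float(out)
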