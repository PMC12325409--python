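"""MCMC engine for the hierarchical CT model.

Sampler architecture (Metropolis-within-Gibbs):

* ``l`` — exact Gibbs: the availability/collection stages are jointly
  Gaussian in ``l`` given everything else;
* ``beta_b0/beta_b``, ``beta_w``, ``rho_i``, ``rho0``, ``alpha1_0``,
  ``alpha2_0`` — conjugate normal draws;
* ``v`` — per-sample random-walk Metropolis (the CT likelihood is
  non-Gaussian in ``v``), vectorised across samples;
* ``gamma`` — exact categorical Gibbs from its full conditional;
* ``(p_c, p_h)`` — joint random-walk Metropolis; proposals violating
  ``p_c + p_h < 0.5`` (or non-positivity) are rejected outright, both
  components together;
* plate coefficients ``alpha1_p``/``alpha2_p`` — per-plate random-walk
  Metropolis, vectorised across plates;
* standard deviations and ``(a1, a2)`` (or ``sigma2_P``) — random-walk
  Metropolis on the log scale.

Step sizes are tuned toward 0.44 acceptance by Robbins-Monro recursion
during burn-in only, so post-burn-in chains are Markov.  Censored
replicates enter through their censoring mass; no latent CT above
``ct_max`` is imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .domain_model import (LatentState, ModelParameters, SurveyDataset)
from .likelihood import (FULL, ModelVariant, PriorSpec, component_logliks,
                         ct_mean, loglik_clean, loglik_contaminated,
                         loglik_inhibited)

__all__ = ["MCMCConfig", "PosteriorDraws", "FlatData", "flatten_dataset",
           "initialize_state", "update_gamma", "propose_probabilities",
           "fit", "posterior_predict_ct"]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class MCMCConfig:
    """Chain layout.  Defaults suit case-scale data; tests scale down."""

    n_chains: int = 3
    n_iterations: int = 50_000
    n_burnin: int = 25_000
    thinning: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.n_iterations > self.n_burnin >= 0):
            raise ValueError("need n_iterations > n_burnin >= 0")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")

    @staticmethod
    def test_preset(seed: int = 0, n_chains: int = 1,
                    n_iterations: int = 1500, n_burnin: int = 750,
                    thinning: int = 1) -> "MCMCConfig":
        return MCMCConfig(n_chains=n_chains, n_iterations=n_iterations,
                          n_burnin=n_burnin, thinning=thinning, seed=seed)


@dataclass
class FlatData:
    """Dataset reshaped into flat replicate/sample tables for the sampler."""

    n: int
    T: int
    P: int
    ct_max: float
    Xb: np.ndarray                    # (n, T, qb)
    M: np.ndarray                     # (n, T)
    samp_site: np.ndarray             # (S,)
    samp_time: np.ndarray             # (S,)
    samp_m: np.ndarray                # (S,)
    samp_occ: np.ndarray              # (S,) site*T + time
    Xw: np.ndarray                    # (S, qw)
    rep_samp: np.ndarray              # (R,)
    rep_plate: np.ndarray             # (R,)
    rep_ct: np.ndarray                # (R,), NaN on censored
    rep_cens: np.ndarray              # (R,)
    std_plate: np.ndarray             # (S*,)
    std_w: np.ndarray                 # (S*,)
    std_ct: np.ndarray                # (S*,)
    std_cens: np.ndarray              # (S*,)

    @property
    def n_samples(self) -> int:
        return self.samp_site.size

    @property
    def n_replicates(self) -> int:
        return self.rep_samp.size


def flatten_dataset(dataset: SurveyDataset) -> FlatData:
    d = dataset.design
    n, T = d.n_sites, d.n_times
    samp_index = {}
    samp_site, samp_time, samp_m, Xw_rows = [], [], [], []
    for i in range(n):
        for t in range(T):
            for m in range(d.samples_per_occasion[i, t]):
                samp_index[(i, t, m)] = len(samp_site)
                samp_site.append(i)
                samp_time.append(t)
                samp_m.append(m)
                Xw_rows.append(dataset.covariates.sample[i, t, m, :])
    rep_samp, rep_plate, rep_ct, rep_cens = [], [], [], []
    for o in dataset.observations:
        rep_samp.append(samp_index[(o.site, o.time, o.sample)])
        rep_plate.append(o.plate)
        rep_ct.append(np.nan if o.is_censored else o.ct)
        rep_cens.append(o.is_censored)
    s = dataset.standards
    samp_site = np.asarray(samp_site, dtype=int)
    samp_time = np.asarray(samp_time, dtype=int)
    return FlatData(
        n=n, T=T, P=d.n_plates, ct_max=d.ct_max,
        Xb=np.asarray(dataset.covariates.site, dtype=float),
        M=d.samples_per_occasion,
        samp_site=samp_site, samp_time=samp_time,
        samp_m=np.asarray(samp_m, dtype=int),
        samp_occ=samp_site * T + samp_time,
        Xw=np.asarray(Xw_rows, dtype=float),
        rep_samp=np.asarray(rep_samp, dtype=int),
        rep_plate=np.asarray(rep_plate, dtype=int),
        rep_ct=np.asarray(rep_ct, dtype=float),
        rep_cens=np.asarray(rep_cens, dtype=bool),
        std_plate=s.plate.copy(), std_w=s.concentration.copy(),
        std_ct=s.ct.copy(), std_cens=s.censored.copy())


# ---------------------------------------------------------------------------
# Sampler state
# ---------------------------------------------------------------------------

@dataclass
class _State:
    params: ModelParameters
    l: np.ndarray          # (n, T)
    v: np.ndarray          # (S,)
    gamma_rep: np.ndarray  # (R,)
    gamma_std: np.ndarray  # (S*,)


def _ll_given_gamma(ct, cens, w, a1p, a2p, gamma, a1, a2, sigma_c, ct_max,
                    sigma2_P=None):
    """Per-replicate log-likelihood conditioned on its gamma.

    Computes each component only on the replicates that carry it (most
    are clean, so this is much cheaper than evaluating all three
    everywhere).
    """
    a1p = np.broadcast_to(a1p, np.shape(w))
    a2p = np.broadcast_to(a2p, np.shape(w))
    out = np.empty(np.shape(w), dtype=float)
    m0 = gamma == 0
    if m0.any():
        out[m0] = loglik_clean(ct[m0], cens[m0], w[m0], a1p[m0], a2p[m0],
                               a1, a2, ct_max, sigma2_P=sigma2_P)
    m1 = gamma == 1
    if m1.any():
        out[m1] = loglik_contaminated(ct[m1], cens[m1], w[m1], a1p[m1],
                                      a2p[m1], sigma_c, ct_max)
    m2 = gamma == 2
    if m2.any():
        out[m2] = loglik_inhibited(ct[m2], cens[m2], w[m2], a1p[m2],
                                   a2p[m2], sigma_c, ct_max)
    return out


def initialize_state(dataset: SurveyDataset, variant: ModelVariant,
                     rng: np.random.Generator,
                     flat: Optional[FlatData] = None,
                     ) -> tuple[ModelParameters, LatentState]:
    """Deterministic (given seed) data-driven initialisation.

    Plate coefficients come from per-plate OLS of CT on ln-concentration
    over that plate's uncensored standards (falling back to the pooled fit
    for plates with fewer than 2 distinct concentrations); ``v`` inverts
    the plate line at each sample's mean observed CT, with all-censored
    samples placed at the concentration whose expected CT equals
    ``ct_max``; ``l`` is the within-occasion mean of ``v``; ``gamma`` is
    all-clean and the probabilities start at (0.01, 0.01).
    """
    if flat is None:
        flat = flatten_dataset(dataset)
    P, n, T = flat.P, flat.n, flat.T
    logw = np.log(flat.std_w)

    # pooled standards line for fallback
    obs = ~flat.std_cens
    if obs.sum() >= 2 and np.unique(logw[obs]).size >= 2:
        pooled = np.polyfit(logw[obs], flat.std_ct[obs], 1)
        pooled_slope, pooled_int = pooled[0], pooled[1]
    else:
        pooled_slope, pooled_int = -1.7, 40.0
    alpha1 = np.full(P, pooled_int)
    alpha2 = np.full(P, pooled_slope)
    for p in range(P):
        sel = (flat.std_plate == p) & obs
        if sel.sum() >= 2 and np.unique(logw[sel]).size >= 2:
            coeff = np.polyfit(logw[sel], flat.std_ct[sel], 1)
            alpha2[p], alpha1[p] = coeff[0], coeff[1]
    alpha1_0 = float(alpha1.mean())
    alpha2_0 = float(alpha2.mean())
    sigma2_alpha = float(max(np.var(alpha1) if P > 1 else 0.1, 1e-2))

    # log-variance regression on squared standard residuals (Cook-Weisberg
    # style moment fit)
    resid = flat.std_ct[obs] - (alpha1[flat.std_plate[obs]]
                                + alpha2[flat.std_plate[obs]] * logw[obs])
    a1_init, a2_init = 0.0, 0.0
    if resid.size >= 4 and np.unique(logw[obs]).size >= 2:
        y = np.log(np.maximum(resid ** 2, 1e-8))
        coeff = np.polyfit(logw[obs], y, 1)
        # E[log chi2_1] = digamma(1/2) + log 2 ~ -1.27; correct the level
        a2_init = float(np.clip(coeff[0], -2.0, 1.0))
        a1_init = float(np.clip(coeff[1] + 1.27, -8.0, 8.0))
    sigma2_P_init = float(max(np.var(resid) if resid.size else 1.0, 1e-2))

    # v from mean observed CT per sample
    S = flat.n_samples
    v = np.empty(S)
    a1p = alpha1[flat.rep_plate]
    a2p = alpha2[flat.rep_plate]
    ct_filled = np.where(flat.rep_cens, 0.0, flat.rep_ct)
    num = np.bincount(flat.rep_samp, weights=ct_filled, minlength=S)
    cnt = np.bincount(flat.rep_samp, weights=(~flat.rep_cens).astype(float),
                      minlength=S)
    # per-sample plate coefficients (a sample sits on a single plate)
    samp_plate = np.zeros(S, dtype=int)
    samp_plate[flat.rep_samp] = flat.rep_plate
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_ct = np.where(cnt > 0, num / np.maximum(cnt, 1.0),
                           flat.ct_max)
    v = (mean_ct - alpha1[samp_plate]) / alpha2[samp_plate]

    l = np.zeros((n, T))
    occ_sum = np.bincount(flat.samp_occ, weights=v, minlength=n * T)
    occ_cnt = np.bincount(flat.samp_occ, minlength=n * T)
    l = (occ_sum / np.maximum(occ_cnt, 1)).reshape(n, T)

    # regression inits
    qb = flat.Xb.shape[-1]
    Xmat = np.concatenate(
        [np.ones((n * T, 1)), flat.Xb.reshape(n * T, qb)], axis=1)
    coef, *_ = np.linalg.lstsq(Xmat, l.reshape(-1), rcond=None)
    beta_b0 = float(coef[0])
    beta_b = coef[1:]
    qw = flat.Xw.shape[-1]
    rw = v - l[flat.samp_site, flat.samp_time]
    beta_w, *_ = np.linalg.lstsq(flat.Xw, rw, rcond=None)

    d = flat.Xb @ beta_b
    e = l - d
    rho = np.ones(n)
    if T >= 3:
        for i in range(n):
            denom = float(np.sum(e[i, :-1] ** 2))
            if denom > 1e-8:
                rho[i] = np.clip(np.sum(e[i, :-1] * e[i, 1:]) / denom,
                                 -2.0, 2.0)
    rho0 = float(rho.mean())
    sigma2_rho = float(max(np.var(rho) if n > 1 else 0.01, 1e-3))
    if T > 1:
        tau2 = float(max(np.var(e[:, 1:] - rho[:, None] * e[:, :-1]), 0.05))
    else:
        tau2 = 1.0
    tau2_1 = float(max(np.var(l[:, 0] - beta_b0 - d[:, 0]) if n > 1
                       else 1.0, 0.05))
    sigma2 = float(max(np.var(rw - flat.Xw @ beta_w), 0.05))

    p_c, p_h = (0.01, 0.01) if variant.mixture else (0.0, 0.0)
    params = ModelParameters(
        beta_b0=beta_b0, beta_b=beta_b, beta_w=beta_w, rho=rho, rho0=rho0,
        sigma2_rho=sigma2_rho, tau2=tau2, tau2_1=tau2_1, sigma2=sigma2,
        alpha1=alpha1, alpha2=alpha2, alpha1_0=alpha1_0, alpha2_0=alpha2_0,
        sigma2_alpha=sigma2_alpha, a1=a1_init, a2=a2_init, p_c=p_c, p_h=p_h,
        sigma_c=flat.ct_max, ct_max=flat.ct_max,
        sigma2_P=sigma2_P_init if variant.constant_ct_variance else None)

    d_design = dataset.design
    max_K = int(d_design.replicates_per_sample.max())
    gamma = np.zeros((n, T, d_design.max_samples, max_K), dtype=int)
    v_grid = np.zeros((n, T, d_design.max_samples))
    v_grid[flat.samp_site, flat.samp_time, flat.samp_m] = v
    latent = LatentState(l=l, v=v_grid, gamma=gamma)
    return params, latent


def _gamma_from_logliks(L0, L1, L2, p_c, p_h,
                        rng: np.random.Generator) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        logits = np.stack([L0 + np.log(1.0 - p_c - p_h),
                           L1 + (np.log(p_c) if p_c > 0 else -np.inf),
                           L2 + (np.log(p_h) if p_h > 0 else -np.inf)])
    logits[np.isnan(logits)] = -np.inf      # -inf + -inf guards
    gumbel = rng.gumbel(size=logits.shape)
    # -inf stays -inf after adding gumbel; all-(-inf) cannot occur since
    # L0 is finite and p_c + p_h < 1
    return np.argmax(np.where(np.isfinite(logits), logits + gumbel,
                              -np.inf), axis=0).astype(int)


def update_gamma(ct, cens, w, a1p, a2p, p_c, p_h, a1, a2, sigma_c, ct_max,
                 rng: np.random.Generator, sigma2_P=None) -> np.ndarray:
    """Draw each replicate's indicator from its categorical full
    conditional with weights proportional to
    ``{(1-p_c-p_h) e^L0, p_c e^L1, p_h e^L2}``."""
    L0, L1, L2 = component_logliks(ct, cens, w, a1p, a2p, a1, a2, sigma_c,
                                   ct_max, sigma2_P=sigma2_P)
    return _gamma_from_logliks(L0, L1, L2, p_c, p_h, rng)


def propose_probabilities(p_c: float, p_h: float, counts, rng,
                          step: float = 0.02) -> tuple[float, float, bool]:
    """Joint random-walk Metropolis move for ``(p_c, p_h)``.

    ``counts = (n0, n1, n2)`` are the current indicator tallies.  Any
    proposal with a non-positive component or ``p_c + p_h >= 0.5`` is
    rejected outright — both components together.  The prior is uniform on
    the constrained simplex, so the acceptance ratio is the multinomial
    likelihood ratio.
    """
    n0, n1, n2 = counts
    prop_c, prop_h = p_c + step * rng.standard_normal(), \
        p_h + step * rng.standard_normal()
    if prop_c <= 0 or prop_h <= 0 or prop_c + prop_h >= 0.5:
        return p_c, p_h, False
    cur = (n0 * np.log(1 - p_c - p_h) + n1 * np.log(p_c)
           + n2 * np.log(p_h))
    prop = (n0 * np.log(1 - prop_c - prop_h) + n1 * np.log(prop_c)
            + n2 * np.log(prop_h))
    if np.log(rng.random()) < prop - cur:
        return float(prop_c), float(prop_h), True
    return p_c, p_h, False


def _mh_log_sd(sd, ssr, n_terms, extra_loglik, step, rng, scale):
    """RW Metropolis on log(sd) for a Gaussian scale parameter.

    Likelihood ``-n log sd - ssr / (2 sd^2) + extra(sd)`` with half-normal
    prior on sd; the log-scale Jacobian contributes ``log sd``.
    """
    def logpost(s):
        return (-n_terms * np.log(s) - ssr / (2.0 * s * s)
                - 0.5 * (s / scale) ** 2 + np.log(s)
                + (extra_loglik(s) if extra_loglik else 0.0))

    prop = sd * np.exp(step * rng.standard_normal())
    if np.log(rng.random()) < logpost(prop) - logpost(sd):
        return float(prop), True
    return float(sd), False


def _conjugate_normal_regression(X, y, noise_var, prior_prec, rng):
    """Draw from N(mean, cov) with cov = (X'X/s2 + P0)^-1."""
    A = X.T @ X / noise_var + prior_prec
    b = X.T @ y / noise_var
    chol = np.linalg.cholesky(A)
    mean = np.linalg.solve(A, b)
    z = rng.standard_normal(mean.shape)
    return mean + np.linalg.solve(chol.T, z)


class _Steps:
    """Adaptive step sizes, tuned toward 0.44 acceptance during burn-in."""

    def __init__(self, S, P):
        self.v = np.full(S, 0.5)
        self.alpha1 = np.full(P, 0.1)
        self.alpha2 = np.full(P, 0.02)
        self.p = 0.02
        self.a = 0.05
        self.log_sd = {k: 0.3 for k in
                       ("sigma_rho", "tau", "tau1", "sigma", "sigma_alpha",
                        "sigma_P")}

    @staticmethod
    def _tune(step, acc, it):
        gain = 1.0 / (1.0 + it) ** 0.6
        return step * np.exp(gain * (np.asarray(acc, dtype=float) - 0.44))


def _run_chain(flat: FlatData, variant: ModelVariant, priors: PriorSpec,
               cfg: MCMCConfig, rng: np.random.Generator,
               init: tuple[ModelParameters, LatentState],
               ) -> dict[str, np.ndarray]:
    p0, lat0 = init
    n, T, P, S = flat.n, flat.T, flat.P, flat.n_samples
    params = replace(p0)  # shallow copy; arrays copied below
    params.beta_b = p0.beta_b.copy()
    params.beta_w = p0.beta_w.copy()
    params.rho = p0.rho.copy()
    params.alpha1 = p0.alpha1.copy()
    params.alpha2 = p0.alpha2.copy()
    l = lat0.l.copy()
    v = lat0.v[flat.samp_site, flat.samp_time, flat.samp_m].copy()
    gamma_rep = np.zeros(flat.n_replicates, dtype=int)
    gamma_std = np.zeros(flat.std_w.size, dtype=int)

    const_var = variant.constant_ct_variance
    s2P = params.sigma2_P if const_var else None
    sigma_c, ct_max = params.sigma_c, params.ct_max
    qb, qw = flat.Xb.shape[-1], flat.Xw.shape[-1]
    steps = _Steps(S, P)
    occ_cnt = np.bincount(flat.samp_occ, minlength=n * T).reshape(n, T)
    std_logw = np.log(flat.std_w)

    kept = (cfg.n_iterations - cfg.n_burnin) // cfg.thinning
    out = {
        "beta_b0": np.empty(kept), "beta_b": np.empty((kept, qb)),
        "beta_w": np.empty((kept, qw)), "rho": np.empty((kept, n)),
        "rho0": np.empty(kept), "sigma2_rho": np.empty(kept),
        "tau2": np.empty(kept), "tau2_1": np.empty(kept),
        "sigma2": np.empty(kept), "alpha1": np.empty((kept, P)),
        "alpha2": np.empty((kept, P)), "alpha1_0": np.empty(kept),
        "alpha2_0": np.empty(kept), "sigma2_alpha": np.empty(kept),
        "p_c": np.empty(kept), "p_h": np.empty(kept),
        "l": np.empty((kept, n, T)), "v": np.empty((kept, S)),
        "gamma": np.empty((kept, flat.n_replicates), dtype=np.uint8),
    }
    if const_var:
        out["sigma2_P"] = np.empty(kept)
    else:
        out["a1"] = np.empty(kept)
        out["a2"] = np.empty(kept)

    kidx = 0
    for it in range(cfg.n_iterations):
        adapt = it < cfg.n_burnin
        w_rep = np.exp(v[flat.rep_samp])
        a1p_rep = params.alpha1[flat.rep_plate]
        a2p_rep = params.alpha2[flat.rep_plate]
        a1p_std = params.alpha1[flat.std_plate]
        a2p_std = params.alpha2[flat.std_plate]

        # --- gamma and (p_c, p_h) -------------------------------------
        cur_ll_rep = None
        if variant.mixture:
            L0e, L1e, L2e = component_logliks(
                flat.rep_ct, flat.rep_cens, w_rep, a1p_rep, a2p_rep,
                params.a1, params.a2, sigma_c, ct_max, sigma2_P=s2P)
            gamma_rep = _gamma_from_logliks(L0e, L1e, L2e, params.p_c,
                                            params.p_h, rng)
            # the freshly drawn gamma selects the replicate's current
            # conditional log-likelihood; reused by the v update below
            comp = np.stack([L0e, L1e, L2e])
            cur_ll_rep = comp[gamma_rep, np.arange(gamma_rep.size)]
            gamma_std = update_gamma(
                flat.std_ct, flat.std_cens, flat.std_w, a1p_std, a2p_std,
                params.p_c, params.p_h, params.a1, params.a2, sigma_c,
                ct_max, rng, sigma2_P=s2P)
            g_all = np.concatenate([gamma_rep, gamma_std])
            counts = (int(np.sum(g_all == 0)), int(np.sum(g_all == 1)),
                      int(np.sum(g_all == 2)))
            pc, ph, acc_p = propose_probabilities(
                params.p_c, params.p_h, counts, rng, step=steps.p)
            params.p_c, params.p_h = pc, ph
            if adapt:
                steps.p = _Steps._tune(steps.p, acc_p, it)

        # --- v: per-sample RW Metropolis ------------------------------
        mean_v = (l[flat.samp_site, flat.samp_time]
                  + flat.Xw @ params.beta_w)
        sd_v = np.sqrt(params.sigma2)
        if cur_ll_rep is None:
            cur_ll_rep = _ll_given_gamma(
                flat.rep_ct, flat.rep_cens, w_rep, a1p_rep, a2p_rep,
                gamma_rep, params.a1, params.a2, sigma_c, ct_max,
                sigma2_P=s2P)
        v_prop = v + steps.v * rng.standard_normal(S)
        prop_ll_rep = _ll_given_gamma(
            flat.rep_ct, flat.rep_cens, np.exp(v_prop[flat.rep_samp]),
            a1p_rep, a2p_rep, gamma_rep, params.a1, params.a2, sigma_c,
            ct_max, sigma2_P=s2P)
        cur_by_samp = np.bincount(flat.rep_samp, weights=cur_ll_rep,
                                  minlength=S)
        prop_by_samp = np.bincount(flat.rep_samp, weights=prop_ll_rep,
                                   minlength=S)
        zc = (v - mean_v) / sd_v
        zp = (v_prop - mean_v) / sd_v
        log_ratio = (prop_by_samp - cur_by_samp
                     - 0.5 * zp * zp + 0.5 * zc * zc)
        acc_v = np.log(rng.random(S)) < log_ratio
        v = np.where(acc_v, v_prop, v)
        if adapt:
            steps.v = _Steps._tune(steps.v, acc_v, it)

        # --- l: exact Gibbs, sequential in t --------------------------
        d_cov = flat.Xb @ params.beta_b                # (n, T)
        resid_v = v - flat.Xw @ params.beta_w
        occ_sum = np.bincount(flat.samp_occ, weights=resid_v,
                              minlength=n * T).reshape(n, T)
        rho = params.rho
        for t in range(T):
            prec = occ_cnt[:, t] / params.sigma2
            pm = occ_sum[:, t] / params.sigma2
            if t == 0:
                prec = prec + 1.0 / params.tau2_1
                pm = pm + (params.beta_b0 + d_cov[:, 0]) / params.tau2_1
            else:
                prec = prec + 1.0 / params.tau2
                pm = pm + (rho * (l[:, t - 1] - d_cov[:, t - 1])
                           + d_cov[:, t]) / params.tau2
            if t < T - 1:
                prec = prec + rho * rho / params.tau2
                pm = pm + rho * (l[:, t + 1] - d_cov[:, t + 1]
                                 + rho * d_cov[:, t]) / params.tau2
            l[:, t] = pm / prec + rng.standard_normal(n) / np.sqrt(prec)

        # --- beta_w (conjugate) ---------------------------------------
        y_w = v - l[flat.samp_site, flat.samp_time]
        params.beta_w = _conjugate_normal_regression(
            flat.Xw, y_w, params.sigma2,
            np.eye(qw) / priors.coef_sd ** 2, rng)

        # --- (beta_b0, beta_b) jointly (conjugate) --------------------
        X1 = np.concatenate([np.ones((n, 1)), flat.Xb[:, 0, :]], axis=1) \
            / np.sqrt(params.tau2_1)
        y1 = l[:, 0] / np.sqrt(params.tau2_1)
        if T > 1:
            Xt = (flat.Xb[:, 1:, :]
                  - rho[:, None, None] * flat.Xb[:, :-1, :])
            Xt = np.concatenate(
                [np.zeros((n, T - 1, 1)), Xt], axis=2).reshape(-1, 1 + qb) \
                / np.sqrt(params.tau2)
            yt = (l[:, 1:] - rho[:, None] * l[:, :-1]).reshape(-1) \
                / np.sqrt(params.tau2)
            Xfull = np.concatenate([X1, Xt], axis=0)
            yfull = np.concatenate([y1, yt])
        else:
            Xfull, yfull = X1, y1
        prior_prec = np.diag(
            [1.0 / priors.beta_b0_sd ** 2]
            + [1.0 / priors.coef_sd ** 2] * qb)
        coef = _conjugate_normal_regression(Xfull, yfull, 1.0, prior_prec,
                                            rng)
        params.beta_b0 = float(coef[0])
        params.beta_b = coef[1:]

        # --- rho_i (conjugate, vectorised over sites) ------------------
        d_cov = flat.Xb @ params.beta_b
        e = l - d_cov
        if T > 1:
            prec_r = np.sum(e[:, :-1] ** 2, axis=1) / params.tau2 \
                + 1.0 / params.sigma2_rho
            pm_r = np.sum(e[:, :-1] * e[:, 1:], axis=1) / params.tau2 \
                + params.rho0 / params.sigma2_rho
            params.rho = pm_r / prec_r \
                + rng.standard_normal(n) / np.sqrt(prec_r)
        else:
            params.rho = params.rho0 + np.sqrt(params.sigma2_rho) \
                * rng.standard_normal(n)

        # --- rho0 (conjugate) and sigma_rho (MH) ----------------------
        prec0 = n / params.sigma2_rho + 1.0 / priors.rho0_sd ** 2
        pm0 = params.rho.sum() / params.sigma2_rho
        params.rho0 = float(pm0 / prec0
                            + rng.standard_normal() / np.sqrt(prec0))
        ssr_rho = float(np.sum((params.rho - params.rho0) ** 2))
        sd, acc = _mh_log_sd(np.sqrt(params.sigma2_rho), ssr_rho, n, None,
                             steps.log_sd["sigma_rho"], rng,
                             priors.sd_scale)
        params.sigma2_rho = sd * sd
        if adapt:
            steps.log_sd["sigma_rho"] = _Steps._tune(
                steps.log_sd["sigma_rho"], acc, it)

        # --- tau, tau1, sigma (MH on log sd) --------------------------
        rho = params.rho
        if T > 1:
            ssr_tau = float(np.sum(
                (e[:, 1:] - rho[:, None] * e[:, :-1]) ** 2))
            sd, acc = _mh_log_sd(np.sqrt(params.tau2), ssr_tau,
                                 n * (T - 1), None, steps.log_sd["tau"],
                                 rng, priors.sd_scale)
            params.tau2 = sd * sd
            if adapt:
                steps.log_sd["tau"] = _Steps._tune(
                    steps.log_sd["tau"], acc, it)
        ssr_t1 = float(np.sum((l[:, 0] - params.beta_b0 - d_cov[:, 0]) ** 2))
        sd, acc = _mh_log_sd(np.sqrt(params.tau2_1), ssr_t1, n, None,
                             steps.log_sd["tau1"], rng, priors.sd_scale)
        params.tau2_1 = sd * sd
        if adapt:
            steps.log_sd["tau1"] = _Steps._tune(
                steps.log_sd["tau1"], acc, it)
        ssr_s = float(np.sum(
            (v - l[flat.samp_site, flat.samp_time]
             - flat.Xw @ params.beta_w) ** 2))
        sd, acc = _mh_log_sd(np.sqrt(params.sigma2), ssr_s, S, None,
                             steps.log_sd["sigma"], rng, priors.sd_scale)
        params.sigma2 = sd * sd
        if adapt:
            steps.log_sd["sigma"] = _Steps._tune(
                steps.log_sd["sigma"], acc, it)

        # --- plate coefficients (per-plate RW, vectorised) -------------
        w_rep = np.exp(v[flat.rep_samp])
        ct_all = np.concatenate([flat.rep_ct, flat.std_ct])
        cens_all = np.concatenate([flat.rep_cens, flat.std_cens])
        w_all = np.concatenate([w_rep, flat.std_w])
        g_all = np.concatenate([gamma_rep, gamma_std])
        plate_all = np.concatenate([flat.rep_plate, flat.std_plate])
        a1_cur, a2_cur = params.alpha1, params.alpha2
        a1_prop = a1_cur + steps.alpha1 * rng.standard_normal(P)
        a2_prop = a2_cur + steps.alpha2 * rng.standard_normal(P)
        ll_cur = _ll_given_gamma(
            ct_all, cens_all, w_all, a1_cur[plate_all], a2_cur[plate_all],
            g_all, params.a1, params.a2, sigma_c, ct_max, sigma2_P=s2P)
        ll_prop = _ll_given_gamma(
            ct_all, cens_all, w_all, a1_prop[plate_all],
            a2_prop[plate_all], g_all, params.a1, params.a2, sigma_c,
            ct_max, sigma2_P=s2P)
        by_plate = (np.bincount(plate_all, weights=ll_prop, minlength=P)
                    - np.bincount(plate_all, weights=ll_cur, minlength=P))
        prior_diff = (
            -(a1_prop - params.alpha1_0) ** 2
            + (a1_cur - params.alpha1_0) ** 2
            - (a2_prop - params.alpha2_0) ** 2
            + (a2_cur - params.alpha2_0) ** 2) / (2.0 * params.sigma2_alpha)
        acc_a = np.log(rng.random(P)) < by_plate + prior_diff
        params.alpha1 = np.where(acc_a, a1_prop, a1_cur)
        params.alpha2 = np.where(acc_a, a2_prop, a2_cur)
        if adapt:
            steps.alpha1 = _Steps._tune(steps.alpha1, acc_a, it)
            steps.alpha2 = _Steps._tune(steps.alpha2, acc_a, it)

        # --- hierarchy means and sigma_alpha ---------------------------
        for vec, mean_attr, prior_mean, prior_sd in (
                (params.alpha1, "alpha1_0", priors.alpha1_0_mean,
                 priors.alpha1_0_sd),
                (params.alpha2, "alpha2_0", priors.alpha2_0_mean,
                 priors.alpha2_0_sd)):
            prec = P / params.sigma2_alpha + 1.0 / prior_sd ** 2
            pm = vec.sum() / params.sigma2_alpha + prior_mean / prior_sd ** 2
            setattr(params, mean_attr,
                    float(pm / prec
                          + rng.standard_normal() / np.sqrt(prec)))
        ssr_a = float(np.sum((params.alpha1 - params.alpha1_0) ** 2)
                      + np.sum((params.alpha2 - params.alpha2_0) ** 2))
        sd, acc = _mh_log_sd(np.sqrt(params.sigma2_alpha), ssr_a, 2 * P,
                             None, steps.log_sd["sigma_alpha"], rng,
                             priors.sd_scale)
        params.sigma2_alpha = sd * sd
        if adapt:
            steps.log_sd["sigma_alpha"] = _Steps._tune(
                steps.log_sd["sigma_alpha"], acc, it)

        # --- CT variance parameters ------------------------------------
        clean_mask = g_all == 0
        ct_c = ct_all[clean_mask]
        cens_c = cens_all[clean_mask]
        w_c = w_all[clean_mask]
        a1p_c = params.alpha1[plate_all[clean_mask]]
        a2p_c = params.alpha2[plate_all[clean_mask]]
        if const_var:
            def extra(sd_val):
                # whole likelihood lives here; ssr/n_terms passed as 0
                return float(np.sum(loglik_clean(
                    ct_c, cens_c, w_c, a1p_c, a2p_c, 0.0, 0.0, ct_max,
                    sigma2_P=sd_val * sd_val)))
            sd, acc = _mh_log_sd(np.sqrt(params.sigma2_P), 0.0, 0.0, extra,
                                 steps.log_sd["sigma_P"], rng,
                                 priors.sd_scale)
            params.sigma2_P = sd * sd
            s2P = params.sigma2_P
            if adapt:
                steps.log_sd["sigma_P"] = _Steps._tune(
                    steps.log_sd["sigma_P"], acc, it)
        else:
            a_prop = (params.a1 + steps.a * rng.standard_normal(),
                      params.a2 + 0.2 * steps.a * rng.standard_normal())
            L0_cur = loglik_clean(ct_c, cens_c, w_c, a1p_c, a2p_c,
                                  params.a1, params.a2, ct_max)
            L0_prop = loglik_clean(ct_c, cens_c, w_c, a1p_c, a2p_c,
                                   a_prop[0], a_prop[1], ct_max)
            lr = float(np.sum(L0_prop) - np.sum(L0_cur))
            lr += (-(a_prop[0] ** 2) + params.a1 ** 2) \
                / (2.0 * priors.a_sd ** 2)
            lr += (-(a_prop[1] ** 2) + params.a2 ** 2) \
                / (2.0 * priors.a_sd ** 2)
            acc = np.log(rng.random()) < lr
            if acc:
                params.a1, params.a2 = a_prop
            if adapt:
                steps.a = _Steps._tune(steps.a, acc, it)

        # --- record ----------------------------------------------------
        if it >= cfg.n_burnin and (it - cfg.n_burnin) % cfg.thinning == 0:
            out["beta_b0"][kidx] = params.beta_b0
            out["beta_b"][kidx] = params.beta_b
            out["beta_w"][kidx] = params.beta_w
            out["rho"][kidx] = params.rho
            out["rho0"][kidx] = params.rho0
            out["sigma2_rho"][kidx] = params.sigma2_rho
            out["tau2"][kidx] = params.tau2
            out["tau2_1"][kidx] = params.tau2_1
            out["sigma2"][kidx] = params.sigma2
            out["alpha1"][kidx] = params.alpha1
            out["alpha2"][kidx] = params.alpha2
            out["alpha1_0"][kidx] = params.alpha1_0
            out["alpha2_0"][kidx] = params.alpha2_0
            out["sigma2_alpha"][kidx] = params.sigma2_alpha
            out["p_c"][kidx] = params.p_c
            out["p_h"][kidx] = params.p_h
            if const_var:
                out["sigma2_P"][kidx] = params.sigma2_P
            else:
                out["a1"][kidx] = params.a1
                out["a2"][kidx] = params.a2
            out["l"][kidx] = l
            out["v"][kidx] = v
            out["gamma"][kidx] = gamma_rep
            kidx += 1
    return out


@dataclass
class PosteriorDraws:
    """Retained MCMC draws, stacked as ``(n_chains, n_kept, ...)``."""

    params: dict[str, np.ndarray]
    flat: FlatData
    variant: ModelVariant
    config: MCMCConfig

    def stacked(self, name: str) -> np.ndarray:
        """Draws of ``name`` pooled over chains: ``(chains*kept, ...)``."""
        arr = self.params[name]
        return arr.reshape((-1,) + arr.shape[2:])

    @property
    def n_draws(self) -> int:
        return self.params["beta_b0"].shape[0] \
            * self.params["beta_b0"].shape[1]

    def scalar_names(self) -> list[str]:
        out = []
        for k, arr in self.params.items():
            if k in ("l", "v", "gamma"):
                continue
            if arr.ndim == 2:
                out.append(k)
            else:
                out.extend(f"{k}[{j}]" for j in range(arr.shape[2]))
        return out

    def scalar_draws(self, name: str) -> np.ndarray:
        """(chains, kept) array for a scalar-or-indexed parameter name."""
        if "[" in name:
            base, idx = name[:-1].split("[")
            return self.params[base][:, :, int(idx)]
        return self.params[name]

    def summary(self) -> pd.DataFrame:
        """Posterior mean, sd, 95% interval, split-Rhat and ESS per scalar."""
        import arviz as az
        rows = []
        for name in self.scalar_names():
            d = self.scalar_draws(name)
            flatd = d.reshape(-1)
            rows.append({
                "parameter": name,
                "mean": float(flatd.mean()), "sd": float(flatd.std()),
                "q2.5": float(np.quantile(flatd, 0.025)),
                "q97.5": float(np.quantile(flatd, 0.975)),
                "rhat": float(az.rhat(az.convert_to_dataset(d))["x"]),
                "ess": float(az.ess(az.convert_to_dataset(d))["x"]),
            })
        return pd.DataFrame(rows)

    def l_mean(self) -> np.ndarray:
        return self.stacked("l").mean(axis=0)

    def l_interval(self, level: float = 0.95):
        lo = (1.0 - level) / 2.0
        ld = self.stacked("l")
        return (np.quantile(ld, lo, axis=0),
                np.quantile(ld, 1.0 - lo, axis=0))


def fit(dataset: SurveyDataset, variant: ModelVariant = FULL,
        priors: Optional[PriorSpec] = None,
        mcmc: Optional[MCMCConfig] = None) -> PosteriorDraws:
    """Run the sampler; deterministic given ``mcmc.seed``."""
    if priors is None:
        priors = PriorSpec()
    if mcmc is None:
        mcmc = MCMCConfig()
    flat = flatten_dataset(dataset)
    chains = []
    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.n_chains + 1)
    init_rng = np.random.default_rng(seeds[-1])
    init = initialize_state(dataset, variant, init_rng, flat=flat)
    for c in range(mcmc.n_chains):
        rng = np.random.default_rng(seeds[c])
        chains.append(_run_chain(flat, variant, priors, mcmc, rng, init))
    params = {k: np.stack([ch[k] for ch in chains]) for k in chains[0]}
    return PosteriorDraws(params=params, flat=flat, variant=variant,
                          config=mcmc)


def posterior_predict_ct(draws: PosteriorDraws, w_grid, plate: int,
                         level: float = 0.95,
                         rng: Optional[np.random.Generator] = None,
                         ) -> pd.DataFrame:
    """Posterior-predictive CT summaries on a concentration grid.

    For each ``w``: predictive mean CT, an equal-tailed interval of the
    clean-component predictive, and the censoring probability, all
    averaged over the retained draws.
    """
    w_grid = np.atleast_1d(np.asarray(w_grid, dtype=float))
    if w_grid.size == 0:
        raise ValueError("w_grid must be non-empty")
    if rng is None:
        rng = np.random.default_rng(0)
    a1p = draws.stacked("alpha1")[:, plate]
    a2p = draws.stacked("alpha2")[:, plate]
    if draws.variant.constant_ct_variance:
        sd = np.sqrt(draws.stacked("sigma2_P"))[:, None]
    else:
        a1 = draws.stacked("a1")[:, None]
        a2 = draws.stacked("a2")[:, None]
        sd = None
    ct_max = draws.flat.ct_max
    rows = []
    logw = np.log(w_grid)
    mu = a1p[:, None] + a2p[:, None] * logw[None, :]   # (draws, grid)
    if sd is None:
        sd = np.exp(0.5 * (a1 + a2 * logw[None, :]))
    else:
        sd = np.broadcast_to(sd, mu.shape)
    samples = mu + sd * rng.standard_normal(mu.shape)
    from scipy.special import ndtr
    p_cens = 1.0 - ndtr((ct_max - mu) / sd)
    lo = (1.0 - level) / 2.0
    for j, w in enumerate(w_grid):
        rows.append({
            "w": w, "mean_ct": float(mu[:, j].mean()),
            "lower": float(np.quantile(samples[:, j], lo)),
            "upper": float(np.quantile(samples[:, j], 1 - lo)),
            "p_censored": float(p_cens[:, j].mean())})
    return pd.DataFrame(rows)
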