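"""Synthetic qPCR survey generator.

Generates surveys under the full generative model: site availability as an
AR(1)-plus-covariates process, sample collection noise, and per-replicate
CT values with a log-linear variance, right censoring at ``ct_max``, and
contamination/inhibition mechanisms:

* a contaminated replicate has a positive amount ``lambda`` of extraneous
  DNA (normal, truncated positive) added to its concentration before the
  CT is drawn;
* an inhibited replicate amplifies as if its concentration were reduced by
  a fixed multiplier (default 0.1, i.e. a 90% effective reduction).

Standards pass through the same contamination/inhibition mixture as
environmental replicates.  A single integer seed controls the whole survey
via per-stage child streams, so e.g. changing K does not perturb the
availability draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .domain_model import (CovariateSet, CTObservation, LatentState,
                           ModelParameters, StandardsSet, SurveyDataset,
                           SurveyDesign)

__all__ = [
    "CovariateColumn", "CovariateSpec", "ContaminationSpec",
    "InhibitionSpec", "StandardsSpec", "SimulationConfig",
    "default_config", "simulate_availability", "simulate_collection",
    "simulate_replicate_status", "simulate_ct", "simulate_standards",
    "simulate_survey",
]


@dataclass(frozen=True)
class CovariateColumn:
    """One covariate column: ``normal(mean, sd)`` or ``bernoulli(p)``."""

    family: str
    params: tuple = ()

    def draw(self, size, rng: np.random.Generator) -> np.ndarray:
        if self.family == "normal":
            mean, sd = self.params if self.params else (0.0, 1.0)
            return rng.normal(mean, sd, size=size)
        if self.family == "bernoulli":
            (p,) = self.params if self.params else (0.5,)
            return rng.binomial(1, p, size=size).astype(float)
        raise ValueError(f"unknown covariate family {self.family!r}")


@dataclass(frozen=True)
class CovariateSpec:
    site: tuple[CovariateColumn, ...]
    sample: tuple[CovariateColumn, ...]


@dataclass(frozen=True)
class ContaminationSpec:
    """Extraneous DNA added to contaminated replicates (truncated > 0)."""

    mean: float = 3e3
    sd: float = 100.0

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise ValueError("contamination mean must be > 0")


@dataclass(frozen=True)
class InhibitionSpec:
    """Effective-concentration multiplier for inhibited replicates."""

    multiplier: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 < self.multiplier < 1.0:
            raise ValueError("inhibition multiplier must be in (0, 1)")


@dataclass(frozen=True)
class StandardsSpec:
    """Concentrations and replicate count of the per-plate standards."""

    concentrations: tuple[float, ...] = tuple(
        3.0 * 10.0 ** z for z in range(1, 8))
    replicates: int = 3

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.concentrations):
            raise ValueError("standard concentrations must be > 0")


@dataclass
class SimulationConfig:
    design: SurveyDesign
    true_params: ModelParameters
    covariate_spec: CovariateSpec
    contamination_spec: ContaminationSpec = field(
        default_factory=ContaminationSpec)
    inhibition_spec: InhibitionSpec = field(default_factory=InhibitionSpec)
    standards_spec: StandardsSpec = field(default_factory=StandardsSpec)
    #: (sd of alpha1_p, sd of alpha2_p) about their hierarchy means; if set,
    #: plate coefficients are redrawn per plate in simulate_survey.
    plate_coef_sd: Optional[tuple[float, float]] = (
        np.sqrt(0.1), np.sqrt(0.01))
    #: whether simulated standards pass through the contamination/
    #: inhibition mixture; lab standards are prepared clean, so the
    #: default is False (the fitted model still allows standards to be
    #: contaminated/inhibited either way)
    standards_mixture: bool = False
    seed: int = 0


def default_config(M: int = 2, K: int = 2, p_c: float = 0.05,
                   p_h: float = 0.1, n_sites: int = 10, n_times: int = 20,
                   seed: int = 0) -> SimulationConfig:
    """Reference simulation setting.

    10 sites x 20 occasions, one distinct plate per occasion, 3 replicates
    of seven standard concentrations 3x10^z (z = 1..7) per plate; two
    covariates (standard normal + Bernoulli(0.5)) at both site and sample
    level with coefficients (1, -1); beta_b0 = 6, rho_i = 1,
    tau2 = tau2_1 = sigma2 = 1, a1 = 0.2, a2 = -0.25; plate coefficients
    drawn about (44, -1.7) with variances (0.1, 0.01); ct_max = 40 and
    sigma_c = ct_max.
    """
    design = SurveyDesign.rectangular(n_sites, n_times, M, K, ct_max=40.0)
    P = design.n_plates
    params = ModelParameters(
        beta_b0=6.0, beta_b=np.array([1.0, -1.0]),
        beta_w=np.array([1.0, -1.0]),
        rho=np.ones(n_sites), rho0=1.0, sigma2_rho=0.01,
        tau2=1.0, tau2_1=1.0, sigma2=1.0,
        alpha1=np.full(P, 44.0), alpha2=np.full(P, -1.7),
        alpha1_0=44.0, alpha2_0=-1.7, sigma2_alpha=0.1,
        a1=0.2, a2=-0.25, p_c=p_c, p_h=p_h,
        sigma_c=40.0, ct_max=40.0)
    cov_spec = CovariateSpec(
        site=(CovariateColumn("normal", (0.0, 1.0)),
              CovariateColumn("bernoulli", (0.5,))),
        sample=(CovariateColumn("normal", (0.0, 1.0)),
                CovariateColumn("bernoulli", (0.5,))))
    return SimulationConfig(design=design, true_params=params,
                            covariate_spec=cov_spec, seed=seed)


def simulate_availability(X_b, beta_b0, beta_b, rho, tau2, tau2_1,
                          rng: np.random.Generator) -> np.ndarray:
    """Draw the site availability matrix ``l`` of shape ``(n, T)``."""
    X_b = np.asarray(X_b, dtype=float)
    n, T = X_b.shape[:2]
    if T < 1:
        raise ValueError("need at least one time point")
    rho = np.broadcast_to(np.atleast_1d(np.asarray(rho, dtype=float)), (n,))
    d = X_b @ np.atleast_1d(beta_b)
    l = np.empty((n, T))
    l[:, 0] = beta_b0 + d[:, 0] + np.sqrt(tau2_1) * rng.standard_normal(n)
    for t in range(1, T):
        mean = rho * (l[:, t - 1] - d[:, t - 1]) + d[:, t]
        l[:, t] = mean + np.sqrt(tau2) * rng.standard_normal(n)
    return l


def simulate_collection(l, X_w, beta_w, sigma2,
                        rng: np.random.Generator) -> np.ndarray:
    """Draw sample log-DNA ``v`` of shape ``(n, T, max_M)`` given ``l``."""
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    l = np.asarray(l, dtype=float)
    if not np.isfinite(l).all():
        raise ValueError("l must be finite")
    mean = l[:, :, None] + np.asarray(X_w, dtype=float) @ np.atleast_1d(
        beta_w)
    return mean + np.sqrt(sigma2) * rng.standard_normal(mean.shape)


def simulate_replicate_status(p_c: float, p_h: float, n_draws: int,
                              rng: np.random.Generator) -> np.ndarray:
    """I.i.d. replicate statuses: 1 w.p. p_c, 2 w.p. p_h, else 0."""
    if p_c < 0 or p_h < 0:
        raise ValueError("probabilities must be non-negative")
    if p_c + p_h > 1:
        raise ValueError("p_c + p_h must be <= 1")
    u = rng.random(n_draws)
    gamma = np.zeros(n_draws, dtype=int)
    gamma[u < p_c] = 1
    gamma[(u >= p_c) & (u < p_c + p_h)] = 2
    return gamma


def _truncated_positive_normal(mean, sd, size, rng):
    out = rng.normal(mean, sd, size=size)
    bad = out <= 0
    while bad.any():                     # negligible at mean/sd = 30
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out <= 0
    return out


def simulate_ct(w, gamma, alpha1_p, alpha2_p, a1, a2,
                contamination_spec: ContaminationSpec,
                inhibition_spec: InhibitionSpec, ct_max: float,
                rng: np.random.Generator,
                ) -> tuple[np.ndarray, np.ndarray]:
    """Draw CT values for replicates of concentration ``w``.

    Contaminated replicates amplify at ``w + lambda`` and inhibited ones
    at ``multiplier * w``; in all cases both the CT mean and the
    log-linear CT variance are evaluated at the effective concentration.
    Returns ``(ct, censored)`` with ``ct`` NaN where censored
    (``ct* >= ct_max``).
    """
    w = np.asarray(w, dtype=float)
    if not np.isfinite(w).all() or np.any(w <= 0):
        raise ValueError("w must be finite and > 0")
    gamma = np.asarray(gamma, dtype=int)
    w_eff = w.astype(float).copy()
    contaminated = gamma == 1
    if contaminated.any():
        lam = _truncated_positive_normal(
            contamination_spec.mean, contamination_spec.sd,
            int(contaminated.sum()), rng)
        w_eff[contaminated] = w_eff[contaminated] + lam
    inhibited = gamma == 2
    w_eff[inhibited] = inhibition_spec.multiplier * w_eff[inhibited]

    mu = alpha1_p + alpha2_p * np.log(w_eff)
    sd = np.exp(0.5 * (a1 + a2 * np.log(w_eff)))
    ct_star = mu + sd * rng.standard_normal(w_eff.shape)
    censored = ct_star >= ct_max
    ct = np.where(censored, np.nan, ct_star)
    return ct, censored


def simulate_standards(P: int, standards_spec: StandardsSpec,
                       alpha1, alpha2, a1, a2, p_c, p_h,
                       contamination_spec: ContaminationSpec,
                       inhibition_spec: InhibitionSpec, ct_max: float,
                       rng: np.random.Generator,
                       ) -> tuple[StandardsSet, np.ndarray]:
    """Simulate the per-plate standards; returns the set and its gammas."""
    concs = np.asarray(standards_spec.concentrations, dtype=float)
    Kstar = standards_spec.replicates
    plate = np.repeat(np.arange(P), concs.size * Kstar)
    w = np.tile(np.repeat(concs, Kstar), P)
    gamma = simulate_replicate_status(p_c, p_h, w.size, rng)
    alpha1 = np.atleast_1d(np.asarray(alpha1, dtype=float))
    alpha2 = np.atleast_1d(np.asarray(alpha2, dtype=float))
    ct, cens = simulate_ct(w, gamma, alpha1[plate], alpha2[plate], a1, a2,
                           contamination_spec, inhibition_spec, ct_max, rng)
    return StandardsSet(plate=plate, concentration=w, ct=ct,
                        censored=cens), gamma


def simulate_survey(config: SimulationConfig,
                    ) -> tuple[SurveyDataset, LatentState, ModelParameters]:
    """Generate a full survey: observables plus the generating truth.

    Identical seeds produce identical output.  Per-stage child RNG streams
    keep the availability/collection draws invariant to the replicate-level
    design.
    """
    d = config.design
    p = config.true_params
    streams = np.random.SeedSequence(config.seed).spawn(8)
    rng_cov, rng_plate, rng_avail, rng_coll, rng_status, rng_ct, \
        rng_std, _ = (np.random.default_rng(s) for s in streams)

    n, T, max_M = d.n_sites, d.n_times, d.max_samples
    Xb = np.stack([c.draw((n, T), rng_cov)
                   for c in config.covariate_spec.site], axis=-1)
    Xw = np.stack([c.draw((n, T, max_M), rng_cov)
                   for c in config.covariate_spec.sample], axis=-1)
    covariates = CovariateSet(Xb, Xw)

    P = d.n_plates
    alpha1 = np.asarray(p.alpha1, dtype=float).copy()
    alpha2 = np.asarray(p.alpha2, dtype=float).copy()
    if config.plate_coef_sd is not None:
        sd1, sd2 = config.plate_coef_sd
        alpha1 = p.alpha1_0 + sd1 * rng_plate.standard_normal(P)
        alpha2 = p.alpha2_0 + sd2 * rng_plate.standard_normal(P)

    l = simulate_availability(Xb, p.beta_b0, p.beta_b, p.rho, p.tau2,
                              p.tau2_1, rng_avail)
    v = simulate_collection(l, Xw, p.beta_w, p.sigma2, rng_coll)

    max_K = int(d.replicates_per_sample.max())
    gamma = np.zeros((n, T, max_M, max_K), dtype=int)
    observations: list[CTObservation] = []
    # flatten the valid replicate cells, draw status and CT in one pass
    cells = [(i, t, m, k)
             for i in range(n) for t in range(T)
             for m in range(d.samples_per_occasion[i, t])
             for k in range(d.replicates_per_sample[i, t, m])]
    idx = np.array(cells, dtype=int)
    g_flat = simulate_replicate_status(p.p_c, p.p_h, len(cells), rng_status)
    w_flat = np.exp(v[idx[:, 0], idx[:, 1], idx[:, 2]])
    plates = d.plate_of_occasion[idx[:, 0], idx[:, 1]]
    ct_flat, cens_flat = simulate_ct(
        w_flat, g_flat, alpha1[plates], alpha2[plates], p.a1, p.a2,
        config.contamination_spec, config.inhibition_spec, d.ct_max, rng_ct)
    for row, (i, t, m, k) in enumerate(cells):
        gamma[i, t, m, k] = g_flat[row]
        observations.append(CTObservation(
            site=i, time=t, sample=m, replicate=k, plate=int(plates[row]),
            ct=None if cens_flat[row] else float(ct_flat[row])))

    std_pc, std_ph = (p.p_c, p.p_h) if config.standards_mixture \
        else (0.0, 0.0)
    standards, _ = simulate_standards(
        P, config.standards_spec, alpha1, alpha2, p.a1, p.a2, std_pc,
        std_ph, config.contamination_spec, config.inhibition_spec,
        d.ct_max, rng_std)

    truth = ModelParameters(
        beta_b0=p.beta_b0, beta_b=p.beta_b.copy(), beta_w=p.beta_w.copy(),
        rho=np.broadcast_to(np.atleast_1d(p.rho), (n,)).copy(),
        rho0=p.rho0, sigma2_rho=p.sigma2_rho, tau2=p.tau2, tau2_1=p.tau2_1,
        sigma2=p.sigma2, alpha1=alpha1, alpha2=alpha2,
        alpha1_0=p.alpha1_0, alpha2_0=p.alpha2_0,
        sigma2_alpha=p.sigma2_alpha, a1=p.a1, a2=p.a2, p_c=p.p_c,
        p_h=p.p_h, sigma_c=p.sigma_c, ct_max=p.ct_max,
        sigma2_P=p.sigma2_P)
    latent = LatentState(l=l, v=v, gamma=gamma)
    dataset = SurveyDataset(d, covariates, observations, standards)
    return dataset, latent, truth
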