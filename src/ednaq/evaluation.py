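"""Simulation-study metrics and diagnostics.

Implements mean squared error of the posterior-mean availability surface,
mean bias of scalar parameters, equal-tailed 95% posterior credible
intervals (PCI width, coverage, contains-zero proportion), a grid-based
simulation study runner, and the per-plate standards regression
diagnostic.

Quantile convention: linear interpolation between order statistics
(``numpy.quantile`` with its default ``linear`` method).
"""

from __future__ import annotations

import hashlib
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .domain_model import StandardsSet
from .inference import MCMCConfig, fit
from .likelihood import ModelVariant, PriorSpec
from .simulator import SimulationConfig, default_config, simulate_survey

__all__ = ["mse_l", "mean_bias", "interval_metrics", "run_sim_study",
           "standards_regression_diagnostic"]


def mse_l(true_l: np.ndarray, posterior_mean_l: np.ndarray) -> float:
    """Mean squared error over datasets, sites and times.

    Both arrays have shape ``(N, n, T)`` (a single dataset may pass
    ``(n, T)``).  Returns ``sum((true - est)^2) / (N n T)``.
    """
    t = np.asarray(true_l, dtype=float)
    e = np.asarray(posterior_mean_l, dtype=float)
    if t.shape != e.shape:
        raise ValueError("true and estimated l must have the same shape")
    return float(np.mean((t - e) ** 2))


def mean_bias(true_theta, posterior_means) -> float:
    """Mean of signed errors ``estimate - truth`` across datasets."""
    t = np.asarray(true_theta, dtype=float)
    e = np.asarray(posterior_means, dtype=float)
    if t.size == 0:
        raise ValueError("mean_bias needs at least one dataset")
    if t.shape != e.shape:
        raise ValueError("shape mismatch")
    return float(np.mean(e - t))


def interval_metrics(draws_per_dataset: Sequence[np.ndarray],
                     truth: Sequence[float], level: float = 0.95,
                     ) -> tuple[float, float, float]:
    """Equal-tailed interval summaries across datasets.

    ``draws_per_dataset[j]`` holds the posterior draws of one scalar for
    dataset ``j`` with true value ``truth[j]``.  Returns ``(mean width,
    coverage, contains-zero proportion)``.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    lo_q = (1.0 - level) / 2.0
    widths, covered, zero_in = [], [], []
    for d, t in zip(draws_per_dataset, truth, strict=True):
        d = np.asarray(d, dtype=float)
        if d.size == 0:
            raise ValueError("empty draw array")
        lo = float(np.quantile(d, lo_q))
        hi = float(np.quantile(d, 1.0 - lo_q))
        widths.append(hi - lo)
        covered.append(lo <= t <= hi)
        zero_in.append(lo <= 0.0 <= hi)
    return (float(np.mean(widths)), float(np.mean(covered)),
            float(np.mean(zero_in)))


def _cell_seed(base_seed: int, M: int, K: int, p_c: float, p_h: float,
               j: int) -> int:
    """Stable per-dataset seed; shared across model variants so the three
    models within a cell are fitted to the same simulated datasets."""
    key = f"{base_seed}|{M}|{K}|{p_c:.6f}|{p_h:.6f}|{j}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:8], "little")


_VARIANT_BY_NAME = {"full": ModelVariant("full"),
                    "const_var": ModelVariant("const_var"),
                    "no_mixture": ModelVariant("no_mixture")}


def run_sim_study(grid: dict, N: int, seed: int = 0,
                  mcmc: Optional[MCMCConfig] = None,
                  priors: Optional[PriorSpec] = None,
                  config_factory: Callable[..., SimulationConfig]
                  = default_config,
                  scalar_params: Sequence[str] = ("beta_b[0]", "beta_b[1]",
                                                  "beta_w[0]", "beta_w[1]",
                                                  "a1", "a2", "p_c", "p_h"),
                  ) -> pd.DataFrame:
    """Run the simulation study over a design grid.

    ``grid`` has keys ``M``, ``K``, ``model`` (variant names) and ``p``
    (list of ``(p_c, p_h)`` pairs).  For each cell, ``N`` datasets are
    simulated with reproducible per-dataset seeds shared across model
    variants (paired comparison), each is fitted, and the availability
    metrics (MSE, mean 95% PCI width R, coverage C) plus per-parameter
    mean bias / width / contains-zero are tabulated.  Fit failures are
    recorded per dataset rather than aborting the cell.
    """
    if mcmc is None:
        mcmc = MCMCConfig.test_preset()
    rows = []
    for (p_c, p_h) in grid["p"]:
        for M in grid["M"]:
            for K in grid["K"]:
                # simulate the N datasets once, share across variants
                sims = []
                for j in range(N):
                    cfg = config_factory(
                        M=M, K=K, p_c=p_c, p_h=p_h,
                        seed=_cell_seed(seed, M, K, p_c, p_h, j))
                    sims.append(simulate_survey(cfg))
                for model_name in grid["model"]:
                    variant = _VARIANT_BY_NAME[model_name]
                    sq_err, widths, cover = [], [], []
                    par_est = {k: [] for k in scalar_params}
                    par_draws = {k: [] for k in scalar_params}
                    par_true = {k: [] for k in scalar_params}
                    n_failed = 0
                    for j, (dataset, latent, truth) in enumerate(sims):
                        try:
                            cfg_j = MCMCConfig(
                                n_chains=mcmc.n_chains,
                                n_iterations=mcmc.n_iterations,
                                n_burnin=mcmc.n_burnin,
                                thinning=mcmc.thinning,
                                seed=_cell_seed(seed + 1, M, K, p_c,
                                                p_h, j))
                            draws = fit(dataset, variant=variant,
                                        priors=priors, mcmc=cfg_j)
                        except Exception:
                            n_failed += 1
                            continue
                        lm = draws.l_mean()
                        sq_err.append(np.mean((latent.l - lm) ** 2))
                        lo, hi = draws.l_interval(0.95)
                        widths.append(float(np.mean(hi - lo)))
                        cover.append(float(np.mean(
                            (lo <= latent.l) & (latent.l <= hi))))
                        for name in scalar_params:
                            try:
                                d = draws.scalar_draws(name).reshape(-1)
                            except KeyError:
                                continue
                            par_draws[name].append(d)
                            par_est[name].append(float(d.mean()))
                            par_true[name].append(
                                _true_scalar(truth, name))
                    row = {"pc": p_c, "ph": p_h, "M": M, "K": K,
                           "model": model_name, "N": N,
                           "n_failed": n_failed,
                           "MSE": float(np.mean(sq_err)) if sq_err
                           else np.nan,
                           "R": float(np.mean(widths)) if widths
                           else np.nan,
                           "C": float(np.mean(cover)) if cover
                           else np.nan}
                    for name in scalar_params:
                        if not par_est[name]:
                            continue
                        mb = mean_bias(par_true[name], par_est[name])
                        w, c, z = interval_metrics(par_draws[name],
                                                   par_true[name])
                        row[f"MB_{name}"] = mb
                        row[f"R_{name}"] = w
                        row[f"zero_{name}"] = z
                    rows.append(row)
    return pd.DataFrame(rows)


def _true_scalar(truth, name: str) -> float:
    if "[" in name:
        base, idx = name[:-1].split("[")
        return float(np.atleast_1d(getattr(truth, base))[int(idx)])
    return float(getattr(truth, name))


def standards_regression_diagnostic(standards: StandardsSet,
                                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-plate OLS of CT on ln-concentration over uncensored standards.

    Returns ``(fits, residuals)``: one row per plate with slope, intercept
    and the number of censored standards excluded; and one row per
    uncensored standard with its residual, keyed by concentration.  Plates
    with fewer than two distinct uncensored concentrations raise.
    """
    obs = ~standards.censored
    logw = np.log(standards.concentration)
    fit_rows, res_rows = [], []
    for p in np.unique(standards.plate):
        sel = (standards.plate == p) & obs
        n_excluded = int(np.sum((standards.plate == p) & ~obs))
        if np.unique(logw[sel]).size < 2:
            raise ValueError(
                f"plate {p}: fewer than 2 distinct uncensored "
                f"concentrations; cannot fit its line")
        slope, intercept = np.polyfit(logw[sel], standards.ct[sel], 1)
        fit_rows.append({"plate": int(p), "intercept": float(intercept),
                         "slope": float(slope),
                         "n_censored_excluded": n_excluded})
        resid = standards.ct[sel] - (intercept + slope * logw[sel])
        for c, r in zip(standards.concentration[sel], resid):
            res_rows.append({"plate": int(p), "concentration": float(c),
                             "residual": float(r)})
    return pd.DataFrame(fit_rows), pd.DataFrame(res_rows)
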