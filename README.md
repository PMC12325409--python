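# ednaq

Hierarchical Bayesian inference of environmental DNA (eDNA) concentration
across sites and time from qPCR cycle-threshold (CT) surveys.

The model has three stages:

1. **Availability** — latent log-DNA `l[i, t]` per site and occasion
   follows an AR(1)-plus-covariates process with site-specific rates
   `rho_i` drawn from a common hierarchy.
2. **Collection** — each environmental sample's log-DNA `v[i, m, t]` is a
   noisy draw around `l[i, t]` shifted by sample-level covariates.
3. **Analysis** — each PCR replicate's CT value is linear in log
   concentration with plate-specific coefficients (hierarchically
   shared), a log-linear CT variance (more spread at low concentration),
   right censoring at `ct_max`, and a three-component mixture allowing a
   replicate to be clean, contaminated (truncated normal below its
   expected CT) or inhibited (truncated normal above). Standards of known
   concentration on every plate calibrate the CT regression, the variance
   model and the contamination/inhibition probabilities.

Three model variants are supported: `full`, `const_var` (constant CT
variance instead of log-linear) and `no_mixture`
(`p_c = p_h = 0`). Inference is a custom vectorised
Metropolis-within-Gibbs sampler with exact Gibbs updates for `l`, the
regression coefficients and the mixture indicators, and the joint
rejection constraint `p_c + p_h < 0.5`.

## CLI

```bash
# generate a synthetic survey (CSV tables + generating truth)
ednaq simulate --config sim.yaml --seed 17 --out data/

# fit a model variant
ednaq fit --data data/ --model full --mcmc mcmc.yaml --seed 7 --out draws/

# posterior summaries
ednaq summarize --draws draws/ --out summary.csv

# simulation study over a design grid
ednaq simstudy --grid grid.yaml --n 100 --seed 1 --out results/

# tiny end-to-end fixture
ednaq make-fixture --seed 0 --out toy/
```

`sim.yaml` keys: `n_sites`, `n_times`, `M`, `K`, `p_c`, `p_h`.
`mcmc.yaml` keys: `n_chains`, `n_iterations`, `n_burnin`, `thinning`.
`grid.yaml` keys: `M`, `K`, `model` (lists) and `p` (list of
`[p_c, p_h]` pairs), optional `mcmc` block.

Data layout (CSV, 1-based indices, empty/`NA` CT cell = censored):
`replicates.csv` (site, time, sample, replicate, plate, ct),
`site_covariates.csv`, `sample_covariates.csv`, `standards.csv`
(plate, standard_id, concentration, ct), plus `design.json`
(n_sites, n_times, ct_max). Concentrations are treated as unitless
positive reals; units are the user's contract.

## Package layout

- `ednaq.domain_model` — survey data structures, validation, CSV I/O
- `ednaq.simulator` — synthetic survey generator (with contamination,
  inhibition, censoring and per-plate standards)
- `ednaq.likelihood` — all model densities and the joint log-posterior
- `ednaq.inference` — the MCMC engine and posterior containers
- `ednaq.evaluation` — simulation-study metrics (MSE, mean bias, PCI
  width/coverage), grid runner, standards regression diagnostic
- `ednaq.cli` — command-line entry points
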