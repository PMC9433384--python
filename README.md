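# growthlaw

A steady-state model of microbial proteome synthesis with **heterogeneous
translation speeds** and **protein degradation**, and the growth law it
implies: the relation between the ribosomal proteome mass fraction
`phi_R` and the growth rate `mu` across nutrient conditions.

## The scientific problem

In the classic simple translation model (STM) every protein is translated at
one speed and never degraded, which forces a straight line
`phi_R = mu * m_R / (k * chi_R_slope) + phi0`. Measured growth laws are not
straight: bacteria show upward-bending curves and budding yeast shows a
nonzero intercept with a distinct slope. This package implements a
coarse-grained model in which each protein `i` has its own translation speed
`k_i` (Da/min) and first-order degradation rate `alpha_i` (1/min), and a
fraction `chi_i` of active ribosomes is allocated to its mRNA:

```
dM_i/dt = k_i chi_i (R - R0) - alpha_i M_i,      R = M_R/m_R,  R0 = phi0 M_tot/m_R
```

At steady state the proteome composition is

```
phi_i(mu) = [k_i chi_i / (mu + alpha_i)] / sum_j k_j chi_j / (mu + alpha_j)
```

and eliminating the environment dependence yields a **universal rational
growth law**

```
phi_R(mu) = (mu + c1) / (c2 mu + c3)
```

whose three coefficients are set by the inactive-ribosome fraction `phi0`,
the ribosomal translation speed `k_R`, the ribosome protein mass `m_R`, and
two environment-weighted means: the allocation-weighted speed
`<k>_chi = <k>(1 + I_chi_k)` and the composition-weighted degradation rate
`<alpha>_phi = <alpha>(1 + I_phi_alpha)`. The correlation indices
`I_chi_k` (allocation vs. speed) and `I_phi_alpha` (composition vs.
degradation) capture all the environment structure that matters. Whenever
`k_R <= <k>_chi` and `alpha_R <= <alpha>_phi`, the curve is monotonically
increasing, and strictly convex (upward-bending) when `k_R < <k>_chi`.

The package provides:

- **`growthlaw.model`** — steady-state solver (Brent root-finding on the
  self-consistency condition), closed-form growth-law coefficients, curve
  shape classification, correlation indices, and an independent ODE oracle
  (`steady_state_from_dynamics`) for validation.
- **`growthlaw.simulate`** — environment ensembles over one fixed proteome:
  lognormal proteomes, free or index-targeted environments (Gaussian-copula
  coupling of log-allocations to speed/degradation ranks), and ablation
  modes (`no_degradation`, `homogeneous_speed`).
- **`growthlaw.fitting`** — nonlinear least-squares fits of the rational
  curve with linearized 95% confidence intervals, exact inversion of the
  coefficients to `(phi0, k_R, <k>_chi)`, confidence-box bounds on the
  derived parameters, the subsample-RMSE universality experiment, and
  per-gene composition prediction scoring against ablations.
- **`growthlaw.synthetic`** — synthetic studies with exact ground truth:
  per-condition gene tables, OD600 growth curves, and `(mu, phi_R)`
  datasets with controllable measurement noise.
- **`growthlaw.io` / `growthlaw.cli`** — validated TSV/CSV readers and
  writers, ribosomal aggregation with paralog handling, length-bias
  calibration, an OD600 sliding-window growth-rate extractor, and a
  `growthlaw` command-line interface.

## Worked example

Solve one random environment at the measured reference conditions
(`k_R = 2.07e4`, `<k> = 4.80e4` Da/min, `alpha_R = 4.83e-4`,
`<alpha> = 1.10e-3` /min, `phi0 = 0.08`, `m_R = 1.40e6` Da):

```python
import growthlaw as gl
from growthlaw.simulate import EnsembleConfig, sample_proteome, sample_environment

cfg = EnsembleConfig(n_genes=200, seed=5)
params = sample_proteome(cfg)
env = sample_environment(cfg, params, env_index=0)
state = gl.steady_state_solve(params, env)
print(state.mu, state.phi_R, state.I_chi_k, state.I_phi_alpha)
```

prints

```
mu = 2.876433e-03 1/min (0.1726 1/h), phi_R = 0.217209
I_chi_k = 0.0297, I_phi_alpha = -0.1972
```

and the independent ODE oracle agrees to `7.2e-12` relative:

```python
mu_dyn, phi_dyn = gl.steady_state_from_dynamics(params, env)
```

An ensemble of environments sharing one `(I_chi_k, I_phi_alpha)` pair falls
on a single exact curve, and fitting that curve recovers the biological
parameters:

```python
from growthlaw.simulate import run_ensemble

cfg = EnsembleConfig(n_genes=500, seed=5, n_environments=8)
res = run_ensemble(cfg, targets=[(0.5, -0.33)] * 8)

ds = gl.GrowthLawDataset(res.records["mu_per_min"].to_numpy(),
                         res.records["phi_R"].to_numpy())
fit = gl.fit_growth_law(ds)
fit = gl.with_derived_params(fit, alpha_R=cfg.alpha_R,
                             alpha_phi=float(res.records["alpha_phi"].mean()),
                             m_R=cfg.m_R)
print(fit.c1, fit.c2, fit.c3, fit.rmse, fit.derived)
```

prints

```
c1 = 0.00475598, c2 = -2.38747, c3 = 0.0491991, rmse = 1.01e-15
derived: {'phi0': 0.08, 'k_R': 20700.0, 'k_chi': 70120.7}
```

— `phi0` and `k_R` are recovered exactly and `k_chi` equals the realized
allocation-weighted speed of the sampled proteome at `I_chi_k = 0.5`.

### Command line

```bash
growthlaw fixtures --out study/ --n-genes 200 --n-conditions 4 --seed 0
growthlaw solve --gene-table study/genes_cond0.tsv --phi0 0.08
growthlaw metrics --gene-table study/genes_cond0.tsv
growthlaw growthrate --od-csv study/od_cond0.csv
growthlaw fit --data study/growth_law.csv
growthlaw simulate --n-genes 500 --n-environments 20 --seed 1 --out ens.tsv
```

## Reproduction

```bash
python -m pytest -q tests/                      # full suite (~1 min)
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script recomputes the package's headline quantities from
scratch — solver-vs-closed-form agreement, ODE-oracle error, shape-theorem
fractions, ensemble curve residuals, the broad-vs-narrow subsample-RMSE
universality medians and ratio, noiseless fit recovery, CI coverage, and
OD-extractor error — and writes them as JSON keyed by short metric names
(`{"<name>": {"value": ..., "n": ...}}`). With `--seed 1` the
broad/narrow median RMSEs are `1.26e-2` / `1.40e-3` (ratio `9.0`) and the
CI coverage is 96.0–96.4% per coefficient.

See `docs/methods.md` for the numerical methods, the copula targeting
scheme, and the documented modeling choices.
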