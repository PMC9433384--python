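# Methods

This note documents the numerical methods and modeling choices behind the
`growthlaw` package, in the package's own terms. Units throughout: minutes
for time, Da for mass, so translation speeds `k_i` are Da/min and
degradation rates `alpha_i` are 1/min.

## Model

Per-protein mass balance with a coarse-grained ribosomal protein at index 0:

```
dM_i/dt = k_i chi_i (R - R0) - alpha_i M_i
R  = M_0 / m_R            (ribosome count)
R0 = phi0 M_tot / m_R     (inactive ribosomes, fixed mass fraction phi0)
```

`chi_i` is the fraction of active ribosomes allocated to protein `i`
(`sum chi_i = 1`); one environment is one allocation vector. The dynamics
are linear in `M`, so a steady state is an exponentially growing mode
`M_i(t) = phi_i e^{mu t}` with a fixed composition.

### Steady-state composition and growth rate

Balancing synthesis, dilution and degradation gives

```
phi_i(mu) = [k_i chi_i / (mu + alpha_i)] / sum_j k_j chi_j / (mu + alpha_j)
```

and the self-consistency condition ("one ribosome's output pays for the
whole proteome"):

```
g(mu) = k_R chi_R (1 - phi0 / phi_R(mu)) / m_R - alpha_R - mu = 0.
```

`steady_state_solve` scans `g` on a log-spaced grid over
`(-min_i alpha_i, k_R chi_R / m_R]` (the upper end is an a-priori bound on
`mu`) and polishes every sign change with Brent's method
(`rtol = 1e-14`).

**Root multiplicity.** With heterogeneous degradation rates `g` generically
has a second root just above `-min(alpha)`. That root is a *subdominant
eigenvalue* of the linear mass dynamics, not the attractor: the eigenvalues
of the exact system matrix identify the largest root as the dominant growth
mode, and direct long-time integration converges to it (relative error
~1e-11 in the validation suite). The solver therefore returns the largest
root by default; `on_multiple="error"` raises instead, listing every root,
for callers who want the strict behavior.

**Uniform degradation.** When all `alpha_i` are equal (including the
degradation-free ablation) the composition is `mu`-independent
(`phi_i = k_i chi_i / sum_j k_j chi_j`) and the growth rate is closed-form,
of either sign. The solver special-cases this instead of bracketing, which
also makes degradation-dominated (negative-`mu`) states reachable; those are
returned with a `NegativeGrowthWarning` and a `negative_growth` flag.

**No steady state.** For some environments (low ribosomal allocation
against strong degradation) `g` has no root above `-min(alpha)`: the
dominant mode decays at the slowest degradation rate and no self-sustaining
composition exists. The solver raises `NoSteadyStateError`; ensemble
samplers treat such draws as rejections.

**Validation oracle.** `steady_state_from_dynamics` integrates the ODE
system (`scipy.integrate.solve_ivp`, LSODA, `rtol = 1e-11`) in chunks,
renormalizing total mass between chunks to avoid overflow, until both the
composition and the log-mass slope converge. Chunk lengths grow
geometrically (factor 1.25) so that instances with a small spectral gap
(very slow growth) still contract. Strong early transients can push masses
negative in this linear model (active ribosomes `R - R0 < 0`); the
integrator then re-seeds from the clipped state, which converges to the
same dominant mode from any positive start.

### Closed-form growth law

Eliminating `chi_R` between `g(mu) = 0` and the composition formula yields

```
phi_R(mu) = (mu + c1) / (c2 mu + c3)
c1 = <k>_chi phi0 / m_R + <alpha>_phi
c2 = 1 - <k>_chi / k_R
c3 = <alpha>_phi - alpha_R <k>_chi / k_R + <k>_chi / m_R
```

with the environment-weighted means over non-ribosomal proteins

```
<k>_chi     = sum k_i chi~_i        (chi~ = chi renormalized without index 0)
<alpha>_phi = sum alpha_i phi~_i    (phi~ likewise)
```

These obey the exact identities `<k>_chi = <k>(1 + I_chi_k)` and
`<alpha>_phi = <alpha>(1 + I_phi_alpha)`, where the correlation index of a
weight vector `w` and values `x` is
`I = (mean(wx) - mean(w)mean(x)) / (mean(w)mean(x))`, bounded below by -1
for nonnegative data.

Reduced forms: with `alpha == 0` the curve is the Hill-type
`phi_R = mu/(a mu + b) + phi0` with `a` proportional to `k_R - <k>_chi`
(negative `a` = upward bending); with homogeneous speeds it is the shifted
line `phi_R = (mu + c)/(k/m_R + d) + phi0`.

Shape classification: the curve is increasing iff the discriminant
`c3 - c1 c2 > 0` and convex iff additionally `c2 < 0`, i.e.
`(c1 c2 - c3) c2 > 0`. Under `k_R <= <k>_chi` and
`alpha_R <= <alpha>_phi` the discriminant is provably positive; the
acceptance suite verifies this on 1000 random parameter sets.

### Inversion

Given `(c1, c2, c3)` plus `(alpha_R, <alpha>_phi, m_R)`:

```
<k>_chi = m_R (c3 - <alpha>_phi + alpha_R (1 - c2))
k_R     = <k>_chi / (1 - c2)            (requires c2 < 1)
phi0    = (c1 - <alpha>_phi) m_R / <k>_chi
```

This is the exact inverse of the forward map (property-tested to 1e-8
relative over wide parameter ranges).

## Ensembles and targeted environments

One proteome is sampled once and held fixed; environments differ only in
`chi`. Non-ribosomal `k_i` and `alpha_i` are lognormal with configured
means and coefficients of variation (CVs); entry 0 is set exactly to
`(k_R, alpha_R)`. The reference conditions are the measured budding-yeast
values `k_R = 2.07e4`, `<k> = 4.80e4` Da/min, `alpha_R = 4.83e-4`,
`<alpha> = 1.10e-3` 1/min, `phi0 = 0.08`, `m_R = 1.40e6` Da. The lognormal
CVs of the underlying study are not published; all three default to 1.0.
`chi_R` is uniform on (0.05, 0.45).

Randomness uses documented substreams of one master seed
(`default_rng([seed, stream, index])`), so any piece can be regenerated in
isolation.

**Targeting correlation indices.** To preselect `(I_chi_k, I_phi_alpha)`
the log-allocations are coupled to the Gaussian-copula normal scores of
`k` and `alpha`:

```
log chi~_i  ∝  sigma_chi (rho1 s_k,i + rho2 s_a,i + lambda w_i),
lambda = sqrt(1 - rho1^2 - rho2^2)
```

with `s` the mid-rank normal scores and `w` fresh noise. For a single
target, Brent's method on `rho1` drives the realized `I_chi_k` to the
target. For a pair, an inner Brent finds the `rho1(rho2)` that matches
`I_chi_k` (cheap — no steady-state solve), and an outer Brent on `rho2`
drives the *solved* steady state's `I_phi_alpha` to its target; the outer
range adapts to the loading budget left after the inner match. Draws whose
steady state fails to exist are rejected and redrawn.

**Feasibility.** The loadings live on the unit disc, so the realizable
index pairs are bounded: at CV = 1 the allocation-speed index is capped
near `exp(sigma_chi sigma_k) - 1 ~ 1` (finite-sample maximum ~0.7 at a few
hundred genes), and joint extremes (large `I_chi_k` with strongly negative
`I_phi_alpha`) can be unreachable. `gaussian_index_pool`, which draws index
pairs from Gaussians for the universality experiment, redraws infeasible
pairs; the realized pool is a feasibility-truncated Gaussian. The
universality comparison below only requires a broad-vs-narrow spread
contrast, which the truncation preserves (the realized broad pool spread
remains ~7-8x the narrow one).

## Fitting and uncertainty

`fit_growth_law` minimizes squared residuals of
`(mu + c1)/(c2 mu + c3)` (Levenberg-Marquardt, initialized from the
straight-line null model with `c2 = 0`). 95% confidence intervals use the
Jacobian-linearized covariance `inv(J'J) * SS_res/(n-3)` with a Student-t
quantile; `rmse = sqrt(SS_res / n)`. Empirical coverage on synthetic data
with Gaussian noise `sd = 1e-3` is 96.0-96.4% per coefficient (500
replicates, seed 1) — inside the accepted [93%, 97%] band.

Bounds on the derived `(phi0, k_R, <k>_chi)` are computed as min/max of the
inversion map over the 3-D coefficient confidence box (21^3 grid plus
Nelder-Mead refinement), excluding infeasible corners (`c2 >= 1` or
`<k>_chi <= 0`) with a warning.

**Universality experiment.** `subsample_rmse_experiment` repeatedly draws
20 environments from a pool, fits the curve, and collects RMSEs. A pool
whose environments share one index pair lies on one exact curve (median
RMSE ~1e-16); pools with Gaussian-spread indices do not. The Gaussian
spreads are not published for the original experiment; this package fixes
`sigma_broad = 0.3` and `sigma_narrow = 0.03` around means (0.5, 0), chosen
once before running the experiment. The resulting medians (seed 1,
reduced scale) are `1.26e-2` vs `1.40e-3`, ratio ~9 — the ordering
property (ratio >= 2) is the acceptance criterion, not the exact medians.

## Synthetic studies

`generate_study` emulates the processed outputs of ribosome-profiling and
proteomics experiments with exact retained ground truth. Protein lengths
are lognormal (mean 450 aa, CV 0.5, floor 30 aa) at 110 Da mean residue
mass; the coarse-grained ribosomal record carries the whole ribosome mass
exactly (`length * a == m_R`). Per-condition index targets default to a
decreasing speed-index schedule (0.5, 0.35, 0.25, 0.15) with the
degradation index pinned at -0.33 — the qualitative measured pattern at
magnitudes the copula can realize at CV = 1. Measurement noise is
multiplicative unit-mean lognormal per table; fraction columns are
renormalized afterwards.

OD600 curves are flat-lag + exponential + logistic saturation
(`od0 = 0.01`, saturation 4.0, 5-min sampling). The extractor computes
5-point sliding regressions of `ln(OD)` vs. time, pools the points of all
windows with slope >= 0.95 of the maximum (each point once), and regresses
once over the pool. It is exact on pure exponentials and within 2% on the
lag+saturation curves (max error 1.5% over rates 1.5e-3 to 1.2e-2 1/min).
Overlapping selected windows are deduplicated before the final regression;
keeping duplicates would weight interior points more but changes the
estimate only at the 1e-3 relative level on these curves.

## Input conventions

Gene tables are TSV with required columns `gene_id`, `chi`, `phi` and
either `k` or both `v` (aa/min) and `a` (Da/aa, `k = v*a`); optional
`alpha` (defaults to 0 with a warning), `length`, `is_ribosomal`,
`paralog_group`. Fraction columns must sum to 1 within 1e-6. Length-bias
calibration rescales `phi` by `L^-p` (`p = 0.57` or 1) and renormalizes.
Ribosomal aggregation uses chi-weighted speed, phi-weighted degradation,
and an effective ribosome mass summing detected ribosomal protein masses
with paralog pairs contributing their average once.

## Limitations

- The copula targeting cannot realize index pairs outside the unit-disc
  loading budget (e.g. `I_chi_k ~ 1.5` at CV = 1); raising `cv_chi`
  extends the range.
- Confidence intervals are Jacobian-linearized, not profile likelihoods;
  coverage was only verified at small noise (`sd ~ 1e-3` on `phi_R`).
- The model is linear in masses and not positivity-preserving during
  strong transients; only steady states are biologically interpretable.
- External datasets (published `(mu, phi_R)` tables) are not bundled;
  `growthlaw fit` accepts any CSV with `mu`, `phi_R` columns.
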