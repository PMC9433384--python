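"""Fitting the rational growth law phi_R = (mu + c1)/(c2 mu + c3) to
(growth rate, ribosomal fraction) datasets.

Covers: nonlinear least squares with Jacobian-linearized 95% confidence
intervals, inversion of the fitted coefficients to biological parameters
(phi0, k_R, <k>_chi) with min/max propagation over the confidence box, the
subsampling-RMSE universality test, and per-condition / per-gene
predictions against measured proteomes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .model import (
    Environment,
    GrowthLawCoefficients,
    GrowthLawError,
    ProteomeParams,
    full_coefficients,
    phiR_growth_law,
    predict_phi,
)

__all__ = [
    "FitFailureError",
    "PoleError",
    "InfeasibleCoefficientsError",
    "GrowthLawDataset",
    "FitResult",
    "SubsampleRMSEResult",
    "PhiPredictionScore",
    "fit_growth_law",
    "invert_coefficients",
    "bound_derived_params",
    "with_derived_params",
    "subsample_rmse_experiment",
    "predict_phiR_for_conditions",
    "evaluate_phi_prediction",
]


class FitFailureError(GrowthLawError):
    """The nonlinear fit did not converge or its Jacobian is singular."""


class PoleError(GrowthLawError):
    """Fitted denominator crosses zero inside the data's growth-rate range."""


class InfeasibleCoefficientsError(GrowthLawError):
    """Coefficient triple maps to unphysical biological parameters."""


@dataclass
class GrowthLawDataset:
    """Records of (mu [1/min], phi_R) with optional condition labels."""

    mu: np.ndarray
    phi_R: np.ndarray
    condition: list[str] | None = None

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.phi_R = np.asarray(self.phi_R, dtype=float)
        if self.mu.shape != self.phi_R.shape or self.mu.ndim != 1:
            raise ValueError("mu and phi_R must be equal-length 1-D arrays")
        if np.any(self.mu < 0):
            raise ValueError("growth rates must be nonnegative")
        if np.any((self.phi_R <= 0) | (self.phi_R >= 1)):
            raise ValueError("phi_R values must lie strictly inside (0, 1)")

    def __len__(self) -> int:
        return self.mu.size

    @classmethod
    def from_csv(cls, path) -> "GrowthLawDataset":
        df = pd.read_csv(path, float_precision="round_trip")
        missing = {"mu", "phi_R"} - set(df.columns)
        if missing:
            raise ValueError(f"growth-law CSV missing columns: {sorted(missing)}")
        cond = df["condition"].astype(str).tolist() if "condition" in df else None
        return cls(df["mu"].to_numpy(), df["phi_R"].to_numpy(), cond)

    def to_csv(self, path) -> None:
        df = pd.DataFrame({"mu": self.mu, "phi_R": self.phi_R})
        if self.condition is not None:
            df["condition"] = self.condition
        df.to_csv(path, index=False, float_format="%.17g")


@dataclass
class FitResult:
    """Fitted growth-law coefficients with uncertainty and (optionally)
    derived biological parameters."""

    c1: float
    c2: float
    c3: float
    ci: np.ndarray               # shape (3, 2): 95% interval per coefficient
    cov: np.ndarray              # 3x3 linearized covariance
    rmse: float                  # sqrt(SS_res / n)
    n: int
    # populated by with_derived_params:
    derived: dict | None = None          # {"phi0": x, "k_R": x, "k_chi": x}
    derived_bounds: dict | None = None   # {"phi0": (lo, hi), ...}
    inversion_inputs: dict | None = None  # {"alpha_R":..., "alpha_phi":..., "m_R":...}

    @property
    def coefficients(self) -> GrowthLawCoefficients:
        return GrowthLawCoefficients(c1=self.c1, c2=self.c2, c3=self.c3)

    def to_json(self, path=None) -> str:
        payload = {
            "c1": self.c1,
            "c2": self.c2,
            "c3": self.c3,
            "ci_95": self.ci.tolist(),
            "cov": self.cov.tolist(),
            "rmse": self.rmse,
            "n": self.n,
            "derived": self.derived,
            "derived_bounds": self.derived_bounds,
            "inversion_inputs": self.inversion_inputs,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _curve(mu: np.ndarray, c1: float, c2: float, c3: float) -> np.ndarray:
    return (mu + c1) / (c2 * mu + c3)


def _initial_guess(mu: np.ndarray, phi_R: np.ndarray) -> np.ndarray:
    """Constant-speed straight line phi_R ~ mu/c3 + c1/c3 as the null model."""
    slope, intercept = np.polyfit(mu, phi_R, 1)
    if slope <= 0 or intercept <= 0:
        c3 = 1.0 / max(slope, 1e-6)
        c1 = max(intercept, 1e-3) * c3
    else:
        c3 = 1.0 / slope
        c1 = intercept * c3
    return np.array([c1, 0.0, c3])


def fit_growth_law(data: GrowthLawDataset, init=None) -> FitResult:
    """Least-squares fit of (mu + c1)/(c2 mu + c3) to the dataset.

    95% confidence intervals come from the Jacobian-linearized covariance
    with a Student-t quantile at n - 3 degrees of freedom; rmse is the root
    mean squared residual of phi_R (normalized by n).
    """
    n = len(data)
    if n < 4:
        raise ValueError("need at least 4 points for a 3-parameter fit")
    mu, phi = data.mu, data.phi_R
    x0 = np.asarray(init, dtype=float) if init is not None else _initial_guess(mu, phi)

    def resid(c):
        denom = c[1] * mu + c[2]
        bad = np.abs(denom) < 1e-300
        if np.any(bad):
            denom = np.where(bad, 1e-300, denom)
        return (mu + c[0]) / denom - phi

    sol = optimize.least_squares(resid, x0, method="lm", xtol=1e-14, ftol=1e-14)
    if not sol.success:
        raise FitFailureError(f"optimizer did not converge: {sol.message}")
    c1, c2, c3 = sol.x
    denom = c2 * mu + c3
    if np.any(denom <= 0):
        pole = -c3 / c2 if c2 != 0 else np.inf
        raise PoleError(
            f"fitted denominator crosses zero inside the data range (pole at mu = {pole:g})"
        )
    ss_res = float(np.sum(sol.fun**2))
    rmse = float(np.sqrt(ss_res / n))
    jtj = sol.jac.T @ sol.jac
    try:
        jtj_inv = np.linalg.inv(jtj)
    except np.linalg.LinAlgError as exc:
        raise FitFailureError(f"singular Jacobian: {exc}") from exc
    s2 = ss_res / (n - 3)
    cov = jtj_inv * s2
    tq = stats.t.ppf(0.975, n - 3)
    diag = np.diag(cov)
    # a numerically singular Jacobian can produce tiny negative variances;
    # report NaN half-widths instead of raising a floating-point warning
    half = tq * np.sqrt(np.where(diag >= 0, diag, np.nan))
    ci = np.column_stack([sol.x - half, sol.x + half])
    return FitResult(
        c1=float(c1), c2=float(c2), c3=float(c3), ci=ci, cov=cov, rmse=rmse, n=n
    )


def invert_coefficients(
    c1: float,
    c2: float,
    c3: float,
    alpha_R: float,
    alpha_phi: float,
    m_R: float,
) -> tuple[float, float, float]:
    """Invert the growth-law coefficients to (phi0, k_R, <k>_chi) given the
    degradation rates and ribosome mass.  Exact inverse of the forward
    coefficient map."""
    if c2 >= 1:
        raise InfeasibleCoefficientsError("c2 >= 1 leaves k_R undefined")
    k_chi = m_R * (c3 - alpha_phi + alpha_R * (1.0 - c2))
    if k_chi <= 0:
        raise InfeasibleCoefficientsError(
            f"inferred <k>_chi = {k_chi:g} Da/min is nonpositive"
        )
    k_R = k_chi / (1.0 - c2)
    phi0 = (c1 - alpha_phi) * m_R / k_chi
    return phi0, k_R, k_chi


def bound_derived_params(
    fit: FitResult,
    alpha_R: float | None = None,
    alpha_phi: float | None = None,
    m_R: float | None = None,
    n_grid: int = 21,
) -> dict[str, tuple[float, float]]:
    """Min/max of phi0, k_R and <k>_chi over the 3-D confidence box.

    Dense ``n_grid**3`` evaluation plus bounded local refinement from the
    best grid cell.  Infeasible corners (c2 >= 1 or <k>_chi <= 0) are
    excluded with a warning.
    """
    if alpha_R is None or alpha_phi is None or m_R is None:
        if fit.inversion_inputs is None:
            raise ValueError("inversion inputs (alpha_R, alpha_phi, m_R) required")
        alpha_R = fit.inversion_inputs["alpha_R"]
        alpha_phi = fit.inversion_inputs["alpha_phi"]
        m_R = fit.inversion_inputs["m_R"]

    lo, hi = fit.ci[:, 0].copy(), fit.ci[:, 1].copy()
    if hi[1] >= 1.0:
        if lo[1] >= 1.0:
            raise InfeasibleCoefficientsError("entire c2 interval is >= 1")
        warnings.warn(
            "confidence box crosses c2 = 1; bounds computed on the feasible sub-box",
            stacklevel=2,
        )
        hi[1] = 1.0 - 1e-12

    axes = [np.linspace(lo[i], hi[i], n_grid) for i in range(3)]
    C1, C2, C3 = np.meshgrid(*axes, indexing="ij")
    k_chi = m_R * (C3 - alpha_phi + alpha_R * (1.0 - C2))
    feasible = k_chi > 0
    if not feasible.any():
        raise InfeasibleCoefficientsError("no feasible point in the confidence box")
    if not feasible.all():
        warnings.warn(
            "part of the confidence box implies <k>_chi <= 0; excluded",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        maps = {
            "phi0": (C1 - alpha_phi) * m_R / k_chi,
            "k_R": k_chi / (1.0 - C2),
            "k_chi": k_chi,
        }

    def refine(x0, sign):
        def f(c):
            try:
                vals = invert_coefficients(c[0], c[1], c[2], alpha_R, alpha_phi, m_R)
            except InfeasibleCoefficientsError:
                return np.inf
            return sign * {"phi0": vals[0], "k_R": vals[1], "k_chi": vals[2]}[name]

        res = optimize.minimize(
            f, x0, method="Nelder-Mead", bounds=list(zip(lo, hi)),
            options={"xatol": 1e-12, "fatol": 1e-14},
        )
        return sign * res.fun if np.isfinite(res.fun) else None

    bounds = {}
    for name, grid_vals in maps.items():
        masked = np.where(feasible, grid_vals, np.nan)
        i_min = np.unravel_index(np.nanargmin(masked), masked.shape)
        i_max = np.unravel_index(np.nanargmax(masked), masked.shape)
        best_min = float(masked[i_min])
        best_max = float(masked[i_max])
        x_min = np.array([axes[d][i_min[d]] for d in range(3)])
        x_max = np.array([axes[d][i_max[d]] for d in range(3)])
        r_min = refine(x_min, +1.0)
        r_max = refine(x_max, -1.0)
        if r_min is not None:
            best_min = min(best_min, float(r_min))
        if r_max is not None:
            best_max = max(best_max, float(r_max))
        bounds[name] = (best_min, best_max)
    return bounds


def with_derived_params(
    fit: FitResult, alpha_R: float, alpha_phi: float, m_R: float
) -> FitResult:
    """Attach the inverted biological parameters and their confidence-box
    bounds to a fit result."""
    phi0, k_R, k_chi = invert_coefficients(
        fit.c1, fit.c2, fit.c3, alpha_R, alpha_phi, m_R
    )
    fit.inversion_inputs = {"alpha_R": alpha_R, "alpha_phi": alpha_phi, "m_R": m_R}
    fit.derived = {"phi0": phi0, "k_R": k_R, "k_chi": k_chi}
    fit.derived_bounds = {
        k: list(v) for k, v in bound_derived_params(fit).items()
    }
    return fit


@dataclass
class SubsampleRMSEResult:
    """Distribution of fit RMSEs across random subsamples of a pool."""

    rmse: np.ndarray
    median: float
    n_failures: int
    n_points: int
    n_reps: int


def _pool_to_arrays(pool) -> tuple[np.ndarray, np.ndarray]:
    if hasattr(pool, "records"):            # EnsembleResult
        df = pool.records
        return df["mu_per_min"].to_numpy(), df["phi_R"].to_numpy()
    if isinstance(pool, pd.DataFrame):
        mu_col = "mu" if "mu" in pool else "mu_per_min"
        return pool[mu_col].to_numpy(), pool["phi_R"].to_numpy()
    if isinstance(pool, GrowthLawDataset):
        return pool.mu, pool.phi_R
    raise TypeError(f"unsupported pool type {type(pool).__name__}")


def subsample_rmse_experiment(
    pool,
    n_points: int = 20,
    n_reps: int = 5000,
    seed: int = 0,
) -> SubsampleRMSEResult:
    """Universality test: repeatedly draw ``n_points`` environments without
    replacement, fit the growth-law curve, and collect the RMSEs.

    A pool whose environments share one (I_chi_k, I_phi_alpha) pair lies on
    a single exact curve and yields near-zero RMSEs; heterogeneous pools do
    not.  Failed replicate fits are excluded and counted.
    """
    mu, phi = _pool_to_arrays(pool)
    if mu.size < n_points:
        raise ValueError("pool smaller than the requested subsample")
    rng = np.random.default_rng(seed)
    rmses = []
    failures = 0
    for _ in range(n_reps):
        idx = rng.choice(mu.size, size=n_points, replace=False)
        try:
            res = fit_growth_law(GrowthLawDataset(mu[idx], phi[idx]))
        except (GrowthLawError, ValueError):
            failures += 1
            continue
        rmses.append(res.rmse)
    rmse_arr = np.asarray(rmses)
    if rmse_arr.size == 0:
        raise FitFailureError("every replicate fit failed")
    return SubsampleRMSEResult(
        rmse=rmse_arr,
        median=float(np.median(rmse_arr)),
        n_failures=failures,
        n_points=n_points,
        n_reps=n_reps,
    )


def predict_phiR_for_conditions(
    params: ProteomeParams,
    mu,
    I_chi_k,
    I_phi_alpha,
    phi0: float | None = None,
):
    """Predict phi_R from (mu, I_chi_k, I_phi_alpha) for one or more
    conditions.

    Builds <k>_chi = <k>(1 + I_chi_k) and <alpha>_phi = <alpha>(1 +
    I_phi_alpha) from the proteome's arithmetic means and evaluates the full
    growth-law curve.  ``phi0`` overrides the proteome's value when a shared
    inactive fraction is imposed across conditions.
    """
    mu_arr = np.atleast_1d(np.asarray(mu, dtype=float))
    I_k = np.broadcast_to(np.asarray(I_chi_k, dtype=float), mu_arr.shape)
    I_a = np.broadcast_to(np.asarray(I_phi_alpha, dtype=float), mu_arr.shape)
    if np.any(I_k <= -1) or np.any(I_a <= -1):
        raise ValueError("correlation indices must exceed -1")
    if phi0 is not None:
        params = ProteomeParams(
            k=params.k, alpha=params.alpha, m_R=params.m_R, phi0=phi0
        )
    out = np.empty_like(mu_arr)
    for i in range(mu_arr.size):
        coeffs = full_coefficients(
            params,
            k_chi=params.mean_k * (1.0 + I_k.flat[i]),
            alpha_phi=params.mean_alpha * (1.0 + I_a.flat[i]),
        )
        out.flat[i] = phiR_growth_law(float(mu_arr.flat[i]), coeffs)
    return float(out[0]) if np.isscalar(mu) or np.asarray(mu).ndim == 0 else out


@dataclass
class PhiPredictionScore:
    """Pearson correlations between predicted and measured non-ribosomal
    mass fractions, for the full model and its two ablations."""

    rho_full: float
    rho_no_degradation: float      # alpha_i = 0
    rho_homogeneous_speed: float   # k_i = <k>


def evaluate_phi_prediction(
    params: ProteomeParams,
    env: Environment,
    mu: float,
    measured_phi,
) -> PhiPredictionScore:
    """Score per-gene composition predictions against a measured proteome.

    The measured vector covers all genes (position 0 ribosomal); only
    non-ribosomal genes enter the correlations.
    """
    measured = np.asarray(measured_phi, dtype=float)
    if measured.size != params.n_genes:
        raise ValueError("measured phi length does not match proteome size")
    if params.n_genes - 1 < 3:
        raise GrowthLawError("need at least 3 non-ribosomal genes for a correlation")

    def rho(pred_params):
        pred = predict_phi(pred_params, env, mu)
        return float(stats.pearsonr(pred[1:], measured[1:]).statistic)

    from dataclasses import replace

    return PhiPredictionScore(
        rho_full=rho(params),
        rho_no_degradation=rho(replace(params, alpha=np.zeros_like(params.alpha))),
        rho_homogeneous_speed=rho(
            replace(params, k=np.full_like(params.k, params.mean_k))
        ),
    )
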