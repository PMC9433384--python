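"""Proteome and environment ensembles.

One proteome (per-protein translation speeds and degradation rates) is
sampled once and held fixed; environments differ only in their ribosome
allocation vector ``chi``.  Environments can be sampled freely, or targeted
to preselected correlation indices ``I_chi_k`` (allocation vs. speed) and
``I_phi_alpha`` (composition vs. degradation) through a Gaussian-copula
coupling of the allocations to the speed/degradation ranks.

Randomness: a single master seed is split into documented substreams —
``[seed, 0]`` for the proteome, ``[seed, 1, j]`` for environment ``j`` and
``[seed, 2, j]`` for noise draws — so any piece can be regenerated in
isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq, root
from scipy.stats import norm

from .model import (
    Environment,
    GrowthLawError,
    ProteomeParams,
    SteadyState,
    correlation_index,
    steady_state_solve,
)

__all__ = [
    "EnsembleConfig",
    "EnsembleResult",
    "InfeasibleTargetError",
    "sample_proteome",
    "sample_environment",
    "sample_environment_targeted",
    "perturb_with_noise",
    "gaussian_index_pool",
    "run_ensemble",
]

MODES = ("full", "no_degradation", "homogeneous_speed")


class InfeasibleTargetError(GrowthLawError):
    """A preselected correlation index cannot be realized."""


class _BracketMiss(Exception):
    """Internal: current draw cannot bracket the target; redraw."""


@dataclass
class EnsembleConfig:
    """Study conditions for an environment ensemble.

    Defaults are the measured S. cerevisiae values used throughout:
    k_R = 2.07e4 Da/min, <k> = 4.80e4 Da/min, alpha_R = 4.83e-4 /min,
    <alpha> = 1.10e-3 /min, phi0 = 0.08, 4000 genes, and unit coefficients
    of variation for the lognormal speed/degradation/allocation spreads.
    """

    n_genes: int = 4000
    mean_k: float = 4.80e4       # Da/min, non-ribosomal arithmetic mean
    k_R: float = 2.07e4          # Da/min
    mean_alpha: float = 1.10e-3  # 1/min, non-ribosomal arithmetic mean
    alpha_R: float = 4.83e-4     # 1/min
    cv_k: float = 1.0
    cv_alpha: float = 1.0
    cv_chi: float = 1.0
    phi0: float = 0.08
    m_R: float = 1.40e6          # Da, full ribosome protein mass
    chiR_range: tuple[float, float] = (0.05, 0.45)
    n_environments: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 2:
            raise ValueError("n_genes must be >= 2")
        if min(self.mean_k, self.k_R, self.m_R) <= 0:
            raise ValueError("speeds and m_R must be positive")
        if min(self.mean_alpha, self.alpha_R) < 0:
            raise ValueError("degradation rates must be nonnegative")
        if min(self.cv_k, self.cv_alpha, self.cv_chi) < 0:
            raise ValueError("CVs must be nonnegative")
        lo, hi = self.chiR_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("chiR_range must be an interval inside (0, 1)")
        if not (0.0 <= self.phi0 < 1.0):
            raise ValueError("phi0 must lie in [0, 1)")


@dataclass
class EnsembleResult:
    """Per-environment steady-state records plus provenance."""

    records: pd.DataFrame        # env_id, mu_per_min, phi_R, I_chi_k, ...
    config: EnsembleConfig
    mode: str
    params: ProteomeParams

    COLUMNS = (
        "env_id",
        "mu_per_min",
        "phi_R",
        "I_chi_k",
        "I_phi_alpha",
        "k_chi",
        "alpha_phi",
        "seed",
    )

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False, float_format="%.17g")

    @staticmethod
    def read_tsv(path) -> pd.DataFrame:
        return pd.read_csv(path, sep="\t", float_precision="round_trip")


def _lognormal(rng: np.random.Generator, mean: float, cv: float, n: int) -> np.ndarray:
    """Lognormal sample with given mean and coefficient of variation
    (standard moment matching).  cv = 0 or mean = 0 degenerate to constants."""
    if mean == 0.0:
        return np.zeros(n)
    if cv == 0.0:
        return np.full(n, mean)
    sigma2 = np.log1p(cv * cv)
    mu_log = np.log(mean) - 0.5 * sigma2
    return rng.lognormal(mu_log, np.sqrt(sigma2), size=n)


def _rng(seed, *key) -> np.random.Generator:
    return np.random.default_rng([int(seed), *map(int, key)])


def sample_proteome(config: EnsembleConfig) -> ProteomeParams:
    """Draw one proteome: non-ribosomal k_i and alpha_i lognormal with the
    configured (mean, CV); entry 0 set exactly to (k_R, alpha_R)."""
    rng = _rng(config.seed, 0)
    n = config.n_genes
    k = np.empty(n)
    alpha = np.empty(n)
    k[0], alpha[0] = config.k_R, config.alpha_R
    k[1:] = _lognormal(rng, config.mean_k, config.cv_k, n - 1)
    alpha[1:] = _lognormal(rng, config.mean_alpha, config.cv_alpha, n - 1)
    return ProteomeParams(k=k, alpha=alpha, m_R=config.m_R, phi0=config.phi0)


def _normal_scores(x: np.ndarray) -> np.ndarray:
    """Gaussian-copula latent scores of a vector via mid-ranks; a
    zero-variance vector maps to all-zero scores."""
    if np.ptp(x) == 0.0:
        return np.zeros_like(x)
    order = np.argsort(x, kind="stable")
    ranks = np.empty_like(order, dtype=float)
    ranks[order] = np.arange(1, x.size + 1)
    return norm.ppf((ranks - 0.5) / x.size)


def _chi_from_latent(
    config: EnsembleConfig,
    chi_R: float,
    scores: np.ndarray,
    noise: np.ndarray,
    rho: np.ndarray,
) -> Environment:
    """Build an allocation vector whose log couples to the latent scores
    with copula loadings ``rho`` (one per score column)."""
    sigma = np.sqrt(np.log1p(config.cv_chi**2)) if config.cv_chi > 0 else 0.0
    load = np.sqrt(max(0.0, 1.0 - float(np.dot(rho, rho))))
    z = scores @ rho + load * noise
    raw = np.exp(sigma * z)
    chi = np.empty(config.n_genes)
    chi[0] = chi_R
    chi[1:] = (1.0 - chi_R) * raw / raw.sum()
    return Environment(chi=chi)


def sample_environment(
    config: EnsembleConfig, params: ProteomeParams, env_index: int = 0
) -> Environment:
    """Random environment: chi_R uniform on chiR_range, non-ribosomal
    allocations lognormal (CV = cv_chi) renormalized to 1 - chi_R."""
    rng = _rng(config.seed, 1, env_index)
    chi_R = rng.uniform(*config.chiR_range)
    raw = _lognormal(rng, 1.0, config.cv_chi, config.n_genes - 1)
    chi = np.empty(config.n_genes)
    chi[0] = chi_R
    chi[1:] = (1.0 - chi_R) * raw / raw.sum()
    return Environment(chi=chi)


def sample_environment_targeted(
    config: EnsembleConfig,
    params: ProteomeParams,
    target_I_chi_k: float,
    target_I_phi_alpha: float | None = None,
    tol: float = 1e-3,
    env_index: int = 0,
    max_attempts: int = 10_000,
) -> Environment:
    """Environment with a preselected I_chi_k (and optionally I_phi_alpha).

    The log-allocations are coupled to the Gaussian-copula scores of k (and
    alpha) with loadings rho; the loadings are root-found so the realized
    indices hit the targets, then the draw is accepted only if within
    ``tol`` (otherwise fresh noise is drawn, up to ``max_attempts``).
    I_phi_alpha is a property of the solved steady state, so targeting it
    requires a steady-state solve per trial point.
    """
    if target_I_chi_k <= -1 or (
        target_I_phi_alpha is not None and target_I_phi_alpha <= -1
    ):
        raise ValueError("correlation-index targets must exceed -1")
    rng = _rng(config.seed, 1, env_index)
    k_nr, a_nr = params.k[1:], params.alpha[1:]
    s_k = _normal_scores(k_nr)
    s_a = _normal_scores(a_nr)
    if np.all(s_k == 0) and abs(target_I_chi_k) > tol:
        raise InfeasibleTargetError(
            "constant translation speeds force I_chi_k = 0; target unreachable"
        )
    two_targets = target_I_phi_alpha is not None
    if two_targets and np.all(s_a == 0) and abs(target_I_phi_alpha) > tol:
        raise InfeasibleTargetError(
            "constant degradation rates force a fixed I_phi_alpha; target unreachable"
        )
    scores = np.column_stack([s_k, s_a])

    for _ in range(max_attempts):
        chi_R = rng.uniform(*config.chiR_range)
        noise = rng.standard_normal(config.n_genes - 1)

        def I_chi(rho_vec: np.ndarray) -> float:
            env = _chi_from_latent(config, chi_R, scores, noise, rho_vec)
            return correlation_index(env.chi_tilde, k_nr)

        def I_phi(rho_vec: np.ndarray) -> float:
            env = _chi_from_latent(config, chi_R, scores, noise, rho_vec)
            return steady_state_solve(params, env).I_phi_alpha

        def solve_1d(objective, target):
            """Brent on a single copula loading; None if no bracket or if the
            draw has no sustainable steady state (e.g. chi_R too low against
            degradation)."""
            f = lambda r: objective(r) - target
            try:
                if f(-0.999) * f(0.999) > 0:
                    return None
                return brentq(f, -0.999, 0.999, xtol=1e-12)
            except GrowthLawError:
                return None

        if not two_targets:
            rho1 = solve_1d(lambda r: I_chi(np.array([r, 0.0])), target_I_chi_k)
            if rho1 is None:
                continue  # target outside this draw's envelope; retry
            env = _chi_from_latent(config, chi_R, scores, noise, np.array([rho1, 0.0]))
            if abs(correlation_index(env.chi_tilde, k_nr) - target_I_chi_k) <= tol:
                return env
            continue

        if np.all(s_k == 0):
            # speeds constant: I_chi_k == 0 for any draw; target only the
            # degradation index through the second loading
            rho2 = solve_1d(lambda r: I_phi(np.array([0.0, r])), target_I_phi_alpha)
            if rho2 is None:
                continue
            return _chi_from_latent(config, chi_R, scores, noise, np.array([0.0, rho2]))
        if np.all(s_a == 0):
            rho1 = solve_1d(lambda r: I_chi(np.array([r, 0.0])), target_I_chi_k)
            if rho1 is None:
                continue
            env = _chi_from_latent(config, chi_R, scores, noise, np.array([rho1, 0.0]))
            try:
                realized = steady_state_solve(params, env).I_phi_alpha
            except GrowthLawError:
                continue
            if abs(realized - target_I_phi_alpha) <= tol:
                return env
            continue

        # nested search: for each rho2 (alpha coupling) the inner Brent finds
        # the rho1 (speed coupling) matching I_chi_k — cheap, no steady-state
        # solve — and the outer Brent drives the solved I_phi_alpha to target
        def rho1_for(rho2: float) -> float | None:
            lim = np.sqrt(max(1e-12, 0.998 - rho2 * rho2))
            f = lambda r1: I_chi(np.array([r1, rho2])) - target_I_chi_k
            if f(-lim) * f(lim) > 0:
                return None
            return brentq(f, -lim, lim, xtol=1e-12)

        def outer(rho2: float) -> float:
            r1 = rho1_for(rho2)
            if r1 is None:
                raise _BracketMiss
            try:
                state = steady_state_solve(
                    params, _chi_from_latent(config, chi_R, scores, noise,
                                             np.array([r1, rho2]))
                )
            except GrowthLawError:
                raise _BracketMiss
            return state.I_phi_alpha - target_I_phi_alpha

        # the speed coupling needed for I_chi_k caps how much loading is
        # left for the alpha coupling; bound the outer search accordingly
        r10 = rho1_for(0.0)
        if r10 is None:
            continue
        r2max = 0.98 * np.sqrt(max(1e-12, 0.998 - r10 * r10))
        try:
            lo, hi = outer(-r2max), outer(r2max)
            if lo * hi > 0:
                continue
            rho2 = brentq(outer, -r2max, r2max, xtol=1e-12)
            rho1 = rho1_for(rho2)
        except _BracketMiss:
            continue
        if rho1 is None:
            continue
        env = _chi_from_latent(config, chi_R, scores, noise, np.array([rho1, rho2]))
        state = steady_state_solve(params, env)
        if (
            abs(state.I_chi_k - target_I_chi_k) <= tol
            and abs(state.I_phi_alpha - target_I_phi_alpha) <= tol
        ):
            return env

    raise InfeasibleTargetError(
        f"could not realize targets (I_chi_k={target_I_chi_k}, "
        f"I_phi_alpha={target_I_phi_alpha}) within tol={tol} "
        f"after {max_attempts} attempts"
    )


def perturb_with_noise(obj, noise_cv: float, seed: int):
    """Multiplicative unit-mean lognormal noise, entrywise.

    For a :class:`ProteomeParams` the speeds and degradation rates are
    perturbed; for an :class:`Environment` the allocations are perturbed and
    renormalized to sum to 1.  ``noise_cv = 0`` returns an identical copy.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be nonnegative")
    rng = _rng(seed, 2)

    def factors(n):
        return _lognormal(rng, 1.0, noise_cv, n)

    if isinstance(obj, ProteomeParams):
        n = obj.n_genes
        return ProteomeParams(
            k=obj.k * factors(n),
            alpha=obj.alpha * factors(n),
            m_R=obj.m_R,
            phi0=obj.phi0,
        )
    if isinstance(obj, Environment):
        chi = obj.chi * factors(obj.chi.size)
        return Environment(chi=chi / chi.sum())
    raise TypeError(f"cannot perturb object of type {type(obj).__name__}")


def gaussian_index_pool(
    config: EnsembleConfig,
    mean_I_chi_k: float = 0.5,
    mean_I_phi_alpha: float = 0.0,
    sigma: float = 0.3,
    mode: str = "full",
    tol: float = 1e-3,
    max_redraws: int = 50,
) -> EnsembleResult:
    """Environment pool whose (I_chi_k, I_phi_alpha) pairs are drawn from
    independent Gaussians around the given means.

    Index pairs that cannot be realized by any allocation vector at the
    configured lognormal spreads (the copula loadings are confined to the
    unit disc) are redrawn, so the realized pool follows a feasibility-
    truncated version of the nominal Gaussian.  Pairs are also kept > -0.95
    (the indices are bounded below by -1).
    """
    params = _apply_mode(sample_proteome(config), mode)
    rng = _rng(config.seed, 5)
    rows = []
    for j in range(config.n_environments):
        env = None
        for attempt in range(max_redraws):
            t1 = max(float(rng.normal(mean_I_chi_k, sigma)), -0.95)
            t2 = max(float(rng.normal(mean_I_phi_alpha, sigma)), -0.95)
            try:
                env = sample_environment_targeted(
                    config, params, t1, t2, tol=tol,
                    env_index=j * max_redraws + attempt, max_attempts=200,
                )
                break
            except InfeasibleTargetError:
                continue
        if env is None:
            raise InfeasibleTargetError(
                f"environment {j}: no feasible index pair after {max_redraws} redraws"
            )
        state = steady_state_solve(params, env)
        rows.append(
            {
                "env_id": j,
                "mu_per_min": state.mu,
                "phi_R": state.phi_R,
                "I_chi_k": state.I_chi_k,
                "I_phi_alpha": state.I_phi_alpha,
                "k_chi": state.k_chi,
                "alpha_phi": state.alpha_phi,
                "seed": config.seed,
            }
        )
    records = pd.DataFrame(rows, columns=list(EnsembleResult.COLUMNS))
    return EnsembleResult(records=records, config=config, mode=mode, params=params)


def _apply_mode(params: ProteomeParams, mode: str) -> ProteomeParams:
    if mode == "full":
        return params
    if mode == "no_degradation":
        return replace(params, alpha=np.zeros_like(params.alpha))
    if mode == "homogeneous_speed":
        return replace(params, k=np.full_like(params.k, params.mean_k))
    raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")


def run_ensemble(
    config: EnsembleConfig,
    mode: str = "full",
    targets=None,
    tol: float = 1e-3,
) -> EnsembleResult:
    """Sample one proteome, then solve ``n_environments`` environments.

    ``mode='no_degradation'`` forces alpha = 0 (heterogeneous speeds only);
    ``mode='homogeneous_speed'`` forces k = <k> everywhere (degradation
    only).  ``targets`` may be a per-environment list of I_chi_k values or
    of (I_chi_k, I_phi_alpha) pairs, in which case targeted environments
    are built.
    """
    params = _apply_mode(sample_proteome(config), mode)
    if targets is not None and len(targets) != config.n_environments:
        raise ValueError("targets must have one entry per environment")

    rows = []
    for j in range(config.n_environments):
        try:
            if targets is None:
                env = sample_environment(config, params, env_index=j)
            else:
                t = targets[j]
                if np.isscalar(t):
                    env = sample_environment_targeted(
                        config, params, float(t), None, tol=tol, env_index=j
                    )
                else:
                    t1, t2 = t
                    env = sample_environment_targeted(
                        config,
                        params,
                        float(t1),
                        None if t2 is None else float(t2),
                        tol=tol,
                        env_index=j,
                    )
            state = steady_state_solve(params, env)
        except GrowthLawError as exc:
            raise type(exc)(f"environment {j}: {exc}") from exc
        rows.append(
            {
                "env_id": j,
                "mu_per_min": state.mu,
                "phi_R": state.phi_R,
                "I_chi_k": state.I_chi_k,
                "I_phi_alpha": state.I_phi_alpha,
                "k_chi": state.k_chi,
                "alpha_phi": state.alpha_phi,
                "seed": config.seed,
            }
        )
    records = pd.DataFrame(rows, columns=list(EnsembleResult.COLUMNS))
    return EnsembleResult(records=records, config=config, mode=mode, params=params)
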