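"""Synthetic studies with known ground truth.

Emulates the *processed* forms of ribosome-profiling and proteomics
experiments: per-condition gene tables of ribosome allocation count
fractions (chi), protein mass fractions (phi), translation speeds (k = v*a),
degradation rates (alpha) and protein lengths, plus OD600 growth curves and
(mu, phi_R) growth-law datasets.  Every emitted quantity derives from an
exactly solved steady state, so pipeline outputs can be checked against the
retained ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import GrowthLawDataset
from .model import (
    Environment,
    GrowthLawCoefficients,
    ProteomeParams,
    SteadyState,
    phiR_growth_law,
    steady_state_solve,
)
from .simulate import (
    EnsembleConfig,
    _lognormal,
    _rng,
    sample_environment_targeted,
    sample_proteome,
)

__all__ = [
    "SyntheticStudy",
    "generate_study",
    "generate_growth_law_dataset",
    "generate_od_curve",
    "DEFAULT_INDEX_SCHEDULE",
]

# Per-condition (I_chi_k, I_phi_alpha) targets.  The speed index falls as
# growth slows while the degradation index stays put near -0.33; the default
# schedule mirrors that qualitative pattern with magnitudes the lognormal
# copula can realize at unit coefficients of variation (the allocation-speed
# index is capped near exp(sigma_chi * sigma_k) - 1 ~ 1 for cv = 1).
DEFAULT_INDEX_SCHEDULE = ((0.5, -0.33), (0.35, -0.33), (0.25, -0.33), (0.15, -0.33))

MEAN_AA_MASS = 110.0      # Da per residue, used for synthetic gene masses
MEAN_LENGTH = 450.0       # amino acids; lognormal with CV 0.5
LENGTH_CV = 0.5


@dataclass
class SyntheticStudy:
    """Ground truth plus emitted (possibly noisy) tables for one study."""

    params: ProteomeParams
    environments: list[Environment]
    states: list[SteadyState]
    gene_tables: list[pd.DataFrame]      # one per condition
    od_curves: list[pd.DataFrame]        # columns time_min, od
    index_schedule: tuple
    noise_cvs: dict
    seed: int

    @property
    def n_conditions(self) -> int:
        return len(self.environments)

    def growth_law_points(self) -> GrowthLawDataset:
        return GrowthLawDataset(
            mu=np.array([s.mu for s in self.states]),
            phi_R=np.array([s.phi_R for s in self.states]),
            condition=[f"cond{i}" for i in range(self.n_conditions)],
        )

    def write(self, outdir) -> list[Path]:
        """Materialize all tables as TSV/CSV under ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        for i, (table, od) in enumerate(zip(self.gene_tables, self.od_curves)):
            p = outdir / f"genes_cond{i}.tsv"
            table.to_csv(p, sep="\t", index=False, float_format="%.17g")
            written.append(p)
            p = outdir / f"od_cond{i}.csv"
            od.to_csv(p, index=False, float_format="%.17g")
            written.append(p)
        p = outdir / "growth_law.csv"
        self.growth_law_points().to_csv(p)
        written.append(p)
        return written


def _noisy(values: np.ndarray, cv: float, rng: np.random.Generator) -> np.ndarray:
    if cv == 0.0:
        return values.copy()
    return values * _lognormal(rng, 1.0, cv, values.size)


def generate_study(
    n_genes: int = 200,
    n_conditions: int = 4,
    index_schedule=None,
    noise_cvs: dict | None = None,
    seed: int = 0,
    config: EnsembleConfig | None = None,
) -> SyntheticStudy:
    """Build a full synthetic study.

    One proteome is sampled once; per-condition environments are targeted to
    the scheduled (I_chi_k, I_phi_alpha) pairs; steady states are solved
    exactly; gene tables and OD curves are emitted with multiplicative
    unit-mean lognormal measurement noise per table (``noise_cvs`` keys
    ``chi``, ``phi``, ``k``, ``alpha``, ``od``; default all 0).  Fraction
    columns are renormalized after noise.
    """
    if index_schedule is None:
        index_schedule = DEFAULT_INDEX_SCHEDULE[:n_conditions]
    if len(index_schedule) != n_conditions:
        raise ValueError("index_schedule must have one entry per condition")
    noise = {"chi": 0.0, "phi": 0.0, "k": 0.0, "alpha": 0.0, "od": 0.0}
    if noise_cvs:
        unknown = set(noise_cvs) - set(noise)
        if unknown:
            raise ValueError(f"unknown noise keys: {sorted(unknown)}")
        noise.update(noise_cvs)

    if config is None:
        config = EnsembleConfig(n_genes=n_genes, seed=seed)
    params = sample_proteome(config)

    rng_struct = _rng(seed, 3)
    lengths = np.maximum(
        np.rint(_lognormal(rng_struct, MEAN_LENGTH, LENGTH_CV, n_genes)), 30
    ).astype(int)
    aa_mass = np.full(n_genes, MEAN_AA_MASS)
    # the coarse-grained ribosomal record carries the whole ribosome mass
    lengths[0] = int(round(params.m_R / MEAN_AA_MASS))
    aa_mass[0] = params.m_R / lengths[0]

    environments, states, tables, od_curves = [], [], [], []
    for j, (t1, t2) in enumerate(index_schedule):
        env = sample_environment_targeted(
            config, params, float(t1), float(t2), env_index=j
        )
        state = steady_state_solve(params, env)
        environments.append(env)
        states.append(state)

        rng_noise = _rng(seed, 2, j)
        chi = _noisy(env.chi, noise["chi"], rng_noise)
        phi = _noisy(state.phi, noise["phi"], rng_noise)
        k = _noisy(params.k, noise["k"], rng_noise)
        alpha = _noisy(params.alpha, noise["alpha"], rng_noise)
        chi /= chi.sum()
        phi /= phi.sum()
        v = k / aa_mass
        table = pd.DataFrame(
            {
                "gene_id": [f"g{m:05d}" for m in range(n_genes)],
                "chi": chi,
                "k": k,
                "v": v,
                "a": aa_mass,
                "alpha": alpha,
                "phi": phi,
                "length": lengths,
                "is_ribosomal": np.arange(n_genes) == 0,
            }
        )
        tables.append(table)
        od_curves.append(
            generate_od_curve(
                mu=state.mu,
                noise_cv=noise["od"],
                seed=int(_rng(seed, 4, j).integers(2**31)),
            )
        )
    return SyntheticStudy(
        params=params,
        environments=environments,
        states=states,
        gene_tables=tables,
        od_curves=od_curves,
        index_schedule=tuple(index_schedule),
        noise_cvs=noise,
        seed=seed,
    )


def generate_growth_law_dataset(
    truth: GrowthLawCoefficients,
    mu_grid,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> GrowthLawDataset:
    """(mu, phi_R) points on a known curve plus Gaussian noise on phi_R,
    truncated to the open interval (0, 1)."""
    mu_grid = np.asarray(mu_grid, dtype=float)
    phi = np.asarray(phiR_growth_law(mu_grid, truth), dtype=float)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        phi = phi + rng.normal(0.0, noise_sd, size=phi.shape)
    phi = np.clip(phi, 1e-9, 1.0 - 1e-9)
    return GrowthLawDataset(mu=mu_grid, phi_R=phi)


def generate_od_curve(
    mu: float,
    od0: float = 0.01,
    lag_min: float = 60.0,
    saturation_od: float | None = 4.0,
    noise_cv: float = 0.0,
    dt_min: float = 5.0,
    duration_min: float | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic OD600 time series: flat lag, exponential growth at rate
    ``mu`` (1/min), then logistic saturation at ``saturation_od``.

    ``saturation_od=None`` gives a pure exponential after the lag, whose
    log-slope equals ``mu`` exactly.  Noise is multiplicative unit-mean
    lognormal.
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    if duration_min is None:
        if saturation_od is not None:
            duration_min = lag_min + np.log(saturation_od / od0) / mu * 1.6
        else:
            duration_min = lag_min + 10.0 * np.log(2.0) / mu
    t = np.arange(0.0, duration_min + 0.5 * dt_min, dt_min)
    tau = np.maximum(t - lag_min, 0.0)
    if saturation_od is None:
        od = od0 * np.exp(mu * tau)
    else:
        K = saturation_od
        e = np.exp(mu * tau)
        od = K * od0 * e / (K + od0 * (e - 1.0))
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        od = od * _lognormal(rng, 1.0, noise_cv, od.size)
    return pd.DataFrame({"time_min": t, "od": od})
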