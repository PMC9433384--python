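"""Table readers/writers, data-preparation transforms and the OD600
growth-rate extractor.

Dialects: gene tables are tab-separated with a mandatory header; growth-law
datasets and OD series are comma-separated; all UTF-8 with decimal points.
Growth rates are stored per minute (a per-hour convenience column is added
on write where relevant).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .model import DomainError, GrowthLawError

__all__ = [
    "ParseError",
    "AggregationError",
    "GeneRecord",
    "RunConfig",
    "CALIBRATIONS",
    "read_gene_table",
    "write_gene_table",
    "ribosomal_mass_fraction",
    "aggregate_ribosomal",
    "nonribosomal_metrics",
    "growth_rate_from_od",
    "read_od_csv",
    "write_od_csv",
]

logger = logging.getLogger("growthlaw")

CALIBRATIONS = {"none": 0.0, "length_pow_057": 0.57, "length_pow_1": 1.0}

MEAN_AA_MASS = 110.0  # Da; fallback residue mass when a gene table lacks `a`


class ParseError(GrowthLawError):
    """Malformed input table."""


class AggregationError(GrowthLawError):
    """Ribosomal aggregation impossible (no ribosomal records)."""


@dataclass
class GeneRecord:
    """One gene-level record of a processed expression/proteomics table."""

    gene_id: str
    chi: float                  # ribosome allocation count fraction
    k: float                    # translation speed, Da/min
    alpha: float                # degradation rate, 1/min
    phi: float                  # protein mass fraction
    length: int                 # amino acids
    is_ribosomal: bool
    v: float | None = None      # amino acids per minute
    a: float | None = None      # mean amino-acid mass, Da
    paralog_group: str | None = None


_REQUIRED = ("gene_id", "chi", "phi")
_NUMERIC = ("chi", "k", "v", "a", "alpha", "phi", "length")


def read_gene_table(path, calibration: str = "none") -> pd.DataFrame:
    """Read and validate a gene-level TSV.

    Required columns: gene_id, chi, phi and either k or both v and a
    (k = v*a).  Optional: alpha (defaults to 0 with a warning — most
    proteins are non-degradable in bacteria), length, is_ribosomal,
    paralog_group.

    ``calibration`` rescales mass fractions by L^-p (p = 0.57 or 1) and
    renormalizes; this is the length-bias correction applied when absolute
    proteomics quantification is unavailable.
    """
    if calibration not in CALIBRATIONS:
        raise ValueError(f"calibration must be one of {sorted(CALIBRATIONS)}")
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str},
                     float_precision="round_trip")
    missing = set(_REQUIRED) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing required columns {sorted(missing)}")
    if "k" not in df.columns and not {"v", "a"} <= set(df.columns):
        raise ParseError(f"{path}: need either a k column or both v and a")

    for col in _NUMERIC:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            lines = (np.nonzero(bad.to_numpy())[0] + 2).tolist()  # 1-based + header
            raise ParseError(f"{path}: non-numeric {col!r} at line(s) {lines}")
        if coerced.isna().any():
            lines = (np.nonzero(coerced.isna().to_numpy())[0] + 2).tolist()
            raise ParseError(f"{path}: empty {col!r} at line(s) {lines}")
        df[col] = coerced

    dup = df["gene_id"].duplicated(keep=False)
    if dup.any():
        lines = (np.nonzero(dup.to_numpy())[0] + 2).tolist()
        raise ParseError(f"{path}: duplicate gene_id at line(s) {lines}")

    if "k" in df.columns and {"v", "a"} <= set(df.columns):
        rel = np.abs(df["k"] - df["v"] * df["a"]) / np.maximum(df["k"].abs(), 1e-300)
        if (rel > 1e-9).any():
            lines = (np.nonzero((rel > 1e-9).to_numpy())[0] + 2).tolist()
            raise ParseError(f"{path}: k != v*a at line(s) {lines}")
    elif "k" not in df.columns:
        df["k"] = df["v"] * df["a"]

    if "alpha" not in df.columns:
        warnings.warn(
            f"{path}: no alpha column; assuming non-degradable proteins (alpha = 0)",
            stacklevel=2,
        )
        logger.warning("%s: alpha column absent, defaulting to 0", path)
        df["alpha"] = 0.0
    if "is_ribosomal" not in df.columns:
        df["is_ribosomal"] = False
    df["is_ribosomal"] = df["is_ribosomal"].astype(bool)

    for col in ("chi", "k", "alpha", "phi"):
        if (df[col] < 0).any():
            raise ParseError(f"{path}: negative values in column {col!r}")

    p = CALIBRATIONS[calibration]
    if p != 0.0:
        if "length" not in df.columns:
            raise ParseError(f"{path}: length column required for calibration")
        phi = df["phi"] * df["length"].astype(float) ** (-p)
        df["phi"] = phi / phi.sum()

    for col in ("chi", "phi"):
        total = float(df[col].sum())
        if abs(total - 1.0) > 1e-6:
            raise ParseError(
                f"{path}: column {col!r} sums to {total!r}, expected 1 within 1e-6"
            )
    return df


def write_gene_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def ribosomal_mass_fraction(df: pd.DataFrame) -> float:
    """phi_R: summed mass fractions of records flagged ribosomal."""
    return float(df.loc[df["is_ribosomal"], "phi"].sum())


def _molecular_mass(sub: pd.DataFrame) -> np.ndarray:
    if "a" in sub.columns and sub["a"].notna().all():
        return sub["length"].to_numpy(float) * sub["a"].to_numpy(float)
    return sub["length"].to_numpy(float) * MEAN_AA_MASS


def aggregate_ribosomal(df: pd.DataFrame) -> tuple[float, float, float]:
    """Collapse the ribosomal records to (k_R, alpha_R, effective m_R).

    k_R is the chi-weighted speed and alpha_R the phi-weighted degradation
    rate within the ribosomal set.  The effective ribosome mass sums the
    molecular masses of the detected ribosomal proteins; paralog pairs
    (same non-null ``paralog_group``) contribute their average mass once.
    """
    rib = df.loc[df["is_ribosomal"]]
    if rib.empty:
        raise AggregationError("no records flagged ribosomal")
    chi_w = rib["chi"].to_numpy(float)
    phi_w = rib["phi"].to_numpy(float)
    if chi_w.sum() <= 0 or phi_w.sum() <= 0:
        raise AggregationError("ribosomal records carry zero chi or phi weight")
    k_R = float(np.dot(chi_w / chi_w.sum(), rib["k"].to_numpy(float)))
    alpha_R = float(np.dot(phi_w / phi_w.sum(), rib["alpha"].to_numpy(float)))

    if "length" not in rib.columns:
        raise AggregationError("length column required for the effective m_R")
    masses = _molecular_mass(rib)
    if "paralog_group" in rib.columns:
        groups = rib["paralog_group"]
        grouped = groups.notna() & (groups.astype(str) != "")
        m_R = float(masses[~grouped.to_numpy()].sum())
        if grouped.any():
            sub = pd.DataFrame({"g": groups[grouped], "m": masses[grouped.to_numpy()]})
            m_R += float(sub.groupby("g")["m"].mean().sum())
    else:
        m_R = float(masses.sum())
    return k_R, alpha_R, m_R


def nonribosomal_metrics(df: pd.DataFrame) -> dict[str, float]:
    """Environment metrics from one gene table: correlation indices,
    arithmetic and weighted means over non-ribosomal genes, plus the
    ribosomal aggregates."""
    from .model import correlation_index

    nr = df.loc[~df["is_ribosomal"]]
    if len(nr) < 2:
        raise GrowthLawError("need at least 2 non-ribosomal genes")
    chi_t = nr["chi"].to_numpy(float)
    chi_t = chi_t / chi_t.sum()
    phi_t = nr["phi"].to_numpy(float)
    phi_t = phi_t / phi_t.sum()
    k = nr["k"].to_numpy(float)
    alpha = nr["alpha"].to_numpy(float)
    out = {
        "I_chi_k": correlation_index(chi_t, k),
        "mean_k": float(k.mean()),
        "k_chi": float(np.dot(chi_t, k)),
        "mean_alpha": float(alpha.mean()),
        "alpha_phi": float(np.dot(phi_t, alpha)),
        "phi_R": ribosomal_mass_fraction(df),
    }
    out["I_phi_alpha"] = (
        correlation_index(phi_t, alpha) if alpha.mean() > 0 else float("nan")
    )
    k_R, alpha_R, m_R = aggregate_ribosomal(df)
    out.update({"k_R": k_R, "alpha_R": alpha_R, "m_R_effective": m_R})
    return out


# ---------------------------------------------------------------------------
# growth rate from OD600
# ---------------------------------------------------------------------------

def growth_rate_from_od(
    times,
    od,
    window: int = 5,
    threshold: float = 0.95,
) -> float:
    """Growth rate (1/min) from an OD600 time series.

    Sliding ``window``-point linear regressions of ln(OD) vs. time are
    computed; the points belonging to windows whose slope is at least
    ``threshold`` times the maximum slope are pooled (each point once) and a
    single regression over the pool gives the growth rate.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(od, dtype=float)
    if t.ndim != 1 or t.shape != y.shape:
        raise ValueError("times and od must be equal-length 1-D arrays")
    if t.size < window:
        raise GrowthLawError(f"need at least {window} points, got {t.size}")
    if np.any(np.diff(t) <= 0):
        raise DomainError("times must be strictly increasing")
    if np.any(y <= 0):
        raise DomainError("OD values must be positive")
    ln = np.log(y)
    n_win = t.size - window + 1
    slopes = np.empty(n_win)
    for i in range(n_win):
        sl = slice(i, i + window)
        slopes[i] = np.polyfit(t[sl], ln[sl], 1)[0]
    smax = slopes.max()
    selected = np.zeros(t.size, dtype=bool)
    for i in np.nonzero(slopes >= threshold * smax)[0]:
        selected[i : i + window] = True
    return float(np.polyfit(t[selected], ln[selected], 1)[0])


def read_od_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"time_min", "od"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: OD CSV missing columns {sorted(missing)}")
    return df


def write_od_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

class RunConfig(BaseModel):
    """Schema-validated run configuration (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")

    # ensemble
    n_genes: int = 4000
    mean_k: float = 4.80e4
    k_R: float = 2.07e4
    mean_alpha: float = 1.10e-3
    alpha_R: float = 4.83e-4
    cv_k: float = 1.0
    cv_alpha: float = 1.0
    cv_chi: float = 1.0
    phi0: float = Field(default=0.08, ge=0.0, lt=1.0)
    m_R: float = 1.40e6
    chiR_range: tuple[float, float] = (0.05, 0.45)
    n_environments: int = 1
    mode: str = "full"
    # fitting
    fit_init: tuple[float, float, float] | None = None
    # io
    input_path: str | None = None
    output_dir: str = "."
    log_level: str = "INFO"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def ensemble_config(self):
        from .simulate import EnsembleConfig

        return EnsembleConfig(
            n_genes=self.n_genes,
            mean_k=self.mean_k,
            k_R=self.k_R,
            mean_alpha=self.mean_alpha,
            alpha_R=self.alpha_R,
            cv_k=self.cv_k,
            cv_alpha=self.cv_alpha,
            cv_chi=self.cv_chi,
            phi0=self.phi0,
            m_R=self.m_R,
            chiR_range=tuple(self.chiR_range),
            n_environments=self.n_environments,
            seed=self.seed,
        )
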