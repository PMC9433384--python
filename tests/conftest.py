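"""Shared fixtures: small deterministic proteomes and environments."""

import numpy as np
import pytest

from growthlaw import (
    Environment,
    ProteomeParams,
    sample_environment,
    sample_proteome,
)
from growthlaw.simulate import EnsembleConfig

# Measured reference conditions used throughout the tests.
REF = dict(
    k_R=2.07e4,
    mean_k=4.80e4,
    alpha_R=4.83e-4,
    mean_alpha=1.10e-3,
    phi0=0.08,
    m_R=1.40e6,
)


@pytest.fixture
def ref_values():
    return dict(REF)


@pytest.fixture
def small_config():
    # seed chosen so the sampled environment sustains growth (small gene
    # counts with low chi_R can be degradation-dominated with no steady state)
    return EnsembleConfig(n_genes=50, seed=2)


@pytest.fixture
def small_params(small_config):
    return sample_proteome(small_config)


@pytest.fixture
def small_env(small_config, small_params):
    return sample_environment(small_config, small_params, env_index=0)


@pytest.fixture
def homogeneous_instance():
    """Uniform speeds, zero degradation, uniform allocations: phi = chi and
    the growth rate is known in closed form."""
    n = 10
    params = ProteomeParams(
        k=np.full(n, REF["mean_k"]),
        alpha=np.zeros(n),
        m_R=REF["m_R"],
        phi0=REF["phi0"],
    )
    chi = np.empty(n)
    chi[0] = 0.3
    chi[1:] = 0.7 / (n - 1)
    return params, Environment(chi=chi)


def random_instance(seed: int, n_genes: int = 200) -> tuple:
    """One random (proteome, environment) pair at the reference conditions."""
    cfg = EnsembleConfig(n_genes=n_genes, seed=seed)
    params = sample_proteome(cfg)
    env = sample_environment(cfg, params, env_index=0)
    return params, env
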