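"""Core model: indices, coefficients, steady states, dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import growthlaw as gl
from growthlaw import (
    AmbiguousSteadyStateError,
    DegenerateEnvironmentError,
    DomainError,
    Environment,
    GrowthLawCoefficients,
    NegativeGrowthWarning,
    ProteomeParams,
    UndefinedIndexError,
)
from growthlaw.model import DynamicState

from conftest import random_instance


# ---------------------------------------------------------------------------
# correlation index
# ---------------------------------------------------------------------------

def test_correlation_index_hand_value():
    # w = (0.5, 0.3, 0.2), x = (1, 2, 3):
    # mean(wx) = 1.7/3, mean(w) = 1/3, mean(x) = 2 -> I = (1.7 - 2)/2 = -0.15
    I = gl.correlation_index([0.5, 0.3, 0.2], [1.0, 2.0, 3.0])
    assert I == pytest.approx(-0.15, abs=1e-15)


def test_correlation_index_zero_for_constant_values():
    assert gl.correlation_index([0.2, 0.3, 0.5], [7.0, 7.0, 7.0]) == pytest.approx(0.0)


def test_correlation_index_validation():
    with pytest.raises(ValueError, match="sum to 1"):
        gl.correlation_index([0.5, 0.4], [1.0, 2.0])
    with pytest.raises(ValueError, match="length mismatch"):
        gl.correlation_index([0.5, 0.5], [1.0, 2.0, 3.0])
    with pytest.raises(UndefinedIndexError):
        gl.correlation_index([0.5, 0.5], [0.0, 0.0])


@settings(max_examples=50, deadline=None)
@given(
    st.lists(st.floats(0.01, 10.0), min_size=3, max_size=30),
    st.data(),
)
def test_weighted_mean_identity_property(raw_w, data):
    """<x>_w = <x> (1 + I_{w,x}) holds exactly for any weights/values."""
    n = len(raw_w)
    x = np.array(data.draw(st.lists(st.floats(0.01, 100.0), min_size=n, max_size=n)))
    w = np.array(raw_w)
    w = w / w.sum()
    I = gl.correlation_index(w, x)
    assert np.dot(w, x) == pytest.approx(x.mean() * (1.0 + I), rel=1e-10)


# ---------------------------------------------------------------------------
# closed-form coefficients (hand oracles at the reference conditions)
# ---------------------------------------------------------------------------

def _ref_params(ref_values, n=4):
    k = np.full(n, ref_values["mean_k"])
    k[0] = ref_values["k_R"]
    alpha = np.full(n, ref_values["mean_alpha"])
    alpha[0] = ref_values["alpha_R"]
    return ProteomeParams(k=k, alpha=alpha, m_R=ref_values["m_R"],
                          phi0=ref_values["phi0"])


def test_hill_coefficients_hand_values(ref_values):
    params = _ref_params(ref_values)
    a, b = gl.hill_coefficients(params, k_chi=ref_values["mean_k"])
    # denom = 20700*0.92 + 48000*0.08 = 22884
    assert a == pytest.approx(-27300.0 / 22884.0, rel=1e-14)
    assert b == pytest.approx(20700.0 * 48000.0 / (1.40e6 * 22884.0), rel=1e-14)
    assert a < 0  # upward-bending: k_R < <k>_chi


def test_linear_coefficients_hand_values(ref_values):
    params = _ref_params(ref_values)
    c, d = gl.linear_coefficients(params, alpha_phi=ref_values["mean_alpha"])
    assert c == pytest.approx(1.10e-3 * 0.92 + 4.83e-4 * 0.08, rel=1e-14)
    assert d == pytest.approx(1.10e-3 - 4.83e-4, rel=1e-14)


def test_full_coefficients_hand_values(ref_values):
    params = _ref_params(ref_values)
    co = gl.full_coefficients(params, k_chi=ref_values["mean_k"],
                              alpha_phi=ref_values["mean_alpha"])
    assert co.c1 == pytest.approx(4.80e4 * 0.08 / 1.40e6 + 1.10e-3, rel=1e-14)
    assert co.c2 == pytest.approx(1.0 - 48000.0 / 20700.0, rel=1e-14)
    assert co.c3 == pytest.approx(
        1.10e-3 - 4.83e-4 * 48000.0 / 20700.0 + 48000.0 / 1.40e6, rel=1e-14
    )


def test_curve_shape_reference_is_increasing_convex(ref_values):
    params = _ref_params(ref_values)
    co = gl.full_coefficients(params, ref_values["mean_k"], ref_values["mean_alpha"])
    shape = gl.curve_shape(co)
    assert shape.increasing and shape.convex
    assert shape.discriminant == pytest.approx(co.c3 - co.c1 * co.c2, rel=1e-14)


def test_curve_shape_decreasing_case():
    # c3 - c1*c2 = 0.1 - 0.5 < 0: decreasing; (c1*c2 - c3)*c2 > 0: still convex
    shape = gl.curve_shape(GrowthLawCoefficients(c1=1.0, c2=0.5, c3=0.1))
    assert not shape.increasing and shape.convex


def test_curve_shape_concave_case():
    # c2 > 0 with c3 > c1*c2: increasing and concave (saturating)
    shape = gl.curve_shape(GrowthLawCoefficients(c1=0.1, c2=0.5, c3=1.0))
    assert shape.increasing and not shape.convex


def test_phiR_growth_law_scalar_array_and_pole():
    co = GrowthLawCoefficients(c1=3.8428571428571427e-3,
                               c2=-1.3188405797101449,
                               c3=3.42657142857142857e-2)
    v = gl.phiR_growth_law(0.0, co)
    assert isinstance(v, float)
    assert v == pytest.approx(co.c1 / co.c3, rel=1e-14)
    arr = gl.phiR_growth_law(np.array([0.0, 0.01]), co)
    assert arr.shape == (2,)
    with pytest.raises(DomainError, match="pole"):
        gl.phiR_growth_law(0.05, co)  # past the pole at -c3/c2 ~ 0.026


# ---------------------------------------------------------------------------
# steady state
# ---------------------------------------------------------------------------

def test_homogeneous_instance_closed_form(homogeneous_instance):
    """phi = chi under uniform speeds and zero degradation; mu is
    k chi_R (1 - phi0/chi_R) / m_R exactly."""
    params, env = homogeneous_instance
    state = gl.steady_state_solve(params, env)
    assert state.mu == pytest.approx(
        4.80e4 * 0.3 * (1.0 - 0.08 / 0.3) / 1.40e6, rel=1e-14
    )
    assert state.mu == pytest.approx(7.542857142857143e-3, rel=1e-13)
    np.testing.assert_allclose(state.phi, env.chi, rtol=0, atol=1e-15)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_solver_matches_closed_form_curve(seed):
    params, env = random_instance(seed, n_genes=200)
    state = gl.steady_state_solve(params, env)
    co = gl.full_coefficients(params, state.k_chi, state.alpha_phi)
    assert gl.phiR_growth_law(state.mu, co) == pytest.approx(state.phi_R, abs=1e-12)
    assert gl.normalization_residual(params, env, state) < 1e-9


def test_steady_state_identities(small_params, small_env):
    state = gl.steady_state_solve(small_params, small_env)
    assert state.k_chi == pytest.approx(
        small_params.mean_k * (1.0 + state.I_chi_k), rel=1e-12
    )
    assert state.alpha_phi == pytest.approx(
        small_params.mean_alpha * (1.0 + state.I_phi_alpha), rel=1e-12
    )
    assert state.phi.sum() == pytest.approx(1.0, abs=1e-12)
    assert state.k_chi == pytest.approx(
        gl.weighted_speed(small_params, small_env), rel=1e-12
    )
    assert state.alpha_phi == pytest.approx(
        gl.weighted_degradation(small_params, state.phi), rel=1e-12
    )


def test_multiple_roots_error_mode_and_largest_selection(small_params, small_env):
    """Heterogeneous degradation creates a spurious subdominant root; the
    default returns the largest (dominant) one."""
    with pytest.raises(AmbiguousSteadyStateError) as err:
        gl.steady_state_solve(small_params, small_env, on_multiple="error")
    roots = err.value.roots
    assert len(roots) >= 2
    state = gl.steady_state_solve(small_params, small_env)
    assert state.mu == pytest.approx(max(roots), rel=1e-12)


def test_negative_growth_warning():
    n = 5
    params = ProteomeParams(
        k=np.full(n, 4.80e4), alpha=np.full(n, 0.01), m_R=1.40e6, phi0=0.08
    )
    chi = np.empty(n)
    chi[0] = 0.1
    chi[1:] = 0.9 / (n - 1)
    with pytest.warns(NegativeGrowthWarning):
        state = gl.steady_state_solve(params, Environment(chi=chi))
    assert state.negative_growth and state.mu < 0


def test_degenerate_environment_rejected(small_params):
    n = small_params.n_genes
    chi = np.zeros(n)
    chi[0] = 1.0
    with pytest.raises(DegenerateEnvironmentError):
        gl.steady_state_solve(small_params, Environment(chi=chi))


def test_predict_phi_normalized(small_params, small_env):
    phi = gl.predict_phi(small_params, small_env, mu=5e-3)
    assert phi.sum() == pytest.approx(1.0, abs=1e-12)
    assert np.all(phi > 0)
    with pytest.raises(DomainError):
        gl.predict_phi(small_params, small_env, mu=-1.0)


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------

def test_ode_oracle_agrees_with_solver():
    params, env = random_instance(7, n_genes=40)
    state = gl.steady_state_solve(params, env)
    mu_dyn, phi_dyn = gl.steady_state_from_dynamics(params, env)
    assert mu_dyn == pytest.approx(state.mu, rel=1e-6)
    np.testing.assert_allclose(phi_dyn, state.phi, rtol=1e-6, atol=1e-12)


def test_integrate_dynamics_transient_flag(homogeneous_instance):
    params, env = homogeneous_instance
    n = params.n_genes
    # ribosome-poor start: phi_R(0) < phi0 -> active ribosomes negative
    M = np.full(n, 1.0 / n)
    M[0] = 0.05 * M[0]
    M0 = DynamicState(M)
    traj = gl.integrate_dynamics(params, env, M0, (0.0, 10.0), n_eval=5)
    assert traj.transient_flagged
    # composition = allocation start is not flagged
    traj2 = gl.integrate_dynamics(params, env, DynamicState(env.chi.copy()),
                                  (0.0, 10.0), n_eval=5)
    assert not traj2.transient_flagged
    assert traj2.M.shape == (n, 5)


def test_proteome_params_validation():
    with pytest.raises(ValueError):
        ProteomeParams(k=np.array([1.0]), alpha=np.array([0.0]), m_R=1.0, phi0=0.0)
    with pytest.raises(ValueError):
        ProteomeParams(k=np.array([1.0, -1.0]), alpha=np.zeros(2), m_R=1.0, phi0=0.0)
    with pytest.raises(ValueError):
        ProteomeParams(k=np.ones(2), alpha=np.zeros(2), m_R=1.0, phi0=1.0)


def test_environment_validation():
    with pytest.raises(ValueError, match="sum to 1"):
        Environment(chi=np.array([0.5, 0.4]))
    with pytest.raises(ValueError, match="nonnegative"):
        Environment(chi=np.array([1.1, -0.1]))
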