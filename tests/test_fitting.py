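"""Growth-law curve fitting, inversion, uncertainty and prediction scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import growthlaw as gl
from growthlaw import (
    Environment,
    GrowthLawCoefficients,
    GrowthLawDataset,
    InfeasibleCoefficientsError,
    ProteomeParams,
)
from growthlaw.fitting import invert_coefficients
from growthlaw.synthetic import generate_growth_law_dataset

# Reference-condition coefficients (hand-checked in test_model.py).
REF_COEFFS = GrowthLawCoefficients(
    c1=4.80e4 * 0.08 / 1.40e6 + 1.10e-3,
    c2=1.0 - 48000.0 / 20700.0,
    c3=1.10e-3 - 4.83e-4 * 48000.0 / 20700.0 + 48000.0 / 1.40e6,
)
MU_GRID = np.linspace(0.0, 0.012, 30)


def test_dataset_validation_and_csv_round_trip(tmp_path):
    with pytest.raises(ValueError, match="nonnegative"):
        GrowthLawDataset(np.array([-0.1, 0.2]), np.array([0.1, 0.2]))
    with pytest.raises(ValueError, match="inside"):
        GrowthLawDataset(np.array([0.1, 0.2]), np.array([0.1, 1.2]))
    ds = GrowthLawDataset(np.array([0.0, 0.01]), np.array([0.1, 0.4]),
                          condition=["a", "b"])
    p = tmp_path / "gl.csv"
    ds.to_csv(p)
    back = GrowthLawDataset.from_csv(p)
    np.testing.assert_array_equal(back.mu, ds.mu)
    np.testing.assert_array_equal(back.phi_R, ds.phi_R)
    assert back.condition == ["a", "b"]


def test_noiseless_recovery():
    ds = generate_growth_law_dataset(REF_COEFFS, MU_GRID)
    fit = gl.fit_growth_law(ds)
    assert fit.c1 == pytest.approx(REF_COEFFS.c1, rel=1e-6)
    assert fit.c2 == pytest.approx(REF_COEFFS.c2, rel=1e-6)
    assert fit.c3 == pytest.approx(REF_COEFFS.c3, rel=1e-6)
    assert fit.rmse < 1e-10
    assert fit.n == MU_GRID.size


def test_fit_needs_enough_points():
    with pytest.raises(ValueError, match="at least 4"):
        gl.fit_growth_law(
            GrowthLawDataset(np.array([0.0, 0.01, 0.02]), np.array([0.1, 0.2, 0.3]))
        )


def test_noisy_fit_ci_and_rmse():
    ds = generate_growth_law_dataset(REF_COEFFS, MU_GRID, noise_sd=2e-3, seed=3)
    fit = gl.fit_growth_law(ds)
    # intervals are ordered and contain the point estimate
    assert np.all(fit.ci[:, 0] < fit.ci[:, 1])
    for i, c in enumerate((fit.c1, fit.c2, fit.c3)):
        assert fit.ci[i, 0] <= c <= fit.ci[i, 1]
    assert fit.rmse == pytest.approx(2e-3, rel=1.0)  # same order as the noise


@settings(max_examples=100, deadline=None)
@given(
    phi0=st.floats(0.0, 0.3),
    k_R=st.floats(1e3, 1e5),
    ratio=st.floats(0.2, 5.0),       # <k>_chi / k_R
    alpha_R=st.floats(0.0, 5e-3),
    alpha_phi=st.floats(0.0, 5e-3),
    m_R=st.floats(1e5, 1e7),
)
def test_inversion_round_trip_property(phi0, k_R, ratio, alpha_R, alpha_phi, m_R):
    """invert_coefficients is the exact inverse of the coefficient map."""
    k_chi = ratio * k_R
    params = ProteomeParams(
        k=np.array([k_R, k_chi]), alpha=np.array([alpha_R, 0.0]),
        m_R=m_R, phi0=phi0,
    )
    co = gl.full_coefficients(params, k_chi, alpha_phi)
    phi0_b, k_R_b, k_chi_b = invert_coefficients(
        co.c1, co.c2, co.c3, alpha_R, alpha_phi, m_R
    )
    assert phi0_b == pytest.approx(phi0, rel=1e-8, abs=1e-10)
    assert k_R_b == pytest.approx(k_R, rel=1e-8)
    assert k_chi_b == pytest.approx(k_chi, rel=1e-8)


def test_inversion_infeasible_inputs():
    with pytest.raises(InfeasibleCoefficientsError, match="c2 >= 1"):
        invert_coefficients(1e-3, 1.2, 0.03, 0.0, 0.0, 1e6)
    with pytest.raises(InfeasibleCoefficientsError, match="nonpositive"):
        invert_coefficients(1e-3, 0.0, -1.0, 0.0, 0.0, 1e6)


def test_with_derived_params_recovers_truth():
    ds = generate_growth_law_dataset(REF_COEFFS, MU_GRID)
    fit = gl.fit_growth_law(ds)
    fit = gl.with_derived_params(fit, alpha_R=4.83e-4, alpha_phi=1.10e-3, m_R=1.40e6)
    assert fit.derived["phi0"] == pytest.approx(0.08, rel=1e-5)
    assert fit.derived["k_R"] == pytest.approx(2.07e4, rel=1e-5)
    assert fit.derived["k_chi"] == pytest.approx(4.80e4, rel=1e-5)
    for name, value in fit.derived.items():
        lo, hi = fit.derived_bounds[name]
        assert lo <= value <= hi


def test_bound_derived_params_contains_point_estimate():
    ds = generate_growth_law_dataset(REF_COEFFS, MU_GRID, noise_sd=1e-3, seed=5)
    fit = gl.fit_growth_law(ds)
    fit = gl.with_derived_params(fit, alpha_R=4.83e-4, alpha_phi=1.10e-3, m_R=1.40e6)
    bounds = fit.derived_bounds
    for name, value in fit.derived.items():
        lo, hi = bounds[name]
        assert lo < hi
        assert lo <= value <= hi
    # Monte-Carlo check: values over random box corners stay inside bounds
    rng = np.random.default_rng(0)
    for _ in range(200):
        c = fit.ci[:, 0] + rng.random(3) * (fit.ci[:, 1] - fit.ci[:, 0])
        try:
            vals = invert_coefficients(c[0], c[1], c[2], 4.83e-4, 1.10e-3, 1.40e6)
        except InfeasibleCoefficientsError:
            continue
        for name, v in zip(("phi0", "k_R", "k_chi"), vals):
            lo, hi = bounds[name]
            assert lo - 1e-9 * abs(lo) <= v <= hi + 1e-9 * abs(hi)


def test_fit_json_serialization(tmp_path):
    ds = generate_growth_law_dataset(REF_COEFFS, MU_GRID)
    fit = gl.fit_growth_law(ds)
    p = tmp_path / "fit.json"
    fit.to_json(p)
    import json

    payload = json.loads(p.read_text())
    assert payload["c1"] == pytest.approx(fit.c1)
    assert payload["n"] == fit.n


def test_subsample_rmse_single_vs_mixed_curve():
    """Points on one exact curve give near-zero subsample RMSE; a mixture of
    two curves does not."""
    mu = np.linspace(0.0, 0.012, 40)
    single = generate_growth_law_dataset(REF_COEFFS, mu)
    other = GrowthLawCoefficients(c1=REF_COEFFS.c1 * 2.0, c2=0.0, c3=REF_COEFFS.c3)
    mixed = GrowthLawDataset(
        mu=np.concatenate([mu[:20], mu[:20]]),
        phi_R=np.concatenate(
            [
                np.asarray(gl.phiR_growth_law(mu[:20], REF_COEFFS)),
                np.asarray(gl.phiR_growth_law(mu[:20], other)),
            ]
        ),
    )
    res_single = gl.subsample_rmse_experiment(single, n_points=20, n_reps=50, seed=1)
    res_mixed = gl.subsample_rmse_experiment(mixed, n_points=20, n_reps=50, seed=1)
    assert res_single.median < 1e-10
    assert res_mixed.median > 100 * max(res_single.median, 1e-12)
    assert res_single.rmse.size + res_single.n_failures == 50


def test_subsample_rmse_pool_too_small():
    ds = generate_growth_law_dataset(REF_COEFFS, np.linspace(0, 0.01, 10))
    with pytest.raises(ValueError, match="pool smaller"):
        gl.subsample_rmse_experiment(ds, n_points=20, n_reps=5)


def test_predict_phiR_for_conditions(small_params):
    mu = np.array([2e-3, 4e-3])
    out = gl.predict_phiR_for_conditions(
        small_params, mu, I_chi_k=[0.2, 0.1], I_phi_alpha=[-0.3, -0.3]
    )
    assert out.shape == (2,)
    assert np.all((out > 0) & (out < 1))
    scalar = gl.predict_phiR_for_conditions(small_params, 2e-3, 0.2, -0.3)
    assert scalar == pytest.approx(out[0])
    with pytest.raises(ValueError, match="exceed -1"):
        gl.predict_phiR_for_conditions(small_params, 2e-3, -1.5, 0.0)


def test_evaluate_phi_prediction_ablation_ordering(small_params, small_env):
    """The full model reproduces its own steady-state composition better
    than either ablation."""
    state = gl.steady_state_solve(small_params, small_env)
    score = gl.evaluate_phi_prediction(
        small_params, small_env, state.mu, measured_phi=state.phi
    )
    assert score.rho_full == pytest.approx(1.0, abs=1e-9)
    assert score.rho_full >= score.rho_no_degradation
    assert score.rho_full >= score.rho_homogeneous_speed
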