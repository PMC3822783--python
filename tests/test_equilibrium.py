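"""Steady state, Jacobian, stability classification, threshold scan."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcellhom import (
    CellState,
    ModelParams,
    default_params,
    integrate,
    jacobian,
    resource_sweep,
    rhs,
    stability_threshold,
    steady_state,
    threshold_scan,
)

U = 1e11


def fd_jacobian(state, p, h_rel=1e-6):
    """Central finite differences of the right-hand side (independent oracle)."""
    X, Y = state.X, state.Y
    h = h_rel * max(state.N, p.cell_unit * 1e-3)
    J = np.empty((2, 2))
    for j, (dx, dy) in enumerate([(h, 0.0), (0.0, h)]):
        fp = rhs(CellState(X + dx, Y + dy), p.theta, p)
        fm = rhs(CellState(max(X - dx, 0), max(Y - dy, 0)), p.theta, p)
        J[0, j] = (fp[0] - fm[0]) / (2 * h)
        J[1, j] = (fp[1] - fm[1]) / (2 * h)
    return J


def test_adult_steady_state(equilibrium):
    """Total just over 1e11 cells, ~0.5% dividing, stable, tiny residual."""
    assert 1.0e11 < equilibrium.N < 1.25e11
    assert 0.004 < equilibrium.ratio < 0.0055
    assert equilibrium.residual < 1e-3  # cells/day, vs fluxes of order 1e9
    assert equilibrium.stable and not equilibrium.marginal
    assert equilibrium.leading_eigen_real < 0
    assert equilibrium.state.X > 0


def test_steady_state_is_fixed_point_of_the_flow(params, equilibrium):
    """Integrating from the computed equilibrium stays put to 0.1% over 1000 days."""
    traj = integrate(params, equilibrium.state, 1000.0)
    assert np.max(np.abs(traj.N - equilibrium.N) / equilibrium.N) < 1e-3


def test_no_input_no_division_gives_empty_pool():
    p = ModelParams(theta=1e-30, lambda0=1e-30)  # positive-field container, zero in effect
    eq = steady_state(p)
    assert eq.N < 1.0  # fewer than one cell


@pytest.mark.parametrize(
    "state",
    [CellState(1.1e11, 5e8), CellState(1e9, 1e7), CellState(2e11, 1e9), CellState(5e10, 1e6)],
)
def test_analytic_jacobian_matches_finite_differences(params, state):
    J = jacobian(state, params)
    J_fd = fd_jacobian(state, params)
    assert np.allclose(J, J_fd, rtol=1e-6, atol=1e-12)


def test_jacobian_at_origin(params):
    """With no cells the dividing compartment relaxes at exactly -r."""
    J = jacobian(CellState(0.0, 0.0), params)
    assert J[1, 1] == pytest.approx(-params.r, rel=1e-12)


def test_perturbation_decays_at_leading_eigenvalue_rate(params, equilibrium):
    """Log-distance to equilibrium decays at the leading eigenvalue's rate (5%)."""
    init = CellState(equilibrium.state.X * 1.01, equilibrium.state.Y * 1.01)
    traj = integrate(params, init, 500.0)
    d = np.abs(traj.N - equilibrium.N)
    m = (traj.times >= 50) & (traj.times <= 300) & (d > 0)
    slope = np.polyfit(traj.times[m], np.log(d[m]), 1)[0]
    assert slope == pytest.approx(equilibrium.leading_eigen_real, rel=0.05)


def test_threshold_scan_reports_no_threshold_for_default_brackets(params):
    """The recomputed steady state stays stable across every default bracket.

    The scan must say so honestly ('both' sides stable, no critical value)
    rather than fabricate a crossing.
    """
    table = threshold_scan(params)
    assert set(table["parameter"]) == {"r", "mu_prime", "epsilon", "lambda0",
                                       "theta", "delta0", "rho"}
    assert table["critical_value"].isna().all()
    assert (table["stable_side"] == "both").all()


def test_stability_threshold_api(params):
    assert stability_threshold(params, "theta", (1e7, 1e10)) is None
    with pytest.raises(ValueError):
        stability_threshold(params, "not_a_param", (0.1, 1.0))
    with pytest.raises(ValueError):
        stability_threshold(params, "r", (1.0, 0.5))


def test_equilibrium_shrinks_with_either_resource(params):
    """Pool size at equilibrium is non-increasing as epsilon or rho shrink."""
    sweep = resource_sweep(params, factors=(0.25, 0.5, 1.0))
    for name in ("epsilon", "rho"):
        sub = sweep[sweep.parameter == name].sort_values("factor")
        n = sub["N_star_cells"].to_numpy()
        assert np.all(np.diff(n) >= 0)  # smaller resource, smaller pool


def test_division_resource_dominates_survival_resource(params):
    """Halving epsilon moves the set point more than halving rho."""
    base = steady_state(params).N
    n_eps = steady_state(params.replace(epsilon=params.epsilon / 2)).N
    n_rho = steady_state(params.replace(rho=params.rho / 2)).N
    assert abs(n_eps - base) / base > abs(n_rho - base) / base


@settings(max_examples=20, deadline=None)
@given(
    theta=st.floats(min_value=1e6, max_value=1e10),
    lam0=st.floats(min_value=1e-3, max_value=0.5),
    r=st.floats(min_value=0.05, max_value=8.0),
)
def test_steady_state_residual_is_tiny_across_parameters(theta, lam0, r):
    p = default_params().replace(theta=theta, lambda0=lam0, r=r)
    eq = steady_state(p)
    assert eq.residual < 1e-6 * max(theta, 1.0)
    assert eq.state.X > 0
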