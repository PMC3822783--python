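"""Rate laws, right-hand side, parameter container."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcellhom import (
    CellState,
    ModelParams,
    default_params,
    dividing_death_rate,
    division_rate,
    resting_death_rate,
    rhs,
)

U = 1e11


def oracle_rates(N, Y, p):
    """Independent scalar re-implementation of the three rate laws."""
    return (
        p.lambda0 * math.exp(-N / p.epsilon),
        p.delta0 * math.exp(N / p.rho),
        p.mu_prime * Y,
    )


@pytest.mark.parametrize(
    "N, expected",
    [
        (0.0, 0.055),
        (1e11, 0.055 / math.e),        # N equal to the division resource scale
        (2e11, 0.055 * math.exp(-2)),
    ],
)
def test_division_rate_closed_form(params, N, expected):
    assert division_rate(N, params) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize(
    "N, expected",
    [
        (0.0, 0.02),
        (100 * U, 0.02 * math.e),      # N equal to the survival resource scale
        (1.1e11, 0.02 * math.exp(0.011)),
    ],
)
def test_resting_death_rate_closed_form(params, N, expected):
    assert resting_death_rate(N, params) == pytest.approx(expected, rel=1e-12)


def test_aicd_rate_linear_in_density(params):
    assert dividing_death_rate(0.0, params) == 0.0
    assert dividing_death_rate(0.005 * U, params) == pytest.approx(0.075, rel=1e-12)
    y = 0.003 * U
    assert dividing_death_rate(2 * y, params) == pytest.approx(
        2 * dividing_death_rate(y, params), rel=1e-12
    )


@pytest.mark.parametrize("fn", [division_rate, resting_death_rate, dividing_death_rate])
def test_negative_inputs_rejected(params, fn):
    with pytest.raises(ValueError):
        fn(-1.0, params)


@settings(max_examples=100, deadline=None)
@given(
    n1=st.floats(min_value=0, max_value=10 * U),
    n2=st.floats(min_value=0, max_value=10 * U),
)
def test_rate_monotonicity(n1, n2):
    """Division entry strictly decreases and resting death strictly increases in N."""
    p = default_params()
    lo, hi = sorted((n1, n2))
    if (hi - lo) / p.rho < 1e-12:  # below float resolution of the exponents
        return
    assert division_rate(hi, p) < division_rate(lo, p)
    assert resting_death_rate(hi, p) > resting_death_rate(lo, p)


@settings(max_examples=50, deadline=None)
@given(
    n=st.floats(min_value=0, max_value=5 * U),
    y_frac=st.floats(min_value=0, max_value=1),
)
def test_rates_match_scalar_oracle(n, y_frac):
    p = default_params()
    y = y_frac * n
    lam, dlt, mu = oracle_rates(n, y, p)
    assert division_rate(n, p) == pytest.approx(lam, rel=1e-12)
    assert resting_death_rate(n, p) == pytest.approx(dlt, rel=1e-12)
    assert dividing_death_rate(y, p) == pytest.approx(mu, rel=1e-12)


def test_rhs_empty_pool_is_pure_influx(params):
    dX, dY = rhs(CellState(0.0, 0.0), 3e8, params)
    assert dX == pytest.approx(3e8)
    assert dY == 0.0


def test_rhs_hand_computed_point(params):
    """X=1e11, Y=0: derivative from the closed forms evaluated by hand."""
    lam, dlt, _ = oracle_rates(1e11, 0.0, params)
    dX, dY = rhs(CellState(1e11, 0.0), 3e8, params)
    assert dX == pytest.approx(3e8 - (lam + dlt) * 1e11, rel=1e-12)
    assert dX == pytest.approx(-3.74e9, rel=0.01)
    assert dY == pytest.approx(lam * 1e11, rel=1e-12)
    assert dY == pytest.approx(2.02e9, rel=0.01)


@settings(max_examples=50, deadline=None)
@given(
    x=st.floats(min_value=0, max_value=5 * U),
    y=st.floats(min_value=0, max_value=0.1 * U),
)
def test_flow_cannot_leave_nonnegative_quadrant(x, y):
    p = default_params()
    dX0, _ = rhs(CellState(0.0, y), p.theta, p)
    assert dX0 >= p.theta >= 0
    _, dY0 = rhs(CellState(x, 0.0), p.theta, p)
    assert dY0 >= 0


def test_default_params_match_published_table():
    p = default_params()
    assert p.r == 4.0
    assert p.lambda0 == 0.055
    assert p.theta == 3e8
    # model-unit views reproduce the published scaling
    assert p.theta_units == pytest.approx(0.003)
    assert p.epsilon_units == pytest.approx(1.0)
    assert p.rho_units == pytest.approx(100.0)
    assert p.mu_prime_units == pytest.approx(15.0)


def test_params_validation_and_yaml_roundtrip(tmp_path):
    with pytest.raises(ValueError):
        ModelParams(r=-1.0)
    with pytest.raises(ValueError):
        ModelParams.from_dict({"r": 4.0, "bogus": 1.0})
    p = ModelParams(lambda0=0.06)
    f = tmp_path / "params.yaml"
    p.to_yaml(f)
    assert ModelParams.from_yaml(f) == p


def test_cellstate_invariants():
    s = CellState(2.0, 1.0)
    assert s.N == 3.0
    assert s.ratio == 0.5
    with pytest.raises(ValueError):
        CellState(-1.0, 0.0)
    with pytest.raises(ZeroDivisionError):
        CellState(0.0, 1.0).ratio
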