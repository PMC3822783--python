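"""Steady states, Jacobian, linear stability and critical-parameter search.

The nontrivial fixed point is found by a scalar reduction: given a total
pool size N, the dividing-compartment balance ``lambda(N) X = r Y + mu' Y^2``
with X = N - Y is a quadratic in Y with a unique nonnegative root Y(N);
substituting into the resting-compartment balance leaves a single equation
F(N) = 0 that is bracketed and solved with Brent's method, then refined in
two dimensions.  Stability is classified from the eigenvalues of the
analytic Jacobian, which accounts for the N-dependence of the division and
death rates (d lambda/dN = -lambda/epsilon, d delta/dN = +delta/rho).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, root

from .model import division_rate, resting_death_rate, rhs
from .params import CellState, ModelParams

__all__ = [
    "Equilibrium",
    "steady_state",
    "jacobian",
    "stability_threshold",
    "threshold_scan",
    "resource_sweep",
    "NoEquilibriumError",
]

#: |Re(eigenvalue)| below this is reported as marginal rather than classified.
MARGINAL_BAND = 1e-10

#: Parameters eligible for a critical-value search.
SCANNABLE = ("r", "mu_prime", "epsilon", "lambda0", "theta", "delta0", "rho")


class NoEquilibriumError(RuntimeError):
    """Raised when no nonnegative fixed point can be bracketed."""


@dataclass(frozen=True)
class Equilibrium:
    """A fixed point of the model with its linear-stability diagnosis."""

    state: CellState
    residual: float          # max |rhs| at the fixed point, cells/day
    leading_eigen_real: float  # largest real part among Jacobian eigenvalues, 1/day
    stable: bool
    marginal: bool = False   # |leading real part| within MARGINAL_BAND

    @property
    def N(self) -> float:
        return self.state.N

    @property
    def ratio(self) -> float:
        return self.state.ratio


def _dividing_at_total(N: float, params: ModelParams) -> float:
    """Unique nonnegative root Y of mu' Y^2 + (r + lambda(N)) Y - lambda(N) N = 0."""
    lam = division_rate(N, params)
    b = params.r + lam
    c = lam * N
    if c == 0.0:
        return 0.0
    # numerically stable quadratic root (b > 0 always)
    return 2.0 * c / (b + math.sqrt(b * b + 4.0 * params.mu_prime * c))


def _resting_balance(N: float, params: ModelParams) -> float:
    """Residual of the resting-compartment balance along the Y(N) manifold."""
    Y = _dividing_at_total(N, params)
    X = N - Y
    lam = division_rate(N, params)
    # clamped exponent: far above the root only the sign matters, and the
    # unclamped value overflows for N >> rho
    dlt = params.delta0 * math.exp(min(N / params.rho, 700.0))
    return params.theta + 2.0 * params.r * Y - (lam + dlt) * X


def steady_state(params: ModelParams) -> Equilibrium:
    """Locate the nontrivial nonnegative fixed point and classify stability.

    Raises
    ------
    NoEquilibriumError
        If no sign change of the reduced balance can be bracketed; the
        message carries the parameter values and the probed range.
    """
    u = params.cell_unit
    lo, hi = 1e-12 * u, 1e4 * u
    f_lo = _resting_balance(lo, params)
    if f_lo <= 0.0:
        # theta ~ 0 and no net production at tiny N: the origin is the fixed point
        st = CellState(0.0, 0.0)
        lead = _leading_eig(st, params)
        res = max(abs(v) for v in rhs(st, params.theta, params))
        return Equilibrium(st, res, lead, lead < -MARGINAL_BAND, abs(lead) <= MARGINAL_BAND)
    # expand upward until the balance turns negative (delta grows without bound)
    while _resting_balance(hi, params) > 0.0:
        hi *= 10.0
        if hi > 1e12 * u:
            raise NoEquilibriumError(
                f"could not bracket a fixed point up to N={hi:.3g} cells for params={params.to_dict()}"
            )
    N_star = brentq(_resting_balance, lo, hi, args=(params,), xtol=1e-12 * u, rtol=1e-14)
    Y = _dividing_at_total(N_star, params)
    X = N_star - Y

    # two-dimensional refinement in model units
    def f2(z):
        s = CellState(max(z[0], 0.0) * u, max(z[1], 0.0) * u)
        dX, dY = rhs(s, params.theta, params)
        return [dX / u, dY / u]

    sol = root(f2, [X / u, Y / u], method="hybr", tol=1e-14)
    if sol.success:
        X, Y = sol.x[0] * u, sol.x[1] * u
    st = CellState(max(X, 0.0), max(Y, 0.0))
    res = max(abs(v) for v in rhs(st, params.theta, params))
    lead = _leading_eig(st, params)
    return Equilibrium(st, res, lead, lead < -MARGINAL_BAND, abs(lead) <= MARGINAL_BAND)


def jacobian(state: CellState, params: ModelParams) -> np.ndarray:
    """Analytic 2x2 Jacobian of (dX/dt, dY/dt) w.r.t. (X, Y), entries 1/day."""
    X, Y = state.X, state.Y
    N = X + Y
    lam = division_rate(N, params)
    dlt = resting_death_rate(N, params)
    lam_p = -lam / params.epsilon   # d lambda / dN
    dlt_p = dlt / params.rho        # d delta / dN
    return np.array(
        [
            [-(lam + dlt) - (lam_p + dlt_p) * X, 2.0 * params.r - (lam_p + dlt_p) * X],
            [lam + lam_p * X, lam_p * X - params.r - 2.0 * params.mu_prime * Y],
        ]
    )


def _leading_eig(state: CellState, params: ModelParams) -> float:
    return float(np.max(np.linalg.eigvals(jacobian(state, params)).real))


def stability_threshold(
    params: ModelParams,
    param_name: str,
    bracket: Sequence[float],
    rtol: float = 1e-4,
) -> Optional[float]:
    """Critical parameter value where the recomputed steady state changes stability.

    Bisects on the sign of the leading Jacobian eigenvalue's real part,
    recomputing the steady state at every trial value, to relative
    tolerance ``rtol``.  Returns ``None`` when stability is the same at
    both bracket endpoints (no threshold in bracket).

    ``bracket`` is in the same absolute units as the corresponding
    :class:`~tcellhom.params.ModelParams` field.
    """
    if param_name not in SCANNABLE:
        raise ValueError(f"param_name must be one of {SCANNABLE}, got {param_name!r}")
    lo, hi = float(bracket[0]), float(bracket[1])
    if not (0 < lo < hi):
        raise ValueError(f"bracket must satisfy 0 < lo < hi, got {bracket}")

    def lead(v: float) -> float:
        return steady_state(params.replace(**{param_name: v})).leading_eigen_real

    f_lo, f_hi = lead(lo), lead(hi)
    if f_lo * f_hi > 0.0:
        return None
    while hi - lo > rtol * min(abs(lo), abs(hi)):
        mid = 0.5 * (lo + hi)
        f_mid = lead(mid)
        if f_mid * f_lo > 0.0:
            lo, f_lo = mid, f_mid
        else:
            hi, f_hi = mid, f_mid
    return 0.5 * (lo + hi)


def threshold_scan(
    params: ModelParams,
    brackets: Optional[dict] = None,
) -> pd.DataFrame:
    """Scan every rate parameter for a critical value within its bracket.

    Returns a table with columns parameter, bracket_lo, bracket_hi,
    critical_value (NaN when none exists in the bracket) and stable_side
    ('both' when stability never changes).  Default brackets are in
    absolute units and cover the ranges examined in the adult analysis.
    """
    u = params.cell_unit
    if brackets is None:
        brackets = {
            "r": (0.01, 4.0),
            "mu_prime": (15.0 / u, 500.0 / u),
            "epsilon": (0.5 * u, 2.0 * u),
            "lambda0": (1e-12, 0.055),
            "theta": (0.01 * params.theta, 10.0 * params.theta),
            "delta0": (0.1 * params.delta0, 10.0 * params.delta0),
            "rho": (0.1 * params.rho, 10.0 * params.rho),
        }
    rows = []
    for name, (lo, hi) in brackets.items():
        crit = stability_threshold(params, name, (lo, hi))
        if crit is None:
            stable_lo = steady_state(params.replace(**{name: lo})).stable
            side = "both" if stable_lo else "neither"
            rows.append((name, lo, hi, float("nan"), side))
        else:
            stable_lo = steady_state(params.replace(**{name: lo})).stable
            rows.append((name, lo, hi, crit, "low" if stable_lo else "high"))
    return pd.DataFrame(
        rows, columns=["parameter", "bracket_lo", "bracket_hi", "critical_value", "stable_side"]
    )


def resource_sweep(
    params: ModelParams,
    factors: Sequence[float] = (0.25, 0.5, 1.0),
) -> pd.DataFrame:
    """Equilibrium pool size as each resource scale is reduced.

    For each factor f the steady state is recomputed with epsilon (or rho)
    scaled to f times its default, all else fixed — the resource-competition
    sensitivity analysis.  Columns: parameter, factor, value, N_star_cells.
    """
    rows = []
    for name in ("epsilon", "rho"):
        base = getattr(params, name)
        for f in factors:
            eq = steady_state(params.replace(**{name: f * base}))
            rows.append((name, f, f * base, eq.N))
    return pd.DataFrame(rows, columns=["parameter", "factor", "value", "N_star_cells"])
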