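"""Numerical integration of the homeostasis model and derived quantities."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Union

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import division_rate
from .params import CellState, ModelParams

__all__ = [
    "Trajectory",
    "integrate",
    "convergence_time",
    "peak_ratio",
    "interdivision_time",
]

#: Default solver tolerances: relative, and absolute in model units.
RTOL = 1e-8
ATOL_UNITS = 1e-12

#: The fast transient (return from division, timescale 1/r = 0.25 day) is
#: resolved on a fine grid over the first few days; daily thereafter.
FINE_SPAN = 10.0
FINE_STEP = 0.01


@dataclass(frozen=True)
class Trajectory:
    """Time course of the two compartments on a fixed output grid.

    times are days; X, Y, N are cells; ratio is Y/X (dimensionless).
    """

    times: np.ndarray
    X: np.ndarray
    Y: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.X < 0) or np.any(self.Y < 0):
            raise ValueError("trajectory states must be nonnegative")

    @property
    def N(self) -> np.ndarray:
        return self.X + self.Y

    @property
    def ratio(self) -> np.ndarray:
        if np.any(self.X <= 0):
            raise ZeroDivisionError("dividing:resting ratio undefined where X = 0")
        return self.Y / self.X

    def state_at(self, t: float) -> CellState:
        return CellState(float(np.interp(t, self.times, self.X)),
                         float(np.interp(t, self.times, self.Y)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_days": self.times,
                "X_cells": self.X,
                "Y_cells": self.Y,
                "N_cells": self.N,
                "ratio": self.Y / np.where(self.X > 0, self.X, np.nan),
            }
        )


def _output_grid(t_end: float) -> np.ndarray:
    fine = np.arange(0.0, min(FINE_SPAN, t_end), FINE_STEP)
    daily = np.arange(min(FINE_SPAN, t_end), t_end, 1.0)
    return np.unique(np.concatenate([fine, daily, [t_end]]))


def integrate(
    params: ModelParams,
    init: CellState,
    t_end: float,
    theta_fn: Union[float, Callable[[float], float], None] = None,
    rtol: float = RTOL,
    atol_units: float = ATOL_UNITS,
) -> Trajectory:
    """Integrate the model from ``init`` for ``t_end`` days.

    ``theta_fn`` is either a constant thymic output (cells/day), a callable
    of time in days, or None to use ``params.theta``.  Integration is
    adaptive (LSODA) on the state expressed in model units, with output
    resampled onto a grid that is fine (0.01 day) over the first 10 days
    and daily thereafter.
    """
    if t_end <= 0:
        raise ValueError(f"t_end must be positive, got {t_end}")
    u = params.cell_unit
    if theta_fn is None:
        th = lambda t: params.theta
    elif callable(theta_fn):
        th = theta_fn
    else:
        const = float(theta_fn)
        if const < 0:
            raise ValueError("thymic output must be nonnegative")
        th = lambda t: const

    lam0, eps, d0, rho, r, mu = (
        params.lambda0, params.epsilon / u, params.delta0,
        params.rho / u, params.r, params.mu_prime * u,
    )

    def f(t, z):
        x, y = z
        n = x + y
        lam = lam0 * np.exp(-n / eps)
        dlt = d0 * np.exp(n / rho)
        return [th(t) / u + 2.0 * r * y - (lam + dlt) * x,
                lam * x - r * y - mu * y * y]

    grid = _output_grid(t_end)
    sol = solve_ivp(
        f, (0.0, t_end), [init.X / u, init.Y / u],
        method="LSODA", rtol=rtol, atol=atol_units, dense_output=True,
    )
    if not sol.success:
        last = sol.y[:, -1] * u if sol.y.size else None
        raise RuntimeError(
            f"ODE solver failed at t={sol.t[-1] if sol.t.size else 0:.3f} d "
            f"(state={last}): {sol.message}"
        )
    Z = sol.sol(grid) * u
    # clip solver-level negative round-off (magnitude bounded by atol)
    Z = np.where((Z < 0) & (Z > -10 * atol_units * u), 0.0, Z)
    return Trajectory(grid, Z[0], Z[1])


def convergence_time(traj: Trajectory, band: float = 0.05) -> float:
    """Earliest time after which the total stays within ±band of its final value.

    ``band`` is a relative half-width; the asymptote is taken as the final
    total of the trajectory, so the trajectory must be long enough to have
    settled.  Raises if the trajectory never enters the band.
    """
    if not 0 < band < 1:
        raise ValueError(f"band must be in (0, 1), got {band}")
    N = traj.N
    N_inf = N[-1]
    inside = np.abs(N - N_inf) <= band * N_inf
    if not inside[-1]:
        raise RuntimeError("trajectory has not converged: final point outside its own band")
    # walk back from the end to the first exit
    idx = len(inside) - 1
    while idx > 0 and inside[idx - 1]:
        idx -= 1
    return float(traj.times[idx])


def peak_ratio(traj: Trajectory) -> float:
    """Maximum dividing:resting ratio Y/X along the trajectory."""
    return float(np.max(traj.ratio))


def interdivision_time(state: CellState, params: ModelParams) -> float:
    """Mean waiting time of a resting cell to its next division entry, days.

    The reciprocal of the per-cell division-entry rate at the current pool
    size, 1/lambda(N); infinite when the rate underflows to zero.
    """
    if state.N <= 0:
        raise ValueError("interdivision time requires a nonempty pool")
    lam = division_rate(state.N, params)
    return float("inf") if lam == 0.0 else 1.0 / lam


def adult_scenarios(params: Optional[ModelParams] = None, t_end: float = 1000.0):
    """The two published adult runs: lymphopenic and excess starting numbers.

    Returns ``{"lymphopenic": Trajectory, "excess": Trajectory}`` for
    initial resting pools of 0.01 and 2 model units with no dividing cells.
    """
    p = params or ModelParams()
    starts = {"lymphopenic": 0.01 * p.cell_unit, "excess": 2.0 * p.cell_unit}
    return {name: integrate(p, CellState(x0, 0.0), t_end) for name, x0 in starts.items()}
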