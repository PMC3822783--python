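"""Right-hand side of the two-compartment homeostasis model.

The naive CD4 pool is split into resting cells X and dividing cells Y,
with thymic input theta into X.  Resting cells enter division at a
per-cell rate that decays exponentially with the total pool size N = X+Y
(competition for IL-7 / self-peptide MHC division signals), die at a rate
that grows exponentially with N (competition for survival signals), and
dividing cells return to rest after one division (producing two resting
daughters) or die by density-dependent AICD:

    dX/dt = theta + 2 r Y - lambda(N) X - delta(N) X
    dY/dt = lambda(N) X - r Y - mu' Y^2

with lambda(N) = lambda0 exp(-N/epsilon) and delta(N) = delta0 exp(N/rho).
"""

from __future__ import annotations

import math
from typing import Tuple

from .params import CellState, ModelParams

__all__ = ["division_rate", "resting_death_rate", "dividing_death_rate", "rhs"]


def division_rate(N: float, params: ModelParams) -> float:
    """Per-cell rate of entry into division at total pool size N, 1/day.

    ``lambda0 * exp(-N/epsilon)``: maximal at N=0 and decaying
    exponentially as cells compete for the division resource.
    """
    if N < 0:
        raise ValueError(f"total cell number must be nonnegative, got {N}")
    return params.lambda0 * math.exp(-N / params.epsilon)


def resting_death_rate(N: float, params: ModelParams) -> float:
    """Per-cell death rate of resting cells at total pool size N, 1/day.

    ``delta0 * exp(N/rho)``: minimal at N=0 and growing exponentially as
    cells compete for the survival resource.
    """
    if N < 0:
        raise ValueError(f"total cell number must be nonnegative, got {N}")
    return params.delta0 * math.exp(N / params.rho)


def dividing_death_rate(Y: float, params: ModelParams) -> float:
    """Per-cell AICD rate of dividing cells, ``mu_prime * Y``, 1/day.

    Linear in the dividing-cell density, so the total death flux out of
    the dividing compartment is quadratic, ``mu_prime * Y**2``.
    """
    if Y < 0:
        raise ValueError(f"dividing cell number must be nonnegative, got {Y}")
    return params.mu_prime * Y


def rhs(state: CellState, theta_now: float, params: ModelParams) -> Tuple[float, float]:
    """Time derivatives (dX/dt, dY/dt) in cells/day.

    ``theta_now`` is the instantaneous thymic output (cells/day), allowing
    a time-varying input in pediatric scenarios.  The factor 2 on ``r Y``
    encodes that one completed division returns two resting daughters.
    """
    if theta_now < 0:
        raise ValueError(f"thymic output must be nonnegative, got {theta_now}")
    X, Y = state.X, state.Y
    N = X + Y
    lam = division_rate(N, params)
    dlt = resting_death_rate(N, params)
    dX = theta_now + 2.0 * params.r * Y - lam * X - dlt * X
    dY = lam * X - params.r * Y - params.mu_prime * Y * Y
    return dX, dY
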