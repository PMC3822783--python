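"""Age-dependent thymic output, blood-volume conversion, pediatric scenario.

Thymic export rises over the first year of life to a peak near 2e9
cells/day, then declines roughly exponentially to the young-adult level of
3e8 cells/day by age 20.  The pediatric pipeline integrates the adult
homeostasis model with this time-varying input from birth, and converts
whole-body naive CD4 numbers to a blood concentration (cells/ul) through
an age-dependent blood volume and the fraction of the naive pool that is
circulating in blood at any instant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .params import CellState, ModelParams
from .simulate import integrate

__all__ = [
    "OntogenyConfig",
    "theta_of_age",
    "blood_volume",
    "concentration",
    "simulate_childhood",
]

DAYS_PER_YEAR = 365.25

#: Default blood-volume-for-age table, litres.  A synthetic fixture built
#: from ~80 ml/kg against a standard weight-for-age reference (neonate
#: ~0.3 L rising to ~5 L by age 20); it stands in for cohort-specific
#: blood-volume data and is plain configuration, replaceable per study.
DEFAULT_BLOOD_VOLUME_TABLE: Tuple[Tuple[float, float], ...] = (
    (0.0, 0.30),
    (0.25, 0.45),
    (0.5, 0.60),
    (1.0, 0.80),
    (2.0, 0.95),
    (3.0, 1.10),
    (5.0, 1.50),
    (10.0, 2.60),
    (15.0, 4.00),
    (20.0, 5.00),
)


@dataclass(frozen=True)
class OntogenyConfig:
    """Configuration of the age-dependent input and the blood conversion.

    theta_* anchors are cells/day; ages are years.  ``blood_fraction`` is
    the share of whole-body naive CD4 cells found in blood (default 0.02,
    the standard whole-body-to-blood conversion assumption), and
    ``initial_total`` the whole-body naive CD4 pool at birth.
    """

    theta_birth: float = 4e8
    theta_peak: float = 2e9
    age_peak: float = 1.0
    theta_adult: float = 3e8
    age_adult: float = 20.0
    blood_volume_table: Tuple[Tuple[float, float], ...] = DEFAULT_BLOOD_VOLUME_TABLE
    blood_fraction: float = 0.02
    initial_total: float = 1e10

    def __post_init__(self) -> None:
        for name in ("theta_birth", "theta_peak", "theta_adult", "initial_total"):
            if getattr(self, name) <= 0:
                raise ValueError(f"OntogenyConfig.{name} must be positive")
        if not 0 < self.age_peak < self.age_adult:
            raise ValueError("need 0 < age_peak < age_adult")
        if not self.theta_birth < self.theta_peak:
            raise ValueError("theta_peak must exceed theta_birth (rising limb)")
        if not self.theta_adult < self.theta_peak:
            raise ValueError("theta_peak must exceed theta_adult (declining limb)")
        if not 0 < self.blood_fraction <= 1:
            raise ValueError("blood_fraction must be in (0, 1]")
        tab = tuple((float(a), float(v)) for a, v in self.blood_volume_table)
        ages = [a for a, _ in tab]
        vols = [v for _, v in tab]
        if len(tab) < 2 or any(b <= a for a, b in zip(ages, ages[1:])) or any(
            b <= a for a, b in zip(vols, vols[1:])
        ):
            raise ValueError("blood_volume_table must be strictly increasing in age and volume")
        object.__setattr__(self, "blood_volume_table", tab)

    @property
    def decay_rate(self) -> float:
        """Post-peak exponential decline rate of thymic output, 1/year."""
        return math.log(self.theta_peak / self.theta_adult) / (self.age_adult - self.age_peak)

    def to_dict(self) -> dict:
        d = {
            "theta_birth": self.theta_birth,
            "theta_peak": self.theta_peak,
            "age_peak": self.age_peak,
            "theta_adult": self.theta_adult,
            "age_adult": self.age_adult,
            "blood_volume_table": [list(p) for p in self.blood_volume_table],
            "blood_fraction": self.blood_fraction,
            "initial_total": self.initial_total,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "OntogenyConfig":
        d = dict(d)
        if "blood_volume_table" in d:
            d["blood_volume_table"] = tuple(tuple(p) for p in d["blood_volume_table"])
        return cls(**d)

    def replace(self, **kwargs) -> "OntogenyConfig":
        return replace(self, **kwargs)


def theta_of_age(age, cfg: OntogenyConfig = OntogenyConfig()):
    """Thymic output (cells/day) at the given age(s) in years.

    A smooth cubic rise (zero slope at both birth and the peak) from
    theta_birth to theta_peak over [0, age_peak], followed by an
    exponential decline calibrated to hit theta_adult at age_adult, then
    constant at theta_adult.  Continuous, with the global maximum at
    age_peak.  Scalar in, scalar out; array in, array out.
    """
    a = np.asarray(age, dtype=float)
    if np.any(a < 0):
        raise ValueError("age must be nonnegative")
    u = np.clip(a / cfg.age_peak, 0.0, 1.0)
    rise = cfg.theta_birth + (cfg.theta_peak - cfg.theta_birth) * u * u * (3.0 - 2.0 * u)
    decay = cfg.theta_peak * np.exp(-cfg.decay_rate * (np.minimum(a, cfg.age_adult) - cfg.age_peak))
    out = np.where(a <= cfg.age_peak, rise, decay)
    return float(out) if np.isscalar(age) else out


def blood_volume(age: float, cfg: OntogenyConfig = OntogenyConfig()) -> float:
    """Blood volume in litres at the given age, by linear interpolation.

    Ages outside the table range are rejected rather than extrapolated.
    """
    ages = np.array([a for a, _ in cfg.blood_volume_table])
    vols = np.array([v for _, v in cfg.blood_volume_table])
    if age < ages[0] or age > ages[-1]:
        raise ValueError(
            f"age {age} outside blood-volume table range [{ages[0]}, {ages[-1]}] years"
        )
    return float(np.interp(age, ages, vols))


def concentration(N_total: float, age: float, cfg: OntogenyConfig = OntogenyConfig()) -> float:
    """Blood naive CD4 concentration, cells/ul, from whole-body numbers."""
    if N_total < 0:
        raise ValueError("N_total must be nonnegative")
    vol_ul = blood_volume(age, cfg) * 1e6
    if vol_ul <= 0:
        raise ValueError("blood volume must be positive")
    return cfg.blood_fraction * N_total / vol_ul


def simulate_childhood(
    params: ModelParams,
    cfg: OntogenyConfig = OntogenyConfig(),
    age_end: float = 3.0,
    age_step: float = 0.05,
) -> pd.DataFrame:
    """Predict whole-body numbers and blood concentration from birth.

    Integrates the homeostasis ODEs from (initial_total, 0) with thymic
    output theta(age) and the published adult kinetic parameters held
    fixed, then converts totals to cells/ul through the blood-volume
    curve.  Returns columns age_years, N_total_cells,
    concentration_cells_per_ul on a uniform age grid.
    """
    max_age = cfg.blood_volume_table[-1][0]
    if not 0 < age_end <= max_age:
        raise ValueError(f"age_end must be in (0, {max_age}] years")
    theta_t = lambda t: theta_of_age(t / DAYS_PER_YEAR, cfg)
    traj = integrate(params, CellState(cfg.initial_total, 0.0),
                     age_end * DAYS_PER_YEAR, theta_fn=theta_t)
    ages = np.round(np.arange(0.0, age_end + 0.5 * age_step, age_step), 10)
    N = np.interp(ages * DAYS_PER_YEAR, traj.times, traj.N)
    conc = np.array([concentration(n, a, cfg) for n, a in zip(N, ages)])
    return pd.DataFrame(
        {"age_years": ages, "N_total_cells": N, "concentration_cells_per_ul": conc}
    )
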