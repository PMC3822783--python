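"""Synthetic cross-sectional pediatric cohort: generation, comparison, fitting.

The clinical cohort the pediatric prediction was originally compared
against is not publicly available, so this module generates a synthetic
stand-in with the statistical structure that comparison assumes: ages
sampled uniformly over early childhood and multiplicative, median-one
lognormal measurement noise around the model's concentration curve.  The
comparison and fitting utilities operate on the log scale to match the
noise model.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar

from .ontogeny import OntogenyConfig, simulate_childhood
from .params import ModelParams

__all__ = ["CohortTable", "FitSummary", "FitResult", "generate_cohort", "compare", "fit_parameters"]

#: Parameters the fitter may free: model kinetics plus the blood conversion.
FITTABLE = ("lambda0", "epsilon", "delta0", "blood_fraction")


@dataclass(frozen=True)
class CohortTable:
    """Cross-sectional observations (subject_id, age_years, naive_cd4_cells_per_ul)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["subject_id", "age_years", "naive_cd4_cells_per_ul"]
        if list(self.table.columns) != required:
            raise ValueError(f"cohort table must have columns {required}")
        if len(self.table) and (self.table["naive_cd4_cells_per_ul"] <= 0).any():
            raise ValueError("naive CD4 counts must be positive")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def ages(self) -> np.ndarray:
        return self.table["age_years"].to_numpy()

    @property
    def counts(self) -> np.ndarray:
        return self.table["naive_cd4_cells_per_ul"].to_numpy()

    def to_csv(self, path: Union[str, Path, None] = None) -> Optional[str]:
        if path is None:
            buf = io.StringIO()
            self.table.to_csv(buf, index=False)
            return buf.getvalue()
        self.table.to_csv(path, index=False)
        return None

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "CohortTable":
        return cls(pd.read_csv(path))


@dataclass(frozen=True)
class FitSummary:
    """Agreement between observations and a prediction, on the log scale."""

    rms_log_error: float  # root-mean-square of log(observed/predicted)
    bias: float           # mean of log(observed/predicted)
    n: int


@dataclass(frozen=True)
class FitResult:
    estimates: Dict[str, float]
    objective: float      # RMS log-error at the optimum
    converged: bool
    n_evaluations: int


def _lognormal_sigma(cv: float) -> float:
    """Log-scale s.d. giving a median-1 lognormal with coefficient of variation cv."""
    return math.sqrt(math.log(1.0 + cv * cv))


def generate_cohort(
    params: ModelParams,
    cfg: OntogenyConfig,
    n_subjects: int,
    noise_cv: float = 0.3,
    seed: int = 0,
    age_range: Tuple[float, float] = (0.0, 3.0),
) -> CohortTable:
    """Sample a synthetic cross-sectional cohort around the model curve.

    Ages are uniform on ``age_range``; each subject's count is the model
    concentration at their age times a median-1 lognormal factor with
    coefficient of variation ``noise_cv``.  Fully reproducible from seed.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if noise_cv < 0:
        raise ValueError("noise_cv must be nonnegative")
    rng = np.random.default_rng(seed)
    ages = np.sort(rng.uniform(age_range[0], age_range[1], n_subjects))
    pred = simulate_childhood(params, cfg, age_end=age_range[1], age_step=0.01)
    curve = np.interp(ages, pred["age_years"], pred["concentration_cells_per_ul"])
    sigma = _lognormal_sigma(noise_cv)
    noise = np.exp(rng.normal(0.0, sigma, n_subjects)) if sigma > 0 else np.ones(n_subjects)
    table = pd.DataFrame(
        {
            "subject_id": [f"S{i:04d}" for i in range(n_subjects)],
            "age_years": ages,
            "naive_cd4_cells_per_ul": curve * noise,
        }
    )
    return CohortTable(table)


def compare(cohort: CohortTable, predicted: pd.DataFrame) -> FitSummary:
    """Quantify agreement between a cohort and a predicted concentration curve.

    ``predicted`` must carry age_years and concentration_cells_per_ul
    columns covering the cohort's age range; the curve is interpolated at
    each subject's age and residuals are taken as log(observed/predicted).
    """
    if len(cohort) == 0:
        raise ValueError("cannot compare an empty cohort")
    ages = predicted["age_years"].to_numpy()
    conc = predicted["concentration_cells_per_ul"].to_numpy()
    if cohort.ages.min() < ages.min() or cohort.ages.max() > ages.max():
        raise ValueError("prediction does not cover the cohort age range")
    at_obs = np.interp(cohort.ages, ages, conc)
    resid = np.log(cohort.counts / at_obs)
    return FitSummary(float(np.sqrt(np.mean(resid**2))), float(np.mean(resid)), len(cohort))


def _objective(cohort: CohortTable, params: ModelParams, cfg: OntogenyConfig,
               age_end: float) -> float:
    pred = simulate_childhood(params, cfg, age_end=age_end, age_step=0.02)
    return compare(cohort, pred).rms_log_error


def fit_parameters(
    cohort: CohortTable,
    free: Sequence[str],
    params: ModelParams,
    cfg: OntogenyConfig,
    bounds_factor: float = 10.0,
) -> FitResult:
    """Estimate free parameters by minimizing the RMS log-error to the cohort.

    ``free`` names a subset of lambda0, epsilon, delta0, blood_fraction;
    the search is over log-parameters within ``bounds_factor`` of the
    starting values in ``params``/``cfg`` (positivity enforced by
    construction).  One free parameter uses bounded scalar minimization;
    several use Nelder-Mead on the log scale.
    """
    free = list(free)
    if not free:
        raise ValueError("need at least one free parameter")
    bad = set(free) - set(FITTABLE)
    if bad:
        raise ValueError(f"cannot fit {sorted(bad)}; fittable: {FITTABLE}")
    if len(cohort) < 2:
        raise ValueError("need at least two observations to fit")
    age_end = float(np.ceil(cohort.ages.max() * 20) / 20)  # cover range, 0.05-yr granularity
    start = {
        name: (cfg.blood_fraction if name == "blood_fraction" else getattr(params, name))
        for name in free
    }
    n_eval = 0

    def build(log_vals: np.ndarray) -> Tuple[ModelParams, OntogenyConfig]:
        vals = dict(zip(free, np.exp(log_vals)))
        p = params.replace(**{k: v for k, v in vals.items() if k != "blood_fraction"})
        c = cfg.replace(blood_fraction=min(vals["blood_fraction"], 1.0)) \
            if "blood_fraction" in vals else cfg
        return p, c

    def obj(log_vals: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        p, c = build(np.atleast_1d(log_vals))
        return _objective(cohort, p, c, age_end)

    x0 = np.log([start[k] for k in free])
    half_width = math.log(bounds_factor)
    if len(free) == 1:
        res = minimize_scalar(
            lambda v: obj(np.array([v])),
            bounds=(x0[0] - half_width, x0[0] + half_width),
            method="bounded",
            options={"xatol": 1e-6},
        )
        x_opt, f_opt, ok = np.array([res.x]), res.fun, bool(res.success)
    else:
        res = minimize(
            obj, x0, method="Nelder-Mead",
            bounds=[(x - half_width, x + half_width) for x in x0],
            options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 2000},
        )
        x_opt, f_opt, ok = res.x, res.fun, bool(res.success)
    estimates = dict(zip(free, np.exp(x_opt)))
    return FitResult({k: float(v) for k, v in estimates.items()}, float(f_opt), ok, n_eval)
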