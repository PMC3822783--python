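"""Pipeline stages tying the library together; each writes CSV artifacts.

These are the computational bodies behind both the command-line interface
and the numbered analysis drivers.  Every stage logs its resolved
configuration next to its outputs so a run is reproducible from the
artifact directory alone.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .cohort import compare, generate_cohort
from .config import RunConfig
from .equilibrium import steady_state, threshold_scan
from .ontogeny import simulate_childhood
from .params import CellState
from .simulate import adult_scenarios, convergence_time, interdivision_time, peak_ratio

log = logging.getLogger("tcellhom")

__all__ = ["run_adult", "run_stability", "run_child", "run_cohort"]


def _prepare(outdir, cfg: RunConfig, stage: str) -> Path:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    resolved = {"stage": stage, "version": __version__, **cfg.to_dict()}
    (out / f"{stage}_config.json").write_text(json.dumps(resolved, indent=2))
    log.info("stage %s (tcellhom %s) -> %s", stage, __version__, out)
    log.info("resolved config: %s", json.dumps(resolved))
    return out


def run_adult(cfg: RunConfig, outdir) -> dict:
    """Adult homeostasis: both published starts, equilibrium and derived stats."""
    out = _prepare(outdir, cfg, "adult")
    eq = steady_state(cfg.model)
    trajs = adult_scenarios(cfg.model, t_end=cfg.t_end_days)
    summary = {
        "N_star_cells": eq.N,
        "X_star_cells": eq.state.X,
        "Y_star_cells": eq.state.Y,
        "ratio_percent": 100.0 * eq.ratio,
        "leading_eigen_real_per_day": eq.leading_eigen_real,
        "stable": eq.stable,
        "residual_cells_per_day": eq.residual,
        "interdivision_time_days": interdivision_time(eq.state, cfg.model),
    }
    for name, traj in trajs.items():
        traj.to_frame().to_csv(out / f"adult_{name}.csv", index=False)
        summary[f"{name}_N_final_cells"] = float(traj.N[-1])
        summary[f"{name}_convergence_days"] = convergence_time(traj)
        summary[f"{name}_peak_ratio"] = peak_ratio(traj)
    (out / "adult_summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def run_stability(cfg: RunConfig, outdir) -> pd.DataFrame:
    """Critical-value scan over every rate parameter; writes the threshold table."""
    out = _prepare(outdir, cfg, "stability")
    table = threshold_scan(cfg.model, brackets=cfg.brackets)
    table.to_csv(out / "stability_thresholds.csv", index=False)
    for row in table.itertuples():
        found = "none in bracket" if pd.isna(row.critical_value) else f"{row.critical_value:.6g}"
        log.info("threshold %s in [%.4g, %.4g]: %s", row.parameter,
                 row.bracket_lo, row.bracket_hi, found)
    return table


def run_child(cfg: RunConfig, outdir, with_cohort: bool = False) -> dict:
    """Pediatric prediction over early childhood; optional synthetic cohort check."""
    out = _prepare(outdir, cfg, "child")
    pred = simulate_childhood(cfg.model, cfg.ontogeny,
                              age_end=cfg.age_end_years, age_step=cfg.age_step_years)
    pred.to_csv(out / "child_prediction.csv", index=False)
    conc = pred["concentration_cells_per_ul"]
    summary = {
        "age_end_years": cfg.age_end_years,
        "concentration_birth": float(conc.iloc[0]),
        "concentration_peak": float(conc.max()),
        "age_at_peak_years": float(pred["age_years"][conc.idxmax()]),
        "concentration_end": float(conc.iloc[-1]),
        "N_total_end_cells": float(pred["N_total_cells"].iloc[-1]),
    }
    if with_cohort:
        cohort = generate_cohort(cfg.model, cfg.ontogeny, cfg.cohort_n,
                                 noise_cv=cfg.cohort_noise_cv, seed=cfg.seed,
                                 age_range=(0.0, cfg.age_end_years))
        cohort.to_csv(out / "child_cohort.csv")
        fit = compare(cohort, pred)
        summary.update(cohort_rms_log_error=fit.rms_log_error,
                       cohort_bias=fit.bias, cohort_n=fit.n)
    (out / "child_summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def run_cohort(cfg: RunConfig, outdir) -> dict:
    """Generate a synthetic cohort and score it against the model curve."""
    out = _prepare(outdir, cfg, "cohort")
    cohort = generate_cohort(cfg.model, cfg.ontogeny, cfg.cohort_n,
                             noise_cv=cfg.cohort_noise_cv, seed=cfg.seed,
                             age_range=(0.0, cfg.age_end_years))
    cohort.to_csv(out / "cohort.csv")
    pred = simulate_childhood(cfg.model, cfg.ontogeny,
                              age_end=cfg.age_end_years, age_step=cfg.age_step_years)
    fit = compare(cohort, pred)
    summary = {"n": fit.n, "rms_log_error": fit.rms_log_error, "bias": fit.bias,
               "noise_cv": cfg.cohort_noise_cv, "seed": cfg.seed}
    (out / "cohort_summary.json").write_text(json.dumps(summary, indent=2))
    return summary
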