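#!/usr/bin/env python
"""Synthetic-cohort round trip and parameter recovery.

The clinical cohort behind the original pediatric comparison is not
available, so this driver generates a synthetic cross-sectional cohort
(ages uniform on 0-3 years, median-one lognormal noise, CV 0.3) around
the model curve, scores the agreement on the log scale, and checks that
the division-entry rate lambda0 is recoverable by fitting.  Finding: the
RMS log-error of the generated cohort matches the injected noise
(sqrt(ln(1+0.3^2)) ~ 0.294) with negligible bias, and the median relative
error of the recovered lambda0 across 10 seeds is a few percent.
Writes cohort and summaries under results/.
"""

import json
import logging
from pathlib import Path

import numpy as np

from tcellhom import RunConfig, default_params, fit_parameters, generate_cohort
from tcellhom.pipelines import run_cohort

logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")

cfg = RunConfig(seed=0, cohort_n=500, cohort_noise_cv=0.3)
s = run_cohort(cfg, "results/cohort")
print(f"cohort n={s['n']}: RMS log-error {s['rms_log_error']:.4f} "
      f"(injected {np.sqrt(np.log(1 + 0.3**2)):.4f}), bias {s['bias']:+.4f}")

params = default_params()
errors = []
for seed in range(10):
    cohort = generate_cohort(params, cfg.ontogeny, 500, noise_cv=0.3, seed=seed)
    fit = fit_parameters(cohort, ["lambda0"], params.replace(lambda0=0.08), cfg.ontogeny)
    err = abs(fit.estimates["lambda0"] - params.lambda0) / params.lambda0
    errors.append(err)
    print(f"seed {seed}: lambda0 = {fit.estimates['lambda0']:.5f} "
          f"(truth 0.055, error {100 * err:.1f}%)")
med = float(np.median(errors))
print(f"median relative error of recovered lambda0: {100 * med:.1f}%")
Path("results/cohort/recovery.json").write_text(
    json.dumps({"errors": errors, "median": med}, indent=2))
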