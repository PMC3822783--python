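"""Run configuration: one structured file carrying every science parameter.

Science parameters (model rates, ontogeny anchors, cohort settings) live in
a single YAML file with ``model``, ``ontogeny`` and ``run`` sections so a
run is reproducible from its logged configuration alone; command-line
flags are reserved for paths and verbosity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

from .ontogeny import OntogenyConfig
from .params import ModelParams

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    model: ModelParams = field(default_factory=ModelParams)
    ontogeny: OntogenyConfig = field(default_factory=OntogenyConfig)
    seed: int = 0
    t_end_days: float = 1000.0        # adult scenario horizon
    age_end_years: float = 3.0        # pediatric horizon
    age_step_years: float = 0.05
    cohort_n: int = 500
    cohort_noise_cv: float = 0.3
    rtol: float = 1e-8
    atol_units: float = 1e-12
    brackets: Optional[dict] = None   # stability-scan brackets, absolute units

    def __post_init__(self) -> None:
        if self.t_end_days <= 0 or self.age_end_years <= 0 or self.age_step_years <= 0:
            raise ValueError("horizons and steps must be positive")
        if self.cohort_n < 1 or self.cohort_noise_cv < 0:
            raise ValueError("invalid cohort settings")

    def to_dict(self) -> dict:
        run = {
            "seed": self.seed,
            "t_end_days": self.t_end_days,
            "age_end_years": self.age_end_years,
            "age_step_years": self.age_step_years,
            "cohort_n": self.cohort_n,
            "cohort_noise_cv": self.cohort_noise_cv,
            "rtol": self.rtol,
            "atol_units": self.atol_units,
        }
        if self.brackets is not None:
            run["brackets"] = {k: list(v) for k, v in self.brackets.items()}
        return {"model": self.model.to_dict(), "ontogeny": self.ontogeny.to_dict(), "run": run}

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        run = dict(d.get("run", {}))
        if "brackets" in run:
            run["brackets"] = {k: tuple(v) for k, v in run["brackets"].items()}
        return cls(
            model=ModelParams.from_dict(d.get("model", {})) if d.get("model") else ModelParams(),
            ontogeny=OntogenyConfig.from_dict(d.get("ontogeny", {})) if d.get("ontogeny")
            else OntogenyConfig(),
            **run,
        )

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
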