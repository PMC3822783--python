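"""Model parameterization and cell-compartment state.

All public quantities are in absolute units (cells, days).  Table-style
"model units" of ``cell_unit`` cells (default 1e11, roughly the replete
adult naive CD4 pool) are used internally for solver conditioning and in
reports, because the resource scales of the competition terms are naturally
of order one on that scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Union

import yaml

__all__ = ["ModelParams", "CellState", "default_params"]

#: Default mapping from absolute cells to model units.
DEFAULT_CELL_UNIT = 1e11


@dataclass(frozen=True)
class ModelParams:
    """Rate constants and resource scales of the two-compartment model.

    Parameters
    ----------
    theta : float
        Thymic output, cells/day.  Constant in adult scenarios; the
        pediatric pipeline supplies an age-dependent value instead.
    lambda0 : float
        Intrinsic rate of entry into cell division under no competition
        (unlimited IL-7 / self-peptide MHC signal), 1/day.
    epsilon : float
        Resource scale for division entry, cells.  The per-cell division
        rate is ``lambda0 * exp(-N / epsilon)``.
    delta0 : float
        Intrinsic death rate of resting cells under no competition, 1/day.
    rho : float
        Resource scale for resting-cell survival, cells.  The per-cell
        resting death rate is ``delta0 * exp(N / rho)``.
    r : float
        Rate of return from the dividing to the resting state, 1/day
        (4/day, i.e. one division completed in about 6 h).
    mu_prime : float
        Slope of the density-dependent death rate of dividing cells
        (Fas/FasL-mediated AICD), 1/day per cell: the per-cell death rate
        of dividing cells is ``mu_prime * Y``.
    cell_unit : float
        Cells per internal model unit; affects only internal scaling and
        reporting, never the dynamics in absolute units.
    """

    theta: float = 3e8
    lambda0: float = 0.055
    epsilon: float = 1.0 * DEFAULT_CELL_UNIT
    delta0: float = 0.02
    rho: float = 100.0 * DEFAULT_CELL_UNIT
    r: float = 4.0
    mu_prime: float = 15.0 / DEFAULT_CELL_UNIT
    cell_unit: float = DEFAULT_CELL_UNIT

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (isinstance(v, (int, float)) and v > 0):
                raise ValueError(f"ModelParams.{f.name} must be strictly positive, got {v!r}")

    # -- model-unit views (for reports matching the published table) -------
    @property
    def theta_units(self) -> float:
        """Thymic output in model units per day."""
        return self.theta / self.cell_unit

    @property
    def epsilon_units(self) -> float:
        return self.epsilon / self.cell_unit

    @property
    def rho_units(self) -> float:
        return self.rho / self.cell_unit

    @property
    def mu_prime_units(self) -> float:
        """AICD slope per model unit of dividing cells (1/day per cell_unit cells)."""
        return self.mu_prime * self.cell_unit

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown model parameter keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump({"model": self.to_dict()}, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "ModelParams":
        data = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(data["model"] if "model" in data else data)

    def replace(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class CellState:
    """Sizes of the resting (X) and dividing (Y) naive CD4 compartments, cells."""

    X: float
    Y: float

    def __post_init__(self) -> None:
        if self.X < 0 or self.Y < 0:
            raise ValueError(f"cell counts must be nonnegative, got X={self.X}, Y={self.Y}")

    @property
    def N(self) -> float:
        """Total naive CD4 cells, X + Y."""
        return self.X + self.Y

    @property
    def ratio(self) -> float:
        """Dividing:resting ratio Y/X."""
        if self.X == 0:
            raise ZeroDivisionError("ratio undefined: no resting cells")
        return self.Y / self.X


def default_params() -> ModelParams:
    """Published adult parameter set (20-year-old thymic output)."""
    return ModelParams()
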