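"""Post-fit summaries: rates, proliferated proportions, mass accounting.

These operations turn a fitted parameter set into the quantities a
regeneration study reports: the time-averaged division rate of active
cells, the fraction of the population descended from a division, and the
contribution of proliferation (and of duct-associated islet-like cell
clusters, ICCs) to tissue mass over the two-week horizon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .kinetics import ModelParameters, cumulative_rate

__all__ = [
    "average_active_rate",
    "proliferated_proportion",
    "proliferation_mass_contribution",
    "icc_mass_contribution",
    "MassAccounting",
]

#: Sections obtainable from one pancreas (stereology convention).
DEFAULT_SECTIONS = 500
#: Single-cell mass from water density, mg per cell.
DEFAULT_CELL_MASS = 1.8e-6
#: An ICC comprises five or fewer insulin-positive cells.
DEFAULT_CELLS_PER_ICC = 5


def average_active_rate(params: ModelParameters, t0: float = 0.0, t1: float = 14.0) -> float:
    """Time-averaged proliferation rate of active cells, percent per day."""
    if not (t0 < t1):
        raise ValueError("t0 must be < t1")
    return 100.0 * cumulative_rate(params, t0, t1) / (t1 - t0)


def _n_active(params: ModelParameters, t: float, origin: float = 0.0) -> float:
    return math.exp(-cumulative_rate(params, origin, t))


def proliferated_proportion(params: ModelParameters, t: float) -> float:
    """Fraction of the whole population that has proliferated by day t.

    With N_A anchored to 1 at day 0, this is 2 (1 - N_A(t)) / n_total(t);
    it is non-decreasing in t and tends to 2 / (f + 2) as the active pool
    exhausts.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    na = _n_active(params, t)
    return 2.0 * (1.0 - na) / (params.f + 2.0 - na)


def proliferation_mass_contribution(
    params: ModelParameters, initial_mass: float, horizon: float = 14.0
) -> tuple[float, float]:
    """Mass produced by cell division over ``horizon`` days.

    The new-cell fraction is (n_total(horizon) - n_total(0)) / n_total(0)
    = (1 - N_A(horizon)) / (1 + f); returns ``(mg, percent of the initial
    mass)``.
    """
    if not (initial_mass > 0):
        raise ValueError("initial_mass must be > 0")
    fraction = (1.0 - _n_active(params, horizon)) / (1.0 + params.f)
    return initial_mass * fraction, 100.0 * fraction


def icc_mass_contribution(
    icc_delta_per_section: float,
    cells_per_icc: float = DEFAULT_CELLS_PER_ICC,
    sections: float = DEFAULT_SECTIONS,
    cell_mass: float = DEFAULT_CELL_MASS,
) -> float:
    """Mass (mg) represented by an increase in ICC counts per section."""
    for name, v in (
        ("icc_delta_per_section", icc_delta_per_section),
        ("cells_per_icc", cells_per_icc),
        ("sections", sections),
        ("cell_mass", cell_mass),
    ):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    return icc_delta_per_section * cells_per_icc * sections * cell_mass


@dataclass(frozen=True)
class MassAccounting:
    """Bookkeeping of the beta-cell mass increase over the study horizon."""

    initial_mass: float
    final_mass: float
    proliferation_new_cell_fraction: float
    proliferation_mass: float
    icc_delta_per_section: float
    icc_mass: float
    sections_per_pancreas: float = DEFAULT_SECTIONS
    cells_per_icc: float = DEFAULT_CELLS_PER_ICC
    cell_mass: float = DEFAULT_CELL_MASS

    def __post_init__(self) -> None:
        for name in ("initial_mass", "final_mass", "proliferation_mass", "icc_mass"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (1 <= self.cells_per_icc <= 5):
            raise ValueError("cells_per_icc must be in [1, 5]")

    @classmethod
    def from_fit(
        cls,
        params: ModelParameters,
        initial_mass: float,
        final_mass: float,
        icc_delta_per_section: float = 0.0,
        horizon: float = 14.0,
        cells_per_icc: float = DEFAULT_CELLS_PER_ICC,
        sections: float = DEFAULT_SECTIONS,
        cell_mass: float = DEFAULT_CELL_MASS,
    ) -> "MassAccounting":
        mg, pct = proliferation_mass_contribution(params, initial_mass, horizon)
        icc_mg = icc_mass_contribution(icc_delta_per_section, cells_per_icc, sections, cell_mass)
        return cls(
            initial_mass=initial_mass,
            final_mass=final_mass,
            proliferation_new_cell_fraction=pct / 100.0,
            proliferation_mass=mg,
            icc_delta_per_section=icc_delta_per_section,
            icc_mass=icc_mg,
            sections_per_pancreas=sections,
            cells_per_icc=cells_per_icc,
            cell_mass=cell_mass,
        )

    @property
    def unexplained_mass(self) -> float:
        """Mass increase not covered by proliferation or ICC neogenesis."""
        return (self.final_mass - self.initial_mass) - self.proliferation_mass - self.icc_mass
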