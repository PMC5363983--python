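"""Benthic food supply: cell counts to bottom carbon, and competitive depletion.

*N. spinipes* is a bottom dweller, so the resource axis of the model is the
food carbon per vessel floor area (ug C/cm2) rather than the volumetric
algal concentration.  A nominal ration in cells/mL is translated through
the vessel volume, a carbon-per-cell conversion and the bottom area.  Food
is fully replaced every second day; between feedings the only sink is
consumption, which is resolved in 1440 one-minute steps per day: every
minute each living individual ingests its Holling type III ration at the
current concentration, and the total is removed from the vessel.  When the
aggregate minute demand exceeds the remaining food, intake is allocated in
proportion to demand and the pool floors at zero.  The loop is
deterministic given the stage composition, so runs are replayable.

The carbon-per-cell conversion (26.4 pg C per *Rhodomonas salina* cell) is
calibrated so that the standard ration of 2.5e5 cells/mL in 6-well geometry
yields the reference bottom concentration of 5.5 ug C/cm2 — the condition
that reproduces the printed food normalizing factors.  See
``scripts/derive_carbon_per_cell.py`` for the derivation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Iterable, Optional, Tuple

import numpy as np

from .responses import STAGES, ResponseFunctionSet, default_responses

__all__ = [
    "CARBON_PER_CELL_UG", "MINUTES_PER_DAY", "VESSEL_PRESETS",
    "Vessel", "FoodState",
    "cells_to_bottom_concentration", "feeding_schedule", "simulate_feeding_day",
]

#: Calibrated carbon content of one R. salina cell, ug C (26.4 pg).
CARBON_PER_CELL_UG = 2.64e-5

MINUTES_PER_DAY = 1440


@dataclass(frozen=True)
class Vessel:
    """Incubation vessel geometry.

    Presets use standard labware dimensions for the plate formats of the
    life-cycle experiments; all values can be overridden.
    """

    volume_mL: float
    bottom_area_cm2: float
    carbon_per_cell_ug: float = CARBON_PER_CELL_UG

    def __post_init__(self) -> None:
        for name in ("volume_mL", "bottom_area_cm2", "carbon_per_cell_ug"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")

    @classmethod
    def from_preset(cls, name: str, **overrides) -> "Vessel":
        try:
            preset = VESSEL_PRESETS[name]
        except KeyError:
            raise ValueError(
                f"unknown vessel preset {name!r}; available: {sorted(VESSEL_PRESETS)}"
            ) from None
        return replace(preset, **overrides)

    def scaled(self, factor: float) -> "Vessel":
        """Vessel scaled in volume and floor area (e.g. a cohort sharing
        several wells at identical per-capita loading)."""
        if factor <= 0:
            raise ValueError(f"scale factor must be > 0, got {factor}")
        return replace(self, volume_mL=self.volume_mL * factor,
                       bottom_area_cm2=self.bottom_area_cm2 * factor)

    def nominal_carbon(self, cells_per_mL: float) -> float:
        """Total food carbon (ug) in the vessel at a nominal ration."""
        if cells_per_mL < 0:
            raise ValueError(f"cells/mL must be >= 0, got {cells_per_mL}")
        return cells_per_mL * self.volume_mL * self.carbon_per_cell_ug


VESSEL_PRESETS = {
    "96-well": Vessel(volume_mL=0.27, bottom_area_cm2=0.32),
    "24-well": Vessel(volume_mL=2.0, bottom_area_cm2=1.9),
    "6-well": Vessel(volume_mL=8.0, bottom_area_cm2=9.6),
}


@dataclass
class FoodState:
    """Food carbon currently in a vessel."""

    total_carbon_ug: float
    bottom_area_cm2: float
    last_feed_day: int = 0

    def __post_init__(self) -> None:
        if self.total_carbon_ug < 0:
            raise ValueError("total carbon must be >= 0")
        if self.bottom_area_cm2 <= 0:
            raise ValueError("bottom area must be > 0")

    @property
    def bottom_concentration(self) -> float:
        """ug C per cm2 of vessel floor."""
        return self.total_carbon_ug / self.bottom_area_cm2


def cells_to_bottom_concentration(cells_per_mL: float, vessel: Vessel) -> float:
    """Translate a nominal algal concentration into ug C/cm2 of vessel floor:
    ``cells_per_mL * volume * carbon_per_cell / bottom_area``."""
    return vessel.nominal_carbon(cells_per_mL) / vessel.bottom_area_cm2


def feeding_schedule(day: int, interval_days: int = 2) -> bool:
    """Whether `day` (0-based) is a feeding day.  Food is fully replaced —
    not topped up — every `interval_days` days (days 0, 2, 4, ...)."""
    if day < 0:
        raise ValueError(f"day must be >= 0, got {day}")
    return day % interval_days == 0


def _minute_loop_py(total_carbon: float, area: float, counts: np.ndarray,
                    a_max: np.ndarray, k2: np.ndarray
                    ) -> Tuple[np.ndarray, float]:
    per_capita = np.zeros(3)
    for _ in range(MINUTES_PER_DAY):
        if total_carbon <= 0.0:
            break
        conc2 = (total_carbon / area) ** 2
        demand = 0.0
        rates = np.empty(3)
        for s in range(3):
            rates[s] = a_max[s] * conc2 / (conc2 + k2[s]) / MINUTES_PER_DAY
            demand += counts[s] * rates[s]
        if demand <= 0.0:
            break
        if demand > total_carbon:
            scale = total_carbon / demand
            for s in range(3):
                rates[s] *= scale
            demand = total_carbon
        for s in range(3):
            per_capita[s] += rates[s]
        total_carbon -= demand
        if total_carbon < 0.0:
            total_carbon = 0.0
    return per_capita, total_carbon


try:  # numba speeds the 1440-step loop up ~100x; the pure loop is equivalent
    from numba import njit

    _minute_loop = njit(cache=False)(_minute_loop_py)
except ImportError:  # pragma: no cover
    _minute_loop = _minute_loop_py


def minute_loop_by_stage(total_carbon_ug: float, bottom_area_cm2: float,
                         counts: Dict[str, int],
                         responses: Optional[ResponseFunctionSet] = None
                         ) -> Tuple[Dict[str, float], float]:
    """Run one day of minute-resolution competitive feeding.

    Parameters
    ----------
    counts
        Living individuals per stage, ``{"nauplius": n, ...}``.

    Returns
    -------
    per_capita, remaining
        Daily ingested carbon per individual of each stage (ug C) and the
        food carbon left in the vessel.  Mass balance is exact:
        ``total - remaining == sum(counts[s] * per_capita[s])``.
    """
    responses = responses or default_responses()
    n = np.array([float(counts.get(s, 0)) for s in STAGES])
    a_max = np.array([responses.ingestion_maximum(s) for s in STAGES])
    k2 = np.array([responses.ingestion_half_saturation(s) ** 2 for s in STAGES])
    per_capita, remaining = _minute_loop(float(total_carbon_ug),
                                         float(bottom_area_cm2), n, a_max, k2)
    return dict(zip(STAGES, per_capita.tolist())), float(remaining)


def simulate_feeding_day(food: FoodState, individuals: Iterable,
                         responses: Optional[ResponseFunctionSet] = None
                         ) -> Tuple[Dict[int, float], FoodState]:
    """Feed a collection of individuals for one day.

    Returns per-individual daily ingested carbon (by ``id``) and the updated
    food state.  Dead individuals do not feed.  Within a stage, intake is
    identical (the loop is deterministic given the stage composition).
    """
    alive = [ind for ind in individuals if ind.alive]
    counts: Dict[str, int] = {}
    for ind in alive:
        counts[ind.stage] = counts.get(ind.stage, 0) + 1
    per_capita, remaining = minute_loop_by_stage(
        food.total_carbon_ug, food.bottom_area_cm2, counts, responses)
    intake = {ind.id: per_capita[ind.stage] for ind in alive}
    new_food = FoodState(total_carbon_ug=remaining,
                         bottom_area_cm2=food.bottom_area_cm2,
                         last_feed_day=food.last_feed_day)
    return intake, new_food
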