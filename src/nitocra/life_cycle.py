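"""Individual copepod state machine: development, survival, sex, reproduction.

An individual passes irreversibly through the aggregated naupliar and
copepodite phases to adulthood (the six naupliar and five copepodite
instars are not resolved).  Each phase carries a gamma-distributed duration
deviate with mean 1 and shape alpha, drawn once on phase entry; development
progress accumulates the daily rate and the phase completes on the day the
cumulative sum reaches the deviate.  Under a constant rate the realized
duration is therefore ``deviate / rate`` — gamma with mean ``1/rate`` and
CV ``1/sqrt(alpha)`` — which reproduces the positive skew ("laggard"
animals) of observed development-time distributions.

Mortality is a daily Bernoulli draw per stage.  Sex is assigned once, at
adulthood.  Fertilized females run a latency phase (fertilization to first
clutch) and then cycle embryonic development, releasing a clutch of
normally-distributed, rounded, zero-truncated size at each completion until
their drawn brood count is exhausted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

__all__ = [
    "NAUPLIUS", "COPEPODITE", "ADULT",
    "LifeCycleParameters", "Individual", "Clutch",
    "draw_development_deviate", "advance_development", "apply_daily_survival",
    "draw_brood_size", "draw_brood_count", "assign_sex", "step_reproduction",
]

NAUPLIUS = "nauplius"
COPEPODITE = "copepodite"
ADULT = "adult"

_STAGE_ORDER = (NAUPLIUS, COPEPODITE, ADULT)


@dataclass
class LifeCycleParameters:
    """Individual-level parameters at reference conditions (22 C, abundant food).

    Rates are in d^-1; ``alpha_*`` are gamma shapes of the duration deviates
    (the rates, as reciprocals of gamma durations, are inverse-gamma
    distributed); ``pS_*`` are daily death probabilities.
    """

    pN_DEV: float = 0.129     # naupliar development rate
    pC_DEV: float = 0.111     # copepodite development rate
    pL: float = 0.308         # latency (fertilization to first clutch) rate
    pE_DEV: float = 0.315     # embryonic development (inter-clutch) rate
    alpha_N: float = 30.0
    alpha_C: float = 14.3
    alpha_L: float = 26.1
    alpha_E: float = 3.5
    pBS: float = 24.0         # mean brood size, nauplii per clutch
    cv_BS: float = 0.44
    pNB: float = 3.64         # mean broods per female
    cv_NB: float = 0.37
    pS_NAU: float = 2.65e-3
    pS_COP: float = 4.83e-3
    pS_ADU: float = 3.19e-3
    p_female: float = 0.5

    def __post_init__(self) -> None:
        for name in ("pN_DEV", "pC_DEV", "pL", "pE_DEV",
                     "alpha_N", "alpha_C", "alpha_L", "alpha_E"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("pBS", "pNB", "cv_BS", "cv_NB"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("pS_NAU", "pS_COP", "pS_ADU", "p_female"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    def alpha_for_stage(self, stage: str) -> float:
        return {NAUPLIUS: self.alpha_N, COPEPODITE: self.alpha_C}[stage]


@dataclass
class Clutch:
    """One clutch release event."""
    female_id: int
    day: int
    size: int
    #: time since fertilization (first clutch) or since the previous clutch,
    #: in days, with the completion day interpolated fractionally
    period: float


@dataclass
class Individual:
    """State of one copepod."""

    id: int
    stage: str = NAUPLIUS
    sex: Optional[str] = None          # None until adulthood; "female"/"male"
    alive: bool = True
    age: float = 0.0                   # days
    born_day: int = 0
    development_deviate: float = 1.0   # gamma(mean 1) threshold of current phase
    development_progress: float = 0.0  # cumulative daily rates this phase
    days_in_stage: int = 0
    fertilized: bool = False
    repro_phase: Optional[str] = None  # "latency" | "embryo" once fertilized
    repro_deviate: float = 1.0
    repro_progress: float = 0.0
    days_in_repro_phase: float = 0.0   # fractional days since phase start
    broods_remaining: int = 0
    brood_records: List[Clutch] = field(default_factory=list)
    ingested_today: float = 0.0        # ug C

    @property
    def is_adult_female(self) -> bool:
        return self.alive and self.stage == ADULT and self.sex == "female"

    @property
    def is_adult_male(self) -> bool:
        return self.alive and self.stage == ADULT and self.sex == "male"


def draw_development_deviate(shape: float, rng: np.random.Generator) -> float:
    """Gamma deviate with mean 1 and shape `shape` (scale ``1/shape``).

    Durations realized as ``deviate / rate`` are gamma with CV
    ``1/sqrt(shape)``; the distribution degenerates to 1 as shape grows.
    """
    if shape <= 0:
        raise ValueError(f"gamma shape must be > 0, got {shape}")
    return float(rng.gamma(shape, 1.0 / shape))


def advance_development(ind: Individual, daily_rate: float) -> Optional[float]:
    """Advance one day of development; return the fractional duration of the
    completed phase, or ``None`` if the phase continues.

    The phase completes on the first day the cumulative rate reaches the
    individual's deviate; the returned duration interpolates the crossing
    within that day, so under a constant rate it equals ``deviate / rate``
    exactly.  The caller is responsible for the stage transition (drawing
    the next phase's deviate and resetting progress).
    """
    if not ind.alive:
        raise ValueError(f"individual {ind.id} is dead")
    if daily_rate < 0:
        raise ValueError(f"daily rate must be >= 0, got {daily_rate}")
    before = ind.development_progress
    ind.development_progress = before + daily_rate
    ind.days_in_stage += 1
    if ind.development_progress >= ind.development_deviate and daily_rate > 0:
        return (ind.days_in_stage - 1) + (ind.development_deviate - before) / daily_rate
    return None


def apply_daily_survival(ind: Individual, p_death: float,
                         rng: np.random.Generator) -> bool:
    """One daily Bernoulli survival trial; returns ``True`` if the individual
    died today.  Expected survival over d days is ``(1 - p_death)^d``."""
    if not 0.0 <= p_death <= 1.0:
        raise ValueError(f"death probability must be in [0, 1], got {p_death}")
    if not ind.alive:
        return False
    if rng.random() < p_death:
        ind.alive = False
        return True
    return False


def draw_brood_size(mean: float, cv: float, rng: np.random.Generator) -> int:
    """Clutch size: normal(mean, cv*mean) rounded to the nearest integer and
    truncated at zero.  A zero draw is a failed brood."""
    if mean < 0:
        raise ValueError(f"mean brood size must be >= 0, got {mean}")
    if cv == 0:
        return max(0, round(mean))
    return max(0, round(rng.normal(mean, cv * mean)))


def draw_brood_count(mean: float = 3.64, cv: float = 0.37,
                     rng: Optional[np.random.Generator] = None) -> int:
    """Number of broods a female will produce; same sampler as brood size."""
    if rng is None:
        raise ValueError("an rng is required")
    return draw_brood_size(mean, cv, rng)


def assign_sex(ind: Individual, p_female: float, rng: np.random.Generator) -> str:
    """Assign sex at adulthood (Bernoulli, once).  No temperature or food
    model function exists for the sex ratio; ``p_female`` defaults to 0.5."""
    if ind.sex is not None:
        raise ValueError(f"individual {ind.id} already has sex {ind.sex!r}")
    if not 0.0 <= p_female <= 1.0:
        raise ValueError(f"p_female must be in [0, 1], got {p_female}")
    ind.sex = "female" if rng.random() < p_female else "male"
    return ind.sex


def step_reproduction(ind: Individual, pL_eff: float, pE_eff: float,
                      bs_mean_eff: float, cv_bs: float, alpha_L: float,
                      alpha_E: float, rng: np.random.Generator,
                      day: int = 0) -> Optional[Clutch]:
    """Advance one day of a fertilized female's reproductive cycle.

    The latency phase (rate `pL_eff`) runs from fertilization to the first
    clutch; afterwards the embryonic phase (rate `pE_eff`) cycles, releasing
    a clutch of ``draw_brood_size(bs_mean_eff, cv_bs)`` nauplii at each
    completion and redrawing a fresh deviate, until ``broods_remaining`` is
    exhausted.  Clutch periods are recorded with the completion day
    interpolated fractionally.
    """
    if not ind.is_adult_female:
        raise ValueError(f"individual {ind.id} is not a living adult female")
    if not ind.fertilized:
        raise ValueError(f"female {ind.id} is not fertilized")
    if ind.broods_remaining <= 0:
        return None
    in_latency = ind.repro_phase == "latency"
    rate = pL_eff if in_latency else pE_eff
    if rate < 0:
        raise ValueError(f"reproductive rate must be >= 0, got {rate}")
    before = ind.repro_progress
    ind.repro_progress = before + rate
    ind.days_in_repro_phase += 1.0
    if rate <= 0 or ind.repro_progress < ind.repro_deviate:
        return None
    # fractional completion time within this day
    overshoot = 1.0 - (ind.repro_deviate - before) / rate
    period = ind.days_in_repro_phase - overshoot
    clutch = Clutch(female_id=ind.id, day=day,
                    size=draw_brood_size(bs_mean_eff, cv_bs, rng),
                    period=period)
    ind.brood_records.append(clutch)
    ind.broods_remaining -= 1
    # embryo production resumes immediately: the remainder of the completion
    # day accrues progress for the next phase at the embryonic rate, so
    # under constant rates the wall-clock inter-clutch period equals
    # deviate / rate exactly
    ind.repro_phase = "embryo"
    ind.repro_deviate = draw_development_deviate(alpha_E, rng)
    ind.repro_progress = pE_eff * overshoot
    ind.days_in_repro_phase = overshoot
    return clutch


def start_fertilization(ind: Individual, params: LifeCycleParameters,
                        rng: np.random.Generator) -> None:
    """Mark a female as fertilized and start her latency clock."""
    if not ind.is_adult_female:
        raise ValueError(f"individual {ind.id} is not a living adult female")
    if ind.fertilized:
        return
    ind.fertilized = True
    ind.repro_phase = "latency"
    ind.repro_deviate = draw_development_deviate(params.alpha_L, rng)
    ind.repro_progress = 0.0
    ind.days_in_repro_phase = 0.0
    ind.broods_remaining = draw_brood_count(params.pNB, params.cv_NB, rng)


def next_stage(stage: str) -> str:
    i = _STAGE_ORDER.index(stage)
    if i == len(_STAGE_ORDER) - 1:
        raise ValueError("adults do not molt further")
    return _STAGE_ORDER[i + 1]
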