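"""Daily scheduler, single-run engine, and Monte-Carlo replication.

Each simulated day applies, in order: (1) food replacement if scheduled;
(2) minute-resolution competitive ingestion; (3) update of every
individual's effective life-cycle parameters from temperature and ingested
carbon; (4) daily survival draws; (5) development advancement with stage
transitions; (6) fertilization and reproduction of adult females, whose
clutches enter the population as nauplii the following day.  Applying
mortality before molting means an individual cannot molt and die on the
same day; the ordering is isolated here so alternatives remain testable.

Three parameterization modes are supported.  ``direct_temperature`` and
``direct_food`` apply one axis' response functions as absolute parameter
values (the verification mode: one factor varied at a time, the other at
reference).  ``normalized`` scales the reference defaults by both axes'
normalized responses multiplicatively.

Monte-Carlo replication derives one child seed per replicate from the
master seed through ``numpy``'s ``SeedSequence(master_seed, spawn_key=(r,))``
splitting, so replicate ``r`` is reproducible in isolation, and summarizes
per-day stage abundances as means with percentile (2.5%, 97.5%) bands —
appropriate for count data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import life_cycle as lc
from .food import FoodState, Vessel, VESSEL_PRESETS, feeding_schedule, minute_loop_by_stage
from .life_cycle import (ADULT, COPEPODITE, NAUPLIUS, Clutch, Individual,
                         LifeCycleParameters)
from .responses import (FOOD_PARAMETERS, STAGE_FOR_PARAMETER,
                        ResponseFunctionSet, default_responses)

__all__ = [
    "SimulationConfig", "SimulationResult", "MonteCarloSummary",
    "ReproductionTestResult", "run_simulation", "run_monte_carlo",
    "run_development_test", "run_reproduction_test",
    "DEVELOPMENT_TEST_SETUPS", "REPRODUCTION_TEST_SETUPS",
]

MODES = ("direct_temperature", "direct_food", "normalized")

#: Measured mean temperatures of the three temperature setups (C).
MEASURED_TEMPERATURE_C = {"15C": 14.86, "20C": 19.34, "25C": 24.90}
NOMINAL_TEMPERATURE_C = {"15C": 15.0, "20C": 20.0, "25C": 25.0}

#: Nominal rations of the food setups, cells/mL.
FOOD_SETUP_CELLS = {
    "0": 0.0, "1.25e4": 1.25e4, "2.5e4": 2.5e4, "5e4": 5.0e4,
    "1.25e5": 1.25e5, "2.5e5": 2.5e5, "5e5": 5.0e5,
}

STANDARD_FOOD_CELLS = 2.5e5


@dataclass
class SimulationConfig:
    """Settings of one simulated treatment.

    ``vessel`` may be a :class:`~nitocra.food.Vessel`, a preset name, or
    ``None`` (6-well geometry scaled to the cohort at the experimental
    per-capita loading of one well per 24 animals).
    """

    temperature_C: float
    food_cells_per_mL: float = STANDARD_FOOD_CELLS
    vessel: Union[Vessel, str, None] = None
    n_initial_nauplii: int = 72
    days: int = 35
    reproduction_enabled: bool = False
    mode: str = "direct_temperature"
    temperature_variant: str = "exp_decay"
    feed_interval_days: int = 2
    p_female: float = 0.5
    replicates: int = 1
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.days < 1:
            raise ValueError(f"days must be >= 1, got {self.days}")
        if self.replicates < 1:
            raise ValueError(f"replicates must be >= 1, got {self.replicates}")
        if self.n_initial_nauplii < 0:
            raise ValueError("n_initial_nauplii must be >= 0")
        if self.food_cells_per_mL < 0:
            raise ValueError("food_cells_per_mL must be >= 0")

    def resolve_vessel(self) -> Vessel:
        if isinstance(self.vessel, Vessel):
            return self.vessel
        if isinstance(self.vessel, str):
            return Vessel.from_preset(self.vessel)
        n = max(self.n_initial_nauplii, 1)
        return VESSEL_PRESETS["6-well"].scaled(n / 24.0)


@dataclass
class SimulationResult:
    """Daily stage abundances, the event log, and per-female brood records
    of one run."""

    config: SimulationConfig
    seed: int
    #: rows: day 0 (initial state) .. day `days`; columns per stage + dead
    abundance: pd.DataFrame
    #: tidy event log: id, day, event, value
    events: pd.DataFrame
    #: realized fractional phase durations of completed transitions
    naupliar_durations: List[float]
    copepodite_durations: List[float]
    clutches: List[Clutch]

    def stage_counts(self, stage: str) -> np.ndarray:
        return self.abundance[stage].to_numpy()


@dataclass
class MonteCarloSummary:
    """Per-day, per-stage mean and 95% percentile band over replicates."""

    config: SimulationConfig
    days: np.ndarray
    mean: Dict[str, np.ndarray]
    #: the median always lies inside the percentile band; for strongly
    #: skewed count distributions the mean occasionally does not
    median: Dict[str, np.ndarray]
    lower: Dict[str, np.ndarray]   # 2.5th percentile
    upper: Dict[str, np.ndarray]   # 97.5th percentile
    replicate_results: Optional[List[SimulationResult]] = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for stage in self.mean:
            for i, day in enumerate(self.days):
                rows.append({"day": int(day), "stage": stage,
                             "mean": self.mean[stage][i],
                             "median": self.median[stage][i],
                             "lower": self.lower[stage][i],
                             "upper": self.upper[stage][i]})
        return pd.DataFrame(rows, columns=["day", "stage", "mean", "median",
                                           "lower", "upper"])


class _DailyParameters:
    """Effective parameters for one day, computed per stage.

    Values within a stage are shared because the minute loop gives every
    individual of a stage the same daily ingested carbon.
    """

    __slots__ = ("rates", "deaths", "bs_mean", "pL", "pE")

    def __init__(self, cfg: SimulationConfig, params: LifeCycleParameters,
                 responses: ResponseFunctionSet, ic_by_stage: Dict[str, float]):
        mode = cfg.mode
        t = cfg.temperature_C
        variant = cfg.temperature_variant

        def eff(parameter: str) -> float:
            # latency has no independently fitted decay curve; the shared
            # Belehradek law is its only temperature function
            var = "belehradek" if parameter == "pL" else variant
            if mode == "direct_temperature":
                return responses.effective_parameter(
                    parameter, t=t, mode="direct", variant=var)
            ic = ic_by_stage[STAGE_FOR_PARAMETER.get(parameter, "adult")]
            if mode == "direct_food":
                if parameter in FOOD_PARAMETERS:
                    return responses.effective_parameter(parameter, ic=ic, mode="direct")
                # latency/embryo development have no food function; the food
                # experiments ran at the reference temperature, so the
                # reference defaults apply
                return getattr(params, parameter)
            return responses.effective_parameter(
                parameter, t=t, ic=ic, mode="normalized", variant=var)

        self.rates = {NAUPLIUS: eff("pN_DEV"), COPEPODITE: eff("pC_DEV")}
        self.deaths = {NAUPLIUS: eff("pS_NAU"), COPEPODITE: eff("pS_COP"),
                       ADULT: eff("pS_ADU")}
        self.bs_mean = eff("BS")
        self.pL = eff("pL")
        self.pE = eff("pE_DEV")


def run_simulation(config: SimulationConfig, seed: Optional[int] = None,
                   params: Optional[LifeCycleParameters] = None,
                   responses: Optional[ResponseFunctionSet] = None
                   ) -> SimulationResult:
    """Run one stochastic realization of a treatment.

    Identical ``(config, seed)`` pairs reproduce identical results
    bit-for-bit.  ``seed`` defaults to ``config.master_seed``.
    """
    params = params or LifeCycleParameters(p_female=config.p_female)
    responses = responses or default_responses()
    if responses.temperature_variant != config.temperature_variant:
        responses = ResponseFunctionSet(
            temperature_variant=config.temperature_variant)
    seed = config.master_seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    vessel = config.resolve_vessel()
    nominal_carbon = vessel.nominal_carbon(config.food_cells_per_mL)
    food = FoodState(total_carbon_ug=nominal_carbon,
                     bottom_area_cm2=vessel.bottom_area_cm2)
    needs_feeding = config.mode in ("direct_food", "normalized")

    individuals: List[Individual] = [
        Individual(id=i, development_deviate=lc.draw_development_deviate(
            params.alpha_N, rng))
        for i in range(config.n_initial_nauplii)
    ]
    next_id = config.n_initial_nauplii
    events: List[dict] = []
    nau_durations: List[float] = []
    cop_durations: List[float] = []
    clutches: List[Clutch] = []
    newborn_queue = 0

    counts_rows = [_count_row(0, individuals)]
    # fast path: in direct_temperature mode parameters are condition-constant
    static_daily = None
    if config.mode == "direct_temperature":
        static_daily = _DailyParameters(config, params, responses,
                                        {s: 0.0 for s in (NAUPLIUS, COPEPODITE, ADULT)})

    for day in range(1, config.days + 1):
        # newborns from yesterday's clutches enter before today's processes
        for _ in range(newborn_queue):
            individuals.append(Individual(
                id=next_id, born_day=day,
                development_deviate=lc.draw_development_deviate(params.alpha_N, rng)))
            events.append({"id": next_id, "day": day, "event": "birth", "value": np.nan})
            next_id += 1
        newborn_queue = 0

        # (1) feeding-day full food replacement
        if feeding_schedule(day - 1, config.feed_interval_days):
            food = FoodState(total_carbon_ug=nominal_carbon,
                             bottom_area_cm2=food.bottom_area_cm2,
                             last_feed_day=day - 1)

        # (2) minute-loop ingestion
        if needs_feeding:
            stage_counts: Dict[str, int] = {}
            for ind in individuals:
                if ind.alive:
                    stage_counts[ind.stage] = stage_counts.get(ind.stage, 0) + 1
            per_capita, remaining = minute_loop_by_stage(
                food.total_carbon_ug, food.bottom_area_cm2, stage_counts, responses)
            food = FoodState(total_carbon_ug=remaining,
                             bottom_area_cm2=food.bottom_area_cm2,
                             last_feed_day=food.last_feed_day)
            for ind in individuals:
                if ind.alive:
                    ind.ingested_today = per_capita[ind.stage]
            daily = _DailyParameters(config, params, responses, per_capita)
        else:
            daily = static_daily

        # (4) survival
        living = [ind for ind in individuals if ind.alive]
        draws = rng.random(len(living))
        for ind, u in zip(living, draws):
            if u < daily.deaths[ind.stage]:
                ind.alive = False
                events.append({"id": ind.id, "day": day, "event": "death", "value": np.nan})

        # (5) development and stage transitions
        for ind in individuals:
            if not ind.alive or ind.stage == ADULT:
                continue
            duration = lc.advance_development(ind, daily.rates[ind.stage])
            if duration is None:
                continue
            if ind.stage == NAUPLIUS:
                nau_durations.append(duration)
                ind.stage = COPEPODITE
                ind.development_deviate = lc.draw_development_deviate(params.alpha_C, rng)
                ind.development_progress = 0.0
                ind.days_in_stage = 0
                events.append({"id": ind.id, "day": day, "event": "molt_to_copepodite",
                               "value": duration})
            else:
                cop_durations.append(duration)
                ind.stage = ADULT
                ind.development_progress = 0.0
                ind.days_in_stage = 0
                lc.assign_sex(ind, params.p_female, rng)
                events.append({"id": ind.id, "day": day, "event": "maturation",
                               "value": duration})

        # (6) fertilization and reproduction
        if config.reproduction_enabled:
            if any(ind.is_adult_male for ind in individuals):
                for ind in individuals:
                    if ind.is_adult_female and not ind.fertilized:
                        lc.start_fertilization(ind, params, rng)
                        events.append({"id": ind.id, "day": day,
                                       "event": "fertilization", "value": np.nan})
            for ind in individuals:
                if ind.is_adult_female and ind.fertilized and ind.broods_remaining > 0:
                    clutch = lc.step_reproduction(
                        ind, daily.pL, daily.pE, daily.bs_mean, params.cv_BS,
                        params.alpha_L, params.alpha_E, rng, day=day)
                    if clutch is not None:
                        clutches.append(clutch)
                        newborn_queue += clutch.size
                        events.append({"id": ind.id, "day": day, "event": "clutch",
                                       "value": clutch.size})

        for ind in individuals:
            if ind.alive:
                ind.age += 1.0
        counts_rows.append(_count_row(day, individuals))

    abundance = pd.DataFrame(counts_rows,
                             columns=["day", NAUPLIUS, COPEPODITE, ADULT, "dead"])
    events_df = pd.DataFrame(events, columns=["id", "day", "event", "value"])
    return SimulationResult(config=config, seed=seed, abundance=abundance,
                            events=events_df, naupliar_durations=nau_durations,
                            copepodite_durations=cop_durations, clutches=clutches)


def _count_row(day: int, individuals: Sequence[Individual]) -> dict:
    row = {"day": day, NAUPLIUS: 0, COPEPODITE: 0, ADULT: 0, "dead": 0}
    for ind in individuals:
        row["dead" if not ind.alive else ind.stage] += 1
    return row


def replicate_seed(master_seed: int, replicate: int) -> np.random.SeedSequence:
    """Counter-based per-replicate seed: replicate ``r`` of a run is
    reproducible in isolation from ``(master_seed, r)``."""
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(replicate,))


def run_monte_carlo(config: SimulationConfig,
                    params: Optional[LifeCycleParameters] = None,
                    keep_replicates: bool = False) -> MonteCarloSummary:
    """Replicate a treatment and summarize per-day stage abundances as the
    mean with a percentile 95% band."""
    if config.replicates < 2:
        raise ValueError("Monte Carlo summaries need replicates >= 2")
    stages = [NAUPLIUS, COPEPODITE, ADULT, "dead"]
    stacks = {s: [] for s in stages}
    kept = [] if keep_replicates else None
    for r in range(config.replicates):
        seed = int(replicate_seed(config.master_seed, r).generate_state(1)[0] % (2**31))
        result = run_simulation(config, seed=seed, params=params)
        for s in stages:
            stacks[s].append(result.stage_counts(s))
        if keep_replicates:
            kept.append(result)
    days = np.arange(config.days + 1)
    mean, median, lower, upper = {}, {}, {}, {}
    for s in stages:
        arr = np.vstack(stacks[s])
        mean[s] = arr.mean(axis=0)
        median[s] = np.percentile(arr, 50, axis=0)
        lower[s] = np.percentile(arr, 2.5, axis=0)
        upper[s] = np.percentile(arr, 97.5, axis=0)
    return MonteCarloSummary(config=config, days=days, mean=mean, median=median,
                             lower=lower, upper=upper, replicate_results=kept)


# -- verification experiment runners ----------------------------------------

def _development_test_setups() -> Dict[str, SimulationConfig]:
    setups: Dict[str, SimulationConfig] = {}
    for name, t in MEASURED_TEMPERATURE_C.items():
        setups[name] = SimulationConfig(
            temperature_C=t, food_cells_per_mL=STANDARD_FOOD_CELLS,
            n_initial_nauplii=72, days=35, mode="direct_temperature",
            reproduction_enabled=False, replicates=1000)
    for name, cells in FOOD_SETUP_CELLS.items():
        setups[f"food-{name}"] = SimulationConfig(
            temperature_C=22.0, food_cells_per_mL=cells,
            n_initial_nauplii=35, days=45, mode="direct_food",
            reproduction_enabled=False, replicates=1000)
    return setups


DEVELOPMENT_TEST_SETUPS = tuple(_development_test_setups())
REPRODUCTION_TEST_SETUPS = ("15C", "20C", "25C", "food-2.5e4", "food-5e4",
                            "food-1.25e5", "food-2.5e5", "food-5e5")


def run_development_test(setup: str, replicates: int = 1000,
                         master_seed: int = 0,
                         use_measured_temperature: bool = True,
                         keep_replicates: bool = False) -> MonteCarloSummary:
    """Monte-Carlo simulation of a development-test treatment.

    Temperature setups (``"15C"``, ``"20C"``, ``"25C"``): 72 initial nauplii
    over 35 days, direct temperature mode at the measured (default) or
    nominal setup temperature.  Food setups (``"food-0"`` ...
    ``"food-5e5"``): 35 nauplii over 45 days at 22 C, direct food mode.
    Reproduction is disabled throughout, emulating individual isolation.
    """
    setups = _development_test_setups()
    if setup not in setups:
        raise ValueError(f"unknown setup {setup!r}; available: {sorted(setups)}")
    cfg = replace(setups[setup], replicates=replicates, master_seed=master_seed)
    if setup in NOMINAL_TEMPERATURE_C and not use_measured_temperature:
        cfg = replace(cfg, temperature_C=NOMINAL_TEMPERATURE_C[setup])
    return run_monte_carlo(cfg, keep_replicates=keep_replicates)


@dataclass
class ReproductionTestResult:
    """Brood sizes and brood-to-brood periods of repeatedly simulated
    individual fertilized females, with the theoretical values implied by
    the response functions at the same conditions."""

    setup: str
    n_females: int
    days: int
    clutch_sizes: List[int]          # all clutches, pooled
    periods: List[float]             # all inter-clutch periods (excl. latency)
    female_mean_sizes: List[float]   # one mean per female with >= 1 clutch
    female_mean_periods: List[float]
    theoretical_brood_size: float
    theoretical_period: float

    def summary(self) -> pd.DataFrame:
        def row(name, values, theo):
            arr = np.asarray(values, dtype=float)
            return {"quantity": name, "mean": arr.mean() if arr.size else np.nan,
                    "sd": arr.std(ddof=1) if arr.size > 1 else np.nan,
                    "n": arr.size, "theoretical": theo}
        return pd.DataFrame([
            row("brood size (per female)", self.female_mean_sizes,
                self.theoretical_brood_size),
            row("brood-to-brood period (per female)", self.female_mean_periods,
                self.theoretical_period),
            row("brood size (per clutch)", self.clutch_sizes,
                self.theoretical_brood_size),
            row("brood-to-brood period (per clutch)", self.periods,
                self.theoretical_period),
        ])


def run_reproduction_test(setup: str, n_females: int = 50, days: int = 15,
                          master_seed: int = 0,
                          use_measured_temperature: bool = True,
                          params: Optional[LifeCycleParameters] = None
                          ) -> ReproductionTestResult:
    """Repeatedly simulate individual fertilized females.

    Temperature setups run in direct temperature mode; food setups run in
    direct food mode with one female feeding in a 24-well vessel (2 mL), as
    in the experiment's isolation of ovigerous females.  Each female starts
    as a fertilized adult; latency precedes her first clutch, and the
    recorded brood-to-brood periods are the embryonic phase completions
    (fractional-day resolution).  The theoretical values are the response
    functions evaluated at the setup's conditions.
    """
    responses = default_responses()
    params = params or LifeCycleParameters()
    if setup in MEASURED_TEMPERATURE_C:
        t = (MEASURED_TEMPERATURE_C if use_measured_temperature
             else NOMINAL_TEMPERATURE_C)[setup]
        cfg = SimulationConfig(temperature_C=t, mode="direct_temperature",
                               n_initial_nauplii=1, days=days)
    elif setup.startswith("food-") and setup[5:] in FOOD_SETUP_CELLS:
        cells = FOOD_SETUP_CELLS[setup[5:]]
        cfg = SimulationConfig(temperature_C=22.0, food_cells_per_mL=cells,
                               vessel="24-well", mode="direct_food",
                               n_initial_nauplii=1, days=days)
    else:
        raise ValueError(
            f"unknown setup {setup!r}; available: {REPRODUCTION_TEST_SETUPS}")

    vessel = cfg.resolve_vessel()
    nominal_carbon = vessel.nominal_carbon(cfg.food_cells_per_mL)
    needs_feeding = cfg.mode == "direct_food"

    all_sizes: List[int] = []
    all_periods: List[float] = []
    female_sizes: List[float] = []
    female_periods: List[float] = []
    ic_adult_ref = None

    for f in range(n_females):
        rng = np.random.default_rng(replicate_seed(master_seed, f))
        female = Individual(id=f, stage=ADULT, sex="female")
        lc.start_fertilization(female, params, rng)
        food = FoodState(total_carbon_ug=nominal_carbon,
                         bottom_area_cm2=vessel.bottom_area_cm2)
        sizes, periods = [], []
        first_clutch_seen = False
        for day in range(1, days + 1):
            if not female.alive:
                break
            if feeding_schedule(day - 1, cfg.feed_interval_days):
                food = FoodState(total_carbon_ug=nominal_carbon,
                                 bottom_area_cm2=food.bottom_area_cm2)
            if needs_feeding:
                per_capita, remaining = minute_loop_by_stage(
                    food.total_carbon_ug, food.bottom_area_cm2, {ADULT: 1},
                    responses)
                food = FoodState(total_carbon_ug=remaining,
                                 bottom_area_cm2=food.bottom_area_cm2)
                ic = per_capita[ADULT]
                if ic_adult_ref is None:
                    ic_adult_ref = ic  # first-day intake at nominal ration
                pL_eff, pE_eff = params.pL, params.pE_DEV
                bs_mean = responses.food_response("BS", ic)
                p_death = responses.food_response("pS_ADU", ic)
            else:
                pL_eff = responses.temperature_response("pL", cfg.temperature_C,
                                                        "belehradek")
                pE_eff = responses.temperature_response("pE_DEV", cfg.temperature_C,
                                                        cfg.temperature_variant)
                bs_mean = responses.temperature_response("BS", cfg.temperature_C)
                p_death = responses.temperature_response("pS_ADU", cfg.temperature_C)
            if lc.apply_daily_survival(female, p_death, rng):
                break
            if female.broods_remaining > 0:
                clutch = lc.step_reproduction(
                    female, pL_eff, pE_eff, bs_mean, params.cv_BS,
                    params.alpha_L, params.alpha_E, rng, day=day)
                if clutch is not None:
                    sizes.append(clutch.size)
                    if first_clutch_seen:      # exclude the latency interval
                        periods.append(clutch.period)
                    first_clutch_seen = True
        all_sizes.extend(sizes)
        all_periods.extend(periods)
        if sizes:
            female_sizes.append(float(np.mean(sizes)))
        if periods:
            female_periods.append(float(np.mean(periods)))

    if cfg.mode == "direct_temperature":
        theo_bs = responses.temperature_response("BS", cfg.temperature_C)
        theo_period = 1.0 / responses.temperature_response(
            "pE_DEV", cfg.temperature_C, cfg.temperature_variant)
    else:
        ic0 = ic_adult_ref if ic_adult_ref is not None else \
            responses.holling_ingestion(ADULT, nominal_carbon / vessel.bottom_area_cm2)
        theo_bs = responses.food_response("BS", ic0)
        theo_period = 1.0 / params.pE_DEV
    return ReproductionTestResult(
        setup=setup, n_females=n_females, days=days, clutch_sizes=all_sizes,
        periods=all_periods, female_mean_sizes=female_sizes,
        female_mean_periods=female_periods, theoretical_brood_size=theo_bs,
        theoretical_period=theo_period)
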