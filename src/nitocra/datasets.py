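"""Transcribed summaries of the calibration life-cycle experiments.

The model was calibrated and verified against a set of laboratory
life-cycle experiments on *N. spinipes*: three temperature setups (nominal
15/20/25 C at the standard ration of 2.5e5 cells/mL) and six food setups
(0 to 5e5 cells/mL at 22 C).  This module packages the published summary
data of those experiments — measured mean temperatures, development-time
and brood-size summaries, alive/dead and female/male count tables, and the
reported exact-test p-values — as programmatic fixtures for verification
recipes and tests.  The zero-food treatment is absent from the summary and
count tables because no individual in it survived to the first copepodite
stage.
"""

from __future__ import annotations

from typing import Dict

import pandas as pd

from .stats import ContingencyTable

__all__ = [
    "MEASURED_TEMPERATURES", "NOMINAL_TEMPERATURES",
    "development_summaries", "reproduction_summaries",
    "contingency_tables", "contingency_table", "REPORTED_FISHER_P",
]

#: Mean of daily temperature extremes over each temperature setup (C).
MEASURED_TEMPERATURES = {"15C": 14.86, "20C": 19.34, "25C": 24.90}
NOMINAL_TEMPERATURES = {"15C": 15.0, "20C": 20.0, "25C": 25.0}

_DEVELOPMENT_ROWS = [
    # setup, endpoint, mean, sd, n
    ("15C", "naupliar_development_d", 9.52, 2.19, 61),
    ("15C", "copepodite_development_d", 12.31, 2.04, 55),
    ("15C", "embryonic_development_d", 4.08, 0.36, 37),
    ("15C", "brood_size", 27.65, 6.59, 34),
    ("20C", "naupliar_development_d", 6.44, 0.66, 66),
    ("20C", "copepodite_development_d", 10.12, 2.89, 65),
    ("20C", "embryonic_development_d", 3.39, 0.76, 136),
    ("20C", "brood_size", 23.76, 10.78, 139),
    ("25C", "naupliar_development_d", 5.57, 1.18, 60),
    ("25C", "copepodite_development_d", 8.86, 1.29, 57),
    ("25C", "embryonic_development_d", 3.18, 0.87, 11),
    ("25C", "brood_size", 10.95, 4.94, 43),
    ("food-1.25e4", "naupliar_development_d", 16.10, 3.73, 20),
    ("food-1.25e4", "copepodite_development_d", 20.50, 6.81, 4),
    ("food-2.5e4", "naupliar_development_d", 12.86, 1.80, 28),
    ("food-2.5e4", "copepodite_development_d", 17.52, 9.64, 21),
    ("food-2.5e4", "brood_size", 12.0, 2.55, 5),
    ("food-5e4", "naupliar_development_d", 11.74, 2.69, 31),
    ("food-5e4", "copepodite_development_d", 13.32, 4.36, 28),
    ("food-5e4", "brood_size", 20.50, 10.77, 40),
    ("food-1.25e5", "naupliar_development_d", 8.51, 1.29, 34),
    ("food-1.25e5", "copepodite_development_d", 12.55, 4.85, 32),
    ("food-1.25e5", "brood_size", 25.88, 9.26, 51),
    ("food-2.5e5", "naupliar_development_d", 7.66, 1.44, 34),
    ("food-2.5e5", "copepodite_development_d", 11.50, 3.32, 31),
    ("food-2.5e5", "brood_size", 30.50, 9.91, 52),
    ("food-5e5", "naupliar_development_d", 6.71, 0.50, 35),
    ("food-5e5", "copepodite_development_d", 11.21, 2.37, 34),
    ("food-5e5", "brood_size", 35.35, 7.59, 49),
]

_REPRODUCTION_ROWS = [
    # setup, quantity, simulated mean, simulated sd, n, theoretical
    ("15C", "brood_to_brood_period_d", 3.96, 0.79, 50, 4.04),
    ("15C", "brood_size", 29.30, 13.74, 50, 27.64),
    ("20C", "brood_to_brood_period_d", 3.33, 0.72, 50, 3.39),
    ("20C", "brood_size", 26.10, 10.97, 50, 23.82),
    ("25C", "brood_to_brood_period_d", 3.21, 0.58, 50, 3.18),
    ("25C", "brood_size", 10.74, 5.16, 50, 10.70),
    ("food-2.5e4", "brood_size", 11.26, 3.57, 50, 11.13),
    ("food-5e4", "brood_size", 21.48, 10.31, 50, 22.51),
    ("food-1.25e5", "brood_size", 31.00, 12.27, 50, 29.49),
    ("food-2.5e5", "brood_size", 31.32, 12.99, 50, 30.58),
    ("food-5e5", "brood_size", 26.92, 15.75, 50, 31.11),
]

_FOOD_SETUPS = ["food-1.25e4", "food-2.5e4", "food-5e4",
                "food-1.25e5", "food-2.5e5", "food-5e5"]

_CONTINGENCY = {
    "temperature-naupliar-mortality": (
        [[61, 5], [66, 3], [60, 9]],
        ["15C", "20C", "25C"], ["alive", "dead"]),
    "temperature-copepodite-mortality": (
        [[55, 6], [65, 0], [57, 3]],
        ["15C", "20C", "25C"], ["alive", "dead"]),
    "temperature-sex-ratio": (
        [[22, 31], [39, 24], [40, 10]],
        ["15C", "20C", "25C"], ["female", "male"]),
    "food-naupliar-mortality": (
        [[19, 17], [28, 8], [34, 2], [35, 1], [34, 2], [35, 1]],
        _FOOD_SETUPS, ["alive", "dead"]),
    "food-copepodite-mortality": (
        [[10, 9], [24, 4], [32, 2], [33, 2], [32, 2], [35, 0]],
        _FOOD_SETUPS, ["alive", "dead"]),
    "food-sex-ratio": (
        [[0, 3], [4, 17], [3, 25], [10, 21], [8, 23], [11, 23]],
        _FOOD_SETUPS, ["female", "male"]),
}

#: Exact-test p-values reported for the six categorical endpoints.
REPORTED_FISHER_P = {
    "temperature-naupliar-mortality": 0.17,
    "temperature-copepodite-mortality": 0.037,
    "temperature-sex-ratio": 3.3e-4,
    "food-naupliar-mortality": 9.8e-9,
    "food-copepodite-mortality": 1.5e-6,
    "food-sex-ratio": 0.29,
}


def development_summaries() -> pd.DataFrame:
    """Measured development-time and brood-size summaries (mean, SD, n) per
    experimental setup."""
    return pd.DataFrame(_DEVELOPMENT_ROWS,
                        columns=["setup", "endpoint", "mean", "sd", "n"])


def reproduction_summaries() -> pd.DataFrame:
    """Published simulated-versus-theoretical reproduction summaries
    (brood-to-brood periods and brood sizes of n = 50 simulated females)."""
    return pd.DataFrame(
        _REPRODUCTION_ROWS,
        columns=["setup", "quantity", "simulated_mean", "simulated_sd", "n",
                 "theoretical"])


def contingency_tables() -> Dict[str, ContingencyTable]:
    """All six categorical-endpoint count tables (treatment rows x outcome
    columns)."""
    return {name: ContingencyTable.from_array(counts, rows, cols)
            for name, (counts, rows, cols) in _CONTINGENCY.items()}


def contingency_table(name: str) -> ContingencyTable:
    """One named count table; see :func:`contingency_tables` for names."""
    try:
        counts, rows, cols = _CONTINGENCY[name]
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; available: {sorted(_CONTINGENCY)}"
        ) from None
    return ContingencyTable.from_array(counts, rows, cols)
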