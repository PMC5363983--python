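"""Temperature and food-quantity response functions for the copepod life cycle.

The life cycle of *Nitocra spinipes* is driven by eight individual-level
parameters: development rates for the naupliar, copepodite, latency and
embryonic phases (``pN_DEV``, ``pC_DEV``, ``pL``, ``pE_DEV``, all in d^-1),
a mean brood size (``BS``, nauplii per clutch), and daily death
probabilities per stage (``pS_NAU``, ``pS_COP``, ``pS_ADU``).  This module
maps environmental conditions onto those parameters:

* temperature (degrees Celsius) through three-parameter exponential-decay
  duration curves, a shared Belehradek power law D = 250 (t + 7.2)^-1.86
  rescaled per phase, and quadratic optimum curves for brood size and
  mortality;
* food through a Holling type III functional response translating benthic
  food concentration (ug C/cm2) into daily ingested carbon per individual
  (``IC``, ug C/d), and empirical best-fit curves of each parameter
  against ``IC``.

Every response function carries a *normalizing factor*, the reciprocal of
the function at the reference condition (22 C; bottom food concentration
5.5 ug C/cm2, the standard 2.5e5 cells/mL ration).  Multiplying a default
parameter by ``factor * f(condition)`` scales it relative to the reference,
so temperature and food effects can be composed multiplicatively
(``normalized`` mode).  In ``direct`` mode a single axis' function is used
as the absolute parameter value, which is how the verification experiments
are reproduced.
"""

from __future__ import annotations

import math
import warnings
from functools import lru_cache
from importlib import resources
from typing import Mapping, Optional

import yaml

__all__ = [
    "PARAMETERS",
    "FOOD_PARAMETERS",
    "STAGES",
    "STAGE_FOR_PARAMETER",
    "REFERENCE_TEMPERATURE_C",
    "REFERENCE_BOTTOM_FOOD",
    "CalibrationRangeWarning",
    "ClampedValueWarning",
    "load_coefficients",
    "ResponseFunctionSet",
    "default_responses",
    "holling_ingestion",
    "temperature_response",
    "food_response",
    "normalization_factor",
    "effective_parameter",
]

#: Individual-level parameters with at least one response function.
PARAMETERS = ("pN_DEV", "pC_DEV", "pE_DEV", "pL", "BS", "pS_NAU", "pS_COP", "pS_ADU")

#: Parameters with a food (ingested-carbon) response function.
FOOD_PARAMETERS = ("pN_DEV", "pC_DEV", "BS", "pS_NAU", "pS_COP", "pS_ADU")

#: Feeding stages of the aggregated life cycle.
STAGES = ("nauplius", "copepodite", "adult")

#: Which stage's ingested carbon each food-responsive parameter uses.
STAGE_FOR_PARAMETER: Mapping[str, str] = {
    "pN_DEV": "nauplius",
    "pS_NAU": "nauplius",
    "pC_DEV": "copepodite",
    "pS_COP": "copepodite",
    "BS": "adult",
    "pS_ADU": "adult",
}

#: Daily death probabilities (clamped to [0, 1]).
_PROBABILITY_PARAMETERS = frozenset({"pS_NAU", "pS_COP", "pS_ADU"})

#: Calibrated temperature range of the quadratic optimum curves (C).
QUADRATIC_CALIBRATED_RANGE = (15.0, 25.0)

REFERENCE_TEMPERATURE_C = 22.0
#: Reference benthic food concentration, ug C/cm2 (2.5e5 cells/mL in 6-well
#: geometry with the default carbon-per-cell conversion).
REFERENCE_BOTTOM_FOOD = 5.5


class CalibrationRangeWarning(UserWarning):
    """Response function evaluated outside its calibrated range."""


class ClampedValueWarning(UserWarning):
    """A response value was clamped to its physical range."""


@lru_cache(maxsize=None)
def _packaged_coefficients() -> Mapping:
    text = resources.files("nitocra").joinpath("data/coefficients.yaml").read_text()
    return yaml.safe_load(text)


_REQUIRED_TEMPERATURE_FORMS = {
    "pN_DEV": {"exp_decay", "belehradek"},
    "pC_DEV": {"exp_decay", "belehradek"},
    "pE_DEV": {"exp_decay", "belehradek"},
    "pL": {"belehradek"},
    "BS": {"quadratic"},
    "pS_NAU": {"quadratic_percent"},
    "pS_COP": {"quadratic_percent"},
    "pS_ADU": {"quadratic_percent"},
}


def load_coefficients(path: Optional[str] = None) -> dict:
    """Load and validate the coefficient tables.

    Parameters
    ----------
    path
        Optional path to an alternative YAML coefficient file; by default the
        packaged tables are used.

    Raises
    ------
    ValueError
        If any required section, parameter or functional form is missing.
    """
    if path is None:
        coeffs = dict(_packaged_coefficients())
    else:
        with open(path) as fh:
            coeffs = yaml.safe_load(fh)
    missing = [k for k in ("ingestion", "temperature", "food", "belehradek_base",
                           "reference", "individual_defaults") if k not in coeffs]
    if missing:
        raise ValueError(f"coefficient file is missing sections: {missing}")
    for stage in STAGES:
        if stage not in coeffs["ingestion"]:
            raise ValueError(f"missing ingestion coefficients for stage {stage!r}")
    for param, forms in _REQUIRED_TEMPERATURE_FORMS.items():
        have = set(coeffs["temperature"].get(param, {}))
        if not forms <= have:
            raise ValueError(
                f"temperature functions for {param!r} incomplete: need {sorted(forms)}, have {sorted(have)}"
            )
    for param in FOOD_PARAMETERS:
        if param not in coeffs["food"]:
            raise ValueError(f"missing food function for {param!r}")
    return coeffs


class ResponseFunctionSet:
    """All response functions of the model, bound to one coefficient table.

    Parameters
    ----------
    coefficients
        Parsed coefficient mapping (see :func:`load_coefficients`).  ``None``
        loads the packaged tables.
    temperature_variant
        Default functional form for the durational temperature responses:
        ``"exp_decay"`` (independent three-parameter fits, the variant used in
        the verification simulations) or ``"belehradek"`` (shared power law,
        presuming equiproportional stage durations).
    """

    def __init__(self, coefficients: Optional[Mapping] = None,
                 temperature_variant: str = "exp_decay"):
        self._c = load_coefficients() if coefficients is None else coefficients
        if temperature_variant not in ("exp_decay", "belehradek"):
            raise ValueError(f"unknown temperature variant {temperature_variant!r}")
        self.temperature_variant = temperature_variant
        ref = self._c["reference"]
        self.reference_temperature_C = float(ref["temperature_C"])
        self.reference_bottom_food = float(ref["bottom_food_ug_C_per_cm2"])

    # -- ingestion -----------------------------------------------------------

    def holling_ingestion(self, stage: str, c_food: float) -> float:
        """Daily ingested carbon (ug C/d) of one individual of `stage` at
        benthic food concentration `c_food` (ug C/cm2); Holling type III."""
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
        if c_food < 0:
            raise ValueError(f"bottom food concentration must be >= 0, got {c_food}")
        k = self._c["ingestion"][stage]
        c2 = c_food * c_food
        return k["a_max"] * c2 / (c2 + k["k_half"] ** 2)

    def ingestion_maximum(self, stage: str) -> float:
        """Saturation ingestion rate of `stage` (ug C/d)."""
        return float(self._c["ingestion"][stage]["a_max"])

    def ingestion_half_saturation(self, stage: str) -> float:
        """Bottom food concentration at half-maximal ingestion (ug C/cm2)."""
        return float(self._c["ingestion"][stage]["k_half"])

    def reference_ingestion(self, stage: str) -> float:
        """Ingested carbon at the reference bottom food concentration."""
        return self.holling_ingestion(stage, self.reference_bottom_food)

    # -- temperature axis ----------------------------------------------------

    def temperature_response(self, parameter: str, t: float,
                             variant: Optional[str] = None) -> float:
        """Parameter value from temperature alone (d^-1, probability per day,
        or nauplii per brood for ``BS``).

        `variant` selects the durational form (``exp_decay``/``belehradek``)
        and is ignored for the quadratic parameters, which have one form.
        """
        self._check_parameter(parameter)
        if not math.isfinite(t):
            raise ValueError(f"temperature must be finite, got {t}")
        forms = self._c["temperature"][parameter]
        if "quadratic" in forms or "quadratic_percent" in forms:
            return self._quadratic(parameter, t)
        requested = variant or self.temperature_variant
        if requested not in forms:
            if variant is None and len(forms) == 1:
                requested = next(iter(forms))  # pL: Belehradek is the only form
            else:
                raise ValueError(
                    f"no {requested!r} temperature function for {parameter!r}; "
                    f"available: {sorted(forms)}"
                )
        variant = requested
        if variant == "exp_decay":
            k = forms["exp_decay"]
            return 1.0 / (k["c"] + k["a"] * math.exp(-k["b"] * t))
        base = self._c["belehradek_base"]
        duration = base["a"] * (t - base["t0"]) ** base["b"] * forms["belehradek"]["scale"]
        return 1.0 / duration

    def _quadratic(self, parameter: str, t: float) -> float:
        lo, hi = QUADRATIC_CALIBRATED_RANGE
        if not lo <= t <= hi:
            warnings.warn(
                f"{parameter} quadratic evaluated at {t} C, outside the "
                f"calibrated range [{lo}, {hi}] C",
                CalibrationRangeWarning, stacklevel=3)
        forms = self._c["temperature"][parameter]
        if "quadratic" in forms:
            k = forms["quadratic"]
            value = k["c0"] + k["c1"] * t + k["c2"] * t * t
            return self._clamp(parameter, value, low=0.0, high=None)
        k = forms["quadratic_percent"]
        value = (k["c0"] + k["c1"] * t + k["c2"] * t * t) / 100.0
        return self._clamp(parameter, value, low=0.0, high=1.0)

    # -- food axis -----------------------------------------------------------

    def food_response(self, parameter: str, ic: float) -> float:
        """Parameter value from the stage-appropriate daily ingested carbon
        `ic` (ug C/d) alone."""
        self._check_parameter(parameter)
        if parameter not in FOOD_PARAMETERS:
            raise ValueError(f"{parameter!r} has no food response function")
        if ic < 0:
            raise ValueError(f"ingested carbon must be >= 0, got {ic}")
        spec = self._c["food"][parameter]
        if "power" in spec:
            k = spec["power"]
            return k["c0"] + k["c1"] * ic ** k["exponent"]
        if "saturating_exponential" in spec:
            k = spec["saturating_exponential"]
            return k["a"] * (1.0 - math.exp(-k["b"] * ic))
        if "rational" in spec:
            k = spec["rational"]
            return self._clamp(parameter, 1.0 / (k["c0"] + k["c1"] * ic), 0.0, 1.0)
        k = spec["cubic"]
        value = k["c0"] + k["c1"] * ic + k["c2"] * ic**2 + k["c3"] * ic**3
        return self._clamp(parameter, value, 0.0, 1.0)

    # -- normalization -------------------------------------------------------

    def normalization_factor(self, parameter: str, axis: str,
                             variant: Optional[str] = None) -> float:
        """Reciprocal of the response function at the reference condition.

        For the temperature axis the reference is 22 C; for the food axis it
        is the ingested carbon of the parameter's stage at the reference
        bottom food concentration.  Agrees with the factors printed alongside
        the coefficient tables within their rounding.
        """
        self._check_parameter(parameter)
        if axis == "temperature":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", CalibrationRangeWarning)
                value = self.temperature_response(
                    parameter, self.reference_temperature_C, variant)
        elif axis == "food":
            ic_ref = self.reference_ingestion(STAGE_FOR_PARAMETER[parameter])
            value = self.food_response(parameter, ic_ref)
        else:
            raise ValueError(f"axis must be 'temperature' or 'food', got {axis!r}")
        if value <= 0:
            raise ValueError(f"{parameter} response is non-positive at reference")
        return 1.0 / value

    def printed_normalizing_factor(self, parameter: str, axis: str,
                                   variant: Optional[str] = None) -> Optional[float]:
        """The normalizing factor as printed in the coefficient tables
        (``None`` where the table leaves it blank)."""
        self._check_parameter(parameter)
        if axis == "temperature":
            forms = self._c["temperature"][parameter]
            form = variant or self.temperature_variant
            if form not in forms:
                form = next(iter(forms))
            return forms[form].get("normalizing_factor")
        return self._c["food"][parameter].get("normalizing_factor")

    # -- composition ---------------------------------------------------------

    def effective_parameter(self, parameter: str, t: Optional[float] = None,
                            ic: Optional[float] = None, mode: str = "normalized",
                            variant: Optional[str] = None) -> float:
        """Effective parameter value under the given conditions.

        ``mode="direct"`` uses one axis' response function as the absolute
        value: exactly one of `t` and `ic` must be given (the verification
        experiments varied one factor at a time, so the direct functions were
        never combined).  ``mode="normalized"`` scales the reference default
        by ``factor_axis * f_axis(condition)`` for each supplied axis, the
        minimal interaction-free (multiplicative) composition; an omitted
        axis is taken at reference (factor 1).
        """
        self._check_parameter(parameter)
        if mode == "direct":
            if (t is None) == (ic is None):
                raise ValueError(
                    "direct mode applies a single axis' function as the absolute "
                    "parameter value: give exactly one of t and ic")
            if t is not None:
                return self.temperature_response(parameter, t, variant)
            return self.food_response(parameter, ic)
        if mode != "normalized":
            raise ValueError(f"mode must be 'direct' or 'normalized', got {mode!r}")
        value = self.default_value(parameter)
        if t is not None:
            factor = self.normalization_factor(parameter, "temperature", variant)
            value *= factor * self.temperature_response(parameter, t, variant)
        if ic is not None:
            if parameter in FOOD_PARAMETERS:
                factor = self.normalization_factor(parameter, "food")
                value *= factor * self.food_response(parameter, ic)
            # latency/embryo development have no food function; food axis is
            # a no-op for them (factor 1)
        if parameter in _PROBABILITY_PARAMETERS:
            return min(max(value, 0.0), 1.0)
        return max(value, 0.0)

    def default_value(self, parameter: str) -> float:
        """Reference-condition default of `parameter` (``BS`` -> ``pBS``)."""
        key = "pBS" if parameter == "BS" else parameter
        return float(self._c["individual_defaults"][key]["value"])

    # -- helpers -------------------------------------------------------------

    def _check_parameter(self, parameter: str) -> None:
        if parameter not in PARAMETERS:
            raise ValueError(f"unknown parameter {parameter!r}; expected one of {PARAMETERS}")

    def _clamp(self, parameter: str, value: float, low: Optional[float],
               high: Optional[float]) -> float:
        clamped = value
        if low is not None and clamped < low:
            clamped = low
        if high is not None and clamped > high:
            clamped = high
        if clamped != value:
            warnings.warn(
                f"{parameter} value {value:.4g} clamped to {clamped:.4g}",
                ClampedValueWarning, stacklevel=4)
        return clamped


@lru_cache(maxsize=None)
def default_responses() -> ResponseFunctionSet:
    """The packaged response-function set (exponential-decay variant)."""
    return ResponseFunctionSet()


# Module-level conveniences bound to the packaged coefficients.

def holling_ingestion(stage: str, c_food: float) -> float:
    return default_responses().holling_ingestion(stage, c_food)


def temperature_response(parameter: str, t: float, variant: Optional[str] = None) -> float:
    return default_responses().temperature_response(parameter, t, variant)


def food_response(parameter: str, ic: float) -> float:
    return default_responses().food_response(parameter, ic)


def normalization_factor(parameter: str, axis: str, variant: Optional[str] = None) -> float:
    return default_responses().normalization_factor(parameter, axis, variant)


def effective_parameter(parameter: str, t: Optional[float] = None,
                        ic: Optional[float] = None, mode: str = "normalized",
                        variant: Optional[str] = None) -> float:
    return default_responses().effective_parameter(parameter, t, ic, mode, variant)
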