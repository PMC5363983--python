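"""Response-function fidelity: printed coefficients, normalizing factors,
and the measured stage means they were fitted to."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from nitocra.responses import (CalibrationRangeWarning, ClampedValueWarning,
                               ResponseFunctionSet, load_coefficients)

# measured mean setup temperatures and the stage means recorded at them
MEASURED = {"15C": 14.86, "20C": 19.34, "25C": 24.90}
DURATION_MEANS = {
    "pN_DEV": {"15C": 9.52, "20C": 6.44, "25C": 5.57},
    "pC_DEV": {"15C": 12.31, "20C": 10.12, "25C": 8.86},
    "pE_DEV": {"15C": 4.08, "20C": 3.39, "25C": 3.18},
}
BROOD_MEANS = {"15C": 27.65, "20C": 23.76, "25C": 10.95}

PRINTED_TEMPERATURE_FACTORS = {
    ("pN_DEV", "exp_decay"): 5.85, ("pN_DEV", "belehradek"): 5.85,
    ("pC_DEV", "exp_decay"): 9.38, ("pC_DEV", "belehradek"): 9.38,
    ("pE_DEV", "exp_decay"): 3.25, ("pE_DEV", "belehradek"): 3.25,
    ("pL", "belehradek"): 3.23,
    ("pS_NAU", None): 975.0, ("pS_COP", None): 147.0, ("pS_ADU", None): 250.0,
}
PRINTED_FOOD_FACTORS = {"pN_DEV": 7.43, "pC_DEV": 11.8, "BS": 0.0324,
                        "pS_NAU": 690.0, "pS_COP": 333.0, "pS_ADU": 1111.0}


class TestHollingIngestion:
    def test_zero_food_gives_zero_intake(self, responses):
        assert responses.holling_ingestion("nauplius", 0.0) == 0.0

    def test_half_saturation(self, responses):
        # at c = k the type-III response sits at half its maximum
        assert responses.holling_ingestion("nauplius", 3.1993) == pytest.approx(
            0.2981 / 2, rel=1e-12)

    def test_reference_adult_ingestion(self, responses):
        assert responses.holling_ingestion("adult", 5.5) == pytest.approx(0.2440, abs=5e-5)

    @given(c=st.floats(0, 1e3), delta=st.floats(0, 100))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_monotone_and_bounded(self, c, delta):
        r = ResponseFunctionSet()
        lo = r.holling_ingestion("copepodite", c)
        hi = r.holling_ingestion("copepodite", c + delta)
        assert 0 <= lo <= hi <= r.ingestion_maximum("copepodite")

    def test_negative_concentration_rejected(self, responses):
        with pytest.raises(ValueError, match=">= 0"):
            responses.holling_ingestion("adult", -0.1)

    def test_unknown_stage_rejected(self, responses):
        with pytest.raises(ValueError, match="unknown stage"):
            responses.holling_ingestion("egg", 1.0)


class TestTemperatureResponses:
    @pytest.mark.parametrize("parameter", DURATION_MEANS)
    @pytest.mark.parametrize("setup", MEASURED)
    def test_decay_fits_pass_through_measured_means(self, responses, parameter, setup):
        """The decay curves were fitted through the stage means measured at
        the setups' mean temperatures (R^2 = 1 on three points)."""
        rate = responses.temperature_response(parameter, MEASURED[setup], "exp_decay")
        assert round(1.0 / rate, 2) == DURATION_MEANS[parameter][setup]

    @pytest.mark.parametrize("setup", MEASURED)
    def test_brood_size_quadratic_passes_through_measured_means(self, responses, setup):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", CalibrationRangeWarning)
            bs = responses.temperature_response("BS", MEASURED[setup])
        assert round(bs, 2) == BROOD_MEANS[setup]

    def test_brood_size_vertex(self, responses):
        """The brood-size quadratic peaks at c1/(2*|c2|) ~ 14.07 C."""
        t_max = 4.0229 / (2 * 0.143)
        assert t_max == pytest.approx(14.07, abs=0.01)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            below = responses.temperature_response("BS", t_max - 1)
            peak = responses.temperature_response("BS", t_max)
            above = responses.temperature_response("BS", t_max + 1)
        assert peak > below and peak > above

    @pytest.mark.parametrize("parameter,c1,c2", [
        ("pS_NAU", -0.8520, 0.0216),
        ("pS_COP", -0.3801, 0.0110),
        ("pS_ADU", -0.5704, 0.0157),
    ])
    def test_survival_optimum_near_20C(self, parameter, c1, c2):
        """Mortality quadratics bottom out near the 20 C survival optimum."""
        assert 17.0 < -c1 / (2 * c2) < 20.5

    def test_exponential_decay_interpolation_oracle(self):
        """Solving the three-parameter decay through the three measured
        (temperature, naupliar duration) points recovers the printed
        coefficients; the inverse problem is well-conditioned only for the
        naupliar fit, whose data span the amplitude best."""
        pts = [(MEASURED[s], DURATION_MEANS["pN_DEV"][s]) for s in MEASURED]
        (t1, d1), (t2, d2), (t3, d3) = pts

        def mismatch(b):
            e1, e2, e3 = (math.exp(-b * t) for t in (t1, t2, t3))
            return (d1 - d2) * (e2 - e3) - (d2 - d3) * (e1 - e2)

        b = brentq(mismatch, 1e-4, 2.0)
        a = (d1 - d2) / (math.exp(-b * t1) - math.exp(-b * t2))
        c = d1 - a * math.exp(-b * t1)
        for got, printed in zip((c, a, b), (5.3676, 373.3086, 0.3027)):
            assert abs(got - printed) / printed < 5e-3

    def test_quadratic_outside_calibrated_range_warns(self, responses):
        with pytest.warns(CalibrationRangeWarning):
            responses.temperature_response("pS_ADU", 30.0)

    def test_negative_survival_clamped_with_warning(self, responses):
        # the naupliar mortality quadratic dips below zero near its vertex
        with pytest.warns(ClampedValueWarning):
            value = responses.temperature_response("pS_NAU", 19.34)
        assert value == 0.0

    def test_unknown_variant_rejected(self, responses):
        with pytest.raises(ValueError, match="no 'exp_decay'"):
            responses.temperature_response("pL", 20.0, "exp_decay")

    def test_latency_defaults_to_its_only_form(self, responses):
        rate = responses.temperature_response("pL", 22.0)
        assert 1.0 / rate == pytest.approx(3.23, abs=5e-3)


class TestFoodResponses:
    def test_starvation_limits(self, responses):
        assert responses.food_response("pN_DEV", 0.0) == pytest.approx(0.0009)
        assert responses.food_response("BS", 0.0) == 0.0
        assert responses.food_response("pS_NAU", 0.0) == pytest.approx(1 / 25.3937)

    def test_negative_intake_rejected(self, responses):
        with pytest.raises(ValueError, match=">= 0"):
            responses.food_response("BS", -0.01)

    def test_parameters_without_food_function_rejected(self, responses):
        with pytest.raises(ValueError, match="no food response"):
            responses.food_response("pE_DEV", 0.1)


class TestNormalization:
    @pytest.mark.parametrize("parameter,variant", PRINTED_TEMPERATURE_FACTORS)
    def test_temperature_factors_reciprocal_at_reference(self, responses,
                                                         parameter, variant):
        printed = PRINTED_TEMPERATURE_FACTORS[(parameter, variant)]
        computed = responses.normalization_factor(parameter, "temperature", variant)
        assert computed * (1.0 / printed) == pytest.approx(1.0, rel=0.01)

    @pytest.mark.parametrize("parameter", PRINTED_FOOD_FACTORS)
    def test_food_factors_reciprocal_at_reference(self, responses, parameter):
        printed = PRINTED_FOOD_FACTORS[parameter]
        computed = responses.normalization_factor(parameter, "food")
        # the copepodite mortality factor is not exactly recoverable from the
        # printed cubic at any single reference ration
        tol = 0.05 if parameter == "pS_COP" else 0.01
        assert computed * (1.0 / printed) == pytest.approx(1.0, rel=tol)


class TestEffectiveParameter:
    def test_normalized_mode_restores_defaults_at_reference(self, responses):
        ref_t = responses.reference_temperature_C
        for parameter in ("pN_DEV", "pC_DEV", "pE_DEV", "pL", "BS",
                          "pS_NAU", "pS_COP", "pS_ADU"):
            ic = responses.reference_ingestion("adult")
            if parameter in ("pN_DEV", "pS_NAU"):
                ic = responses.reference_ingestion("nauplius")
            elif parameter in ("pC_DEV", "pS_COP"):
                ic = responses.reference_ingestion("copepodite")
            value = responses.effective_parameter(parameter, t=ref_t, ic=ic,
                                                  mode="normalized")
            assert value == pytest.approx(responses.default_value(parameter), rel=0.01)

    def test_direct_mode_single_axis(self, responses):
        rate = responses.effective_parameter("pE_DEV", t=19.34, mode="direct")
        assert 1.0 / rate == pytest.approx(3.39, abs=5e-3)

    def test_direct_mode_rejects_both_axes(self, responses):
        with pytest.raises(ValueError, match="single axis"):
            responses.effective_parameter("pN_DEV", t=20.0, ic=0.1, mode="direct")
        with pytest.raises(ValueError, match="single axis"):
            responses.effective_parameter("pN_DEV", mode="direct")

    def test_normalized_starvation_composition(self, responses):
        """Combined temperature and starvation effect on naupliar mortality:
        default scaled by both normalized responses multiplicatively."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ClampedValueWarning)
            value = responses.effective_parameter("pS_NAU", t=22.0, ic=0.0,
                                                  mode="normalized")
        expected = 2.65e-3 * 975 * responses.temperature_response("pS_NAU", 22.0) \
            * 690 * (1 / 25.3937)
        assert value == pytest.approx(expected, rel=0.02)

    def test_unknown_parameter_rejected(self, responses):
        with pytest.raises(ValueError, match="unknown parameter"):
            responses.effective_parameter("pX", t=20.0, mode="direct")


class TestCoefficientFile:
    def test_loader_validates_completeness(self, tmp_path):
        bad = tmp_path / "broken.yaml"
        bad.write_text("ingestion: {}\n")
        with pytest.raises(ValueError, match="missing sections"):
            load_coefficients(str(bad))

    def test_individual_defaults_match_dataclass(self, responses):
        from nitocra.life_cycle import LifeCycleParameters
        params = LifeCycleParameters()
        assert responses.default_value("pN_DEV") == params.pN_DEV
        assert responses.default_value("BS") == params.pBS
        assert responses.default_value("pS_ADU") == params.pS_ADU
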