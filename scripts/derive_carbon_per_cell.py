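"""Derivation of the calibrated carbon-per-cell conversion.

The response-function tables give food dependence against *bottom food
concentration* (ug C/cm2), but treatments are specified as nominal algal
concentrations (cells/mL).  The conversion requires the carbon content of
one R. salina cell, which is not part of the coefficient tables.  This
script back-derives it: the reference bottom concentration C_ref is chosen
so that the printed food normalizing factors are simultaneously reproduced
by 1 / f(IC_stage(C_ref)), and the carbon-per-cell constant then follows
from requiring that the standard ration (2.5e5 cells/mL) in 6-well
geometry (8 mL over 9.6 cm2) lands on C_ref.

Run:  python scripts/derive_carbon_per_cell.py
"""

import numpy as np
from scipy.optimize import minimize_scalar

from nitocra.responses import (FOOD_PARAMETERS, STAGE_FOR_PARAMETER,
                               default_responses)

PRINTED_FOOD_FACTORS = {"pN_DEV": 7.43, "pC_DEV": 11.8, "BS": 0.0324,
                        "pS_NAU": 690.0, "pS_ADU": 1111.0}
# pS_COP is excluded from the fit: its printed factor (333) is not exactly
# recoverable from the printed cubic at any single reference concentration.


def factor_mismatch(c_ref: float) -> float:
    r = default_responses()
    sq = 0.0
    for param, printed in PRINTED_FOOD_FACTORS.items():
        ic = r.holling_ingestion(STAGE_FOR_PARAMETER[param], c_ref)
        computed = 1.0 / r.food_response(param, ic)
        sq += (np.log(computed) - np.log(printed)) ** 2
    return sq


def main() -> None:
    res = minimize_scalar(factor_mismatch, bounds=(1.0, 20.0), method="bounded")
    c_ref = res.x
    print(f"best-fit reference bottom concentration: {c_ref:.4f} ug C/cm2")
    r = default_responses()
    for param in FOOD_PARAMETERS:
        ic = r.holling_ingestion(STAGE_FOR_PARAMETER[param], c_ref)
        print(f"  {param:8s} 1/f(IC(C_ref)) = {1.0 / r.food_response(param, ic):10.4f}"
          f"   printed {r.printed_normalizing_factor(param, 'food')}")
    cells = 2.5e5
    volume_mL, area_cm2 = 8.0, 9.6
    cpc = c_ref * area_cm2 / (cells * volume_mL)
    print(f"\nC_ref rounded to 5.5 ug C/cm2 => carbon per cell "
          f"= 5.5 * {area_cm2} / ({cells:g} * {volume_mL}) = {5.5 * area_cm2 / (cells * volume_mL):.3g} ug")
    print(f"(unrounded best fit would give {cpc:.3g} ug = {cpc * 1e6:.1f} pg C/cell)")


if __name__ == "__main__":
    main()
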