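# Response-function coefficients for the Nitocra spinipes life-cycle model.
# Units: temperatures in degrees Celsius (t), ingested carbon (IC) in ug C per
# individual per day, bottom food concentration (C_food) in ug C per cm2 of
# vessel floor, rates in 1/day, daily death probabilities dimensionless.
version: "1.0"

reference:
  temperature_C: 22.0
  bottom_food_ug_C_per_cm2: 5.5

# Holling type III functional response of daily ingestion per individual:
#   IC(stage) = a_max * C_food^2 / (C_food^2 + k_half^2)
ingestion:
  nauplius:   {a_max: 0.2981, k_half: 3.1993}
  copepodite: {a_max: 0.0677, k_half: 0.8491}
  adult:      {a_max: 0.2623, k_half: 1.5053}

# Shared Belehradek duration kernel D(t) = a * (t - t0)^b (days), scaled per
# parameter; rate = 1 / (D(t) * scale).
belehradek_base: {a: 250.0, t0: -7.2, b: -1.86}

# Temperature dependence.  exp_decay: rate = 1 / (c + a * exp(-b * t)).
# quadratic: value = c0 + c1*t + c2*t^2 (brood size); survival quadratics are
# given in percent and divided by 100.
temperature:
  pN_DEV:
    exp_decay:  {c: 5.3676, a: 373.3086, b: 0.3027, normalizing_factor: 5.85}
    belehradek: {scale: 12.432, normalizing_factor: 5.85}
  pC_DEV:
    exp_decay:  {c: 7.9317, a: 43.4835, b: 0.1545, normalizing_factor: 9.38}
    belehradek: {scale: 19.956, normalizing_factor: 9.38}
  pE_DEV:
    exp_decay:  {c: 3.13, a: 70.612, b: 0.2899, normalizing_factor: 3.25}
    belehradek: {scale: 6.911, normalizing_factor: 3.25}
  pL:
    belehradek: {scale: 6.860, normalizing_factor: 3.23}
  BS:
    quadratic: {c0: -0.5569, c1: 4.0229, c2: -0.143, normalizing_factor: null}
  pS_NAU:
    quadratic_percent: {c0: 8.3922, c1: -0.8520, c2: 0.0216, normalizing_factor: 975}
  pS_COP:
    quadratic_percent: {c0: 3.7204, c1: -0.3801, c2: 0.0110, normalizing_factor: 147}
  pS_ADU:
    quadratic_percent: {c0: 5.3501, c1: -0.5704, c2: 0.0157, normalizing_factor: 250}

# Food dependence, as functions of stage-appropriate ingested carbon.
food:
  pN_DEV:
    power: {c0: 0.0009, c1: 0.1789, exponent: 0.1943}
    normalizing_factor: 7.43
  pC_DEV:
    power: {c0: 0.0002, c1: 0.1827, exponent: 0.2824}
    normalizing_factor: 11.8
  BS:
    saturating_exponential: {a: 33.2374, b: 10.626}
    normalizing_factor: 0.0324
  pS_NAU:
    rational: {c0: 25.3937, c1: 2972.583}
    normalizing_factor: 690
  pS_COP:
    cubic: {c0: 0.0016, c1: -0.0175, c2: 5.4615, c3: -73.4746}
    normalizing_factor: 333
  pS_ADU:
    rational: {c0: 12.8226, c1: 4504.1407}
    normalizing_factor: 1111

# Individual-level defaults at reference conditions (22 C, food in abundance).
# alpha: gamma shape of the duration deviate; cv: coefficient of variation of
# the normal sampler; survival entries are daily death probabilities.
individual_defaults:
  pN_DEV: {value: 0.129, alpha: 30.0}
  pC_DEV: {value: 0.111, alpha: 14.3}
  pL:     {value: 0.308, alpha: 26.1}
  pE_DEV: {value: 0.315, alpha: 3.5}
  pBS:    {value: 24.0, cv: 0.44}
  pNB:    {value: 3.64, cv: 0.37}
  pS_NAU: {value: 2.65e-3}
  pS_COP: {value: 4.83e-3}
  pS_ADU: {value: 3.19e-3}
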