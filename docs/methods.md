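# Methods

## Model structure

The simulator is an individual-based, daily-time-step model of *Nitocra
spinipes* cohorts in microplate vessels. Each day applies, in order:
feeding-day food replacement → minute-resolution ingestion → update of
effective parameters → survival draws → development advancement and stage
transitions → fertilization and reproduction. Mortality precedes molting,
so an individual cannot molt and die on the same day; the ordering is
confined to the scheduler (`simulator.run_simulation`) so alternatives
remain testable. Newborn nauplii from clutches enter the population the
following day with age 0 and fresh deviates.

### Development

Durations are modelled as gamma deviates (mean 1, shape α) divided by a
daily rate. The deviate is drawn once per phase per individual, which
preserves individual consistency under time-varying rates (a slow
individual stays slow when food fluctuates). Progress accumulates the
daily rate; the phase completes on the day the sum crosses the deviate.
Two numerical choices matter:

- **Fractional duration recording.** Recorded durations interpolate the
  crossing linearly within the completion day, so under constant rates the
  realized duration equals deviate/rate exactly. Pure day-counting would
  bias every mean duration upward by about half a day, which is
  incompatible with simulated reproduction summaries sitting at or
  slightly below their theoretical values.
- **Carry-over at clutch release.** After a clutch, the remainder of the
  completion day accrues progress for the next embryonic phase at the
  embryonic rate (continuous accrual sampled daily). Without carry-over,
  wall-clock inter-clutch periods are biased upward by the expected idle
  day fraction (≈ 0.5 d). Stage molts do not need the equivalent
  correction because stage durations are measured on the phase's own
  clock, from first accrual to crossing.

The α footed to each phase is the gamma shape of the *duration* deviate;
the rates, as reciprocals of gamma durations, are inverse-gamma
distributed.

### Survival, sex, reproduction

Stage mortalities are daily Bernoulli probabilities. Sex is assigned once
at adulthood with p(female) = 0.5 by default; temperature shifts the
observed sex ratio in the calibration data, but no functional form exists
for it, so the probability is exposed as a plain parameter. In population
mode a female is fertilized (once, permanently) on the first day a living
adult male shares the vessel — the simplest rule consistent with
simulating individually fertilized females; mating behaviour is not
modelled. The latency clock starts at fertilization; each clutch draws its
size from the female's *current* effective brood-size mean, so food or
temperature changes act on clutches at initiation.

## Response functions and normalization

Coefficients ship in `nitocra/data/coefficients.yaml` (versioned,
validated for completeness at load). Temperature responses: independent
three-parameter exponential-decay fits per developmental phase (the
default, used by all verification runs), a shared Bělehrádek power law
D = 250·(t + 7.2)^−1.86 rescaled per phase (optional; presumes
equiproportional stage durations, which the calibration data do not
support), and quadratics for brood size and stage mortalities. Latency has
only the Bělehrádek form. Quadratics are calibrated on 15–25 °C;
evaluation outside that range emits a `CalibrationRangeWarning`, and
probabilities are clamped to [0, 1] (the naupliar-mortality quadratic dips
marginally below zero near its 19.7 °C vertex; the clamp to 0 is the
physical reading).

Food responses are functions of daily ingested carbon (IC, µg C/d) per
stage, obtained from the benthic concentration via stage-specific Holling
type III curves. Normalizing factors are computed as reciprocals of each
function at the reference condition rather than read from the printed
rounded values; they agree with the printed factors within 1% (the
copepodite-mortality food factor within 5% — its printed value is not
exactly recoverable from the printed cubic at any single reference
ration). `normalized` mode composes both axes multiplicatively on the
reference default — the minimal interaction-free assumption; temperature ×
food interactions are documented as unsupported, not estimated.

## Food dynamics

Nominal rations (cells/mL) translate to vessel-floor carbon through the
vessel volume, floor area, and a carbon-per-cell constant of 2.64×10⁻⁵ µg
(26.4 pg C per *R. salina* cell). The constant is a calibration, not a
measurement: it is chosen so the standard ration (2.5×10⁵ cells/mL) in
6-well geometry lands on the reference concentration 5.5 µg C/cm² that
simultaneously reproduces the printed food normalizing factors
(`scripts/derive_carbon_per_cell.py` shows the derivation; the unrounded
best fit is 5.54 µg C/cm²). Vessel presets use standard labware
dimensions (96-well: 0.27 mL/0.32 cm²; 24-well: 2 mL/1.9 cm²; 6-well:
8 mL/9.6 cm²), all overridable.

Feeding replaces the full ration every second day (the laboratory
protocol alternated 2- and 3-day intervals across weekends; the model uses
the 2-day simplification). Between feedings the only sink is consumption:
1440 one-minute steps per day recompute each living individual's Holling
intake at the current concentration and subtract the total from the pool;
when aggregate minute demand exceeds the remaining food, allocation is
proportional to demand and the pool floors at zero. The loop is
deterministic given the stage composition (all stochasticity lives in
survival/development), conserves carbon to floating tolerance, and is
evaluated per stage, so its cost is independent of cohort size. Algal
growth, degradation and spatial structure within a well are not modelled.

## Verification experiments

- **Development test** (`run_development_test`): temperature setups run 72
  nauplii for 35 days in direct-temperature mode at the measured mean
  setup temperatures (14.86, 19.34, 24.90 °C; nominal temperatures are a
  flag away); food setups run 35 nauplii for 45 days at 22 °C in
  direct-food mode. Reproduction is disabled to emulate individual
  isolation. Food setups use a 6-well-intensity vessel scaled to the
  cohort (n/24 wells), which keeps the standard ration exactly at the
  calibrated reference concentration and matches the experimental
  per-capita loading of 0.33 mL per animal.
- **Reproduction test** (`run_reproduction_test`): n = 50 females start as
  fertilized adults and run 15 days; food-setup females feed alone in a
  24-well vessel (the experiment isolated ovigerous females in 2 mL
  wells). Clutch sizes and inter-clutch periods (latency interval
  excluded) are reported both pooled per clutch and as per-female means,
  because the aggregation used for the published n = 50 summaries is
  ambiguous — the reported SDs are smaller than either aggregation implies
  under α_E = 3.5. Comparisons against theoretical values use a one-sided
  one-sample t-test in the direction of the observed deviation (the
  reported test's direction is unstated).

Completed-period statistics carry a small downward selection bias: slow
broods are censored by the 15-day window, so the typical realization sits
slightly below the theoretical mean (the published simulated summaries
show the same pattern at two of three temperatures). The acceptance test
therefore requires the majority of 20 seeded realizations to pass, not
every one.

## Monte Carlo and reproducibility

Replicate r of a run derives its seed from
`SeedSequence(master_seed, spawn_key=(r,))`, so any replicate is
reproducible in isolation; identical configs and seeds reproduce outputs
bit-for-bit. Bands are percentile (2.5%, 97.5%) summaries — appropriate
for counts — alongside the mean and median. For strongly skewed count
distributions the mean can fall marginally outside a percentile band
(e.g. one straggler nauplius in 1 of 50 runs); the median never does.

## Exact statistics

The Fisher–Freeman–Halton test enumerates every r×2 table with the
observed margins (feasible-table count checked by dynamic programming
against a 10⁷ guard; the packaged tables need at most ~4×10⁴) and sums
multivariate hypergeometric probabilities ≤ that of the observed table,
with a 10⁻⁷ relative tie tolerance. On 2×2 input this reduces to the
classical hypergeometric construction, which is cross-checked against an
independent implementation in the tests. Computed p-values for the six
packaged count tables (0.183, 0.023, 3.0×10⁻⁴, 5.0×10⁻⁸, 1.5×10⁻⁵, 0.287)
agree with reference statistical software to six digits; the published
values differ for five of the six tables (only the food sex-ratio value
matches at its printed precision), although every significance conclusion
at α = 5% is identical. The packaged fixtures retain the published counts
and p-values verbatim.

Kruskal–Wallis, Shapiro–Wilk and Bartlett pretests of the original study
are not implemented: they operate on raw individual measurements that are
not available, only summarized.

## What the verification shows — and what it does not

Passing tests show that the implementation reproduces the response
functions exactly, recovers its own parameters in direct-mode simulation
(mean naupliar/copepodite durations to ±0.1/±0.15 d at 10⁴ individuals),
conserves individuals and carbon, and yields reproduction output
statistically consistent with the theoretical values. The synthetic
cohorts inherit every simplification above — aggregated instars, constant
p(female), no mating dynamics, 2-day feeding, no algal dynamics, no
temperature × food interaction — so agreement with the model's own theory
does not certify predictions for real cultures outside the calibrated
ranges (15–25 °C, 0–5×10⁵ cells/mL) or for endpoints the calibration data
did not constrain (e.g. sex-ratio shifts, latency under starvation, which
is known to lengthen but has no functional form and is not modelled).

## Problem sizes used by the test suite

Monte-Carlo checks in the suite use 50–200 replicates and cohorts of
18–288 (10⁴ individuals for the parameter-recovery check; 20 seeds × 50
females for reproduction consistency; 60 replicates × 6 setups for the
food-stress monotonicity check). These sizes put Monte-Carlo error well
below the asserted tolerances; the full published protocol (1000
replicates) runs in a few seconds via `nitocra devtest`.
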