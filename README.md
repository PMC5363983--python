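# nitocra

An individual-based life-cycle model of the brackish-water harpacticoid
copepod *Nitocra spinipes* — a standard ecotoxicological test species —
under combined temperature and food-quantity stress, together with the
verification experiments (development test, reproduction test) and the
exact contingency-table statistics used to evaluate them.

The package is aimed at ecotoxicologists and population modellers who want
to extrapolate individual-level temperature/food effects to cohort and
population dynamics, e.g. as a baseline for population-level risk
assessment of chemicals under non-optimal environmental conditions.

## The model

Each copepod passes irreversibly through aggregated naupliar and
copepodite phases to adulthood. Phase *i* carries a gamma-distributed
duration deviate *v* ~ Gamma(α_i, 1/α_i) (mean 1), drawn once at phase
entry; development progress accumulates the daily rate *p_i* and the phase
completes when the cumulative sum reaches *v*, so under constant
conditions durations are Gamma with mean 1/p_i and CV 1/√α_i — capturing
the positive skew ("laggard" animals) of observed development times.
Mortality is a daily Bernoulli trial per stage; sex is assigned once at
adulthood. Fertilized females run a latency phase (rate p_L), then cycle
embryonic development (rate p_E), releasing a clutch of
round(N(BS, 0.44·BS))⁺ nauplii at each completion until their drawn brood
count N(3.64, 0.37·3.64) is exhausted.

Environmental drivers enter through response functions:

- **Temperature** t (°C): three-parameter exponential-decay duration
  curves 1/p = c + a·e^(−b·t) fitted per phase, an optional shared
  Bělehrádek law D = 250·(t + 7.2)^−1.86 (equiproportional variant),
  and quadratic optimum curves for brood size and the three stage
  mortalities (survival optimum near 20 °C).
- **Food**: a Holling type III functional response
  IC = a_max·C²/(C² + k²) maps the benthic food concentration C
  (µg C/cm² of vessel floor — the resource axis relevant to a bottom
  dweller) to daily ingested carbon per individual, and empirical
  best-fit curves map IC to each life-cycle parameter. Food is fully
  replaced every second day and depleted competitively in 1440
  one-minute steps per day, so crowded or poorly fed vessels develop
  genuine resource competition.

Each function carries a *normalizing factor* (its reciprocal at the
reference condition: 22 °C, C = 5.5 µg C/cm² ≙ 2.5×10⁵ cells/mL), so
responses can either be applied **directly** as absolute parameter values
(one axis at a time — the verification mode) or **normalized**, scaling
the reference defaults multiplicatively on both axes.

Monte-Carlo replication summarizes per-day stage abundances as means with
percentile (2.5%, 97.5%) bands. The exact-test module implements the
Fisher–Freeman–Halton test for r×2 tables by complete enumeration, used on
the packaged alive/dead and female/male count tables.

## Worked example

Simulate the 20 °C development test (72 nauplii, 35 days, reproduction
disabled, temperature functions applied directly) with 200 replicates:

```python
from nitocra import run_development_test, run_reproduction_test

s = run_development_test("20C", replicates=200, master_seed=1)
f = s.to_frame()
print(f[(f.stage == "adult") & (f.day.isin([10, 15, 20, 25, 35]))])
```

```
 day stage   mean  median  lower  upper
  10 adult  0.180     0.0  0.000  1.025
  15 adult 17.255    17.0 11.000 23.000
  20 adult 57.865    58.0 50.975 63.000
  25 adult 66.625    67.0 62.000 70.000
  35 adult 65.865    66.0 61.000 70.000
```

The cohort matures between days 12 and 25 (naupliar phase ≈ 6.4 d,
copepodite phase ≈ 10.1 d at the measured 19.34 °C) and ~92% of the 72
animals are alive as adults on day 35, matching the low (4%) mortality
observed at the 20 °C optimum. The reproduction test simulates 50
individual fertilized females for 15 days and compares clutch sizes and
inter-clutch periods with the theoretical values implied by the response
functions:

```python
print(run_reproduction_test("25C", master_seed=1).summary().round(2))
```

```
                          quantity  mean   sd   n  theoretical
           brood size (per female) 11.92 2.79  48        10.95
brood-to-brood period (per female)  3.16 1.27  42         3.18
           brood size (per clutch) 11.70 4.74 138        10.95
brood-to-brood period (per clutch)  3.09 1.72  90         3.18
```

The same experiments are available from the shell:

```bash
nitocra devtest --setup 20C --replicates 200 --seed 1 --out runs/dev20
nitocra reprotest --setup 25C --seed 1
nitocra stats --fixture temperature-sex-ratio
nitocra verify all
```

`nitocra stats` prints the exact p-value of a packaged (or CSV) count
table; for the temperature sex-ratio table it reports p ≈ 3.0×10⁻⁴ — the
shift toward females at warmer temperatures is highly significant.

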