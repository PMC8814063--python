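# Methods

## Model

`samplecast` predicts the number of study-eligible patients a single hospital
yields per year as a deterministic multiplicative chain, then layers a
Poisson arrival process on top of the resulting rate.

**Expected availability.** With population size `n`, prevalence `Pr` (percent,
against base `Pc = 100`), `X` hospitals and `X'` attrition strata, the
per-hospital, per-stratum annual expectation is

    A = n · (Pr/Pc) · (1/X) · (1/X').

The chain assumes (i) prevalence is an adequate stand-in for the annual
pool of ascertainable cases, (ii) cases distribute uniformly over hospitals,
and (iii) case attrition splits cases *equally* over `X'` fates — did not
seek care, sought care elsewhere, misdiagnosed, death/remission before
diagnosis, and an unknown catch-all — of which exactly one stratum is
reachable by the researcher. The equal split is a deliberate
maximum-ignorance choice: unequal weights would assert knowledge of the
attrition structure the designer does not have, so they are rejected with a
validation error rather than silently accepted.

**Time refinement.** Access to the out-patients department (OPD) is limited
to `h` hours per day on working days. The accessible fraction of the year is

    R / A = h · dM · dY / (Yd · Hd),

with `Yd = 365` days/year, `Hd = 24` h/day, `dM` working days/month and
`dY = 12` months/year. `refine()` is implemented as `h` times the one-hour
value, so scaling in hours is bit-exactly linear. The availability
probability `P = (R/A)·(Pc/100)` is this same fraction and is therefore
independent of `n`, `Pr`, `X`, `X'` — a property the test suite checks over
randomized scenarios.

**Integer reporting.** Patient counts are reported as floors (truncation) of
the continuous values: `predicted = ⌊R⌋`, and
`predicted_wst = ⌊R·X'⌋` for the count before the stratification split
("WST", without stratification). Rounding is presentation-only; every
internal comparison uses unrounded values.

## The dM = 27 calendar constant

A Sunday-closed month nominally has about 26 working days, and user docs for
similar calculators quote 26. The packaged worked scenarios, however, are
reproduced in their entirety only by `dM = 27`: a brute-force scan over
`dM ∈ {25, 26, 27, 28}` (automated in the test suite) shows 27 is the unique
value recovering all six before-stratification sweep counts
(651/1955/2172/2607/3259/3693). The default is therefore 27 — the refinement
factor at 1 h/day is 324/8760 ≈ 0.03699 — and `dM` is exposed as a parameter
(`--dm`) for users who prefer the stricter 26.

Two printed multi-hour values in the source material (1304 and 1956 for
2 h/3 h before stratification at 3 % prevalence) correspond to continuous
values 1303.70 and 1955.55: they follow round-half-up, while every other
printed integer follows truncation. This internal inconsistency is
documented by a test (floor gives 1303/1955; round gives 1304/1956) and the
two integers are intentionally not reproduced.

## Stochastic layer

**What it emulates.** Day-to-day fluctuation in OPD arrivals: the count on
each working day is an independent Poisson draw with intensity
`daily_rate = R / (dM·dY)` (R/324 by default), and exactly zero on Sundays,
when OPDs are closed. Poisson is the minimal arrival model — independent
patients, constant intensity — and its variance-equals-mean property is what
the dispersion test asserts.

**Two working-day calendars coexist by design.** The deterministic model
uses `dM·dY = 324` working days/year; a true Sunday-excluded calendar year
has 312–313. `daily_rate` deliberately uses the model's 324 so that a
simulated 324-working-day span has mean total exactly `R`; simulating over a
true calendar year therefore undershoots `R` by ~3 %. Accrual estimates
(`time_to_target`) count *working* days and inherit the same convention.

**What it does not emulate.** No day-of-week or seasonal intensity
variation, no holidays beyond Sundays, no over-dispersion
(negative-binomial clustering), no multi-site correlation, and no
patient-level covariates. Passing tests therefore demonstrate internal
consistency of the rate model and its Poisson layer — not that real OPD
attendance is Poisson. Observed accruals at real clinics have exceeded the
prediction by tens of samples per year; the model is a planning threshold,
not a point forecast.

## Numerical and design choices

- **Validation philosophy:** out-of-range inputs are rejected with an error
  naming the offending field, never clamped. Degenerate zero cases (`n = 0`,
  `Pr = 0`) are valid and propagate zeros; the availability probability at
  `A = 0` raises a distinct `UndefinedProbabilityError`, and a zero arrival
  rate makes any accrual target raise `UnreachableTargetError`.
- **pct_base** is kept as an explicit parameter but fixed at 100; overriding
  it warns, because the `(Pc/100)` factor then changes the meaning of `P`.
- **Closed form vs chain:** `per_hospital_availability` (the single-product
  closed form) and the S→U→S′ chained divisions are both implemented and
  asserted equal to relative tolerance 1e-12; reported results come from the
  chain.
- **Hospital count:** the spread of cases over hospitals is a single plain
  constant `X` (default 100, per-scenario settable); no population-dependent
  scaling rule is modelled.
- **Seeds:** the library requires an explicit integer seed for every
  simulation (`numpy.random.default_rng`); the CLI defaults it to 1234 and
  prints it. Identical (scenario, calendar, seed) triples give bit-identical
  series.
- **Report precision:** continuous values to 2 decimals, `P` to 5, in both
  CSV and JSON; writers are byte-deterministic for fixed inputs.

## Problem sizes used in the test suite

Monte-Carlo checks run at sizes chosen to keep the whole suite in a few
seconds while leaving comfortable statistical margins: mean-recovery uses
1000 replicate 324-working-day years (a 3-standard-error band on the annual
total), stopping-time consistency uses 200 replicates at a ~1/day rate with
a 5 % tolerance, and dispersion uses a single 324-working-day year with a
[0.7, 1.3] acceptance band on the variance/mean ratio.

## Limitations

The model is a back-of-envelope feasibility chain: every step is a constant
proportional split, so all structure the designer cannot quantify (referral
patterns, hospital size heterogeneity, diagnosis rates, seasonality) is
absorbed into `X`, `X'` and the equal-split assumption. Its outputs should
be read as an order-of-magnitude threshold for single-site feasibility and a
trigger for multi-site recruitment when the threshold falls short of the
required sample size.
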