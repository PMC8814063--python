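# samplecast

Forecast how many study-eligible patients a **single hospital** will yield per
year, and how long recruitment will take, before an epidemiological
(typically case–control) study starts.

Online sample-size calculators tell you how many participants you *need* for
statistical power; none tell you whether one hospital's out-patients
department (OPD) can actually *supply* them within your study window.
`samplecast` answers that feasibility question from quantities a study
designer already knows: population size, disease prevalence, the number of
hospitals the cases are spread over, and the daily hours during which the
research team has OPD access.

## The model

The deterministic chain from population to a per-hospital, time-refined
annual count is

```
S  = n · Pr / Pc                     annual diseased individuals (prevalence Pr
                                     in %, percentage base Pc = 100)
U  = S / X                           uniform split over X hospitals (default 100)
S' = U / X'                          equal split over X' = 5 attrition strata:
                                     did not seek care, seen elsewhere,
                                     misdiagnosed, death/remission, unknown —
                                     exactly one stratum is reachable
A  = n · (Pr/Pc) · (1/X) · (1/X')    the same quantity in closed form
R  = A · h · dM · dY / (Yd · Hd)     time refinement: h sampling hours/day,
                                     dM = 27 working days/month, dY = 12,
                                     Yd = 365 days/year, Hd = 24 h/day
P  = (R / A) · (Pc / 100)            availability probability — the accessible
                                     fraction of the year
```

Reported counts are floors of the continuous values; `predicted_wst`
(= floor(R·X'), "without stratification") is the count before the five-way
attrition split. On top of the deterministic rate, a stochastic layer models
arrivals as an independent Poisson draw per working day (Sundays excluded —
OPDs are closed), with per-working-day intensity R / (dM·dY), and estimates
the expected working days to reach a target sample size.

See `docs/methods.md` for assumptions, the dM = 27 calendar constant, and
known limitations.

## Worked example

Migraine in a population of 12.3 million with ~12 % prevalence, sweeping the
daily OPD access time from 1 to 5 hours:

```
$ samplecast predict --population 12300000 --prevalence 12 --hours 1 2 3 4 5
h=1: S=1476000.00 annual cases -> U=14760.00 per hospital -> S'=2952.00 per stratum -> R=109.18 refined (P=0.03699); predicted 545 before stratification, 109 after
h=3: S=1476000.00 annual cases -> U=14760.00 per hospital -> S'=2952.00 per stratum -> R=327.55 refined (P=0.11096); predicted 1637 before stratification, 327 after
...
prevalence_pct,hours,S,U,S_prime,A,R,predicted_wst,predicted,P
12,1,1.476e+06,14760,2952,2952,109.18,545,109,0.03699
12,2,1.476e+06,14760,2952,2952,218.37,1091,218,0.07397
12,3,1.476e+06,14760,2952,2952,327.55,1637,327,0.11096
12,4,1.476e+06,14760,2952,2952,436.73,2183,436,0.14795
12,5,1.476e+06,14760,2952,2952,545.92,2729,545,0.18493
```

Reading the 3-hour row: the 1.476 M annual cases spread over 100 hospitals
give 14 760 per hospital; after the five-way attrition split 2 952 remain
reachable per hospital per year, of which a team present 3 h/day can expect
to see R ≈ 327.6, i.e. **327 recruitable patients per year** (P ≈ 0.111 of
annual availability). A one-year study targeting ~327 migraine cases from a
single hospital at 3 h/day is therefore just feasible; at 1 h/day (109/year)
it is not.

Other options: `--target-n` prints the expected working days to reach a
sample-size target; `--simulate --seed S --start-date YYYY-MM-DD --days D`
writes a day-by-day Poisson arrival series (zero on Sundays) as CSV;
`--config run.yaml` reads the same keys from YAML/TOML, with flags taking
precedence; `--out report.csv --format csv|json` writes the sweep table.

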