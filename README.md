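# stockdemog

Life-table demography of exploited, age-structured marine fish stocks.

Fisheries stock assessments publish, for each stock and year, the
numbers-at-age, fishery removals, mean weight, maturity and natural
mortality that the assessment model settled on. `stockdemog` turns those
tables into the metrics conservation biology uses to judge a
population's trajectory and its capacity to rebuild: annual population
growth rates with and without fishing, cohort lifetime reproductive
success and generation length, the dependence of growth on relative
abundance, and Monte Carlo doubling-time projections. It is aimed at
quantitative fisheries scientists and conservation ecologists who want
stock-specific demographic rates rather than life-history proxies.

## The model

For each stock-year a period life table is reconstructed and the
discrete Euler-Lotka (renewal) equation is solved for the annual growth
rate λ:

```
1 = Σ_{a=ν}^{ω}  λ^(−a) · s_{y,a} · f_{y,a}
```

with survivorship-to-age `s` built from proportional annual mortality
(`F = C/N` from catch and abundance, `Z = F + M`, survival `l = 1 − Z`)
and per-spawner fecundity `f` obtained by attributing the recruits
observed in year *y+1* back to the spawning biomass that produced them
(`RPS_y = R_y / SSB_{y−b}`, offset by the recruit age *b*; each kilogram
of spawning biomass contributes equally). The root of the renewal
equation equals the dominant eigenvalue of the corresponding Leslie
matrix, which the test suite uses as an independent oracle.

Because observation error in assessed series cannot be propagated
directly, each year's schedule is *calibrated*: natural mortality and
fecundity receive small multiplicative step changes (0.5% by default,
mortality first, then fecundity) until the predicted next-year abundance
`λ_y · N_y` lands within 5% of the assessed `N_{y+1}`. Two rates come
out of the same adjusted schedule: **λ_real** (fishing included) and
**λ_dem** (survivorship under natural mortality only) — the growth the
stock could have achieved that year had the harvest not been taken.

Downstream, complete cohorts are read along the diagonals of the
calibrated schedules to give `R0 = Σ s_x f_x` (spawners per spawner;
1 = replacement) and generation length `LG = Σ x·s_x·f_x / Σ s_x·f_x`;
log λ is regressed on the proportion of maximum abundance with a
hierarchical penalized-spline smooth (a global curve plus shrunken
per-stock deviation curves); and doubling times are projected by
resampling each stock's observed annual fecundity and natural-mortality
schedules with fishing removed (high recovery potential: ≥75% of 1000
trajectories doubled by year 10; moderate: ≥50% by year 20; low
otherwise).

Real assessment repositories are not bundled; a synthetic-stock
generator with the same statistical structure (proportional cohort
survival, spawning-biomass-proportional recruitment with lognormal
variability and infrequent strong year classes, age-selective fishing)
drives the examples and tests, alongside exact hand-checkable fixtures.

## Worked example

```
python analysis/01_simulate_stocks.py  --seed 1
python analysis/02_growth_rates.py
python analysis/03_cohort_metrics.py
python analysis/04_density_dependence.py
python analysis/05_recovery.py         --seed 1
python analysis/06_summaries.py
```

The drivers write their tables under `results/` and print what they
found. With the default 12 stocks × 40 years at seed 1:

```
wrote 468 stock-years to results/lambda_series.csv (100.0% converged)
median lambda_real = 0.919, median lambda_dem = 1.075
wrote 360 complete cohorts to results/cohorts.csv
median R0: 1.19 with fishing, 2.79 without
median generation length: 3.95 yr with fishing, 5.58 yr without
[dem] global curve: lambda(0.2)=1.201, lambda(0.4)=1.142 [1.105, 1.180], lambda(1.0)=0.999
recovery classes: {'high': 8, 'moderate': 4}
```

Read: the simulated fleet is fished slightly past replacement (median
λ_real < 1) yet retains innate growth capacity (median λ_dem ≈ 1.08);
an average spawner would nearly triple herself absent fishing (R0 ≈
2.8); fishing shortens generations by about 1.6 years; the fitted
density-dependence curve declines from low to high relative abundance
and sits at ≈1 at the maximum, as the abundance-ratio constraints
require; and most stocks would double within a decade if fishing
stopped.

The same operations are available as a CLI
(`stockdemog simulate|lambdas|cohorts|density|recovery|report`) and as
plain library calls:

```python
import stockdemog as sd

stock  = sd.make_stationary_fixture()        # exact reference stock
series = sd.lambda_series(stock)             # lambda_real = 1, lambda_dem = 1.106
res    = sd.project_doubling(sd.annual_rates(series))
print(res.classification)                    # "high" (doubles in year 7)
```

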