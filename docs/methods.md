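# Methods

## Life-table reconstruction

Each stock-year yields a *period* life table: all schedules are indexed
by calendar year and age, not by cohort (cohort schedules are assembled
later along diagonals). Mortality is proportional throughout — `M`, `F`
and `Z = F + M` are fractions of fish dying within the year, and
survival is `l = 1 − Z` — rather than instantaneous rates. Fishing
mortality is the simple ratio `F = C/N` of removals to assessed numbers,
with no mid-year timing adjustment; catch in the synthetic generator is
produced the same way, so the two conventions are consistent. The last
assessed age is terminal: no plus-group survives it or reproduces beyond
it.

Survivorship to the first assessed age class is fixed at 1. This
slightly overstates productivity when the first assessed age is older
than 1; `backfill_young_ages` provides the sensitivity alternative,
back-calculating abundance down to age 1 along cohorts
(`N[y−1, a−1] = N[y, a] / (1 − M[y−1, a−1])`, with the youngest
available M reused for unassessed ages, zero catch and zero maturity at
the synthetic ages, and trailing years repeating the last
back-calculated value where the source cell falls outside the span).
For stationary inputs the calibrated growth rates with and without the
backfill agree closely (tested).

Fecundity is per *spawner*, not per egg: recruits observed in year
`y+1` are attributed to the spawning age classes of year `y+1−b`
(b = recruit age) in proportion to their spawning biomass, then divided
by spawner numbers. Under this biomass-proportional attribution the
schedule reduces algebraically to `f_a = W_a × RPS_{y+1}` at mature ages,
an identity the tests assert. Two conventions were genuinely open:

* **Per-spawner vs per-capita.** The renewal equation nominally wants
  the fecundity of *individuals* of age a, which differs from
  per-spawner fecundity by the maturity fraction at partially mature
  ages. Both bases are implemented
  (`CalibrationConfig.fecundity_basis`); per-spawner is the default and
  is exactly self-consistent on the knife-edge-maturity fixtures.
* **Degenerate cells.** `Z ≥ 1` clamps survival to a floor of 1e-6 with
  a logged warning (the proportional-rate formulation admits this case);
  a mature age with zero spawners gets fecundity 0 with a warning; a
  stock-year with no spawners at all gets an all-zero schedule.

## Growth rates and calibration

The renewal equation `1 = Σ λ^(−a) s_a f_a` has a strictly decreasing
left-hand side in λ, so its positive root is unique. It is solved on the
log scale `r = ln λ` with a log-sum-exp residual (no overflow anywhere
in the bracket `λ ∈ [1e-6, 1e3]`) by safeguarded Newton to ~1e-12
relative precision; warm starts from the previous iterate keep the
calibration loop cheap. The root equals the dominant eigenvalue of the
Leslie matrix built from the same survival and fecundity, which the
tests verify to 1e-8 on 1000 random schedules.

Calibration matches `λ_y · N_y` (totals over ages) to the assessed
`N_{y+1}` within a relative tolerance (default 5%). Steps are
*multiplicative*, `×(1 ± step)` applied uniformly across ages — a
multiplicative step preserves positivity where an additive one would
not — with mortality stepped first and fecundity only if the prediction
is still outside tolerance, alternating one step each. Over-prediction
raises M and lowers fecundity; under-prediction does the reverse. The
default step is 0.5% with 0.05% available for series that need finer
control. Iteration counts are capped (1e5); hitting the cap flags the
year as non-converged rather than raising. The terminal year has no
successor to match and is reported as missing, not extrapolated.
λ_dem is solved from the *adjusted* natural mortality and fecundity with
survivorship under M only, so both rates describe the same calibrated
reconstruction; since the fecundities agree and survivorship can only
rise when F is dropped, `λ_dem ≥ λ_real` always.

Calibration pins the rates at the observed extremes: a year at
proportion p of the maximum whose successor is the maximum calibrates to
1/p (so ≤ 2 at 50%, ≤ 4 at 25%), the interior maximum-abundance year to
≤ 1, the interior minimum to ≥ 1. These identities are the package's
main acceptance checks because they hold for *any* input series.

## Cohort metrics

A cohort entering the first assessed age in year c is complete when a
reconstructed schedule exists for every age α..ω along its diagonal.
Because fecundity for year y requires the recruits observed in year
y+1, the final data year carries no schedule, so an n-year series with
k = ω − α + 1 ages yields `(n − 1) − (k − 1)` complete cohorts.
R0 and LG use the calibrated schedules (an uncalibrated variant exists
for sensitivity). The fishing-excluded variant recomputes survivorship
from M alone but keeps the observed fecundities — the age structure
behind those fecundities still carries the imprint of fishing, so F=0
does not fully remove it. No ×0.5 sex-ratio factor is applied: with a
50:50 sex ratio, recruits-per-spawner equals female-recruits-per-female
-spawner, and R0 = 1 retains its replacement reading; the stationary
fixture realizes R0 = 1 and λ_real = 1 simultaneously.

## Density dependence

log λ is modelled against the proportion of maximum observed abundance
as an intercept, a global cubic B-spline smooth (10 basis functions,
second-difference penalty), ridge-penalized per-stock intercepts, and
per-stock cubic deviation smooths (5 basis functions) whose whole
coefficient block — including its linear null space — is shrunk under a
single shared penalty, making the per-stock curves behave as random
effects. The three smoothing parameters are chosen jointly by GCV over a
log-spaced grid; pointwise 95% intervals use the Bayesian posterior
covariance `σ²(XᵀX + S)⁻¹` of the penalized fit. Gaussian errors on the
log scale are the working form of a lognormal response. The data are
known to be heteroskedastic and heavy-tailed near low abundance, so the
fit is used to extract relative patterns (anchors at each stock's
minimum proportion, at 40% of maximum, and at the maximum, plus their
pairwise differences), not for formal inference on the smooths; the
40% anchor is reported as missing for stocks that never dropped to 40%.
Acceptance is by generate-and-recover: with a known log-linear λ(prop)
the interval at prop = 0.4 covers the truth in ≥ 90% of replicates.

## Recovery projections

Each projection year of each trajectory redraws one observed year's
fecundity schedule and, independently, one observed year's M schedule
(uniformly with replacement; the data offer no basis for imposing a
correlation, and none is), solves the F = 0 renewal equation, and
advances relative abundance from 1. Redraw is per projection year, not
one fixed draw per trajectory. Doubling is absorbing, so the curve is
the earliest possible doubling time. A drawn pair with no reproduction
contributes λ = 0 (the trajectory continues at zero). Because draws come
from a finite year pool, λ is precomputed for every (fecundity-year,
M-year) pair and the simulation reduces to indexing — 1000 trajectories
× 100 years run in well under a second. Classification: high if ≥75%
doubled by year 10, else moderate if ≥50% by year 20, else low; a stock
reaching 75% only by year 20 is moderate, since "high" is defined
strictly at year 10. Initial abundance is normalized to 1 (only ratios
matter), and per-stock seeds are derived from the master seed via a
stable hash so stocks are reproducible independently.

## Synthetic stocks

The generator emulates what the analysis assumes about real assessed
stocks: cohorts decaying under proportional `M + F` with no plus group,
recruitment proportional to spawning biomass b years earlier, and
fishery removals `F × N` with age-selective F. Recruitment noise is
mean-corrected lognormal (CV 0.6 by default) times an independent
Bernoulli large-event multiplier (8× with probability 0.1/yr, the
mixture also mean-corrected) — infrequent strong year classes skew the
distribution right without making the stock trend. Defaults are a
40-year, 10-age stock with M = 0.2/yr, selectivity ramping to 0.25/yr by
age 4, a logistic maturity ogive centred at age 3, and
`recruits_per_kg_mean` set to the replacement rate of the fished stock,
so simulated stocks wander around their initial abundance the way
assessed series with ~39-year histories do. What the generator does
*not* emulate: density-dependent recruitment (the spawner-recruit
relation is linear), environmental covariates, autocorrelated regimes,
observation error in the "assessed" numbers, and time-varying M or
selectivity. Passing tests therefore demonstrate correctness of the
reconstruction-calibration machinery under the model's own assumptions,
not robustness to assessment error in real repositories.

Two exact fixtures anchor the arithmetic: a stationary stock (ages 1–3,
N = [1000, 800, 400], W = [1, 2, 4] kg, knife-edge maturity at age 2,
M = 0.2, F = [0, 0.3, 0.3]) whose every derived quantity is hand
checkable (RPS = 0.3125, fed λ_real = 1, λ_dem ≈ 1.10603, R0 = 1 fished
/ 1.3 unfished, LG = 2.5 / 2.615, first doubling in year 7), and
trajectory/geometric fixtures whose totals follow a prescribed sequence
with a stable age composition, used to exercise the calibration against
known year-to-year ratios.

## Problem sizes and numerics

The shipped analysis runs 12 stocks × 40 years; the acceptance script
uses 20 random stocks for the calibration contract and 1000 trajectories
× 100 years for projections — sizes chosen so a desk run of the whole
chain completes in seconds while keeping Monte Carlo error small (the
binomial SE of a doubled proportion at 1000 trajectories is ≤ 0.016).
CSV interchange uses a long format (one row per stock, year and age)
with an invented but documented schema, since assessment repositories
publish no single standard layout. All randomness flows from explicit
seeds; reruns are byte-identical.
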