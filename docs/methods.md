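# Methods

## Observation model

The unit of observation is a cage census on a Monday/Wednesday/Friday
cadence, giving repeating +2, +2, +3 day gaps on an integer day axis
with day 0 at eclosion. Each census records, per cage and sex, the
number of dead and censored flies since the previous census, and the
number of eggs laid by the cage's females in a 3-hour window. Deaths are
therefore interval-grouped: the package treats an event tallied at a
census as occurring at that census day (right-endpoint convention). A
midpoint convention is available via the `convention` argument of the
survival functions for sensitivity analysis; at 2–3 day granularity the
difference is small and systematic, not stochastic.

## Synthetic generator

`synth` simulates individual lifespans from a Gompertz hazard
h(t) = a·e^{bt} by inverse-CDF, T = (1/b)·log(1 − (b/a)·log U), with
b = 0 degenerating to an exponential. Defaults (per regime and sex)
share b = 0.1/day and set the baseline hazard a so the closed-form
median matches the regime- and sex-specific medians observed in this
experimental system (females 26/36/31/36 days, males 38/38/38/43 days
for HH/HL/LH/LL). Egg output is cage-level (no per-female identity):
counts on census day d are Poisson with mean (per-female rate at d) ×
(females alive at d), where the rate is piecewise-constant in age. The
adult-low regimes (HL, LL) shift every segment boundary by
`peak_delay_days` = 14, reproducing the ~two-week delay in peak laying
under adult protein restriction; days before the shifted onset have
rate zero. Censoring is a small per-census, per-fly Bernoulli event
(default 0.002, "occasional escapes"), applied only before the fly's
death day.

Default cohort sizes are 80 flies per cage (sex ratio 0.5, overridable)
at two cages per regime. This demo scale keeps simulation-heavy tests
fast while preserving the study geometry (4 regimes × 2 cages, both
sexes, hundreds of events); study-scale cohorts (~300–450 flies/cage)
are a single `n_flies` argument away and are used nowhere as a hidden
assumption. Randomness uses one master seed with independent
`SeedSequence` substreams per cage, so cages are statistically
independent and runs are byte-reproducible.

What the generator does **not** emulate: larval development and density
effects, male harassment as a mortality mechanism, overdispersed or
zero-inflated egg counts, weekend heaping or missed censuses, and
between-cage heterogeneity beyond sampling noise. Passing tests
therefore demonstrate correctness of the estimators under the stated
sampling model, not robustness to those real-data features.

A noiseless mode (`synth.noiseless_study`) emits the exact expected
censuses of the generating model — survivorship drops as fractional
death counts and eggs as rate × females alive — truncated to zero at
the first census day where survivorship falls below 1e-6. Because the
observation path is measure-preserving on these inputs, the life table
rebuilt from them reproduces the generating schedule to machine
precision, which is how λ recovery is verified at 1e-8.

## Survival estimation

`km_estimate` is the standard product-limit estimator on grouped data;
censored flies count as at risk through their census day and are
removed after it (they were alive when last seen at that census).
Greenwood's formula supplies pointwise variances. It agrees with
`lifelines` to machine precision on shared inputs (cross-checked in the
test suite; lifelines is never used in the implementation).

Percentile lifespans are first-crossing times: day(p) = min{t: S(t) ≤ p}
for p ∈ {0.9, 0.5, 0.1} (early mortality, median, maximal longevity).
Confidence intervals invert the pointwise log(−log S) bands
S^{exp(±z·σ̂)} with σ̂² = Var(S)/(S·log S)² — the Brookmeyer–Crowley
construction on the complementary log-log scale, chosen because it
respects the [0, 1] range at the extreme percentiles where a linear
interval does not. When S never reaches the level, the percentile is
returned flagged undefined, never imputed.

The log-rank test accumulates observed-minus-expected deaths with the
hypergeometric variance at each distinct event day; ties are handled by
that variance directly (at day granularity the Efron/Breslow
distinction does not arise). χ² uses a pseudo-inverse of the (k−1)
submatrix for numerical safety; df = k − 1; reported p-values are
floored at 1e-16. Pairwise comparisons are BH step-up adjusted
(statsmodels). Calibration: under a simulated null the empirical type-I
error at α = 0.05 sits in [0.03, 0.07] over 500 replicates, and the
χ² p-value agrees with a permutation null within Monte-Carlo plus
approximation error at n = 8 + 8.

## Fecundity and effect sizes

k_x counts females alive at the start of the 3-hour window on day x:
events recorded at censuses ≤ x have already left the cage, because a
death tallied at a census happened during the preceding interval. A
midpoint alternative (average of entering/leaving counts) is exposed as
a flag. Per-3-hour rates are never rescaled to daily totals — all
per-female numbers in this package are per laying window. Eggs observed
with k_x = 0 are flagged as inconsistency records rather than silently
dropped or divided.

Hedges' d uses the pooled ddof-1 variance and the small-sample
correction J = 1 − 3/(4(n_a+n_b) − 9); magnitude bands small/medium/
large/very large at |d| thresholds 0.2/0.5/0.8, with the sign carried
separately (positive = first sample larger). Zero pooled variance with
unequal means is flagged undefined.

## Life tables and Leslie matrices

Interval boundaries are eclosion plus the census days, so interval
widths are 2 or 3 days. Survivorship l_x is anchored at l_0 = 1 and
computed from cumulative female events; nL_x is the per-interval
trapezoid (l_x + l_{x+n})/2 on the proportion scale, the natural
mid-interval survivorship for grouped data. Eggs counted in the window
at day x belong to the interval starting at x, so m_x = b_x/k_x is the
rate in force during that interval; the eclosion interval has zero
observable fecundity (no laying window at day 0).

The Leslie matrix puts F_i = m_i on the top row (no birth-flow
correction — a demogR-style discounted variant would multiply by
survival factors, but the uncorrected form matches the life table's
direct construction here and is the package's convention) and
P_i = nL_{i+1}/nL_i, capped at 1, on the subdiagonal. One projection
step is one census interval despite unequal real durations; λ is
therefore per census step, not per day, and is documented as such. An
optional resampling to a uniform daily grid was considered and left out:
it changes λ's units, not the regime ranking, and invents within-
interval information the census does not contain.

Eigen analysis uses the full `numpy.linalg.eig` decomposition (matrices
are at most ~60×60); the dominant eigenvalue is chosen by modulus with
a real-part tie-break, must be real within 1e-8 (a strictly complex
dominant pair indicates a non-primitive matrix and raises), and the
damping ratio is λ/|λ₂|. The stable age distribution is the right
eigenvector normalized to sum 1; reproductive values V_x are the left
eigenvector normalized to V = 1 at the first age class. With that
normalization V_x magnitudes depend on the age-class grid, so V_x
ranges are comparable within an analysis but not across different
census grids. Correctness is checked against an independent
characteristic-polynomial root search (Faddeev–LeVerrier coefficients)
on small fixtures, plus residual checks A·w = λw and vᵀA = λvᵀ and
Perron–Frobenius positivity on primitive matrices.

Degenerate cases: a 1×1 matrix returns λ = its entry with ρ undefined;
an all-sterile matrix returns λ = 0 (extinction); an exactly zero
matrix raises.

## Changepoint segmentation

The model is piecewise-constant mean with i.i.d. noise; the objective
is Σ_segments SSE + β·(#changepoints). `exhaustive` is the O(n²)
optimal-partitioning dynamic program; `pelt` adds pruning and returns
the identical global optimum — with a minimum segment length the
pruning of a dominated candidate is delayed by min_seg_len − 1 steps,
since the domination argument requires a feasible path through the
dominating end point; `binseg` is the greedy heuristic. The default
penalty is SIC-style β = 2·σ̂²·log(n): each changepoint introduces two
free parameters (a new segment mean and the break location), hence the
factor 2 — with log(n)·σ̂² alone the search systematically
over-segments planted series. σ̂² is the Rice difference-based
estimator Σ(Δy)²/(2(n−1)), largely insensitive to the mean structure
being sought (each true shift inflates it slightly, which errs on the
conservative side). min_seg_len defaults to 2 censuses. Segmentation is
done on raw cage-level counts by default; per-female series can be
segmented by passing them explicitly.

## Pipeline and numerics

`run_all` executes simulate → survival → fecundity → demography →
changepoint, writes each table as CSV (UTF-8, header row, days as
integers, missing as empty), and records a manifest with a config hash,
the seed, and per-table SHA-256 digests; reruns with the same config
and seed are byte-identical. Rounding happens only at the report layer
(λ and V_x to 3 decimals, percents to 1). A stage failure removes
partial outputs and raises with the stage named.

Problem sizes used in the test and acceptance suites — 40–80 flies per
cage, 500 null replicates for the type-I error, 200 series for the
PELT/exhaustive and recovery checks — were chosen as the package's own
defaults for fast, reproducible verification at demo scale; every size
is a parameter, and nothing in the implementation depends on them.

## Known limitations

- Interval-grouped survival is treated by event-day convention rather
  than interval-censored likelihoods; at 2–3 day granularity the
  percentile bias is bounded by the interval width.
- Egg sampling is Poisson; real egg counts are often overdispersed, so
  per-female standard errors on real data will be anti-conservative.
- λ per census step is not directly comparable to published per-
  generation or per-day growth rates without unit conversion.
- The V_x normalization (first age class = 1) differs from conventions
  that report unnormalized reproductive values; ranges scale
  accordingly.
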