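# flydemog

Demographic analysis of cage-census lifespan and fecundity data from
diet-manipulated *Drosophila* cohorts, built around a 2×2 larval×adult
protein factorial (regimes HH, HL, LH, LL: first letter larval, second
adult protein level).

In this kind of experiment, adult flies live in large cages and are
observed three times a week (Monday/Wednesday/Friday): dead and censored
flies are counted by sex at each census, and eggs laid in a 3-hour
window are counted per cage. The data are therefore grouped on a mixed
2/3-day interval grid, and everything in this package works directly on
that census format:

- **Survival** — Kaplan–Meier product-limit curves
  S(t) = ∏_{t_i ≤ t} (1 − d_i/n_i) with Greenwood variance, percentile
  lifespans at 90/50/10% survival with log(−log S)-inverted confidence
  intervals, and k-sample log-rank tests with Benjamini–Hochberg
  correction for pairwise comparisons.
- **Fecundity** — age-specific per-female fecundity m_x = b_x/k_x (eggs
  in the window over females alive at the window), lifetime totals, and
  Hedges' d effect sizes with the usual 0.2/0.5/0.8 interpretation
  bands.
- **Fitness** — census-interval life tables with mid-interval
  survivorship nL_x = (l_x + l_{x+n})/2, Leslie projection matrices
  (fecundities on the top row, survival ratios nL_{x+n}/nL_x on the
  subdiagonal), and their eigen analysis: asymptotic growth rate λ
  (dominant eigenvalue), stable age distribution w, reproductive values
  V_x (left eigenvector, V at the first age class = 1), and damping
  ratio ρ = λ/|λ₂|.
- **Changepoints** — penalized least-squares mean-shift segmentation of
  egg-laying series (PELT and an exhaustive dynamic program, both
  globally optimal, plus greedy binary segmentation) to find sustained
  high/low laying periods.
- **Synthetic generator** — individual-level Gompertz mortality
  (regime- and sex-specific hazards), piecewise-constant per-female
  laying rates with an optional onset delay (adult low protein delays
  peak laying by ~two weeks), census binning, Poisson egg counts, and
  occasional censoring, so the whole pipeline is testable against known
  ground truth. A noiseless mode emits the exact expected censuses for
  machine-precision recovery checks.

## Worked example

```python
import flydemog as fd

cfg = fd.RunConfig(outdir="demo_out", seed=42, n_flies=80)
results = fd.run_all(cfg)
print(results["demography"].to_string(index=False))
```

```
group  lambda   rho  max_vx  min_vx  range_vx
   HH   1.902 1.519   6.886     1.0     5.886
   HL   1.321 1.073  15.718     1.0    14.718
   LH   2.153 1.494  10.342     1.0     9.342
   LL   1.316 1.081  17.006     1.0    16.006
```

λ is the per-census-step growth rate of each regime's Leslie matrix:
here the early-laying regimes (HH, LH) grow fastest per step, while the
delayed-laying adult-low regimes (HL, LL) spread reproduction into late
life — visible as larger V_x ranges (late-age classes retain high
expected future output relative to newborns) and damping ratios near 1
(slow convergence to the stable age distribution). The survival summary
from the same run gives percentile lifespans per regime:

```
group  level  day  ci_low  ci_high
   HH    0.9 16.0    11.0     20.0
   HH    0.5 32.0    30.0     34.0
   HH    0.1 48.0    46.0     51.0
```

i.e. the HH cohort fell to 90% survival by day 16, to half by day 32,
and to 10% by day 48. The same pipeline is available from the shell:

```
flydemog run-all --seed 42 --out demo_out
flydemog report --out demo_out
```

or stage by stage (`simulate`, `survival`, `fecundity`, `demography`,
`changepoint`) on existing `deaths.csv`/`eggs.csv` files.

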