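# occuadjust

Descriptive inference about a landscape from data collected wherever
people happened to look.

Biodiversity monitoring usually estimates a population quantity — here the
proportion of 1-km grid squares a plant species occupies, and its change
between two recording periods — from observations at a *nonprobability*
sample of squares: opportunistic, volunteer-collected records whose
inclusion probabilities are unknown. When recorders preferentially visit
(or avoid) the kinds of places the species lives, the sample mean is
biased no matter how large the sample is. `occuadjust` implements the
standard survey-statistics toolkit for this problem, for ecologists and
quantitative researchers who need to know both how much adjustment can
help and when its uncertainty statements stop being trustworthy.

## What's inside

Every estimator targets the finite-population mean
ȳ_N = (1/N)Σy_i = Σw_i y_i / Σw_i and most are Hájek ratio means
Σ_{i∈s} w_i y_i / Σ_{i∈s} w_i over the sampled squares s with method-specific
weights:

| method | weights / idea |
|---|---|
| naive | constant w — the unadjusted sample mean |
| design-based | w = 1/p with *known* inclusion probabilities (benchmark; synthetic frames only) |
| quasirandomization | w = 1/p̂ from a binary model of inclusion on covariates fitted over the whole frame |
| poststratification | w = N_j/n_j in cells of elevation deciles × protected-area {0, >0} (20 cells) |
| superpopulation model | linear model of y on the auxiliaries predicts nonsampled squares; exact implied-weight form |
| doubly robust | (1/N)Σ_s r_i/p̂_i + (1/N)Σ_N ŷ_i — unbiased if either component model is right |
| subsampling | stratified with-replacement miniature of the population (size N/10), plain mean |
| MRP | hierarchical binomial model of cell occupancy, poststratified by population cell shares |

Plus diagnostics built on the **data defect correlation**
ddc = corr(R, y) over all N squares, including the exact error identity
ȳ_n − ȳ_N = ddc·√((N−n)/n)·σ_y, the partial ddc given the auxiliaries,
and 50-bin auxiliary-distribution comparisons scored by MAE; percentile
bootstrap / survey-linearization / posterior 95% intervals; and the
between-period trend with percentile or normal intervals. A synthetic
landscape generator with known ground truth (and a switchable violation of
the missing-at-random assumption) makes every claim testable. See
`docs/methods.md` for the full model descriptions and design choices.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
two-period landscape (N = 10,000 squares, ~44% sampled in period one, 63%
in period two, recorder effort declining with elevation while occupancy
rises with it):

```bash
python analysis/01_simulate_landscape.py
python analysis/02_estimate_means_and_trend.py
python analysis/03_representativeness_diagnostics.py
python analysis/04_validation_studies.py
```

`01` prints the ground truth:

```
simulated landscape: N = 10000 units, seed = 20240101
  period 1: sampled n = 4428 (44.3%), true mean occupancy = 0.3123
  period 2: sampled n = 6325 (63.2%), true mean occupancy = 0.2754
  true trend (period 2 - period 1) = -0.0369
```

`02` estimates the means and trend with all seven methods (abridged):

```
            method  period  point     lo     hi      interval_method
             naive       1 0.2446 0.2319 0.2572               normal
quasirandomization       1 0.2980 0.2722 0.3008 percentile-bootstrap
poststratification       1 0.3008 0.2838 0.3178               normal
   superpopulation       1 0.3010 0.2882 0.3141 percentile-bootstrap
     doubly_robust       1 0.3035 0.2881 0.3150 percentile-bootstrap
       subsampling       1 0.3120 0.2730 0.3310 percentile-bootstrap
               mrp       1 0.2979 0.2850 0.3105   posterior-credible

            method   trend      lo      hi interval_method
             naive  0.0084 -0.0082  0.0250          normal
quasirandomization -0.0251 -0.0357 -0.0003      percentile
     doubly_robust -0.0309 -0.0453 -0.0117      percentile
             truth -0.0369     NaN     NaN            none
```

Read it like this: the sample under-represents the high-elevation squares
the plant prefers, so the naive mean (0.245) sits far below the truth
(0.312) — and the naive trend even has the wrong *sign* (+0.008 against a
true decline of −0.037). Every adjustment pulls the period means close to
the truth and recovers a negative trend, though attenuated; several 95%
intervals still miss the true values, which is the package's central
caution about uncertainty statements from adjusted nonprobability samples.

`03` quantifies representativeness (period one: ddc = −0.130, partial ddc
given the auxiliaries = −0.014; weighting cuts the elevation-distribution
MAE roughly five-fold), and `04` runs the replicated validation studies:
bias ordering (all six adjustments beat naive by an order of magnitude
under MAR), unbiasedness/double-robustness checks against 3-Monte-Carlo-SE
bands, and interval coverage, which collapses to ~0% once occupancy feeds
inclusion directly.

A `occuadjust` CLI wraps the same pipeline
(`occuadjust simulate|run|diagnose --help`), reading frames from CSV so
real population tables can be analyzed the same way.

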