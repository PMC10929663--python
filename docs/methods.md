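# Methods

## The inferential problem

The target is descriptive: the mean of a binary variable — occupancy of a
plant species — over a finite population of N areal units (1-km grid
squares), in each of two time periods, and the difference between the two
(the trend). The data are a nonprobability sample: a subset of units was
visited by volunteer recorders, with unknown and uncontrolled inclusion
probabilities. Writing y_i ∈ {0,1} for occupancy and R_i ∈ {0,1} for
sample inclusion, the population mean is

    ȳ_N = (1/N) Σ_i y_i = Σ_i w_i y_i / Σ_i w_i   with   w_i = 1/N,

and every estimator in the package is a recipe for weights in the Hájek
ratio form over the sampled units s,

    ȳ_w = Σ_{i∈s} w_i y_i / Σ_{i∈s} w_i.

Two auxiliary variables are available for **every** unit: mean elevation
and the proportion of the unit under protected-area designation. They are
plausibly common causes of both occupancy and recorder effort, which is
what makes adjustment possible at all.

## Estimators

* **Naive** — w constant; the unadjusted sample mean.
* **Design-based** — w_i = 1/p_i with known inclusion probabilities;
  available only for synthetic frames (where p_i is known by construction)
  and used as the unbiasedness benchmark.
* **Quasirandomization** — pretend the sample was drawn probabilistically:
  fit a binary model of R on covariates over the whole frame (inclusion is
  observed for every unit, so this is prediction, not inference), set
  w_i = 1/p̂_i. The default model is essentially-unpenalized logistic
  regression on the two auxiliaries; a random-forest classifier is a
  pluggable alternative. Probabilities are clipped to [1e-6, 1] before
  inversion.
* **Poststratification** — cut elevation at its population deciles
  (left-open/right-closed, ties collapsed), dichotomize protection at 0 vs
  >0, cross them (default 10 × 2 = 20 cells) and set w_i = N_j/n_j in cell
  j. Weights calibrate exactly: Σ_{i∈s∩j} w_i = N_j, hence Σ w = N.
  A populated cell with no sampled units is collapsed into the nearest
  elevation bin of the same protected class (standard survey practice;
  logged when it happens).
* **Superpopulation model** — ordinary least squares of y on the
  auxiliaries over the sampled units; predictions fill in the nonsampled
  units: ȳ_sp = (Σ_{i∈s} y_i + Σ_{i∉s} ŷ_i)/N. A *linear* model is used on
  the binary outcome deliberately: it admits the exact implied-weight
  representation w_i = 1 + t'_{x,s̄}(X'_s X_s)^{-1} x_i (t_{x,s̄} the
  auxiliary total over nonsampled units), which reproduces ȳ_sp in Hájek
  form to machine precision and satisfies Σ w = N. Those weights may be
  negative, and predictions are not clipped to [0,1] — clipping would
  break the identity. Estimates are reported as-is.
* **Doubly robust** — ȳ_dr = (1/N) Σ_{i∈s} r_i/p̂_i + (1/N) Σ_{i=1}^N ŷ_i,
  with r_i the outcome-model residuals and p̂ the quasirandomization
  propensities. Unbiased if either component model is correct. The second
  sum runs over all N fitted values (not the sample/nonsample mix of the
  prediction-form superpopulation estimator); the two agree when the
  residual term is added, and the package implements the formula as
  written here.
* **Stratified subsampling** — a representative "miniature": from each
  poststratum, draw round(size · N_j/N) sampled units with replacement
  (largest-remainder rounding, so draws total exactly `size`; default
  N/10), and take the plain subsample mean. Its expectation over draws
  equals the poststratified estimate.
* **MRP** — multilevel regression and poststratification. A hierarchical
  binomial model with logit link estimates occupancy in every cell of the
  same 20-cell crossing:

      k_j ~ Binomial(n_j, θ_j),  logit θ_j = μ + a_{e(j)} + b_{p(j)} + c_j,
      a_e ~ N(0, σ_a), b_p ~ N(0, σ_b), c_j ~ N(0, σ_c),

  with μ ~ N(0, 2.5), σ ~ half-N(1). Partial pooling lets sparse or empty
  cells borrow strength, which plain poststratification cannot do. The
  estimate per posterior draw is Σ_j (N_j/N) θ_j.

## Representativeness diagnostics

The data defect correlation (ddc) is the finite-population Pearson
correlation corr(R, y) over all N units (1/N moment convention). It drives
an exact decomposition of the naive estimator's error,

    ȳ_n − ȳ_N = ddc · √((N−n)/n) · σ_y,

which holds to floating-point precision on every frame and is the primary
correctness oracle for the ddc code. Under simple random sampling the ddc
is of order N^{−1/2}; an appreciable ddc means the sample is
unrepresentative regardless of its size. The partial ddc is the
correlation of the residuals after linearly projecting the auxiliaries out
of both R and y; it is near zero exactly when the missing-at-random
(MAR)-given-auxiliaries assumption (approximately, linearly) holds.

Whether an adjustment "worked" on the auxiliaries is scored by splitting
each auxiliary into 50 equal-width bins spanning its population range (top
bin right-closed so the maximum is counted) and comparing relative
frequencies: N_k/N for the population, n_k/n for the raw sample, and
Σ_{i∈k} w_i / Σ_{i∈s} w_i for the weighted sample — the only reading of
the weighted form that yields a proper distribution. The summary is the
mean absolute error (MAE) across bins; a smaller weighted MAE means the
adjustment moved the sample's auxiliary distribution toward the
population's. For subsampling, which has no unit weights, the subsample's
own distribution plays the adjusted role. No auxiliary-distribution
diagnostics are produced for the doubly robust estimator or MRP: the
doubly robust "model-assisted" unit weights are known to go badly negative
with a linear outcome model on binary data, and no unit-weight formula
exists for a binomial-GLM MRP.

## Uncertainty and trend

* Percentile bootstrap (default B = 1000) for quasirandomization,
  superpopulation, doubly robust and subsampling: resample the n sampled
  units with replacement, refit everything, take the 2.5/97.5 percentiles.
  Resamples are represented as per-unit multiplicity vectors so the
  population frame is never copied; model fits use the multiplicities as
  frequency weights. Replicates in which an estimator fails are dropped
  and counted; more than 5% failures aborts.
* Analytic intervals for naive and poststratification: ±z·SE with the
  standard with-replacement linearization variance of the Hájek ratio
  mean, which reduces to SE = √(p̂(1−p̂)/(n−1)) for equal weights. No
  finite-population correction is applied.
* MRP: central 95% posterior credible interval.
* Trend = ȳ_2 − ȳ_1. Methods with replicate distributions get percentile
  intervals of the differences of independently resampled replicates (the
  two periods' samples are distinct, so nothing is paired); naive and
  poststratification get ±1.96·√(var_1 + var_2).

## The synthetic landscape

Real frames load from CSV; the generator provides populations with known
truth. Per unit: elevation ~ Gamma(shape 2, scale 120 m) — right-skewed
like a national elevation raster; protected proportion zero-inflated
(P(=0) = 0.5, else Uniform(0,1)) — most squares have no protected land;
occupancy and inclusion are independent Bernoulli draws per period with
logits linear in the z-scored auxiliaries; a `gamma_y` term adds a direct
effect of occupancy on inclusion log-odds, the switch that breaks MAR
(`gamma_y = 0` gives y ⟂ R | auxiliaries by construction). Inclusion is
Poisson/Bernoulli sampling — no fixed n, as with real recording effort —
with bounded retries (100) against degenerate all/none-sampled draws.

The defaults are the emulated study conditions: N = 10,000 units;
occupancy rising with elevation and protection (intercepts −0.90 and −1.18
in periods 1 and 2, slopes +1.10 and +0.45 on the z-scores), recorder
effort falling with elevation (inclusion slopes −0.85/−0.40 per period,
+0.30 on protection; intercepts −0.30/+0.55). These reproduce: sampling
fractions ≈ 44% and 63%, ddc ≈ −0.12 and −0.06 (the sample
under-represents the high-elevation squares the plant prefers, so naive
means are biased *down*), mean occupancy ≈ 0.31 and 0.28, and a true
decline of ≈ 0.05. The two periods are generated independently — the
generator does not model shared recorder behaviour across periods, nor
spatial autocorrelation, landscape pattern, or detection error (a sampled
occupied square is always recorded). Passing tests therefore demonstrate
estimator correctness under the assumed sampling structure, not robustness
to spatial structure or imperfect detection in real atlas data.

## Numerical and design choices

* Auxiliaries are z-scored inside the generator links so coefficients are
  comparable across configurations; estimators consume the raw columns.
* Decile cuts use the population (not sample) distribution.
* OLS/WLS by `numpy.linalg.lstsq`; rank-deficient designs are rejected
  with the collinear columns named (QR pivot test at 1e-8).
* Propensity clipping at 1e-6; a clip count is logged.
* Largest-remainder rounding makes subsample allocations total exactly.
* MCMC backend is an affine-invariant ensemble sampler with
  differential-evolution moves (80% DE / 20% snooker), 2·ndim+2 walkers,
  5 independent ensembles as chains, 2000 iterations each with the first
  half discarded. The ensemble sampler needs more iterations than a
  gradient-based sampler; 2000 typically brings the split-R̂ of the
  reported quantities to ≈1.05 at the default 20-cell crossing (raise
  `iterations` when the flag reports marginal convergence). Because the likelihood constrains only each cell's
  total linear predictor (the μ + a + b + c decomposition is identified
  only through the priors), convergence is diagnosed on the reported
  quantities — cell probabilities and the population estimate — not the
  raw parameters. Non-convergence flags the result; it is never hidden.
* End-to-end determinism: every random step is seeded, and a rerun with
  the same configuration and seed is byte-identical.

## Validation studies and their sizes

The replicated studies (module `occuadjust.studies`) use scaled-down
problem sizes chosen so the full suite runs comfortably on one CPU while
keeping Monte-Carlo error far below the effects being measured:

* bias ordering: one N = 4,000 landscape, 200 replicate inclusion draws
  (20 for MRP, which costs ~1 s per fit against ~10 ms for the rest);
* unbiasedness/double robustness: N = 5,000, 500 replicate draws, with a
  3-Monte-Carlo-SE acceptance band and a both-models-wrong negative
  control;
* coverage: 200 independently simulated worlds at N = 2,000, bootstrap
  B = 200, under a strong MAR violation (gamma_y = −1.5).

Under MAR with informative auxiliaries, every adjusted estimator's |bias|
is an order of magnitude below the naive estimator's; under the MAR
violation, nominal 95% intervals essentially never cover the truth —
residual bias dominates the shrinking sampling variance. That asymmetry is
the package's central caution: adjustment reduces bias when the right
auxiliaries are in hand, but nominal uncertainty intervals from an
adjusted nonprobability sample should not be read as calibrated.

## Known limitations

* The superpopulation and doubly robust point estimates can stray slightly
  outside [0,1] on extreme frames (unclipped linear predictions).
* The forest propensity model is not probability-calibrated; its clipped
  probabilities can make 1/p̂ weights volatile.
* The partial ddc uses linear projection; strongly nonlinear
  auxiliary-inclusion relationships leave a nonzero partial ddc even under
  exact conditional independence.
* MRP unit-level weights are not derivable for the binomial GLM, so MRP is
  excluded from the auxiliary-distribution diagnostics.
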