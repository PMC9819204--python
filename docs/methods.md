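# Methods

## Model

For subject *j* with quantile-scored taxa `q_ij` and covariates `Z_j`, the
mixture index is `WQS_j = Σ_i w_i q_ij` with weights on the simplex
(`w_i ≥ 0`, `Σ w_i = 1`), entering a GLM

    g(μ_j) = α + β₁ · WQS_j + δ′ Z_j

with a binomial (logit) or gaussian (identity) family. Weight estimation
may constrain `sign(β₁)`; the validation-set GLM never does.

### Zero-anchored ranking

Microbiome tables are zero-inflated (35–88% zeros per taxon in the data
this package emulates), so ordinary quantiles tie massively at 0. We
anchor exact zeros at score 0 and quantile-split only the positive
values: with `levels=4`, tertile cut points at the 1/3 and 2/3 empirical
quantiles (linear interpolation) of the positives; values tied with a cut
point fall to the lower group. The 3-level `median` split scores
positives 1 below their median and 2 at-or-above it (the ≥ convention is
deliberate and tested). Ranking is computed once on the full dataset
before any train/validation split; `WQSConfig(rank_within_training=True)`
switches to cut points estimated on each training partition, off by
default. Whether quantile ties should break upward instead is a dialect
choice; ours is downward, deterministic, and documented here.

### Subset fits are concave programs

Each random subset of *m* taxa requires maximizing the GLM likelihood
over `(α, β₁, δ, w)` with `w` on the simplex and `sign(β₁)` possibly
fixed. We solve this exactly in the product parameterization
`v_i = β₁ · w_i`: the constrained set `{β₁·w : w ∈ simplex, β₁ ≥ 0}` *is*
the nonnegative orthant `{v ≥ 0}` (and `v ≤ 0` for the negative
direction), so the problem becomes a sign-constrained GLM — concave, with
a unique optimum and no restarts needed. L-BFGS-B with an analytic
gradient (max 500 iterations, ftol 1e-10, gtol 1e-8) solves it in ~2 ms;
back on the original scale `β₁ = Σv`, `w = v/Σv`. An
unconstrained-direction fit solves both orthants and keeps the better
likelihood. If the optimum is `v = 0` the index drops out of the model:
we report `β₁ = 0`, `t = 0`, equal weights (the fit then contributes
nothing to the signal average). The `restarts` argument survives for
line-search robustness but defaults to 1 — extra starts cannot find a
different optimum in a concave problem.

The per-subset Wald `t = β₁/SE(β₁)` comes from the observed information
of the GLM in `(α, β₁, δ)` evaluated at the optimum with the weights held
at their estimate (profile information). The gaussian family uses the
REML-style `RSS/(n−q)` variance.

### Signal-weighted averaging

Subset fits are combined per taxon by averaging each taxon's weight over
the converged subsets containing it, weighting subsets by a signal
function of their t statistic — `t²` (default), `exp(min(|t|,30))`
(clipped to avoid overflow), or `|t|` — and renormalizing the full
p-vector to sum 1. Averaging only over containing subsets (rather than
imputing zeros for absent taxa) keeps the final weights a convex
combination of estimated ones; taxa appearing in no converged subset get
weight 0 with a warning. Non-converged subsets are dropped and counted,
never re-drawn, so B stays interpretable and runs deterministic.

### Direction resolution and repeated holdouts

With `direction="auto"` an unconstrained pass is run first and the
majority sign of β₁ across converged subsets fixes the constraint — once
per ensemble, before the repetitions, mirroring the
scan-then-confirm-with-constraints workflow; an exact tie defaults to
negative with a warning. Each of the R repetitions (default 30) draws an
independent stratified partition: samples are grouped by the joint levels
of the outcome and declared categorical covariates, and each stratum is
split by largest-remainder allocation so both partitions contain every
level and `|train| = round(0.40·n)`. Sub-seeds derive from the master
seed by a counter scheme (`SeedSequence([master, repetition])`), so
ensembles are bit-reproducible and repetitions independent.

Across holdouts we report mean weights (renormalized), the mean and
2.5–97.5 percentile interval of validation β₁ (the package's realization
of "error bars that do not cross 0"), sign fractions, and per-holdout
odds ratios for the binomial family. Genus pooling sums taxon weights
within genus per holdout (conserving the total of 1), labels unclassified
genera "unclassified (<phylum>)" so they pool within phylum, and flags
genera whose mean pooled weight exceeds 1/c for c genera.

### Validation GLM details

The validation fit is an ordinary statsmodels GLM of the outcome on
`[1, WQS, Z]` with Wald 95% CIs and, for binomial, `OR = exp(β₁)`.
Complete separation (non-finite SEs or |coef| > 10³) triggers a
ridge-penalized IRLS fallback (λ = 1e-4, sandwich-style SEs) with a
recorded warning. Rank-deficient designs raise an error naming the
columns rather than fitting silently.

## Synthetic data generator

`synthesize_abundance_table` emulates the structure of a first-visit
adult stool 16S working set: defaults n=210 samples, p=868 taxa,
per-taxon zero probabilities uniform on [0.35, 0.88], positive cells
lognormal with a per-taxon location spread (σ=1.5 within taxon, SD 1
across taxa) so a few taxa dominate, rows closed to relative abundances,
a generated taxonomy over 48 genera in 5 phyla, and a balanced two-level
`sex` column. All-zero rows (possible at small p) are redrawn row-wise.
It does **not** emulate inter-taxon correlation, phylogenetic structure,
or sequencing depth variation — so recovery results on synthetic data
speak to zero-inflation and dominance structure, not to compositional
correlation effects in real tables.

The simulated binary test variable follows
`logit = β₀ + Σ_signal β_s · potency(x) + covariate effects` with
strengths β = 8/4/2 for 2 strong / 8 medium / 10 weak signal taxa,
β₀ = −5, and a −1 effect for females (males the reference). The potency
adjustment `log2(log10(x+1)/log10(max+1))` is evaluated on the *percent*
scale (the formula is not scale-invariant; percent matches how relative
abundances are conventionally reported) with `max` the taxon's own
maximum. It is 0 at `x = max` and negative below, hence two conventions
for absent taxa: `zero_contribution` (default — an absent taxon adds 0 to
the logit; the literal value is −∞) and `as_formula` (literal, clipped at
−50 with a warning). Because all potency terms are ≤ 0, a fixed β₀ = −5
drives the prevalence to ~0; `calibrate_prevalence` bisects β₀ until the
mean fitted probability hits the target within 0.005 (the calibrated
value is stored on the design). The control variable is i.i.d.
Bernoulli, independent of the table.

A consequence worth understanding when interpreting recovery results:
under this model the per-taxon dose–response is V-shaped — absence
(score 0) carries the highest outcome probability, low positive scores
the lowest, near-maximum abundance intermediate — so a monotone index can
exploit only part of the planted signal. On 210 × 868 tables with 20
signal taxa the ensemble separates signal from noise weights (~2.5× mean
ratio) and holds specificity near 0.8 at the equi-weight cutoff, while
per-holdout sensitivity sits near 0.45; for comparison, top-20 univariate
correlation screening recovers ~3/20 and a cross-validated lasso selects
nothing on the same data. Sensitivity/specificity are computed with
strict inequalities (weights tied exactly at the cutoff count as neither
identified nor excluded), per holdout and averaged by default;
`mode="mean-weights"` evaluates the ensemble mean weight vector instead.

## Comparators

Shannon diversity uses the natural log. Bray–Curtis is `Σ|a−b|/Σ(a+b)`;
Aitchison is the Euclidean distance between clr transforms of
pseudocounted, re-closed compositions. PERMANOVA partitions the
Gower-centered squared-distance matrix sequentially (Type-I, the adonis2
convention) with free label permutations and
`p = (1 + #{F* ≥ F}) / (1 + n_perm)`; residual SS within 1e-12 of zero is
floored so degenerate geometries yield an extreme finite F rather than a
sign flip. Our implementation reproduces vegan's adonis2 SS/R²/F on a
fixture to printed precision (frozen in the test suite). SIMPER averages
each taxon's share `|a_k−b_k| / Σ_t(a_t+b_t)` over all between-group
pairs; contributions sum exactly to the mean between-group dissimilarity
(the documented contract), taxa are ranked descending, and the identified
set is the shortest prefix reaching 70% cumulative share; per-taxon
permutation p-values shuffle group labels. The random forest is
deliberately delegated to scikit-learn (100 trees); this package owns
only the normalization of importances to sum 1, the 1/(number of
predictors) cutoff, and reporting.

## Problem sizes and tolerances

Simplex membership is asserted to 1e-8 everywhere; optimizer optima match
an exhaustive 0.01-step simplex grid oracle (GLM profiled at each grid
weight) within 1e-4 log-likelihood for m ≤ 3. The test suite runs the
full-scale recovery study at 200 subsets per training set over 5 seeds,
null calibration of PERMANOVA over 200 runs at n=24 with 99 permutations,
and negative-control coverage over 20 ensembles of 30 holdouts at
150 × 20; the acceptance script runs one full 210 × 868 study (200
subsets, 30 holdouts, 999-permutation PERMANOVA). These sizes keep a
complete run in a few minutes while leaving every estimator at its
study-scale configuration where it matters (n, p, ranking, train
fraction, holdout count).

## Known limitations

* Subset weight estimation assumes the GLM likelihood; no
  quasi-likelihood or overdispersion handling.
* No bootstrap-based classic WQS, stratified/Bayesian variants, index
  interactions, or phylogenetic (UniFrac-type) distances.
* BIOM support covers the JSON dialect only (no HDF5).
* The generator's independence across taxa means synthetic specificity
  is, if anything, optimistic relative to correlated real communities.
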