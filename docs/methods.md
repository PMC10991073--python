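# Methods

This note documents the statistical procedures implemented in `mipcr`, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic-data experiments do and do not establish.

## Chained equations

Missing values are treated by fully conditional specification: each
incomplete variable `x_j` gets a univariate conditional model
`f(x_j | X_−j, θ_j)`, and the sampler cycles through the incomplete columns,
always conditioning on the most recently imputed values of all other
variables. Design choices:

- **Visit order** is fixed left-to-right over the incomplete columns. Any
  fixed order yields a valid Gibbs-like sampler; a fixed one makes runs
  reproducible.
- **m imputations = m independent chains**, each run for `maxit` iterations
  from its own random starting fill (a uniform draw from the observed values
  of each column). Independent chains avoid autocorrelation between
  imputations at the cost of burning in each chain separately.
- **Defaults m = 5, maxit = 20.** Five imputations are the conventional
  default for moderate missingness; twenty iterations comfortably passes the
  trace-stationarity check below for these data.
- **Convergence** is assessed from the per-(chain, variable, iteration)
  means and SDs of the imputed values (`ImputationResult.traces`). The test
  suite fits a regression to the trace means over iterations 10–20 and
  requires a non-significant slope (α = 0.01) in at least 95% of
  trajectories.

### Samplers

*Bayesian normal linear model.* With observed rows `(y, X)` (intercept
included, q columns), draw `σ²* = SSR/χ²_{n−q}` (df floored at 1), then
`β* ~ N(β̂, σ²*(XᵀX + κI)⁻¹)`, then impute `X_mis β* + N(0, σ²*)`. The ridge
constant κ (default 1e−5) stabilizes nearly collinear designs; κ = 0
recovers the exact posterior draw under the Jeffreys prior and is verified
against a brute-force transcription of the formulas in the tests. Ordinal
(coarsened) predictors enter as their integer level codes.

*Predictive mean matching* (used in the generic CSV mode, default donor pool
5): type-1 matching — observed rows predicted with β̂, missing rows with the
Bayesian draw β* — then each missing row receives the observed value of a
donor drawn uniformly from the 5 closest predictions. PMM guarantees
imputations stay in the observed support, which matters for skewed or
bounded items; it is not used in the simulation studies, whose targets are
conditionally normal by construction.

## PCA and the three PCR strategies

PCA is always computed on the Pearson correlation scale (columns z-scored
with sample moments, ddof = 1), including for coarsened ordinal items, which
are treated as numeric. Polychoric alternatives were deliberately not
implemented: they are far costlier and do not improve the *predictive* use
of the components, which is all imputation needs. Component signs are fixed
by making the largest-magnitude weight of each component positive, so
results do not depend on the eigensolver backend.

- **AUX**: the auxiliary basis is fitted once, before MICE, on the
  (completed, if necessary) auxiliary block, and never refitted — the
  auxiliary scores are constants of the run. Feasibility cap: `npc` is
  reduced (with a logged warning) so that raw analysis predictors +
  intercept + scores stay below the smallest observed-row count.
- **ALL**: requires a preliminary single imputation (one chain, maxit 20,
  quickpred predictor selection at r = 0.3, falling back to intercept-only
  models when nothing passes). The single imputation is used only to enable
  PC extraction, never for inference. Because the scores are complete, each
  imputation needs a single sweep; the m imputations share one pretreat fill
  by default (`share_pretreat=False` gives each imputation its own).
- **VBV**: the basis is refitted on `X_−j` of the *current* completed matrix
  at every (chain, iteration, target), standardization constants included,
  since imputations move the column moments. This is the most faithful way
  to keep the reduced predictor space aligned with the chain state, at
  `t × maxit × m` PCA fits per run.

`npc = "max"` resolves per strategy: all auxiliary columns (AUX), all p
columns (ALL), p − 1 (VBV), always additionally capped at n − 1.

## Synthetic data generator

The generator emulates multi-scale questionnaire data: `X = FΛ′ + E` with 7
latent factors, simple structure, loadings λ = 0.85, uniquenesses 1 − λ²,
latent correlations ψ ∈ {0.7, 0.1}. The noise proportion `pn` sets how many
of the six auxiliary factors are "noise" (ψ = 0.1 with the first factor
*and* with each other — the simplest positive-definite completion, since
only the correlation with the measured factor is substantively pinned down).
Study 1 uses 8 items per factor (p = 56); study 2 widens the auxiliary
factors to 39 items each (p = 242). Columns are rescaled to mean 5 /
variance 6.5 using sample moments (so sample moments are exact, population
moments approximate), mimicking 10-point Likert items.

Coarsening (`nCat ∈ {∞, 7, 5, 3, 2}`) applies equal-probability
(sample-quantile) cuts with labels 1..nCat to the M and A columns; the four
analysis items stay continuous. Equal-probability cuts keep category
frequencies balanced across conditions, the common convention for simulated
Likert items.

**Amputation** imposes right-tail MAR on each analysis item independently:
`logit Pr(δ=1) = β₀ + Mβ` with all slopes 1 on the *continuous* M items
(even when the observable M columns are coarsened, so the mechanism's
strength is constant across `nCat`), and β₀ root-found (Brent, expanding
bracket around −mean(Mβ), tolerance 1e−6 on the achieved proportion) to hit
the target proportion 0.3. Because all four indicators share the linear
predictor Mβ, missingness is positively correlated across the analysis
items; roughly 64% of rows remain complete, not the 24% an independence
approximation would give.

**What the generator does not emulate:** item-level non-normality beyond
coarsening, cross-loadings, correlated uniquenesses, MNAR mechanisms, and
unit non-response. A green simulation result therefore establishes recovery
under a well-specified factor world with logistic MAR — not robustness to
structural misspecification.

A consequence worth knowing: in the `nCat = 2` conditions, the observable M
columns are median splits of the true (continuous) missingness predictors,
so *no* method — including the oracle — can condition away all of the
mechanism; every method carries residual bias of roughly PRB 9–10 for the
item correlation there. This is a property of the stated world, not of any
particular imputation strategy.

## Pooling and outcome measures

Per completed data set, the analysis estimates the 4 means, 4 variances, 6
covariances and 6 correlations of the analysis items, each with a
normal-theory SE on its pooling scale: means on the identity scale
(`s/√n`), variances on the log scale (`√(2/(n−1))`), covariances untransformed
(delta-method SE `√((s_x²s_y² + s_xy²)/(n−1))`), correlations on the Fisher-z
scale (`1/√(n−3)`). Transform choices keep the back-transformed intervals
inside the parameter space and make the normality assumption behind Rubin's
rules tenable for bounded estimands.

Rubin's rules are applied on the transform scale: `q̄ = mean`,
`Ū = mean(se²)`, `B = sample variance`, `T = Ū + (1 + 1/m)B`, with
Barnard–Rubin degrees of freedom (complete-data df n − 1; at n = 500 and
m = 5 the small-sample adjustment is non-negligible for coverage). 95%
interval bounds are back-transformed. With extremely dispersed inputs the
Fisher-z back-transform can saturate to ±1.0 in floating point; this does
not occur for imputation-scale dispersion.

Outcome measures across S replications, per estimand: absolute percent
relative bias `PRB = |mean(φ̂) − φ|/|φ| × 100` (flagged above 10), average
CI width, and coverage `CIC` (flagged below 0.90), with truth φ defined as
the mean of the full-data estimates over the same S replications. When
φ = 0, PRB is undefined and the absolute bias is reported with a flag.

## Component-retention rules

All four rules operate on the descending eigenvalues of a Pearson
correlation matrix, computed from either the fully observed data or the
complete cases:

- **kc** (Kaiser): count of eigenvalues above 1.
- **pa** (parallel analysis): the leading run of observed eigenvalues above
  the mean reference spectrum from 100 simulated independent-normal data
  sets of the same n × p (a 95th-percentile reference is available as an
  option; the mean is the base definition).
- **oc** (optimal coordinates): the predicted eigenvalue at position i is
  extrapolated from the line through scree coordinates (i+1, λ_{i+1}) and
  (p, λ_p); the rule counts positions whose observed eigenvalue meets both
  its prediction and the Kaiser baseline. On an exactly degenerate spectrum
  (tied population eigenvalues) the prediction test is a knife-edge; on
  sampled data the rule behaves as intended.
- **af** (acceleration factor): the position preceding the maximizer of the
  second difference of the scree — i.e., the sharpest elbow. On these data
  the giant first eigenvalue makes af select 1 almost always; it
  systematically underestimates multi-factor structure.

All rules return at least 1.

## Numerical and degenerate-input choices

- Root finding for β₀ uses an expanding bracket centered at
  `logit(target) − mean(η)`; a fixed symmetric bracket cannot work because
  the linear predictor is not centered (mean ≈ 20 on the rescaled data).
- Zero-variance columns are rejected by PCA and the moment estimator with
  the offending column named.
- Singular cross-product matrices with κ = 0 raise immediately with advice
  to set κ > 0.
- PMM requires `donors ≤ n_obs`; χ² degrees of freedom are floored at 1.
- Completely missing columns are rejected at the starting-fill stage.
- Failures inside a single (replication, method) cell of a study are logged
  and recorded as error rows; the study continues.

## Reproducibility

Every source of randomness descends from `numpy.random.SeedSequence`. A
study derives one stream per (cell, replication) from
`SeedSequence([base_seed, cell_index, rep])` and spawns children for
generation, amputation, and each method, so any single cell can be re-run
bit-identically in isolation and results are independent of execution order.

## Known limitations

- Only continuous (or ordinal-as-numeric) targets: no logistic/polytomous
  samplers.
- The oc/af formulations follow the non-graphical scree literature, but
  implementations of these rules differ across packages in tie handling and
  the prediction line; kc and pa are the robust choices here.
- MI-PCR-ALL inherits whatever distortion the pretreat single imputation
  introduces into the component space.
- The desk-scale simulations use S = 100 replications; Monte Carlo error on
  coverage estimates is about ±0.04 at that size.
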