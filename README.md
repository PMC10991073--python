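# mipcr

Multiple imputation by chained equations (MICE) with
principal-component-regression (PCR) univariate imputation models, plus the
Monte Carlo machinery to evaluate such methods: a confirmatory-factor-model
data generator, calibrated right-tail MAR amputation, Rubin's-rules pooling,
and non-graphical rules for choosing the number of components.

## The problem

Imputers working with social-science surveys face a *many-variables*
problem: a well-specified imputation model should condition on everything
related to the incomplete variables and to their missingness, but surveys
carry hundreds of candidate predictors, and regression-based univariate
imputation models become slow, collinear, or outright singular long before
all of them can be included. One data-driven way out is to replace the raw
predictor pool of each univariate model with a handful of principal
components. This package implements three ways of doing that inside the
chained-equations loop:

- **MI-PCR-AUX** — one PCA on the auxiliary variables, fitted before MICE;
  each incomplete variable is imputed from the raw remaining analysis-model
  variables plus the first `npc` auxiliary component scores.
- **MI-PCR-ALL** — one PCA on *all* variables of a singly-imputed completed
  matrix; the scores are the only predictors, and because they are complete
  a single sweep per imputation suffices.
- **MI-PCR-VBV** — the PCA is refitted on all other columns of the current
  completed matrix at every (chain, iteration, target), so the component
  scores track the evolving imputations.

Two comparators are included: correlation-thresholding predictor selection
(**MI-QP**, quickpred-style: keep predictors correlating with the target or
its missingness indicator at `r ≥ 0.1`) and the oracle imputer (**MI-OR**,
which knows the true missingness predictors).

## Core model

Every univariate model is Bayesian imputation under the normal linear model:
for target `x_j` with design `X` (intercept + predictors) and observed rows
`(y_obs, X_obs)`,

    σ²* = SSR / χ²_{n_obs − q},
    β*  ~ N(β̂, σ²* (XᵀXₒᵦₛ + κI)⁻¹),        κ = 1e−5 ridge stabilizer
    x_j^mis ~ N(X_mis β*, σ²* I)

Predictive mean matching (type-1 matching, donor pool 5) is available as an
alternative sampler. Estimates from the m completed data sets are pooled by
Rubin's rules — `T = Ū + (1 + 1/m) B` with Barnard–Rubin degrees of freedom —
with correlations pooled on the Fisher-z scale and variances on the log
scale.

The simulation laboratory generates `X = FΛ′ + E` from a 7-factor model
(λ = 0.85, latent correlations 0.7 or 0.1 according to the noise proportion
`pn`), rescales items to mean 5 / variance 6.5, optionally coarsens the
auxiliary items to `nCat` ordinal levels, and imposes 30% right-tail MAR on
the four analysis items via `logit Pr(missing) = β₀ + Mβ` with β root-found
so the achieved proportion is exact in expectation.

## Worked example

```python
import numpy as np
from mipcr import (build_design, generate_data, impose_mar, MissingnessSpec,
                   impute_mi_pcr_vbv, estimate_moments, pool_rubin)

design = build_design(pn=0.0, study=1)                 # 7 factors, 56 items
full = generate_data(design, n=500, ncat=float("inf"), seed=7)
incomplete = impose_mar(full, MissingnessSpec(target_prop=0.3), seed=8)
print("missing per T column:",
      incomplete.values[full.roles["T"]].isna().mean().round(3).tolist())

result = impute_mi_pcr_vbv(incomplete, npc=8, m=5, maxit=20, seed=9)
per_imp = [estimate_moments(c, full.roles["T"]) for c in result.completed]
idx = next(i for i, e in enumerate(per_imp[0])
           if e.estimand == "correlation" and e.columns == ("x1", "x2"))
pooled = pool_rubin([est[idx] for est in per_imp])
truth = estimate_moments(full.values, full.roles["T"])[idx].estimate
print(f"pooled r(x1,x2) = {pooled.qbar:.3f}  "
      f"95% CI [{pooled.ci_lower:.3f}, {pooled.ci_upper:.3f}]")
print(f"full-data r(x1,x2) = {truth:.3f}")
```

Output:

```
missing per T column: [0.286, 0.3, 0.298, 0.28]
pooled r(x1,x2) = 0.709  95% CI [0.631, 0.773]
full-data r(x1,x2) = 0.724
```

The amputation removed ~30% of each analysis item, concentrated among
respondents with high scores on the M items; imputing with eight components
(one more than the seven generating factors) recovers the item correlation,
and the 95% interval covers the full-data estimate.

## Command line

```sh
mipcr simulate --study 1 --n 500 --ncat inf --pn 0 --seed 3 --out data.csv
mipcr impute   --in data.csv --method vbv --npc 8 --m 5 --maxit 20 --out-prefix imp
mipcr npc      --in imp_1.csv --rule kc
mipcr pool     --in imp_1.csv --in imp_2.csv --in imp_3.csv --targets x1,x2,x3,x4
mipcr study    --config study1.yaml --out metrics.csv
```

`mipcr study` runs a factorial simulation (replications × `nCat` × `pn` ×
methods × component counts) and writes a long-format table of absolute
percent relative bias (PRB), average 95% CI width (CIW), and CI coverage
(CIC) per estimand.

## Acceptance script

`scripts/acceptance.py` recomputes the package's headline simulation
quantities from scratch at desk scale (S = 100 replications): the achieved
missingness proportion of the calibrated amputation, PRB and coverage of the
pooled correlation between the first two imputed items for MI-PCR-VBV (8 and
5 components), MI-OR and MI-PCR-AUX in selected design cells, and the
minimum Kaiser-criterion component count over fully observed data sets.

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

It runs in a few minutes on one CPU and writes one JSON object mapping each
quantity to its measured value.
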