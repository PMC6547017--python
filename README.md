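# fmisim

A Monte-Carlo simulation toolkit for studying **multiple imputation (MI) of
a missing outcome**: how the proportion of missing data, the availability of
auxiliary variables, and the **fraction of missing information (FMI)**
jointly determine the bias and precision of a regression estimate, compared
with complete-case analysis (CCA).

It is aimed at biostatisticians and epidemiologists who want a controlled
test bed for imputation strategy questions — "is 60% missingness too much
for MI?", "which auxiliary variables actually buy precision?" — with exact
control over the information content of every auxiliary variable.

## The model

Cohorts of n individuals are drawn from a standardised multivariate normal
(outcome Y, exposure X, auxiliaries Z1..Z11) in which every variable
correlates with Y (0.6 for X; 0.4, 0.2 or 0.1 for the auxiliaries) and the
non-outcome variables are mutually uncorrelated, so a predictor set S has

  R²_Y(S) = Σ_{v∈S} ρ²_{Y,v}

exactly. Outcome values are deleted either completely at random (MCAR) or
through a logistic selection model logit P(missing) = α + Z1 + X (MAR) with
α calibrated numerically to a target proportion. The analysis model is
y = β0 + β1 x + ε (true β1 = 0.6). Missing outcomes are multiply imputed by
proper Bayesian linear regression under predictor sets of increasing
strength; each completed data set is fitted by OLS and the m results are
pooled by Rubin's rules:

  T = W + (1 + 1/m) B,  r = (1+1/m)B/W,  df = (m−1)(1+1/r)²,
  FMI = (r + 2/(df+3)) / (r + 1).

Across replicates the package reports bias, empirical SE (with Monte-Carlo
standard errors), median/IQR of the FMI, and percentage reductions in SE
and |bias| relative to CCA.

## Worked example

```python
import numpy as np
from fmisim import (CorrelationSpec, simulate_cohort, apply_mcar,
                    ImputationModelSpec, impute_stack, pool_imputed_stack,
                    fit_analysis_model, multiple_r2)

spec = CorrelationSpec()                      # n=1000, canonical correlations
print(multiple_r2(spec, ("X", "Z1")))         # 0.52

cohort = simulate_cohort(spec, seed=1)
masked = apply_mcar(cohort, p=0.4)            # first 400 outcomes deleted

cca = fit_analysis_model(masked, complete_rows_only=True)
print(round(cca.slope, 3), cca.n_used)        # 0.648 600

model = ImputationModelSpec.canonical("2", m=200)     # predictors {X, Z3}
stack = impute_stack(masked, model, seed=3)
pooled = pool_imputed_stack(stack)
s = pooled.slope
print(round(s.estimate, 3), round(s.se, 4), round(s.fmi_adjusted, 3))
# 0.642 0.0309 0.363
```

The pooled slope stays near the complete-case estimate (MCAR deletion is
unbiased for both), the pooled SE 0.0309 sits close to the CCA SE, and the
FMI of ≈ 0.36 is *below* the 40% missingness proportion because the
auxiliary Z3 returns part of the lost information. One replicate's FMI is
noisy; study-level conclusions come from the replicated grids below.

A full study is driven by a YAML config (see `configs/`):

```sh
fmisim run configs/reduced.yaml        # 200 replicates x 200 imputations
fmisim table2 results/reduced/summary_tidy.csv -o table2.csv
fmisim fig1 results/reduced/summary_tidy.csv -o fig1.png
fmisim fig2 results/reduced/summary_tidy.csv -o fig2.png
```

`fmisim run` writes a per-replicate archive (with a seed ledger making every
number independently recomputable), tidy and wide summary tables, and the
config actually used.

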