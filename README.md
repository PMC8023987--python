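# trajmix

Latent-class trajectory analysis for longitudinal disease activity in
juvenile dermatomyositis (JDM) — growth mixture models with BIC/entropy model
selection, a GEE missingness diagnostic, chained-equations imputation, and
posterior-probability-weighted lasso identification of baseline predictors of
a severe disease course.

## Who this is for

Biostatisticians and clinical researchers analysing registry cohorts of
repeated disease-activity scores — here the physician's global assessment
(PGA, 0–10) and the cutaneous modified disease activity score (modified DAS,
0–5) — who want to (i) separate heterogeneous patient trajectories into
latent classes, (ii) check whether outcome missingness is plausibly missing
at random, and (iii) find baseline clinical features that predict membership
in the severe class.  Because registry data of this kind are rarely
shareable, the package ships a seeded synthetic-cohort generator with the
same statistical structure (≈500 patients, ~2 visits/year over up to two
decades, an 89%/11% two-class split for global activity and a 16%/12%/72%
three-class split for skin activity, MAR missingness of PGA driven by
baseline PGA and centre), so every stage can be exercised and tested end to
end.

## The model

For patient *i* with visits at times *t* (years since diagnosis), the
transformed outcome *y*\*<sub>i</sub> = √y<sub>i</sub> follows, given latent
class *g*,

    y*_i | c_i = g  ~  N( X_i β_g + W_i γ + Z_i b_i ,  σ² I ),
    b_i ~ N(0, D),      P(c_i = g) = π_g,

where X<sub>i</sub> is the cubic time polynomial (class-specific fixed
effects), W<sub>i</sub> holds common covariates (centre), and Z<sub>i</sub>
is the random intercept + slope design.  Marginalizing *b*<sub>i</sub>, the
observed-data log-likelihood is

    ℓ = Σ_i log Σ_g π_g N( y*_i ; X_i β_g + W_i γ , Z_i D Z_iᵀ + σ² I ),

maximized directly by L-BFGS with an analytic gradient over an unconstrained
parameterization (multinomial-logit π, Cholesky factor of D, log σ), from
multiple starts.  The class count is chosen by BIC = −2ℓ + k·ln(n patients),
with relative entropy E = 1 − Σ<sub>ig</sub>(−p<sub>ig</sub> ln
p<sub>ig</sub>)/(n ln G) reported alongside.  Visits with a missing outcome
drop out of the likelihood, which is ignorable under MAR once the
missingness predictors are in the mean model — hence the companion logistic
GEE (exchangeable working correlation, robust errors) that screens candidate
predictors of missingness.

For prediction of severe-class membership, each patient contributes two
fractional observations — (y=1, weight p<sub>i,severe</sub>) and (y=0,
weight 1−p<sub>i,severe</sub>) — to an L1-penalized logistic regression

    min  −(1/W) Σ_i w_i [ y_i log p_i + (1−y_i) log(1−p_i) ]  +  λ ‖β‖₁

solved by cyclic coordinate descent with warm starts along a descending λ
grid (KKT-checked); λ is picked by patient-level 10-fold cross-validation
(AUC, deviance or misclassification loss) separately within each of 10
imputed baseline tables, and coefficients are pooled across imputations by
majority retention.

## Worked example

The numbered scripts under `analysis/` run the full study on a simulated
cohort and write their tables under `results/analysis/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_missingness_gee.py
python analysis/03_fit_gmm_pga.py
# ... through 07
```

`03_fit_gmm_pga.py` prints the class-count selection table and the selected
model:

```
 G   loglik  k     bic  entropy  converged
 1 -1951.20  9 3958.66      NaN       True
 2 -1847.02 14 3781.58     0.92       True
 3 -1842.13 19 3803.05     0.87      False

selected G = 2 by BIC (entropy concurs)
modal class shares: {1: '91.1%', 2: '8.9%'}
entropy 0.924; mean posterior by class [0.984 0.937]
```

Two classes minimize BIC: a large improving class (~91% of patients, global
activity declining towards remission) and a small persistent class (~9%,
activity staying high), recovering the generator's 89%/11% split; the
entropy of 0.92 says the posterior assigns most patients to a class almost
deterministically.  `02_missingness_gee.py` flags baseline PGA and centre
(z = 5.3 and 6.3 here) as the predictors of missing PGA — exactly the
variables that drive missingness in the generator — and
`07_lasso_predictors.py` prints the per-imputation retained predictors and
the pooled odds ratios of the severe class.

The same stages can be driven programmatically via
`trajmix.pipeline.run_pipeline(PipelineConfig(...))`, which writes each
stage's artifacts and a manifest into a run directory.

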