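# Methods

## Model

The core model is a growth mixture model: a finite mixture of linear mixed
models for a repeatedly measured disease-activity score.  Each latent class
g ∈ {1..G} has its own mean trajectory — a polynomial in time since
diagnosis of degree d (default 3) on the transformed outcome scale — while
individual patients deviate from their class curve through a shared
bivariate normal random intercept + slope and i.i.d. Gaussian residual
noise.  A square-root transform is the default outcome scale for both the
global score (PGA, 0–10) and the skin score (modified DAS, 0–5): both are
right-skewed non-negative scores, and the transform also makes the
back-transformed class mean the *median* on the original scale (monotone
transforms commute with quantiles), which is what the predicted-trajectory
plots report.

Assumptions worth stating explicitly:

- **Conditional independence**: visits are independent given the class and
  the random effects; the marginal within-patient covariance is
  Z D Zᵀ + σ²I.
- **MAR outcome missingness**: visits with a missing outcome are dropped
  from that patient's likelihood contribution.  This is valid when
  missingness depends only on modelled quantities; the GEE diagnostic
  (below) screens candidate drivers, and the identified ones (baseline
  score, centre) are respectively part of the outcome process and included
  as a covariate.
- **Non-informative visit times**: the likelihood conditions on observed
  visit times.  The generator mildly violates this (the severe class enters
  follow-up slightly later, see below), mirroring the real design; the
  recovery tests show the induced bias at the study's size is well inside
  Monte-Carlo error.

## Estimation

The marginal log-likelihood is maximized directly by L-BFGS with an analytic
gradient, over an unconstrained parameterization: multinomial-logit class
intercepts (last class as reference), class-specific polynomial
coefficients, common covariate effects, the lower-triangular Cholesky factor
of D, and log σ.  EM was deliberately not used: with 10–20 parameters the
quasi-Newton path is shorter, and the gradient is exact (verified against
finite differences at random points to ~1e-10 relative).

Implementation notes that matter for correctness and speed:

- Time is internally rescaled to [0, 1] before building the polynomial and
  random-slope designs (coefficients are reported on the raw scale); raw
  cubic terms up to 10³ would otherwise ruin the optimizer's conditioning.
- The per-patient marginal covariance is never formed densely: with q ≤ 2
  random effects, determinants and solves reduce to q×q algebra via the
  Woodbury identity, batched across patients.  K = σ²I + LᵀZᵀZL is
  positive definite for any parameter value with σ > 0, so no jitter is
  needed on this path.
- Mixture sums are evaluated in the log domain (log-sum-exp).
- Multistart: one start from k-means on per-patient OLS (intercept, slope)
  summaries, the rest from randomly perturbed single-class fits; the best
  final likelihood wins.  Well-separated simulated cohorts are reliably
  solved by the k-means start; the default of 30 starts is conservative for
  messier data, and the analysis scripts use 2–4.
- Convergence is declared at relative log-likelihood change < 1e-6 with the
  gradient sup-norm below 1e-3; both are recorded in the fit, and a
  non-converged best solution is returned flagged rather than raised.
- Classes are re-ordered by descending class probability after fitting, so
  reported class labels are deterministic under label switching.

BIC uses the number of *patients* as the sample size (the mixture's
independent units), not visits.  Relative entropy
E = 1 − Σ(−p log p)/(n ln G) is the selection companion: BIC is primary,
and when the entropy-maximal class count disagrees with the BIC-minimal one
the conflict is flagged in the selection output rather than silently
resolved.  The mean posterior probability among patients modally assigned to
each class is reported alongside, since "how well are individuals
allocated" is sometimes read that way instead.

Trajectory confidence bands come from a parametric bootstrap (default 500
draws) of the asymptotic normal of the parameters, with the Hessian obtained
by finite differences of the analytic gradient; a delta-method interval is
available as a fast alternative (the analysis scripts use it).

## Missingness diagnostic

A logistic GEE for the indicator "outcome missing at this visit", with
patients as clusters, an exchangeable working correlation and the sandwich
covariance.  statsmodels' GEE does the estimation; the unit tests pin the
two reductions that make the output interpretable — independence working
correlation reproduces ordinary logistic ML, and the robust covariance
equals the hand-computed A⁻¹BA⁻¹ sandwich.

## Imputation

Missing baseline features (three scores, five binary features; 6–34%
missing under the generator's registry-style completeness rates) are completed m = 10 times
by chained equations with predictive mean matching (k = 5 donors), via
statsmodels.  PMM draws observed donor values, so imputed binaries stay in
{0, 1} and scores stay in their observed range by construction.  Each of the
m chains runs from its own seed stream.  The latent class is not an
imputation predictor by default (conservative: avoids building the
association being estimated into the completed data); a flag allows it.

## Predictive stage

The weighted lasso objective, path algorithm (cyclic coordinate descent on
the IRLS quadratic with warm starts, KKT verification at every solution),
CV selection, interaction re-fit, and pooling rule are authored in the
package — scikit-learn's L1 logistic solver and a weighted IRLS fit serve
as independent oracles in the tests.  Choices the literature leaves open:

- Fractional two-row encoding of class uncertainty (y=1 with weight
  p_severe, y=0 with 1−p_severe); degenerates to modal classification for
  one-hot posteriors.
- λ grid: 100 log-spaced values from λ_max (the KKT threshold at which all
  slopes vanish) down to 10⁻³·λ_max.
- λ at the minimum of the mean out-of-fold loss, ties towards the sparser
  model.  The 1-SE rule is deliberately not used; a consequence is that on
  pure-noise data the selected model often carries one stray predictor,
  which the tests assert as the expected behaviour.
- Folds are patient-level and stratified by modal class; both fractional
  rows of a patient share a fold (otherwise the same patient appears in
  train and test).
- Pooling across imputations: a predictor is retained if non-zero in more
  than m/2 of the m fits; its pooled coefficient is the mean over the fits
  where it is non-zero.  No standard errors are reported — they are not
  trustworthy after L1 shrinkage.
- Diagnosis enters as dummies against the definite-JDM reference;
  autoantibody status is excluded as a predictor (too incomplete).

## Synthetic cohorts

The generator emulates a national JDM registry: n = 519 patients, Centre A
with probability 0.464, log-normal follow-up (median 5.1 y, capped at
23.4 y), entry lag log-normal with median 0.2 y, and Gamma-distributed
inter-visit gaps averaging 0.5 y.  Outcomes follow the mixture model
exactly on the transformed scale — two PGA classes (89%/11%) and three DAS
classes (16%/12%/72%) with cubic mean curves chosen so the classes read
clinically (improving vs persistent disease) and are well separated at the
study's size — then are back-transformed and clipped to the instrument
range.  Class-dependent baseline features use logistic models whose severe
class log-odds equal the study's reported effects (odds ratios 1.91 for
abnormal respiration, 1.92 for lipodystrophy); the entry-lag dependence is
an exponential tilt worth 1.32 per year; CMAS and DAS baselines get small
class shifts matching odds ratios 0.99 and 0.96.  Visit-level PGA
missingness follows a logistic model in true baseline PGA and centre
calibrated to ~13% of visits overall; baseline features are masked MCAR at
the registry's documented incompleteness rates.  The skin outcome shares
the visit grid, with its severe (persistent) class tilted towards the severe
global class by 0.7 log-odds so the cross-tabulation has the study's
positive association.

What the generator does *not* emulate — and hence what passing tests do not
establish about real registries: integer-valued scores and rater effects,
floor inflation at true remission (clipping only touches the tails here),
informative dropout, feature–feature correlation beyond what the class
induces (an optional Gaussian-copula knob exists in the design but classes
are the only default source of dependence), and medication effects.

Two boundary artifacts are acknowledged: the cubic class means can cross
zero beyond ~15 years (outside the 10-year analysis window; values are
clipped), and back-transform clipping makes the observed scale mildly
non-Gaussian near 0.

## Problem sizes

The test-suite and acceptance-script experiments use the study's n = 519
with 20 replicate cohorts for recovery checks (class proportions, model
selection, pooled odds ratios), 3 replicates for the averaged descriptive
summaries, G up to 3 in selection runs (the generating counts are 2 and 3),
2 multistarts (k-means + one perturbation; sufficient for the separations
involved, as the from-truth refits confirm), and 3 chained-equation sweeps
per imputation.  These sizes are the package's own choices for routine runs;
all are parameters.

## Known limitations

- The likelihood treats visit times as fixed; jointly modelling an
  informative visit process is out of scope.
- Ordered-logistic mixtures for categorical outcomes, time-varying
  covariates, and joint multivariate (PGA + DAS) mixtures are not
  implemented.
- The bootstrap trajectory bands reflect parameter uncertainty only, not
  class-assignment uncertainty.
- With weak class separation the modal-class shares of small classes are
  biased upward relative to the mixing proportions (visible in the
  three-class skin model, whose entropy is genuinely lower).
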