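# Methods

## Model and estimation

The analysis model is a covariance-based structural equation model over one
latent variable (gender) and 20-odd observed variables, parameterized in
reticular (RAM) form: stacking observed and latent variables into *v*,

    v = A v + e,   Cov(e) = S,   Sigma(theta) = F (I - A)^-1 S (I - A)^-T F',

with loadings, indicator regressions and structural paths in `A`, residual
variances in `S`, and `F` selecting the observed variables. Observed
exogenous covariates (sex, age, partner, children, East residence, sexual
orientation, immigration dummies, before-outcome risk flags) are handled in
the fixed-x convention: their variance/covariance block in `S` is held at the
sample values, so it is reproduced exactly, contributes no free parameters,
and is subtracted from the testable moment count. Degrees of freedom are
therefore `p(p+1)/2 - q(q+1)/2 - k` for `p` observed variables, `q` fixed
exogenous variables and `k` free parameters. No mean structure is modeled;
factor scoring centers at the sample means.

Estimates minimize `F_ML = ln|Sigma| - ln|S| + tr(S Sigma^-1) - p` by
L-BFGS-B with an analytic gradient (the RAM derivative identities
`dF/dA_ij = 2 (C M B)_{ji}`, `dF/dS_ij = (B' M B)_{ij}` with
`B = (I-A)^-1`, `C = B S B'`, `M = F' W F`, `W = Sigma^-1 - Sigma^-1 S
Sigma^-1`), followed by up to five Newton polish steps using a
finite-difference Hessian of that gradient; the polish brings just-identified
fixtures to their closed-form solutions within 1e-6. Residual variances are
bounded below at 1e-8. Convergence is declared on optimizer success or an
infinity-norm gradient below 1e-4; one restart from perturbed starting
values is attempted otherwise. Starting values: loadings from anchor
covariance ratios, regressions 0, residual variances at half the sample
variances.

Standard errors come from the inverse observed information of the
discrepancy, `acov = (2/(n-1)) H^-1`; t-ratios are referred to the standard
normal (the |t| > 1.96 decision rule), and 95% CIs are estimate ± 1.96 se.
Chi-square is `(n-1) F_ML`; `RMSEA = sqrt(max(chi2 - df, 0)/(df (n-1)))`;
SRMR is the root mean square of the correlation-scaled residual moments over
all `p(p+1)/2` unique entries; `AIC = -2 loglik + 2k` with the Gaussian
log-likelihood evaluated at the `(n-1)`-scaled sample covariance.

### Outcome link

Binary incident outcomes are modeled as continuous endogenous variables
under normal-theory ML — a linear-probability formulation whose coefficients
live on the cumulative-incidence scale (a 0.044 sex effect means 4.4
percentage points). A probit/threshold variant is deliberately out of scope;
the linear formulation matches the scale of the coefficients it is meant to
recover and keeps the joint latent-plus-outcome model in one ML pass.

### Identification and the sex-anchored gender scale

During estimation the latent is identified by fixing the housework loading
to 1 (latent mean 0). Because that scale is arbitrary, reported gender-scale
quantities are transformed afterwards: with factor-score group means `mu_F`,
`mu_M`, scores map through `a*s + b`, `a = 1/(mu_F - mu_M)`,
`b = -mu_M * a`, which forces the female mean to exactly 1 and the male mean
to exactly 0. Coefficients *of* gender and loadings are divided by `a`,
paths *into* gender multiplied by `a`, and the gender residual variance by
`a^2`, so fitted values and the discrepancy are unchanged (an affine
reparameterization). Regression factor scores condition on the full observed
vector including sex, so their group-mean gap is a consistent estimate of
the model-implied latent gap and the transformed coefficients carry no
shrinkage bias. In the sensitivity model without the sex→gender path the
same transform is applied using the observed sex groups — an interpretive
choice that keeps coefficients comparable across models; it fails loudly if
the score means coincide.

### Factor scores

`regression` (default): `E[eta | all observed]` under the fitted model.
`bartlett`: GLS over the indicator block only, conditionally unbiased given
the latent. Both require complete (imputed) rows.

## Synthetic panel generator

The generator emulates the structure of a long-running German household
panel: annual waves 2009-2022, biennial diagnosis assessment (2011-2021),
binary sex (female share 49.9%), age at entry uniform on 18-80, immigration
history at 72.5/6.3/21.3% (none/indirect/direct), partner 55.1%, children
none/single/multiple at 69.0/14.2/16.9%, East residence 21%, and sexual
orientation 2.2% probably bi- or homosexual. Latent gender is
`shift * 1[female] + N(0,1)` with `shift = 1` by default. Indicators are
`loading * gender + covariate effects + N(0,1)` on a per-person basis
(constant across waves); the default loadings carry the published sign
pattern with housework +0.670 and monthly income -0.708 as anchors, and
plausible fill-in magnitudes (0.2-0.6) for the remaining indicators whose
published values are not tabulated numerically. Binary/ordinal indicators
(parental leave 2%; employment and political interest, four levels) are
produced by empirical-quantile thresholding of the same Gaussian index, so
one generation mechanism serves all scales; thresholding attenuates the
observed-scale loading relative to the index loading, which is why the
replicate-based recovery checks run on the all-continuous configuration.

Outcomes follow a person-level linear-probability law: cumulative incidence
probability = intercept + sum of configured effects (defaults: migraine
intercept 0.020 with sex +0.044; stroke intercept 0.050 with sex -0.010 and
gender +0.006). Any implied probability outside [0, 1] aborts generation —
out-of-range probabilities are a configuration error, never silently
truncated. With a unit-variance Gaussian latent and a nonzero gender effect
the intercepts must sit well above the minimum effect sum, so the default
stroke intercept (5%) exceeds the incidence a real cohort would show (~1.4%);
this is the price of an exactly valid linear law and is a deliberate realism
trade-off. Incident cases draw their switch wave uniformly from the second
health wave onward (an incident case needs an observable prior "no");
prevalent cases (migraine 6%, stroke 2%) answer "yes" from their first
response. Risk-factor onsets are drawn 2002-2009, before follow-up, so the
derived before-outcome flags coincide with the generating person-level flags.
Wave weights are lognormal(0, 0.5) with a 5% zero-weight person fraction.

MAR blanking draws cell-level missingness from a logistic model in observed
age, sex and wave, with the intercept calibrated by bisection to hit the
requested marginal rate; configured rates are capped at 24.5%. Keys and sex
are never blanked.

What the generator does *not* emulate: household clustering, attrition and
refreshment samples, time-varying indicator trajectories, mid-follow-up
risk-factor onset (exercised in unit tests only), non-normal latent
distributions, and realistic weight construction (the weight model is a
stand-in). Passing recovery tests therefore demonstrate correctness of the
estimation machinery under the stated generative laws, not robustness to
real-data violations of them.

## Preprocessing rules

Biennial responses are copied to the immediately following wave (only where
that wave has none of its own). Classification per person and outcome:
prevalent iff the first valid response is 1 (excluded); incident at the
first wave where a 0-history is followed by 1; non-case otherwise. Exclusion
order: no-valid-response, prevalent, under-18-at-baseline; the report counts
sum exactly to input minus output. Baseline is the first valid
health-assessment wave; age, weight and (by default) indicator values are
taken there — collapsing at baseline predates the outcome and limits reverse
causation; a mean-over-waves collapse is available. Before-outcome flags:
for incident cases, first report strictly before the incident wave; for
non-cases, ever reported during follow-up (keeps the flag defined for the
whole sample, as the outcome equations require). The migraine and stroke
samples are assembled independently.

## Imputation and pooling

Chained equations visit incomplete variables in ascending missingness order
for 10 passes (default), with m = 20 completed datasets from independent
seeded streams. Continuous variables use predictive mean matching with k = 5
donors and a posterior draw of the regression coefficients (type-1 matching:
missing-cell predictions from the drawn coefficients, observed-cell
predictions from the least-squares fit); dichotomous variables use logistic
draws with a coefficient draw from the estimated sampling distribution;
ordinal variables use proportional-odds logistic draws (falling back to
observed-frequency draws if the ordinal fit fails). Observed cells are never
altered; incidence flags are never imputed, since incidence is defined by
observed response switches. Pooling uses Rubin's rules with normal-based
intervals (`Qbar`, `Wbar`, `B`, `T = Wbar + (1 + 1/m) B`); the
Barnard-Rubin small-sample df correction is omitted — at the sample sizes
this pipeline targets the normal reference matches the |t| > 1.96 rule.
Coverage of the full blank-impute-fit-pool loop is verified by simulation
(96/100 and 95/100 over 100 replicates for the two outcome-equation
parameters).

## Study variants

The weighted variant feeds the weight-normalized covariance and the Kish
effective sample size `(sum w)^2 / sum w^2` into the same fitter (covariance
reweighting, not person-level weighted likelihood). Age stratification
subsets the already-completed imputation datasets per stratum rather than
re-imputing within stratum, and refuses strata under 50 persons explicitly.
Effect-measure modification is expressed only through stratified fits, never
through product terms. Fit indices are reported per imputation plus their
arithmetic mean.

## Problem sizes used in the shipped checks

Replicate-based checks run at deliberately modest sizes chosen as the
package's own test design: parameter recovery with 50 replicates of n =
5,000; imputation coverage with 100 replicates of n = 900 on a reduced
three-indicator model with m = 20; generator self-consistency at n = 50,000.
The exact scaling-constraint and closed-form checks are size-independent.

## Known limitations

- The linear-probability outcome link is the scale-faithful choice but can
  imply out-of-range probabilities for extreme covariate patterns; the
  generator refuses such configurations rather than truncating, and the
  fitted model inherits the usual LPM caveats.
- Physician visits sits in the default indicator set although indicator
  lists in the motivating literature are not fully consistent about it; it
  can be removed via the graph/config.
- No FIML for missing data (imputation is the supported path), no robust
  (sandwich) errors, no WLSMV/probit estimator, no multi-group equality
  constraints.
- The latent-normality assumption is untestable from the fitted covariance
  alone; real gender distributions are plausibly non-normal.
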