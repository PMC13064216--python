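# gendersem

Structural equation modelling of **sex and latent gender effects on incident
health outcomes** in longitudinal survey panels.

Quantitative health research routinely conflates sex assigned at birth with
gender — the socially constructed roles, relations and positions that shape
behaviour and exposure. `gendersem` implements an analysis strategy that keeps
the two apart inside one model: gender is treated as an unobserved continuous
latent variable, *caused* by sex and *reflected* by a set of observed
gender-related indicators (housework and childcare hours, parental leave,
income, wage, education, employment status, risk-taking, political interest,
physician visits), and both sex and latent gender enter the outcome equations
of binary incident diagnoses (migraine, stroke) side by side. Because the
real microdata such analyses run on (a large German household panel) are
access-restricted, the package ships a synthetic panel generator with known
ground truth, so every stage is testable end to end.

## The model

A hypothesized causal DAG is compiled into a structural equation model with
measurement part

&nbsp;&nbsp;&nbsp;&nbsp;*y*<sub>j</sub> = λ<sub>j</sub> η + **γ**<sub>j</sub>′ **x**<sub>j</sub> + ε<sub>j</sub>,&nbsp;&nbsp;&nbsp;j = 1, …, 10,

where η is latent gender, λ<sub>j</sub> the loadings (anchor: housework,
λ<sub>1</sub> ≡ 1 during estimation), and **x**<sub>j</sub> indicator-specific
covariates (children/partner for the caregiving indicators, age/East-German
residence for income and wage); and structural part

&nbsp;&nbsp;&nbsp;&nbsp;η = c·sex + ζ,
&nbsp;&nbsp;&nbsp;&nbsp;outcome = β<sub>s</sub>·sex + β<sub>g</sub>·η + **β**′**z** + ε,

with **z** = sexual orientation, partner, age (decades), immigration history,
and the smoking/diabetes/hypertension-before-outcome flags. Parameters
minimize the maximum-likelihood discrepancy
F<sub>ML</sub> = ln|Σ(θ)| − ln|S| + tr(S Σ(θ)<sup>−1</sup>) − p
(RAM parameterization, analytic gradient, quasi-Newton iteration with a
Newton polish); inference uses |t| > 1.96 Wald tests, fit is summarized by
RMSEA, SRMR and AIC. Because the latent scale is arbitrary, fitted gender is
rescaled by the affine map that forces mean gender to **1 for female and 0 for
male** participants, making β<sub>s</sub> and β<sub>g</sub> directly
comparable. Missing data are handled by chained-equation multiple imputation
(PMM / logistic / proportional-odds, m = 20) and Rubin's-rules pooling;
variants cover weighted covariance input, age-group-stratified fits, and a
sensitivity model without the sex→gender link.

## Worked example

```python
from gendersem import SyntheticConfig, StudyConfig, run_study

cfg = StudyConfig(synthetic=SyntheticConfig(n_persons=5000),
                  m=1, seed=1, variants=("main",))
res = run_study(cfg)
pooled = res.results["stroke"]["main"]["pooled"]
print(pooled[pooled["name"].str.contains("stroke|gender~")]
      [["name", "estimate", "se", "t", "p", "ci_low", "ci_high"]])
```

Selected rows of the output (n = 4,909 after excluding 91 prevalent cases):

```
                      name  estimate     se        t      p  ci_low  ci_high
         gender=~childcare    0.5301 0.0201  26.4209 0.0000  0.4908   0.5694
            gender=~income   -0.7492 0.0242 -30.9603 0.0000 -0.7967  -0.7018
         gender~sex_binary    1.0000 0.0398  25.1198 0.0000  0.9220   1.0780
stroke_incident~sex_binary   -0.0092 0.0073  -1.2579 0.2084 -0.0235   0.0051
    stroke_incident~gender    0.0119 0.0038   3.1308 0.0017  0.0045   0.0194
```

Reading: income loads negatively on latent gender (−0.749; higher income,
lower gender value) and childcare positively (+0.530), matching the
generator's measurement pattern; on the sex-anchored 0/1 scale the gender
gap between the sexes is 1.000 by construction. The structural estimates
recover the generating incidence-scale effects (sex→stroke −0.010,
gender→stroke +0.006) within sampling error at this n. Fit indices for the
same run: χ² = 130.5 on 147 df, RMSEA = 0.000, SRMR = 0.009 — the generating
model is correctly specified, so the test statistic sits at its null level.

A command-line interface mirrors the stages:

```bash
gendersem simulate --seed 1 --out data/
gendersem preprocess --in data/synthetic_panel.csv --out data/
gendersem study --seed 1 --variant main --variant weighted --out results/
```

## Layout

- `src/gendersem/dag.py` — causal graph, validation, compilation to an SEM spec
- `src/gendersem/simulate.py` — synthetic panel generator + MAR blanking
- `src/gendersem/preprocess.py` — incidence derivation, before-outcome flags,
  carry-forward, analysis-table assembly
- `src/gendersem/impute.py` — MICE (PMM/logistic/proportional-odds), Rubin pooling
- `src/gendersem/sem.py` — ML SEM, fit indices, factor scores, sex-anchored scaling
- `src/gendersem/study.py`, `cli.py` — orchestration, descriptives, CLI
- `docs/methods.md` — modelling assumptions, defaults, numerical choices,
  known limitations
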