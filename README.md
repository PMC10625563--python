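# pairmnar

Analysis of longitudinal outcomes whose *self-reporting depends on the
outcome itself*. The motivating setting is a weight-loss maintenance trial
in which participants weigh themselves daily on a connected scale: people
tend to skip the scale after disappointing days, so the daily weights are
plausibly **missing not at random (MNAR)**, and standard marginal methods
(GEE, complete-case least squares) estimate biased covariate effects.

The package implements a two-stage framework:

**Stage I — test the missing-data mechanism.** The working model is a GLM
whose response belongs to the exponential dispersion family,
`p(y|x) = exp{(yη − b(η))/λ + c(y;λ)}`, `h(μ(η)) = α + xᵀβ₁`. Two
estimators of β = (α, β₁) are compared on the natural-parameter scale: the
complete-case maximum likelihood estimator β̂ and a semiparametric
pseudo-likelihood estimator β̃ whose slope comes from a pairwise
conditional objective in which the baseline outcome distribution cancels.
Both are consistent when selection ignores the outcome (MCAR, or MAR
through covariates); they diverge under outcome-dependent selection. The
statistic

    T = n (β̃ − β̂)ᵀ Ŵ⁻¹ (β̃ − β̂)

with Ŵ the covariance of the influence-function differences (estimated by
delete-one jackknife pseudo-values by default) is asymptotically χ² with
m + 1 degrees of freedom under the null; large T is evidence of MNAR.

**Stage II — estimate effects without modelling the reporting process.**
The marginal model is a density-ratio (exponential tilt) model
`f(y|x) ∝ exp(βᵀx·y) g(y)` with g unspecified. For two observations from
different subjects, conditioning on the order statistics of the pair gives

    P(pair | order stats) = 1 / (1 + exp(−(βᵀ(x₁−x₂))(y₁−y₂))),

in which both g and any *separable* selection process
P(report | y, x) = a(x)·q(y) cancel. Summing log-probabilities over all
cross-subject observation pairs yields a concave composite likelihood whose
maximizer estimates β on the tilt scale (mean-scale effects divided by the
outcome variance, for Gaussian outcomes), with a subject-clustered Godambe
sandwich (or delete-one-subject jackknife) covariance. The reporting
process is never modelled — that is the point of the method.

A synthetic-cohort generator (three arms ~1:2:2, daily weights, baseline
age/sex/BMI matched to published cohort summaries, MCAR / MAR /
product-form MNAR selection) makes every stage testable without access to
any trial data, and a Monte-Carlo harness measures size/power of the test
and bias/coverage of the estimators.

## Worked example

Simulate a trial-shaped cohort with outcome-dependent reporting and run the
full pipeline:

```
$ pairmnar simulate --n-subjects 189 --schedule-length 30 \
      --mechanism mnar --gamma1 -0.5 --seed 7 --out demo/cohort.csv
wrote demo/cohort.csv (5670 rows, 50.0% observed)

$ pairmnar pipeline --input demo/cohort.csv --seed 7 --out demo/run
Stage I: T=2.578 df=3 p=0.4613 -> no evidence against MAR/MCAR
                     effect_size      se  p_value
sex                      -0.2854  0.0643   0.0000
baseline_bmi             -0.0027  0.0056   0.6249
age                       0.0134  0.0016   0.0000
time                     -0.6840  0.1013   0.0000
lottery_time             -0.5657  0.0964   0.0000
direct_payment_time      -0.5393  0.0980   0.0000
```

The Stage-II table is on the tilt scale with time in months. The generator
default truth is (sex −0.246, BMI −0.002, age 0.013, time −0.582,
lottery×time −0.616, direct×time −0.512); despite half the daily weights
being missing in an outcome-dependent way, the pairwise fit recovers these
effects within sampling error — e.g. time −0.684 ± 0.101: each month in the
study is associated with additional weight loss, and both incentive arms
show a further negative (beneficial) interaction with time. The Stage-I
p-value of 0.46 illustrates a documented property, not a bug: smooth
logistic selection of this strength is locally an exponential tilt of the
Gaussian outcome — nearly a pure location shift — and carries little
detectable signature (see docs/methods.md).

The same steps are available as library calls
(`simulate_complete_cohort`, `apply_missingness`, `mnar_test`,
`build_analysis_table`, `fit_pairwise`) and as further subcommands
(`test`, `fit`, `benchmark`).

## Acceptance script

`scripts/acceptance.py` re-runs the package's end-to-end computation from
scratch — simulating the trial-shaped MNAR cohort, running the Stage-I test
and the Stage-II pairwise fit — and writes its results JSON:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
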