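# Methods notes

## Aging clocks

### Klemera–Doubal biological age

Training regresses each biomarker on chronological age (CA), in that
direction — some KDM variants invert the regression, but the form
implemented here keeps biomarker-on-age, with the inversion happening
inside the $BA_E$ estimator. Regressions are unweighted by default with a
survey-weighted option (`fit_kdm(..., weights=)`); on a probability sample
the weighted fit estimates the population regression, the unweighted fit
the sample one, and both are exercised in tests.

Numerical guards: a biomarker whose residual RMSE falls below
$10^{-8}\times$ its SD is rejected as a degenerate fit (it would otherwise
dominate the precision-weighted sum); $S_{BA}^2$ from the variance
decomposition can come out non-positive when the biomarker panel explains
less of the age signal than its own noise term, and is then floored at
$10^{-6}\,\mathrm{y}^2$ with a warning — the floored clock collapses to
BA ≈ CA, which is the correct degenerate behaviour. The variance in the
$S_{BA}^2$ step uses divisor $n$ (population variance), matching the
printed form; the deviation is the per-subject $BA_{E,i} - CA_i$ centred
at its own mean. Negative-slope biomarkers need no special casing: the
slope's sign cancels between numerator and denominator (there is a sign
test).

Whether the clock is trained on the analytic sample or a wider one is a
genuine choice; the pipeline trains on the analytic sample (the default
in `add_age_measures`), so a clock file can be saved and reused for exact
reproduction.

### Phenotypic age

The printed closed form nests `ln(exp(.))`, which cancels algebraically:
PA is an affine function of the linear score, $141.50 + (xb + \ln(0.00553
\cdot 1.51714 / 0.0076927))/0.09165$. The nested form is kept only as a
test oracle, evaluated in 50-digit arithmetic because in double precision
the inner exponential underflows above $xb \approx -3.5$ and cancels
catastrophically below $xb \approx -25$. Whether the affine collapse was
intended by the method's authors cannot be settled here; the printed form
is what is implemented. CRP enters as the natural log of the mg/dL
concentration; a non-positive CRP is an input error rather than being
clamped.

## Cohort derivation

Threshold semantics follow the written rules literally: HbA1c strictly
above 6.5%, fasting glucose ≥ 7.0 mmol/L, random/2-h OGTT ≥ 11.1 mmol/L,
hypertension at ≥ 140/≥ 90 mmHg inclusive. Either a random-glucose or an
OGTT column (or both) may be present; they are OR-ed.

Blood-pressure averaging applies two rules whose order is unstated in
words: the implementation drops the first reading first, then excludes
zero-diastolic readings from the remainder unless every remaining
diastolic is zero. The result is invariant to the order of readings 2..k.

Person-level retinopathy is the worse eye, with an ungradable eye taking
the other eye's grade; for the binary lesion outcome, worse-eye and
either-eye logic coincide. Grades are a per-eye ordinal (modified Airlie
House order; ≥ 14 means at least one microaneurysm or blot hemorrhage).
DR is defined only among diabetes cases, so it is identically false for
non-DM records whatever the grades show.

The exclusion cascade removes each record at the earliest step it fails
(imaging/biomarkers → demographics → other covariates), so the per-step
counts are order-dependent by design and sum with the remainder to the
input size.

Drinking categories: never < 12 lifetime drinks; former ≥ 12 but none in
the past year; then sex-specific per-day cutoffs with heavy at ≥ 3 (F) /
≥ 4 (M), mild at ≤ 1 (F) / ≤ 2 (M) and moderate between (a fractional
2–3 drinks/day for women counts as moderate).

## Design-based estimation

Variance is Taylor linearization throughout (no replicate weights):
per-record influence vectors are summed to PSU totals, centred within
stratum, scaled by $n_h/(n_h-1)$, and accumulated. The sandwich for the
logistic fit is assembled as $(ZH^{-1})'(ZH^{-1})$ from the factored
between-PSU matrix $Z$, so it is positive semidefinite by construction
even when the parameter count exceeds the design rank.

Documented knobs where survey software differs:

* **Lonely PSUs** — a stratum contributing a single PSU is centred at the
  grand mean of PSU totals, with a warning.
* **Subpopulations** — `SurveyDesign.subset` performs proper domain
  estimation: the full PSU inventory is retained and PSUs with no domain
  members contribute zero totals, rather than re-deriving the design from
  the subset rows.
* **Reference distribution** — single-coefficient Wald tests and CIs use
  a t reference with df = (#PSUs − #strata) − p + 1, the convention of
  R's `svyglm`. A 500-replicate Monte-Carlo at the package's standard
  simulation conditions shows the linearized SE is mildly downward-biased
  (mean SE / true SD ≈ 0.92 with ~55 events and 15 design df), and this
  df convention keeps the realized type-I error within the nominal band;
  the raw design-df convention left it marginally above. Joint Wald tests
  are F-referenced with denominator df = design df − q + 1.
* **Ill-conditioning** — columns are equilibrated internally before the
  Newton solve; a weighted information matrix whose condition number still
  exceeds $10^{14}$, or divergence of the coefficients, raises an explicit
  convergence error. Subgroup analyses convert such failures into flagged
  rows instead of crashing.

The Rao–Scott test uses the second-order (Satterthwaite) correction: the
Pearson statistic on weighted proportions is divided by
$\bar\delta(1+a^2)$ and referred to $\chi^2$ with $d/(1+a^2)$ df, where
$\delta_k$ are the generalized design effects (eigenvalues of the scaled
linearized covariance of the independence residuals). Under an
equal-weight iid design it reproduces classical Pearson up to the
$n/(n-1)$ factor and the evaluation of the design effects at the sampled
table — agreement is asymptotic, not bitwise, which matches the behaviour
of standard survey software.

Model ladder: Model 1 crude; Model 2 + age, sex, race/ethnicity, income
ratio, marital status, education; Model 3 + physical activity, diet
score, drinking, smoking, BMI, CVD history, hypertension. A
chronological-age exposure (continuous or grouped) omits the age
covariate. Trend tests refit with ordered level codes as a single
continuous term; interaction tests add cross-product terms and test them
jointly.

## Splines

Three knots at the weighted 10th/50th/90th percentiles; Harrell's
restricted truncated-power basis normalized by the squared outer-knot
span, giving exactly one nonlinear column. Curves are reported as odds
ratios against the weighted median of the exposure (configurable), with
pointwise CIs from the design covariance of the two-coefficient contrast.
The nonlinearity p is the Wald test of the cubic coefficient. One power
caveat discovered in testing and worth knowing: a threshold (step) effect
placed near the exposure median is nearly orthogonal to the single
restricted-cubic component and is detected weakly; off-centre
nonlinearity is detected reliably at n = 4000.

## Evaluation

AUC is the trapezoidal area of the ROC curve, identical to the
Mann–Whitney pair count with ties at 0.5 (scikit-learn computes the
curve; brute-force pair counting is the test oracle, including the
weight-product definition in the weighted variant). Decision-curve net
benefit is $TP/n - FP/n \cdot p_t/(1-p_t)$ over a 0.01–0.99 grid with
treat-all and treat-none references. Whether these should be
survey-weighted is genuinely ambiguous; the default is unweighted with a
weighted option. Model probabilities come from the fully-adjusted
(Model-3) fit per exposure by default; a crude single-exposure mode is
also implemented.

## The synthetic cohort generator

What it emulates: a stratified two-PSU-per-stratum design (15 × 2 by
default) with lognormal weights scaled to a configured pseudo-population;
latent biological age $B = CA + \Delta$, $\Delta \sim N(0, 9^2)$ years,
independent of CA ~ Uniform(40, 85); all 13 clock biomarkers as
independent-noise linear functions of $B$ (log-CRP simulated on the log
scale) with slopes and scatter resembling adult cross-sectional trends;
diabetes via a latent metabolic subpopulation whose glucose/HbA1c are
shifted upward and then *classified* by the same threshold rules applied
to real data; retinopathy only among DM, log-odds linear in $B$ with a
designed slope (default OR 1.11/year) plus configured covariate effects.
The DM and DR intercepts are fixed so that roughly one in five subjects
is diabetic and about 27% of them (≈ 5% of the cohort) have retinopathy,
the prevalence pattern of the study population this bench emulates. For
null-calibration experiments (`beta_latent = 0`) the DR intercept is set
to −1.0 so the DR prevalence among DM stays near that 27% rather than
collapsing.

A single seed feeds named substreams (design, covariates, latent,
biomarkers, dm, dr, missingness), so switching a later stage on or off
never perturbs earlier draws.

What it does **not** emulate, hence what passing tests do not show about
real data: NHANES nonresponse adjustment and weight construction
(weights are outcome-independent unless the stress-test flag is set);
correlated biomarker noise; measurement error structure in repeated BP
readings beyond simple iid noise; covariate marginals matched to any real
population; informative missingness (the missingness knobs are MCAR and
default to zero — the exclusion cascade is exercised by switching them
on). Recovery of the designed odds ratio here demonstrates the
correctness of the estimation machinery, not the substantive claim on any
real cohort.

## Problem sizes

Simulation-based checks use 200 replicate cohorts of n = 2000 for effect
recovery, 500 replicates of n = 1000 for null calibration, and single
cohorts of n = 1500–4000 elsewhere; these sizes give Monte-Carlo error
well inside the asserted bands while keeping the full test suite and the
acceptance script fast.

## Known limitations

* The variance estimator is with-replacement linearization only; BRR,
  jackknife and finite-population corrections are out of scope.
* Complete-case analysis only, mirroring the exclusion-cascade design; no
  imputation.
* No AUC confidence intervals or DeLong comparisons.
* Subgroup fits inherit the full Model-3 covariate list minus the
  stratifier; in small subgroups these fits are often flagged as
  degenerate rather than estimated, which is the intended behaviour.
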