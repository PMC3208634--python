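# Methods

This note records the modelling choices behind `sdinet`: what is assumed,
which defaults matter, what the synthetic cohorts do and do not emulate,
and where the design was genuinely open.

## Grading and the Spinal Deformity Index

A vertebra's deformity is summarised by its worst relative height loss
`c = max(1 − h_a/h_p, 1 − h_m/h_p, 1 − h_p/h_ref)`, where `h_a`, `h_m`,
`h_p` are the anterior, middle and posterior heights from six-point
morphometry and `h_ref` is the posterior height of adjacent vertebrae
(crush deformities compress all three heights, so the vertebra's own
posterior height cannot serve as its reference).  Grades follow the
semiquantitative bands: 0 below 20% compression, 1 mild (20–25%), 2
moderate (25–40%), 3 severe (>40%).

Two conventions had to be fixed:

* **Band ties.** The printed bands overlap at 25%.  We use the half-open
  convention c = 0.20 → 1, c = 0.25 → 2, c = 0.40 → 2, c > 0.40 → 3, with a
  1e-9 tolerance so that exact ratios such as 24/30 are not pushed across a
  boundary by floating-point rounding.
* **Vertebral span.** The SDI sum runs over the thirteen vertebrae T4–L4.
  (A span starting at T5 would contain only twelve; the sum formula and the
  count 13 are mutually consistent only for T4–L4, which is the span we
  implement.)
* **Crush reference.** Mean posterior height of the two neighbours where
  both exist; the single neighbour at the column ends.

Endpoints: `sdi1` contrasts SDI ≥ 1 against SDI = 0 and drops no one;
`sdi5` contrasts SDI ≥ 5 against SDI = 0 and excludes the intermediate
burden 1–4 from the contrast entirely.

## The 45-variable design

The data dictionary holds eight continuous variables (age, age at
menopause, years since menopause, BMI, calcium mg/day, pregnancies,
breast-feeding months, alcohol units/day), nine derived bins
(age < 68 / ≥ 68; BMI ≤ 21 / 21–30 / ≥ 30; YSM < 18 / ≥ 18; calcium
≤ 300 mg/day yes/no) and fourteen yes/no risk factors complement-coded as
pairs — 45 columns in total.  The published variable list enumerates 43
analysis rows; we reach the stated 45 by carrying the two collected
continuous sources of derived dichotomies (age at menopause and alcohol
units/day) as analysis columns in their own right.  Complement pairs always
sum to one, so a wrapper selector can pick either polarity without losing
information; upper bins are closed at their printed cutpoint (age 68 counts
as "≥ 68").

Records with any missing field are excluded, never imputed, and logged
with the names of their missing fields.  Continuous inputs to the network
are min-max scaled to [0, 1] using training-half extremes only, with test
values clipped — scaling is part of the trained model, so no test
information leaks into it.

## Synthetic cohorts

No patient-level data exist for this analysis, so the generator is a
first-class module, and its defaults are the study conditions:

* **Marginals.** Age ~ clamped normal (68.0, 8.5); age at menopause ~
  clamped normal (50, 4) on [35, 60]; YSM = age − age-at-menopause
  (preserving the strong age–YSM coupling and yielding the observed median
  ≈ 18, range ≈ 1–50); BMI ~ clamped normal (23.5, 3.5) on [16, 41];
  calcium ~ clamped normal (636, 404) truncated at zero — which already
  reproduces the ~20% prevalence of intake ≤ 300 mg/day.  Risk-factor
  prevalences are the published cohort values (hypertension 0.296, low BMD
  0.651, current smoking 0.153, …); current and former smoking are drawn
  from one categorical so they stay exclusive.  Pregnancies are Poisson(2)
  capped at 8; breast-feeding months a zero-inflated rounded lognormal;
  alcohol a mixture with 33.3% at ≥ 3 units/day, capped below the
  100 g/day exclusion bound.  Risk factors are conditionally independent
  given the liability: their mutual correlations were never published.
* **Fracture burden.** A two-stage hurdle.  Stage one draws fractured
  yes/no from `logit P = α + x'β` with β the published multivariable log
  odds ratios (YSM 1.07, previous fracture 1.28, hypertension 1.54, COPD
  2.63, calcium 1.00 per mg, low BMD 1.06, dyslipidemia-absence 2.21) and
  α = −2.245, calibrated once so the default covariate mix yields the
  clinic prevalence P(SDI ≥ 1) ≈ 0.473.  Stage two spreads the burden:
  conditional on fractured, each of the 13 vertebrae fractures with
  probability `sigmoid(η − 1.8)` (at least one forced), and fractured
  vertebrae draw grades from Multinomial(0.6, 0.3, 0.1) over 1–3.  The
  shift −1.8 puts P(SDI ≥ 5) ≈ 0.14 with a right tail past SDI 20,
  matching the clinic's burden distribution.

  The hurdle construction makes the configured odds ratios *exactly* the
  estimands of a logistic refit of the any-fracture endpoint.  A
  per-vertebra Bernoulli scheme with a logistic per-vertebra link would
  not have this property: marginalising "any of 13 fractures" through the
  complementary link distorts the patient-level coefficients by tens of
  percent at this prevalence, so calibration-recovery against the
  published odds ratios would test the link algebra rather than the
  estimator.  Severity still rises monotonically with the same liability,
  so higher-risk patients carry more and worse fractures.
* **What it does not emulate.** The liability is linear on the logit scale
  and covariates are independent given it.  Real cohorts carry correlated
  risk factors and (plausibly) interactions — which is exactly where a
  neural classifier can beat a main-effects logistic model.  Consequently,
  on default synthetic cohorts the two pipeline arms perform similarly,
  and the superiority of the network arm is demonstrated only on
  constructions with planted nonlinearity (XOR-type interaction tests).
  Passing tests therefore validate the machinery and calibration, not any
  claim about real patients.
* Heights synthesised from grades keep each compression strictly inside
  its band and share the posterior height within a column, making
  regrade-the-heights an exact round trip.

All randomness flows from one master seed through named substreams, so any
stage can be re-run in isolation bit-for-bit.

## Evolutionary selection

The proprietary optimiser the original analysis used is not published
operator-by-operator; we implement a standard generational GA and document
it as this package's design: tournament selection (k = 3), uniform
crossover (rate 0.9), bit-flip mutation at 1/L per bit-string, 2 elites,
and a doping step replacing 5% of each offspring generation with random
immigrants.  Defaults: population 50, 100 generations, stagnation patience
20.  The split and the mask live on one chromosome (joint mode, default);
a sequential mode (balance the split first, then select inputs on the
frozen split) is available because the original description is ambiguous
about the coupling.  Split repair keeps both halves within ±10% of n/2
with both classes present, stratified within class.

Fitness = mean of the two crosswise balanced test accuracies − λ × the
distribution penalty, λ = 0.5 by default.  The published description names
both goals (balanced-density halves; maximal transferable information) but
not their coupling; a single weighted objective is the simplest faithful
reading, and λ = 0 recovers pure accuracy.  The exact fitness the original
system optimised is likewise unpublished; balanced accuracy matches the
study's own headline metric.  Inner networks train with a reduced budget
(100 epochs) for tractability; chromosome fitness is cached by genome, so
elites are never re-trained.

## The network

Sigmoid MLP with 4 hidden units, full-batch gradient descent with momentum
on SSE (cross-entropy optional), defaults lr 0.1, momentum 0.9, 500
epochs, early stop after 25 epochs without improvement, init uniform
(−0.5, 0.5).  None of these training constants were published; all are
configurable.  Scores of exactly 0.5 classify as 0 (the 0–0.5 / 0.51–1
rule).  Divergence (non-finite loss or weights) raises rather than
returning garbage.

## Logistic baseline

IRLS with step-halving, asserting per-iteration monotone log-likelihood;
Wald CIs `exp(β ± 1.96·SE)`.  Quasi-separation is flagged (|β| > 15) and
the fit marked non-converged rather than penalised (no Firth correction —
a possible extension).  Singular designs raise an error naming the
collinear terms — necessary because the full 45-column design contains
exact complement pairs, which stepwise simply skips.  Entry/removal use
likelihood-ratio tests (the conventional "forward: LR" choice; the
original analysis does not say Wald vs score vs LR) at the study's printed
α-enter 0.3 / α-stay 0.35 — implemented verbatim despite the unusual
ordering; since α-enter ≤ α-stay the procedure cannot cycle, and a
visited-state guard protects arbitrary user thresholds.  Ties in entry p
break lexicographically, making the result order-invariant up to exact
ties.

## Evaluation conventions

* **Overall accuracy** is (SN + SP)/2.  This is forced by the published
  fold arithmetic (72.5/78.5 → 75.5; 74.8/87.8 → 81.3; 37.3/90.3 → 63.8);
  the raw proportion correct is kept as a secondary field.
* **ROC/AUC** empirical over all thresholds, trapezoid area, ties → 1/2;
  verified equal to Mann–Whitney pair counting.
* **Correlated AUCs**: Hanley–McNeil SE with Q1 = A/(2−A),
  Q2 = 2A²/(1+A); paired correlation r = mean of the within-case and
  within-control Pearson correlations of the two score vectors (the
  original citation leaves the r estimator as a table lookup; the
  correlation average is the standard reading).
* **5×2 CV**: five stratified halvings; each repeat trains on one half
  with frozen weights tested on the other, then reverses.  The report AUC
  is the mean of the five per-repeat AUCs computed on each repeat's pooled
  out-of-sample scores; its CI uses the Hanley SE at the full sample's
  group sizes.  Both arms can share partitions for paired comparison.
* **Fold homogeneity**: goodness-of-fit chi-square of per-fold
  correct/incorrect counts against the pooled rate (df = folds − 1).  The
  published footnote does not define its statistic precisely; this is one
  reasonable reading and is flagged as such.
* **Group comparisons**: KS normality gate at α = 0.05 per group
  (plain KS, not Lilliefors) choosing t-test vs Mann–Whitney and the
  mean±SD vs median (range) summary; 2×2 factors use the Yates-corrected
  chi-square — which reproduces the published hypertension p = 0.017,
  where the uncorrected test gives 0.013.  Plain Pearson and Fisher exact
  are available by option (one published p-value, anxiety/depression
  0.048, is not reproduced by any of the three on the printed counts and
  is left as a documented discrepancy).
* Report percentages round to 1 decimal and p-values to 3, halves away
  from zero, to match the tables' style.

## Problem sizes

Defaults mirror the study (372 patients, 45 variables, 5×2 CV).  The test
suite exercises the GA at reduced sizes (population 8–16, ≤ 15
generations, 25–60-epoch inner networks) chosen as the smallest
configurations at which the selection behaviour under test (planted-signal
recovery, elitism, determinism) is stable; calibration recovery runs at
n = 50,000, where the sampling SE of the recovered YSM odds ratio is ~0.001,
an order of magnitude below the ±0.01 acceptance band.

## Known limitations

* The evolutionary optimiser is an approximation of an unpublished
  proprietary algorithm; only its published outline (genetic algorithm,
  doping, twin-classifier crossover fitness) is preserved.
* No real-data parity is claimed for the headline classification numbers
  (sensitivity/specificity/AUC): the patient data were never deposited,
  and published AUC confidence intervals are narrower than Hanley's SE
  implies for the stated group sizes, so the CI method is configurable and
  no CI parity is asserted either.
* The SDI label columns of the published variable list are treated purely
  as targets, never as inputs.
* Missingness in the generator is injected completely at random; the
  complete-case filter is therefore unbiased by construction, which real
  clinic data would not guarantee.
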