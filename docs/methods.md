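# Methods

This note documents the models, rules and numerical choices behind the
`ednt` package: a pipeline for scoring and modeling two reaction-time
markers of cognitive control in the emotional day-night task (EDNT) —
post-error slowing (PES, reactive control) and delayed disinhibition
(DD, proactive control).

## Task structure

The EDNT crosses two stimulus categories (sun/"day", moon/"night") with
three face types (happy, angry, neutral), giving six stimuli.  Each
block presents every stimulus six times (36 trials; 18 per category).
A per-block NoGo rule withholds responses to one face type in the child
variant (12 NoGo trials/block) or to one specific stimulus in the adult
variant (6 NoGo trials/block).  The child task has 4 blocks (3
congruent + 1 with the response mapping reversed); the adult task has
12 (6 + 6).  Scoring uses blocks 2 onward — the first block has no
preceding rule, so DD is undefined there — leaving at most 72 child and
330 adult Go trials.

Two details of the task are not fully determined by its published
description and are configurable here:

* **Rule repetition.** `forbid_repeat_nogo=True` by default: consecutive
  blocks never share a NoGo rule.  Under no-repeat rules an error-free
  child has a PI proportion of exactly .5 and an adult .2; observed
  child/adult PI proportions (~.43/~.18) sit near these values and far
  from the with-repeat expectations (1/3, 1/6), so no-repeat is the
  default.
* **Child response deadline.** Unpublished; 4000 ms is used, which
  comfortably exceeds the slowest observed child mean RTs (~2.7 s).
  The adult deadline is the task's 2000 ms stimulus timeout.

## Trial classification

* **PE/NPE** — a trial is post-error when the immediately preceding
  trial in the same block was an error: an incorrect Go (wrong key or
  omission) or a responded NoGo.  Lookback does not cross block
  boundaries by default (blocks are separated by instruction screens),
  so each block's first trial is NPE; `pe_lookback_across_blocks`
  enables carryover.
* **PI/NPI** — a Go trial in block b ≥ 2 is previously inhibited when
  its stimulus was covered by block b−1's NoGo rule (face type for
  children, exact stimulus for adults).  Congruency never enters this
  classification: incongruent blocks change only the response mapping.

Labels are a function of the raw sequence only; RT filtering never
relabels trials.

## Screening and RT filters

Subjects are excluded when their correct-Go rate over the whole task
falls below 50% (chance), or when blocks are missing.  A subject with
no post-error trials keeps their DD but has no PES (they drop from PES
modeling only, by casewise deletion).

Correct-Go RTs pass two filters: (1) RT < 150 ms removed (below the
visual perceptual floor); (2) RT > mean + 3·SD removed, with mean and
sample SD (ddof = 1) computed per subject over the correct-Go RTs
surviving stage 1.  The trim is upper-tail only, single-pass, and by
default pooled over all blocks (a `post_block1` scope and a two-sided
variant are available as switches).  A single extreme RT among n−1
identical ones has z = (n−1)/√n, so such an outlier escapes a 3-SD trim
for n ≤ 10 and is removed for n ≥ 11 — masking by self-inflation of the
SD is a property of the rule, not a defect of the implementation.

## Effect scoring and reliability

PES = mean RT over kept PE trials − mean over kept NPE trials; DD =
mean over PI − mean over NPI, both in ms.  An empty condition cell
makes the effect missing, never zero.  Both scores are invariant to
adding a constant to all of a subject's RTs.

Odd-even split-half reliability assigns parity **within each condition
cell** (ranked by task order), so both halves contain every condition
whenever a cell has ≥ 2 trials; splitting over the raw stream would
let small cells land entirely in one half.  Reliability is the raw
Pearson correlation between half effects across subjects, without
Spearman-Brown correction.

## Inference

Per outcome, three nested OLS models on the subject-level scores:

1. intercept only — identical to the sample mean and one-sample t-test;
2. \+ matched condition proportion (PE prop for PES, PI prop for DD),
   Raven score, sex (0 = male, 1 = female), age;
3. \+ sex×Raven and sex×age.

Age and Raven are z-scored (sample SD) over the modeled subset; the
condition proportions are mean-centered but not rescaled, keeping the
intercept interpretable as the grand effect at average proportions (a
`standardize_props` switch rescales them).  Casewise deletion is
applied once over the largest model's columns so all three fits share
the same n and the nested F tests (on residual sums of squares) are
valid.  For the adult (mothers) sample, sex is constant, so only models
1–2 are fitted, without interaction terms.

Simple slopes: boys' age slope is the age coefficient; girls' adds the
sex×age coefficient; variances come from the coefficient covariance and
the test is F(1, df_resid) = (slope/SE)².

The region of significance evaluates the model-implied effect ŷ(age)
for each sex (other covariates at their centered means) with pointwise
95% CIs.  Two boundaries are reported: the continuous Johnson–Neyman
root of ŷ² = t²·Var(ŷ) (a quadratic in standardized age), and the first
month on a monthly grid whose CI excludes zero.  The grid month is the
headline number — ages are recorded in whole months, and a boundary
quoted with a non-zero CI lower bound is a grid-style statement — while
the continuous root serves as a cross-check (the two agree to within
one grid step whenever the onset is interior to the age range).

Zero-order correlations (Pearson, with a Spearman variant) use pairwise
deletion; Benjamini–Hochberg adjustment is applied once across the
unique off-diagonal p-values of each table.

The SES factor is a one-factor maximum-likelihood factor analysis of
four standardized indicators (mother education years, household income,
rooms, cars) with Thomson regression-method scores, oriented so income
loads positively; Heywood cases are clipped to |λ| ≤ 1 and flagged.
The factor model is fitted with scikit-learn's ML `FactorAnalysis`.

Sample-size planning inverts the power of the fixed-model multiple
regression F test: f² = R²/(1−R²), the alternative statistic is
noncentral F(u, N−u−1) with λ = f²·N, and the smallest N with power ≥
the target is returned.  The implementation reproduces standard
G*Power solutions (f² = .15, u = 6 → N = 98; f² = .35 → N = 46).  For
R² = .10, u = 6, α = .05, power = .80 it yields N = 130.

## Synthetic cohorts

The generator produces subjects with known ("true") effects so the
pipeline can be validated by parameter recovery:

* true PES and DD are linear in sex, standardized age and their
  product, plus Gaussian noise;
* Raven raw scores link to age through a linear-Gaussian draw
  calibrated to a target correlation (default .37), rounded and clipped
  to 0–36;
* errors are trialwise-independent Bernoulli events with
  Beta-distributed per-subject rates (child defaults: Go error mean
  .10, NoGo false-alarm mean .35; adults lower), Go errors split evenly
  between wrong key and omission;
* Go RT = base RT + PES·[previous trial in block was an error] +
  DD·[stimulus previously inhibited] + optional congruency cost +
  noise, truncated into (150 ms, deadline].  Noise is lognormal with
  matched mean/SD by default (RTs are right-skewed); a normal family
  exists for algebraic tests.

Default child scales follow the sample this analysis targets: n = 155,
~51% boys, ages 43–70 months, base RT ~ N(1676, 305²) ms, true effect
scales PES ≈ N(217 + 48·sex + 33·age_z, 374²) and DD ≈ N(23 + 76·sex −
8·age_z + 63·sex·age_z, 185²) ms.  Trial-level noise defaults to 700 ms
SD for children (280 ms for adults): with ~60 kept trials and the cell
sizes the task yields, this reproduces the weak split-half
reliabilities characteristic of preschool difference scores (DD ≈
.2–.4) together with the observed marginal effect SDs; smaller noise
values produce implausibly reliable scores.  The adult defaults mirror
the mothers' scale (n = 174, grand PES ≈ 138 ms, DD ≈ 33 ms, far less
spread).

What the generator does **not** emulate: sequential error dependence,
conflict adaptation, fatigue/practice drifts, emotional-valence effects
of the faces, or heavy-tailed contaminant RTs.  Passing recovery tests
therefore shows the pipeline is correct and calibrated under an
idealized but scale-matched data-generating process — not that real
data meet those assumptions.

## Monte-Carlo validation

The calibration harness simulates complete studies end to end.  Problem
sizes were chosen to keep the full suite comfortably under typical CI
budgets while retaining statistical resolution: 400 recovery replicates
at n = 154 (true grand PES 238 ms, DD 58 ms, SDs 374/185, sex×age DD
interaction 62.6 ms) for CI coverage and interaction bias, and 1200
null replicates for type-I calibration.  Targets: empty-model 95% CI
coverage in 93–97%, unbiased interaction recovery within Monte-Carlo
error, and null rejection rates in 4–6%.

One calibration property is worth knowing: under the lognormal noise
default, the PES score of a null subject is the mean of a handful of
right-skewed draws minus the mean of many, so the per-subject score
distribution is itself right-skewed and the two-tailed one-sample t
rejects nulls slightly above nominal (the suite measures ≈6.3% at
n = 154 for PES, vs ≈4.4% for DD, whose cells are more balanced; with
normal trial noise both sit at ≈4–5%).  This is a property of
small-cell difference scores, not of the implementation, and it
implies mildly anticonservative PES intercept tests in data with
skewed RTs and low error counts.

## Known limitations

* PES here is the classic difference score; robust pairings (e.g.,
  pre/post-error matching) are out of scope.
* The 3-SD rule is one interpretation of an under-specified filter;
  switches expose the main alternatives (scope, sidedness) but
  iterative trimming is deliberately not implemented.
* The Johnson–Neyman machinery assumes the model-3 parameterization
  (sex-coded 0/1 moderated by standardized age).
* Factor scores from a single factor with four indicators are noisy;
  they are intended as a covariate screen, not a precise SES measure.
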