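# Methods

## Model and procedure

The package analyses drug response in a longitudinal trial where
subjects start a *primary medication* at individual times and take
other medications concurrently. The response for subject *i* is the
phenotype change over their *treatment window*:

- window start = first monthly-log day of the primary medication (or
  any member of its class) in-trial;
- pre-treatment value = latest phenotype measurement with
  `start − pre_lookback ≤ day ≤ start` (a same-day draw counts as
  pre-treatment, since the measurement precedes any pharmacological
  effect of that day's dose);
- post-treatment value = earliest measurement with
  `min_days ≤ day − start ≤ max_days`.

Defaults are `min_days=90`, `max_days=270`, `pre_lookback=30` (days),
appropriate for a slow phenotype such as HbA1c, which needs roughly 90
days of red-cell turnover to reflect a treatment change; a 90–120 day
window suits faster phenotypes such as LDL and is available through
`WindowParams`.

The response is modelled by OLS, `y = β₀ + Σ βⱼxⱼ + ε`, with
co-medication exposure entering as categorical trajectory scores
dummy-coded against referent 0.

## Compliance and imputation

Per-visit compliance is a four-level code (1: 80–100%, 2: 1–79%,
3: 0%, 4: more than prescribed). Code 4 is treated as full compliance.
Missing codes are imputed by **next observation carried backward**:
compliance recorded at a visit describes the interval *since the
previous visit*, so the later record is the informative one for a
missing interval. Trailing gaps, which have no later observation, fall
back to last-observation-carried-forward; this package-level choice
preserves subjects with a single trailing missing visit rather than
discarding them, and such sequences are flagged in the log. A sequence
that is entirely missing is returned unchanged and flagged.

Cohort inclusion requires full compliance (codes 1/4 after imputation)
at ≥ 80% of the medication's in-window records and no code-3 record.
The 80% denominator counts the medication's own records within the
window; whether a trial's convention counts visits or medication
records is extract-specific, and records-within-window is the
operational choice here.

## Exclusion filters

Reasons are evaluated in a documented order (inconsistent records,
never on, on at baseline, insufficient duration, stop–restart, zero
compliance, low compliance, missing phenotype) but membership is
order-insensitive: every applicable reason is recorded for each
excluded subject, and the tally counts subjects per reason. Specific
operationalizations:

- **on at baseline** — a monthly record at day 0 or an annual record
  with the class on-flag at day ≤ 0. These subjects have no
  pre-treatment phenotype and cannot contribute a response.
- **insufficient duration** — last record of the medication earlier
  than `start + min_days`.
- **stop–restart** — at visit granularity, one or more attended visits
  (any medication logged) inside the window with no record of the
  medication, followed by a later visit with one. The gap tolerance is
  configurable; the default (zero skipped visits tolerated) is the
  strictest reading.

## Trajectory scores

The monthly 0–4 score is a pure function of the medication's records
relative to the subject's *primary-medication* window:

- *on at start* — any record (monthly, or annual class on-flag) at or
  before the window start;
- *persisted* — last in-window record within `persistence_grace_days`
  (default 30, one visit interval) of `start + max_days`, **and** the
  medication's own in-window compliance passes the 80% rule with no
  code-3 record.

Never recorded → 0; on at start and not persisted → 1; started in
window and not persisted → 2; started in window and persisted → 3; on
at start and persisted → 4. A medication carried to the window end but
failing its compliance requirement is scored as stopped (1 or 2): the
five-level scheme has no other slot, and the compliant-to-end scores
explicitly require compliance.

Drug classes are scored on the union of their members' record days
(per-visit ties resolved to the most compliant code); annual-only
medications score 1 if the most recent annual record at or before the
window start shows use, 0 otherwise, with a separate *not scorable*
flag when no annual record exists at all (kept at referent 0 in models
by default). Insulin, recorded as a continuous dose, is summarized as
(mean units/day over records in `[start+min_days, start+max_days]`)
minus (most recent units/day at or before start, 0 if none); a
pre-start user with no in-window records scores minus the pre-start
dose. The delta convention is a package choice — only "change in daily
units" is externally specified — and is configurable.

## Screening

Relating response to "days on" each co-medication requires a grouping
for a two-sample test; the package dichotomizes at days-on > 0
(ever vs never) computed over the whole trial record by the
inter-visit-interval convention (an interval counts when its earlier
visit has a record; a record at the final visit adds nothing). The
rank-sum test uses an exact permutation p-value when the smaller group
has ≤ 8 observations and no ties, otherwise the normal approximation
with tie and continuity corrections. FDR control is Benjamini–Hochberg
step-up — the conventional default where only "an FDR-controlling
procedure" is specified. The screen is deliberately permissive
(univariate, accepts false positives); model selection downstream is
the arbiter.

## Model selection

- Continuous covariates are standardized by default (configurable);
  indicators and dummies are left alone.
- Complete-case rule: rows with any missing covariate are dropped with
  a logged count.
- Collinearity: pairwise Pearson |r| over selectable units (dummy
  groups summarized by the raw 0–4 score), iteratively dropping the
  member of the worst offending pair whose |correlation| with the
  outcome is weaker, until no pair exceeds the 0.5 threshold. Forced
  units are never dropped; two forced units above threshold are kept
  with a warning. Which member of a pair the original analyses dropped
  is not externally specified; the weaker-outcome-correlation rule is
  this package's deterministic substitute.
- Backward elimination: dummy groups move **en bloc** (published score
  tables retain all four levels of a medication together, implying
  block treatment). At each step the non-forced unit whose removal
  lowers BIC most is removed (ties broken lexicographically); the
  procedure stops when no removal lowers BIC, so the trace is strictly
  decreasing and the result is deterministic.
- BIC uses the Gaussian profile form `n·ln(rss/n) + (k+1)·ln(n)`,
  counting the error variance as a parameter. Only within-run
  differences are compared, so the additive convention is arbitrary but
  fixed.
- `fit_linear` refuses rank-deficient designs (naming the dependent
  columns) rather than pseudo-inverting, and refuses exact fits
  (rss below 1e−12 relative) where BIC is undefined.

## Genetics

Dosages live in [0, 2] with missing allowed. MAF is the folded mean
dosage over non-missing entries; SNPs below 3% are removed. PCA runs on
the column-standardized, mean-imputed dosage matrix via SVD, components
ordered by variance explained with each component's largest-magnitude
SNP loading made positive (a deterministic sign convention). Scans drop
subjects with missing dosage per SNP and surface rank-deficient
(e.g. monomorphic) SNPs as NA rows with a warning rather than failing
the scan.

The paired bootstrap resamples **subjects** with replacement and refits
both models — with and without the confounder score group — on the
same resample, preserving the paired structure; 95% CIs are percentile
(2.5/97.5) intervals, the simplest faithful default. The t-test between
the two B-length bootstrap distributions is implemented exactly as
described even though its null calibration is nonstandard (bootstrap
draws are not independent observations, so its p-value is a descriptive
contrast, not a calibrated test); the CI-overlap rule is the primary
criterion. Rank-deficient resamples are redrawn (max 10 retries);
B < 100 is refused.

## Synthetic-trial generator

`simulate_trial` emulates: monthly visits every 30 days over a
1460-day trial; a primary medication with a start-time mixture (30%
never, 25% already on at baseline, the rest starting uniformly over
eligible visits, with 2% insufficient-duration and 5% stop–restart
trajectories); co-medications with baseline-use probabilities, start
and stop hazards; the four-level compliance process (default code
probabilities 0.92/0.04/0.01/0.03, 10% missing); annual class records;
a small inconsistent-records fault rate (0.1%); 83% genetic-consent
rate; and independent SNPs with a designated causal variant
(frequency 0.3).

The confounding pathway is genotype → pre-phenotype → prescription →
response: the causal SNP shifts the pre-treatment phenotype by
`gamma_g` per allele; baseline use of the confounder co-medication
follows a logistic in the standardized pre-phenotype with slope
`link_lambda`, its intercept calibrated by bisection to the target
marginal probability (0.6 for the statin-like confounder); the
response is the primary effect plus per-score co-medication effects
plus an optional direct SNP effect plus Gaussian noise. Main-effect
adjustment attenuates the SNP coefficient precisely because the
pathway operates through the score's main effect — a genotype×score
interaction alone would not be corrected this way.

Demonstration conditions (`confounding_config`): every subject starts
the primary in-trial with clean compliance and phenotypes,
`beta_direct = 0`, `gamma_g = 0.8`, `link_lambda = 3.0`, statin score
effects (−0.3, −0.45, −1.2, −1.5) for scores 1–4 and noise sd 0.8.
These values were chosen once so that the marginal SNP bias
(≈ −0.25 phenotype units per allele at n = 2000) clearly exceeds the
bootstrap CI widths (≈ ±0.08), making the qualitative
attenuation-with-separated-CIs property reproducible replicate by
replicate rather than borderline.

What the generator does **not** emulate: linkage disequilibrium
(SNPs are independent), realistic covariate correlation structure,
visit-schedule irregularity, dose titration for non-insulin drugs, or
informative missingness. Passing tests therefore demonstrate the
pipeline's internal correctness and the confounding mechanism, not
performance on any real trial's quirks.

`truth_scores` re-derives each subject's expected trajectory score
from the latent start/stop/compliance draws through an independent
code path; on noiseless-compliance configurations the production
scorer must (and does) match it exactly for every subject.

Randomness flows through one seeded `numpy` generator with named
substreams per component, so changing one component's parameters does
not perturb the draws of another.

## Problem sizes used in the test suite

Scoring-oracle equivalence runs at n = 2000 subjects; selection
recovery at n = 500 with effect 1.0 sd over 100 replicates; screening
calibration over 200 null replicates of n = 120; the confounding
demonstration at n = 2000 with B = 1000 bootstrap resamples over 100
replicates; scan CI coverage at n = 1000 over 100 replicates. These
sizes make the binomial success criteria (e.g. ≥ 95/100) sharp while
keeping the full suite to a few minutes on one core.

## Known limitations

- The treatment window end for persistence is `start + max_days`, not
  the subject's actual post-measurement day; a subject measured at day
  100 must still carry the co-medication to day 270 to score 3/4. This
  matches the "exact time points established for the primary
  medication" reading but is configurable disagreement territory.
- The ever/never dichotomy in screening discards dose–duration
  information; a rank-correlation screen would use it but has no
  two-sample exact small-sample theory.
- Percentile bootstrap CIs can undercover for skewed coefficient
  distributions; BCa would be the next refinement.
- The day-offset time convention assumes the caller has already
  anchored calendar dates to randomization day 0.
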