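# Methods

This note documents the models, parameter choices and numerical conventions
behind `fairdem`, in the spirit of a statistical software appendix.  It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## 1. Synthetic cohort model

No individual-level data from the populations this audit design targets are
publicly available, so the package's first-class input is a seeded
generator (`fairdem.synthetic`) that emulates their *published aggregate*
structure.  A generated person carries sex, birth date, a 2004–2020 record
span, an optional dementia-onset date, three raw SES measure values, and a
visit history with per-visit diagnosis-category sets.

**Outcome and demographics.** Case status is Bernoulli with configurable
prevalence: 0.375 for the population archetype (default) and 0.223 for the
research-panel preset, the approximate case shares of the two cohort types
the audit is designed around.  Sex is Bernoulli (female fraction 0.57 /
0.485 by archetype).  Age at the anchor date is drawn from a binned
distribution concentrated in the 75–94 range, matching the age structure of
incident-dementia cohorts; onset dates fall at least six years after the
first record so cases always have a full observation window.

**SES measures and concordance.** Three correlated latent standard-normal
deprivation factors are sampled per person and mapped to native measure
scales: a 0–100 housing-index percentile (bottom quartile of the reference
population = low SES; cut fixed at 25), a 0–100 national deprivation
percentile (≥ 76 = low), and a 1–10 state decile (≥ 8 = low).  The scale
anchors are chosen so the configured low-SES marginals (0.21, 0.05, 0.27)
are hit exactly in expectation.  Pairwise latent correlations are solved
from the configured concordance targets by inverting the bivariate-normal
orthant probability (Brent's method); the resulting 3×3 correlation matrix
is checked for positive semidefiniteness and jointly infeasible targets
raise an explicit error.  Default targets: 12% of housing-index-low persons
are also national-low, 40% are state-low, reproducing the limited
cross-measure overlap reported for real deprivation indices.  (A
single-factor loading parameterization was considered but cannot reach an
arbitrary feasible target triple; solving the pairwise correlations
directly keeps the same feasibility contract with more generality.)

**Visit process.** Per calendar year, an "any visit" gate is followed by a
truncated-Poisson visit count implemented as `1 + Poisson(λ−1)` (exact mean
λ, support ≥ 1; for λ < 1 the count degenerates to one visit).  λ depends
on case status (population archetype: 15.24/11.16 visits per year for
cases/controls, i.e. ≈ 76 vs ≈ 56 per 5-year window; research panel:
18.66/15.9, ≈ 93 vs ≈ 80).  The gate probability is *calibrated*: the
configured `empty_year_prob` (0.024 high-SES / 0.034 low-SES per year,
i.e. 0.12 vs 0.17 missed years per 5-year window) is the target for the
**observed** anniversary-aligned empty-window-year rate.  Because feature
windows are anchored to the index date while the gate operates on calendar
years, one window year straddles two gated years; the calibration inverts
the closed-form phase-averaged emptiness probability so the downstream
missed-years statistic recovers the configured values (verified at
n = 10,000 in the test suite).

**Diagnosis categories and SES degradation.** Each visit records category
`c` with a per-visit probability calibrated (Brent's method on the
closed-form five-year window-prevalence expression, including the SES mix,
the empty-year gates, and dropout) so that the *population-level* fraction
of patients with ≥ 1 window visit carrying `c` matches the configured
case/control prevalence targets.  Defaults give the leading categories the
published prevalence pairs of the two cohort archetypes (population:
0.762/0.670 and 0.613/0.384; research panel: 0.854/0.784 and 0.700/0.546)
with a geometrically declining tail at a constant case/control uplift.
Low SES degrades **data completeness only**: a higher empty-year
probability and a recording-dropout probability (`ses_signal_strength`,
default 0.30) that thins each recorded category instance.  True outcome
prevalence is identical across SES groups — the generator encodes the
data-completeness explanation for subgroup performance gaps, not a
biological one.

**What the generator does not emulate.** Real ICD code strings (categories
are emitted directly; the mapping stage is exercised with toy fixtures),
geographic clustering of deprivation, informative care-seeking dynamics,
label noise from socioeconomically differential diagnosis ascertainment,
and temporal drift.  Passing tests therefore demonstrate that the audit
machinery detects and mitigates *completeness-driven* bias under this
generative model; they do not certify behavior on real EHR extracts.

## 2. Cohort construction

Case index = onset date minus the prediction window (1 year), computed as a
calendar anniversary (Feb 29 clamps to Feb 28).  Cases younger than 50 at
the incident date are excluded (`age_lt_min`).  Controls draw a target age
from the eligible cases' empirical age histogram (10-year bins anchored at
45, matching conventional reporting bins) and invert it to an index date,
rejection-sampling (≤ 50 rounds) against record-span feasibility: the full
observation window and at least one prediction window of follow-up must lie
inside the record span.  Controls with no feasible draw are excluded
(`insufficient_followup`).  Any member without a visit in the half-open
observation window `[index − 5y, index)` is excluded
(`no_observation_record`).  Each excluded member carries exactly one
primary reason; ledger counts sum to input minus eligible.

Design choices worth flagging: frequency matching is per-control histogram
draw (not per-stratum quota), the control:case ratio defaults to "all
eligible" since the two archetypes differ (≈ 1.7:1 vs ≈ 3.5:1), and the
bottom-quartile SES rule uses a fixed reference-population threshold by
default (the convention for housing-based indices, and the reason observed
cohort low-SES shares sit near 21% rather than 25%) with an
empirical-quantile fallback computed on the eligible cohort.

## 3. Features

For each eligible member, five annual blocks of category counts over
anniversary-aligned half-open yearly windows (block 1 = most recent), one
hot per *unique* category per visit (a category listed twice in one visit
counts once), plus sex (0 = M, 1 = F), age in completed years at index, and
five binary no-visit flags (set iff the year contains no visit at all,
whether or not any code mapped).  A visit on the index date itself
contributes nothing.  Unknown diagnosis codes are dropped with a logged
count, never an error.  Feature length is `5·C + 2 + 5`; the column order
is persisted in a JSON manifest so downstream stages agree bit-exactly.

## 4. Models

Stratified seeded 70/30 split.  Hyperparameters are chosen by 5-fold
stratified cross-validation maximizing balanced accuracy (= 1 − BER),
aligning tuning with the audit metric, then refit on the full training
partition.  Default grids: forest — 200/500 trees × depth ∅/10; logistic —
L2 strength over 5 log-spaced values; SVM — RBF, cost over 4 log-spaced
values, kernel width "scale"; Gaussian naive Bayes — variance smoothing
over 3 values.  A `fast` preset pins each family to a single grid point
(200 trees/∅, C = 1, C = 1/scale, 1e−9) for simulation sweeps.  Continuous
features are z-scored inside the estimator pipeline for the scale-sensitive
families and left raw for the forest, so standardization parameters are fit
on training rows only by construction.  Hard labels use the 0.5 probability
threshold (decision-function sign for the SVM).

## 5. Audit

Subgroup metrics are computed for six strata per measure (M/F/pooled ×
high/low).  Pooled-sex metrics come from pooled confusion counts — the
pooled BER is *not* the mean of per-sex BERs.  Uncertainty: B = 1000
within-subgroup bootstrap resamples of equal size; percentile 95% CI
(BCa was not used; the percentile construction is the simplest consistent
with reporting "the distribution of the bootstrap BERs").  Resamples
missing an outcome class are redrawn with bounded retries and the redraw
count logged; strata whose point sample misses a class are reported as
undefined with their counts, never dropped.

Pairwise comparisons (low vs high within each sex stratum, plus each
subgroup against the male/high-SES baseline) use a two-tailed two-sample
t test on the bootstrap replicate vectors, with Levene's test (center =
mean, α = 0.05) gating Welch vs the pooled-variance form.  The replicate
vectors are the only sampling unit consistent with testing subgroup BERs
"independently"; since bootstrap replicates are not independent draws,
nominal significance is inflated — the construction is reported as-is
rather than hidden.  All p-values are pooled per model and
Benjamini-Hochberg-corrected at FDR 0.05 (via `statsmodels`, property-
tested against the brute-force step-up definition); baseline direction
flags are reported only where the adjusted decision is significant, gated
on the same per-model family.  Disparity summaries use
`(BER_low − BER_high)/BER_high`, and clinical burden uses
`round((BER_b − BER_a) · n_per_group)` excess misclassifications.

## 6. Mitigation

The SMOTE-NC sampler is implemented from first principles.  Distance
between mixed rows: `sqrt(Σ continuous diffs² + (#nominal mismatches) ·
med²)` with `med` the median of the minority cell's continuous-feature
standard deviations (population convention, ddof = 0).  Nearest-neighbor
search embeds nominal columns (binary scaled by `med`, multi-valued one-hot
scaled by `med/√2`) so Euclidean k-NN reproduces the mixed distance
exactly; tests cross-check both routes against a brute-force oracle.
A synthetic row interpolates the continuous block toward one of the seed
row's k = 5 nearest within-cell neighbors with Uniform(0,1) fraction and
takes nominal entries by majority vote among the k neighbors (ties toward
the lowest value); sampler seed defaults to 42.  Balancing targets: the
low-SES total is raised to the high-SES total, split across (low-SES ×
outcome) cells so the low-SES case fraction is preserved to within one
sample.  Cells smaller than k + 1 reduce k with a warning; single-row or
empty cells raise an explicit infeasibility error.  Annual counts and age
are continuous (synthetic counts are left un-rounded; models consume
reals); sex and the no-visit flags are nominal.  Synthetic rows inherit the
dichotomized SES label only, are flagged in the output, and never enter the
test partition.  Rows are processed in sorted identifier order so results
are independent of input row order.

## 7. Problem sizes used by the test suite

The package's property checks run at desk scale, chosen as the sizes at
which the targeted effects are comfortably resolvable: marginal/concordance
/prevalence recovery at n = 10,000; bias recovery at n = 6,000 across 12
seeds × 4 families with the `fast` grid preset (the low-SES pooled BER must
exceed the high-SES one in ≥ 90% of runs); mitigation at n = 4,000 across
9 seeds with logistic regression (balancing on a measure must shrink the
absolute relative BER difference on that measure in a majority of seeds,
with the parity and ratio invariants holding exactly on every run); null
calibration at n = 2,000 with 60-seed bootstrap-coverage checks.  Oracle
equivalences (BER vs per-class error enumeration, BH vs step-up, mixed
distance vs brute force) run exhaustively at small n plus seeded random
sampling.

## 8. Known limitations

* The generator's SES degradation is a two-knob completeness model; real
  SES gradients also act through utilization patterns, coding practice and
  ascertainment, which are out of scope.
* The t-test-on-replicates construction overstates significance; treat
  flags as descriptive orderings, not calibrated inference.
* Percentile bootstrap CIs undercover slightly for very small strata.
* No cross-cohort or temporal validation, no probability calibration, and
  no fairness criteria beyond balanced-error parity (equalized odds,
  within-group calibration etc. are deliberately out of scope).
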