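# Methods

This note documents the modelling choices behind `dsindex`: the index
itself, the evaluation design, the synthetic-data generator, and the
numerical conventions that make results reproducible.

## The Disease State Index

The DSI scores a subject's similarity to the case class on [0, 1] by
recursively averaging per-factor *fitness* values weighted by *relevance*.

### Fitness curves

For a quantitative factor, every distinct observed training value is used
as a classification threshold t. Under the fitted orientation
(`cases_high`: call a case when value ≥ t; `cases_low` mirrored, with the
threshold value itself always on the case side), the fitness at t is
FN(t) / (FN(t) + FP(t)). This rises from 0 on the control side of the
distribution to 1 on the case side.

Two conventions are ours:

- **Perfectly separating threshold.** At a threshold with FN = FP = 0 the
  ratio is 0/0. That threshold's value is then unique to cases under the
  ≥-convention, and case-unique values must score 1, so the 0/0 corner is
  assigned fitness 1. This is the only assignment consistent with the
  endpoint behaviour of the curve.
- **Between support points.** The fitness is defined by the training
  distribution only; new subjects fall between training values. We
  interpolate linearly between adjacent support points and clamp constant
  beyond the extremes. No smoothing is applied to the curve.

For binary/categorical factors, fitness is the per-category case share
p_case(c) / (p_case(c) + p_control(c)) — the direct transcription of the
FN/(FN+FP) share to unordered categories. Categories unseen in training
are treated as missing (logged once per category).

### Relevance

Relevance is the Youden index J = sensitivity + specificity − 1 maximised
over all observed thresholds and both orientations; the orientation
achieving the maximum is stored with the factor (ties resolve to
`cases_high`). The maximum over the sweep is the only operating-point
choice that yields exactly 0 for identical distributions and exactly 1 for
disjoint ones regardless of shape. Categorical relevance is the Youden
index of the rule "call a case when fitness(category) > 0.5"; it is
non-negative by construction. Two identical constant classes yield
relevance 0 (the sweep finds no separating threshold); two different
constants are disjoint distributions and yield 1.

### Aggregation and group relevance

A group's value is the relevance-weighted mean of its non-missing
children; the score is missing only when every child is. If all
non-missing children have relevance 0 the unweighted mean is used (this
preserves the weighted-average contract without a 0/0). Negative
relevances are rejected. Group relevance is computed by applying the same
maximum-Youden sweep to the group's aggregated training values, so groups
weigh into their parents exactly as factors do; a group whose training
values are entirely missing in one class gets relevance 0 with a warning
rather than failing (this occurs in small cross-validation folds).

Consequences worth knowing: duplicating a factor inside its group does not
change group values (weighted mean of equal values), deleting a leaf value
from a record changes the score exactly as removing that leaf from the
mean, and any strictly increasing transform of a factor leaves its
relevance and its fitness at transformed support points unchanged.

## Screening

Factors enter the model only if they differ between outcome groups at
p < 0.05: Mann-Whitney U for continuous *and* ordinal factors (ordinal
scales are reported as mean (SD) with the quantitative test in the source
cohort's baseline table), Pearson chi-square without continuity correction
for binary/categorical. No multiple-testing correction is applied. The
APOE block is screened once as the full-genotype contingency table; the
derived carrier binaries inherit that single test's selection.

The Mann-Whitney p-value uses an exact enumeration of all case/control
assignments of the pooled values (tie-aware, two-sided around the null
mean of U) when the combined sample size is ≤ 10, and the tie-corrected
normal approximation otherwise.

Screening is performed once on the full analysis population, before
cross-validation — faithful to the published workflow, and optimistic in
the usual way because the held-out folds have participated in selection.
`CVConfig(nested_screening=True)` repeats the screening inside each
training fold for leak-free estimates; the default reproduces the study
design.

## Cross-validation and reporting

10 repeats of 10-fold cross-validation by default: each repeat draws a
fresh uniformly random partition into k near-equal folds (unstratified by
default, matching "random subgroups"; stratification is available). Per
fold, the model is refitted on the k−1 training folds and the held-out
fold is scored at every node, so the three-level table (entire model /
group / factor) is itself cross-validated. A fold whose test split lacks a
class is excluded from aggregation with a warning — unavoidable for rare
outcomes (e.g. 7% prevalence) under unstratified 10-fold splitting.

The 95% CI is the 2.5th–97.5th percentile interval of the k × repeats
fold-level AUCs (no normality assumption; a normal-approximation option
exists). Sensitivity and specificity are computed per fold at the fixed
cutoff DSI = 0.5 with score ≥ cutoff called a case — the same tie side as
the fitness sweep — and averaged across folds, symmetric with the AUC
aggregation.

## Pathology outcomes and the component analysis

The nine binary autopsy outcomes (plus the two macroinfarct subtypes) are
derived deterministically: strict "> 0" rules for amyloid load, tangle
count, CAA percentage and infarct counts (exactly 0 maps to absent);
alpha-synuclein present for brainstem/limbic/diffuse neocortical staging;
hippocampal sclerosis present for severe/marked/total neuronal loss;
TDP-43 as recorded. Neuropathological AD is present when the
Braak × CERAD lookup yields intermediate or high likelihood. The default
lookup encodes: high = Braak V–VI with moderate/frequent plaques;
intermediate = Braak III–IV with moderate/frequent, or Braak V–VI with
sparse; all else low. The matrix is data, not code — pass a custom mapping
to override it.

The component analysis is a centered PCA (columns centered, *not* scaled
to unit variance) of the pathology panel in complete cases, via SVD. The
default input is the 0/1 present/absent panel of the eight main outcomes
(amyloid, tangles, CAA, macroinfarcts, microinfarcts, alpha-synuclein, HS,
TDP-43). We deliberately use the binary panel rather than raw magnitudes:
the raw measures live on incommensurate scales (area fractions vs counts
vs percentages), and an unscaled PCA of them reflects measurement units
rather than pathology co-occurrence; the binary panel puts all outcomes on
a common scale while keeping the centered-unscaled method. Quantitative
columns can be supplied instead via the `matrix` argument. Component signs
are fixed by making each component's largest-magnitude loading positive.
Each component's subject scores are evaluated as dementia predictors by
rank AUC; components with AUC < 0.5 are flagged inverted and also reported
on the oriented scale.

## The synthetic cohort generator

The generator emulates the *published marginal structure* of the study
population, not its joint covariance (which is unavailable):

- **Class counts are exact**, never sampled: 97 incident-dementia cases and
  148 controls in the dementia cohort, plus 94 flagged early deaths (339
  baseline non-demented before filtering); 163 autopsy subjects with
  exactly 59 dementia-at-death cases in the pathology cohort.
- **Continuous variables** are truncated normals on the instruments' hard
  ranges (MMSE [0, 30], SPMSQ [0, 10], competence 1–6, BMI [12, 60],
  education ≥ 0, ...), with the pre-truncation location moment-matched so
  the truncated mean equals the published group mean. Ordinal scales are
  the same draw rounded onto the discrete support; the small rounding bias
  is accepted (the convergence guarantee is stated for continuous
  variables). Binary factors use the printed group proportions, APOE
  genotypes the printed genotype tables.
- **Missingness** is injected as exactly the printed per-variable counts
  (3 education and 3 APOE in the dementia model; the larger footnote list
  in the pathology model), uniformly at random, never touching the outcome.
  APOE carrier binaries are re-derived after masking so they are missing
  exactly when the genotype is.
- **Predictors are independent within and across groups** given the
  outcome, apart from the couplings below. Synthetic cross-validated AUCs
  therefore need not — and do not — reproduce the published model AUCs;
  independence makes the synthetic classes more separable than real
  correlated data.
- **The pathology panel** couples amyloid, tangle and CAA presence, the
  NIA-AA likelihood class and the dementia propensity to one latent AD
  severity via a Gaussian threshold model (pairwise latent correlation
  0.6 for the pathology trio, 0.6 loading for dementia). This plants the
  co-occurrence structure the component analysis is meant to find: PC1
  loads amyloid/tangles/CAA and is the best dementia-predicting component.
  APOE genotype is drawn conditional on the AD-likelihood class using the
  published genotype distributions of the AD-present and AD-absent groups,
  which reproduces both the ~21% ε4-carrier marginal and the
  APOE-pathology association. Other baseline factors are
  outcome-independent in the pathology cohort, mirroring the finding that
  very few non-APOE factors predicted pathology. Alpha-synuclein
  prevalence is not printed for the study population; the default 0.30 is
  a typical Lewy-pathology frequency for 85+ autopsy series. Quantitative
  magnitudes are lognormal when present (e.g. amyloid load around 0.12
  area fraction) and exactly 0 when absent. The residual ("other")
  macroinfarct rate is solved from the total, cortical and white-matter
  targets; infeasible combinations raise an error naming the conflict.

What passing tests on these cohorts shows: the pipeline's accounting,
calibration under the null, and its ability to recover planted structure
at the study's sample sizes. What it does not show: predictive performance
on real, correlated oldest-old data.

## Numerical and design conventions

- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical configurations give
  byte-identical result files, and each run writes a provenance record
  (seed, configuration hash, library versions).
- Subject identifiers are opaque strings; no computation depends on row
  order (screening and CV results are invariant to shuffling).
- Problem sizes used by the heavier checks were fixed in advance as
  realistic for the field: 1000 replicates of 60/60 null cohorts for the
  screening-rate calibration, 20 seeds of 100/100 four-factor null cohorts
  with 2 × 5-fold CV for the null-AUC band, and 10 seeds each for the
  cognition-recovery and PCA-recovery checks at the study's own sample
  sizes (245 and 163).
- The cross-validation records fold membership (train and test indices per
  fold), so leak-freedom is verifiable after the fact.

## Known limitations

- The generator reproduces marginals, not the real joint distribution;
  absolute synthetic AUCs are optimistic and are not comparable to the
  published ones.
- Default screening-before-CV inherits the published design's optimism;
  use nested screening for unbiased estimates.
- The exact interaction between early death and dementia onset within the
  first two years is not modelled; flagged subjects are simply excluded,
  as in the source design.
- Unstratified folds can lack a class for rare outcomes; affected folds
  are dropped from aggregation rather than imputed, which widens CIs for
  low-prevalence pathologies (HS, TDP-43).
- The Braak × CERAD lookup is a simplified encoding of the published
  likelihood criteria at the resolution the cohort data support; sites
  using the full ABC scheme should supply their own matrix.
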