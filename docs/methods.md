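# Methods

## The model

`prognosig` implements a deliberately simple, fully univariate recipe for
discovering prognostic gene signatures from a gene × patient expression
matrix of log-ratio intensities paired with survival follow-up.

**Outcome binarization.** Overall survival is reduced to a binary endpoint
at a horizon *h* (default 12 years): a patient *died* iff the death event
occurred at time *t* ≤ *h*. Deaths after the horizon, and censoring at or
beyond it, are *survived*. Patients censored before the horizon have
unknown status there; the default policy labels them survived (keeping the
full cohort), and an `exclude` policy drops them from the labeling
instead. Both are exposed because neither choice is forced by the method;
the default preserves cohort sizes and is what the rest of the pipeline
assumes unless told otherwise.

**Discretization.** For each gene *g*, the reference cohort defines a
confidence interval of the **mean** expression,

    CI_g = mean_g ± q · s_g / √n_g ,

with *s* the sample standard deviation (n−1 denominator) over non-missing
values and *q* the two-sided normal quantile (1.96 at the default 95%
level; a Student-t quantile with n−1 df is selectable). A patient's value
is called *high* (+1) if strictly above the upper bound, *low* (−1) if
strictly below the lower bound, and *average* (0) otherwise — boundary
values are average. Because this is a standard-error band, not a
population interval, it shrinks as ~1/√n: with hundreds of patients most
calls are non-neutral, and the fraction of average calls decreases with
cohort size (a tested property). Missing values are skipped when the CI
is computed and map to the neutral level. Genes with one observation or
zero variance get the degenerate interval [mean, mean] and call everyone
average.

**Gene scoring.** With levels L ∈ {−1, 0, +1} and outcomes coded
σ = +1 (died) / −1 (survived), the poor-prognosis score of a gene is

    poor_score = Σ_patients L · σ ,

which is exactly the four-rule tally: +1 for (high, died) and
(low, survived), −1 for (low, died) and (high, survived), 0 whenever the
level is average. The good-prognosis score applies the mirrored rules and
equals −poor_score identically; the package computes both in one pass and
asserts the identity. Genes are ranked per orientation by descending
score, ties broken by ascending gene identifier so rankings are
deterministic.

**Signature assembly.** The signature is the top *k_poor* genes of the
poor ranking plus the top *k_good* of the good ranking (default 10 + 10),
together with their *frozen* CI bounds from the training cohort. With
nondegenerate scores the two lists cannot overlap (the rankings are
reversals of each other); in the all-tied degenerate case a contested gene
stays in the orientation with the larger score and the other list takes
its next candidate.

**Patient scoring and cutoff.** Each patient receives
`overall_score = poor_sum − good_sum`. Two summation modes exist:
*continuous* (default) sums raw log-ratio expression over each gene list
(missing values contribute 0); *discrete* re-applies the frozen
thresholds and sums levels. The continuous mode is the default because
the procedure is described as summing expression and because it preserves
effect-size information; the discrete mode is retained since the gene
selection itself is level-based — the ambiguity is real and both are
first-class. The classification cutoff is selected on the training
cohort's scores by scanning all candidate cutoffs — midpoints between
consecutive distinct scores, plus ∓∞ sentinels — and maximizing
sensitivity + specificity (the Youden total), where sensitivity counts
died patients with score strictly above the cutoff and specificity counts
survivors at or below it. Ties resolve to the smallest cutoff, which
favors sensitivity. The same strict inequality classifies patients
(score > cutoff → poor prognosis), so the selected operating point is
reproduced exactly by the classifier. The cutoff is stored inside the
signature file; applying the signature to validation patients reuses both
the frozen CI bounds and the frozen cutoff, so no information flows from
held-out data into the predictor.

## Evaluation battery

- **Classification metrics** with poor/died as the positive class:
  accuracy (tp+tn)/n, sensitivity tp/(tp+fn), specificity tn/(tn+fp), and
  positive predictive value tp/(tp+fp). An empty denominator yields NaN
  (undefined), never 0.
- **Survival comparison**: per-group right-censored Kaplan–Meier curves
  and the two-sided log-rank test (delegated to `lifelines`), plus a
  two-sided Mann–Whitney U test on raw time-to-death-or-censure between
  groups (Welch's t-test selectable). The log-rank implementation is
  cross-checked in the tests against a hand-computed
  observed-minus-expected tally and calibrated under a simulated null
  (5% rejection within [3%, 7%] over 1,000 replicates).
- **Score–time regression**: OLS of follow-up time on the overall score;
  the zero-slope F statistic (the squared t) and its p-value are
  reported. A working signature shows a significant negative slope.
- **Single-gene comparator**: mean-expression-cutoff classifier for one
  gene (value strictly above the gene's mean over measured patients →
  poor under `high_is_poor`, the right orientation for proliferation
  markers such as Aurora kinase A).

## Synthetic cohorts

The generator emulates the shape of a two-color breast-tumor microarray
compendium: defaults of 295 patients × 25,000 gene probes, log-ratio
values centered at 0 with unit noise, ~30% deaths by the 12-year horizon,
10% early censoring among survivors, and 1% missing cells. The generative
model is **outcome-conditional**: the binary outcome is drawn first
(death with probability `death_fraction`), planted poor-prognosis genes
are Normal(+δ, σ) in patients who die and Normal(−δ, σ) in survivors
(good genes mirrored), null genes Normal(0, σ) throughout. Survival times
decorate the outcomes: deaths at Uniform(0, h) with the event observed,
survivors at h + Uniform(0, 5) censored, except a `censor_rate` fraction
of survivors censored at Uniform(0, h) — so default-policy labeling
reproduces the generating outcomes exactly while still exercising the
early-censoring code path. Everything is deterministic given the seed.

Because expression is conditioned directly on the binary label, the
generator controls precisely the quantity the scorer measures. It does
*not* model hazard-driven expression, dye bias, spatial artifacts,
correlated gene modules, or non-Gaussian intensity distributions —
passing tests demonstrate that the pipeline recovers planted
outcome-conditional shifts and transfers across a blind split, not that
it handles microarray technical artifacts or correlated nulls.

Simulation-based checks in the test-suite and acceptance script run at
1,000 genes × 300 patients with 10 + 10 planted genes, δ = 0.5, σ = 1 and
a 50% death fraction over 10 seeds — large enough for stable recovery
statistics at desk scale. At these conditions the 10+10 signature
recovers ≥ 90% of planted genes on average, and the frozen
signature-plus-cutoff separates the held-out half (log-rank p < 0.01,
accuracy > 0.70) in ≥ 9 of 10 seeds, while 50 size-matched random
signatures on a δ = 0 cohort reject at ≈ the nominal 5% rate with chance
accuracy.

## Numerical and interface choices

- Ranking tie-break: ascending gene identifier; cutoff tie-break:
  smallest candidate. Both exist purely for determinism.
- Candidate cutoffs are midpoints rather than observed scores, avoiding
  ambiguity about which side a boundary patient falls on.
- Missing-value tokens on input: empty string, NA, NaN, null, none
  (case-insensitive); stored as NaN, never as 0.
- The blind cohort split is seeded-random (`split_cohort(..., seed=)`);
  the seed is the user's record of the split.
- Signature files are YAML with embedded per-gene thresholds; the CI
  table also exports as TSV (`gene_id, systematic_name, average, upper,
  lower`) matching the layout in which such signatures are published.
- Degenerate inputs: a gene absent from the frozen CI set, a labeled
  patient missing from the matrix, single-class labels at cutoff
  selection, constant scores at regression — all hard errors naming the
  offender, not silent repairs.

## Known limitations

- The discretization is tied to the cohort composition through the CI of
  the mean; adding patients changes all thresholds. Freezing
  training-cohort thresholds inside the signature is the supported way to
  apply it elsewhere (a flag allows recomputing on the scored cohort).
- Gene scoring treats patients and genes independently; correlated genes
  are double-counted and no multiplicity control is applied to the
  ranking — by design, the method is a simple univariate filter.
- The binary endpoint discards time-to-event information at training
  time; survival statistics enter only at evaluation.
- No microarray preprocessing: input is assumed already normalized
  log-ratio data.
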