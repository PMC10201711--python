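# Methods

## The analysis problem

High-density frameshift-peptide (FSP) microarrays measure serum IgG
binding to hundreds of thousands of candidate neoantigen ligands at
once. Unlike expression microarrays, the informative signal is sparse
and effectively binary: for any single serum sample only on the order
of 10³ of ~374,000 peptides show reproducible signal roughly 50-fold
above background, so the raw RFU distribution is bimodal and positively
skewed, and linear models built for log-normal intensity data are a
poor fit. `seroselect` implements the discrete pipeline appropriate to
this structure: threshold-based positivity calling, prevalence
filtering, resampled chi-square feature selection, and integer contrast
scoring with an abstention (indeterminate) class.

## Pipeline

1. **Positivity calling.** A (sample, peptide) pair is
   *patient-positive* when at least `min_positive_replicates` (default
   2) of the replicate arrays (default 4) read strictly over
   `rfu_threshold` (default 20,000 RFU). "Over" is implemented as a
   strict inequality; the boundary is configurable. Missing replicates
   contribute nothing and the required count is unchanged, so
   incomplete pairs can only lose calls — the conservative direction.
2. **Prevalence filtering.** A study-wide pre-filter keeps peptides
   positive in at least one sample anywhere; each analysis cohort then
   keeps peptides positive in at least `min_prevalence` (default 3) of
   its own samples. Both passes are the same operation
   (`prevalence_filter`) at different thresholds and sample sets, which
   reproduces the two distinct cohort-specific universes that arise
   from one assay run.
3. **Cohort construction.** Three named contrasts are built from the
   clinical annotations: disease progression (CR/PR/SD vs PD), clear
   response (CR/PR vs PD, stable disease held out), and adverse events
   (irAE grade 2–4 vs 0–1). Response contrasts first drop samples with
   under six weeks of therapy (the six-week boundary itself is
   included); the adverse-event contrast drops samples with unknown
   grades. The two exclusion rules are treated as independent. Optional
   homogeneity filters (`monotherapy_only`, `nsclc_only`) compose after
   the contrast filter, and every filter is recorded so membership is a
   pure function of the annotations.
4. **Stability selection.** Each of `n_iterations` (default 100)
   iterations draws `floor(0.8·n)` cohort samples without replacement
   and computes, per candidate peptide, the Pearson chi-square on the
   2×2 table positivity × pole. Peptides with p < 0.05 in at least 70
   of 100 iterations are retained. Recurrence across subsamples is the
   error control; no multiple-testing correction is applied.
5. **Direction assignment.** Each retained peptide is coded +1 or −1
   toward the pole with more full-cohort positive samples; exact ties
   carry no majority and drop the peptide.
6. **Scoring.** A sample's score is the sum of the codes of the model
   peptides it binds. Bidirectional models classify by the sign of the
   sum; a zero sum (no model binding, or balanced binding) is
   *indeterminate*. When every retained peptide points to one pole the
   model switches to unidirectional scoring: binding at least
   `unidirectional_threshold` (default 1) model peptides predicts the
   associated pole and everything else defaults to the opposite pole,
   with no indeterminate class. Holdout samples are scored with the
   same rule and the same sample-local positivity calls; no
   re-thresholding depends on cohort membership.
7. **Evaluation.** The performance matrix is observed pole ×
   (predicted pole, predicted opposite, indeterminate). Accuracy is
   reported among classified samples, alongside *coverage* (fraction
   classified); an intent-to-classify accuracy counting indeterminates
   as errors is also stored. Sensitivity and specificity treat the
   contrast's positive pole as the positive class and exclude
   indeterminates from both denominators. Unidirectional evaluation has
   no indeterminates, so sub-threshold symptomatic patients count as
   false negatives in both accuracy and sensitivity. `model_overlap`
   reports exact-subset (Venn) peptide counts across models.

## Statistical and numerical choices

- **Chi-square.** The closed form N(ad−bc)²/((a+b)(c+d)(a+c)(b+d)) with
  1 df, p from the χ²₁ survival function. No continuity correction by
  default — the more liberal screen, appropriate when recurrence is the
  error control — with the Yates correction available as a config
  toggle. Any zero marginal yields statistic 0 and p = 1: an
  uninformative peptide simply fails the screen rather than producing a
  NaN. An all-zero table is an error.
- **Subsampling.** Unstratified by default (one draw from the pooled
  cohort); a stratified per-pole draw is available behind a flag. The
  subsample size uses `floor`, erring toward smaller subsamples. If a
  draw empties one pole, that iteration is uninformative for every
  peptide (the zero-marginal convention) and a warning is logged.
- **Seeding.** A master seed spawns one independent child stream per
  iteration (`numpy` `SeedSequence.spawn`), so extending
  `n_iterations` never perturbs earlier draws and results are
  bit-reproducible across runs and platforms; recurrence uses integer
  counting after the p-threshold comparison.
- **Degenerate inputs.** Empty prevalence-filter results warn and
  return an empty list (selection then fails loudly with an
  empty-model error); an empty pole after cohort filtering is an
  error; samples present in binding data but absent from annotations
  simply never enter a cohort.

## Synthetic-data generator

The generator emulates the features of FSP-array serology the pipeline
relies on, with the fewest parameters that reproduce them:

- **Background**: lognormal with median 400 RFU (chosen as ~50-fold
  under the 20,000-RFU threshold; the assay literature gives the ratio,
  not an absolute value) and log-sd 0.5.
- **Bound signal**: uniform on [25,000, 60,000] RFU — comfortably over
  threshold but under the 16-bit scanner saturation of 65,535, at which
  all values clip.
- **Replicates**: multiplicative lognormal jitter with CV 0.15 around
  the pair's latent level, plus an optional per-replicate dropout that
  resets a positive replicate to background (default rate 0). At the
  defaults ≥99% of truly bound pairs pass the 2-of-4 rule, so
  positivity calling is nearly noiseless — by design, since the
  pipeline's interesting failure modes are statistical, not chemical.
- **Sparsity**: every sample binds each peptide with baseline
  probability 0.003 (~10³ of 374k, scaled), independent of outcome.
- **Planted structure**: disjoint peptide sets are elevated to
  prevalence 0.5 in one pole vs 0.03 outside it — 30 peptides per
  response pole (markers exist for both outcomes) and 11 one-sided
  adverse-event peptides (toxicity markers only), mirroring the
  observed asymmetry between the two analyses. Adverse-event status is
  assigned independently of response pole.
- **Cohort margins** default to the motivating study: 74 samples — 39
  non-progressors (1 CR, 25 PR, 13 SD), 27 progressors, 8
  short-treatment; 18 symptomatic irAE, 42 grade 0–1, 14 unknown; ~40%
  combination therapy; 14% SCLC; 2 EGFR-mutant progressors. The array
  is scaled to a 5,000-peptide desk size; full-scale generation is
  supported but not the default.

What the generator does **not** emulate: spatial array artifacts,
batch/slide effects, cross-reactive antibody families (correlated
peptides), heavy-tailed per-sample reactivity breadth, and any
sequence-level biology. Passing recovery tests therefore show that the
statistics behave as designed under the assumed independence structure,
not that the pipeline is robust to correlated assay noise.

`reference_cohort_annotations()` additionally provides a deterministic
74-sample annotation table with exactly the marginal outcome counts
above, so cohort-construction arithmetic (66/60/53/40/57 samples) is
checkable without any binding data.

## Recovery experiments

`recovery_experiment` runs the full pipeline per seed on fresh
cohorts with extra holdout samples per pole (generated by the same
process, excluded from selection) and reports planted-peptide recall,
null admission (retained non-planted peptides over all non-planted
peptides), and holdout accuracy/coverage. At the default conditions
(25+25 training samples, 30 planted peptides per pole at prevalence
0.5 vs 0.03, 5,000 peptides, 20 seeds) mean recall exceeds 0.9 with
null admission well under 1% — consistent with the chi-square power at
~20-per-pole subsamples and the binomial tail of the 70-of-100
recurrence rule. Problem sizes in the test suite and acceptance script
(desk-scale arrays, tens of seeds) are the package's default study
conditions; full-scale arrays only change memory, not the statistics.

## Known limitations

- The printed performance matrices of the motivating study are exactly
  reproducible from their counts, but model *content* (specific peptide
  counts such as 226/266/525/281/11, or Venn cores) depends on the
  undeposited raw binding data and is not reproducible; synthetic
  cohorts demonstrate the mechanism instead.
- Published text and tables disagree in two places (one-sided model
  sensitivity/specificity vs its count table; the clear-response
  model's accuracy vs its table). All metrics here are computed from
  count tables, and the discrepant text figures are not targeted.
- The indeterminate class makes accuracy and coverage jointly
  interpretable but means a model can look perfect while classifying
  few samples; always read the two together.
- With a one-sided model, any nonzero out-group prevalence of the model
  peptides directly bounds specificity from above (at out-group
  prevalence q and m peptides, specificity ≤ (1−q)^m for threshold 1);
  the generator's default q = 0.03 makes this visible in examples.
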