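# Methods

`fragscreen` implements a cfDNA fragmentomics screening assay for prostate
cancer: two binned fragmentomic feature families extracted from aligned
cfDNA fragments, a stacked machine-learning classifier with nested
feature selection, an integrated model adding serum PSA, a
specificity-anchored decision threshold, and the statistics used to
evaluate such an assay. Everything is exercisable end to end on synthetic
cohorts produced by the bundled simulator; no patient data ships with the
package.

## Genomic tilings

Features live on fixed-width tilings of the autosomes (chromosomes 1–22):
1 Mb bins for copy-number features and 5 Mb bins for fragment-size
coverages. Bins are laid from position 0 of each chromosome; the terminal
remainder shorter than the bin width is dropped, so every bin has exactly
the configured width. Coordinates are 0-based, half-open throughout; BED
input/output converts accordingly. A bin overlapping blacklist intervals
by ≥ 50% of its width is flagged unusable — enough to remove centromeric
or low-mappability bins without discarding lightly clipped ones. GC
fraction is computed on the reference sequence, (G+C)/(A+C+G+T) with
ambiguous bases excluded from both numerator and denominator; a bin with
more than 20% ambiguous bases is unusable. On the hg19 autosomes with no
blacklist this yields 2,846 usable 1 Mb bins and 1,134 FSC features; the
canonical assay configuration (with its inherited blacklist, which is not
reproduced here) uses 2,475 CNV bins and 541 FSC bins (1,082 features).
The published bin counts are treated as configuration, not as something
derivable from the tiling alone.

## FSC features (fragment-size coverage)

Fragments are classified by length into short (100–150 bp, inclusive) and
long (151–220 bp, inclusive) classes; other lengths are excluded. Each
fragment is assigned to the bin containing its midpoint
⌊(start+end)/2⌋ — unambiguous for boundary-straddling fragments and
standard in fragmentation-profile work. Short and long per-bin counts are
each standardized to z-scores *within sample, across bins*; the feature
vector concatenates shorts then longs in bin order. Within-sample
standardization makes profiles invariant to sequencing depth, which a
cross-sample classifier requires; whether the original assay standardized
jointly or separately, across bins or across samples, is not public — the
separate within-sample choice is this package's documented convention. A
zero-variance count vector (e.g. an empty fragment table) standardizes to
all zeros and flags the profile `degenerate` instead of failing. FSC
counts are not GC-corrected.

## CNV features (binned log2 depth ratios)

Per 1 Mb bin, fragment depth is tallied by the same midpoint rule with no
size filter. GC correction is a robust LOWESS of raw count on bin GC
(span 0.75, 2 robustness iterations), applied as
`corrected = raw · median(raw) / fitted` with the fitted curve floored at
a small epsilon; a degenerate all-equal-GC input skips correction with a
warning. A panel of normals built from ≥ 3 designated non-cancer samples
(each normalized to its own median) provides a per-bin median baseline
and MAD dispersion; bins with baseline < 0.1 or MAD above the 99th
percentile are removed from the feature space for *all* samples of a run,
keeping the dimension constant cohort-wide. The sample's log2 ratio is
`log2((corrected/median(corrected)) / baseline)`, with the
median-normalized depth floored at 10⁻³ so zero-count bins stay finite.
Median normalization makes the profile invariant to uniform depth
scaling. No segmentation, tumor-fraction or ploidy estimation is
performed: the classifier consumes raw per-bin log2 ratios.

## Synthetic cohorts

The simulator generates what the assay assumes about real cohorts,
nothing more:

- **Fragment lengths.** Background ~ Normal(167, 25) truncated to
  [50, 400] bp and rounded; tumor-origin fragments shift the location left
  by δ = 22 bp by default, moving mass into the short class. Two truncated
  normals with a location shift is the simplest law reproducing the
  short-fragment enrichment the assay exploits.
- **Placement.** With tumor fraction *tf* and tumor copy number *c(bin)*
  (diploid neutral = 2), bin placement weight is
  `width · (2(1−tf) + tf·c) · exp(β·(gc−0.5))`, and a fragment in the bin
  is tumor-origin with probability `tf·c / (2(1−tf) + tf·c)`. The
  expected depth ratio of a bin with copy number c is therefore
  `(2(1−tf) + c·tf)/2` — e.g. 1.25 (log2 ≈ 0.3219) for c = 3 at
  tf = 0.5 — which the tests verify by simulation against this closed
  form. Fragment starts are uniform within the chosen bin.
- **Defaults as study conditions.** Tumor fraction ~ Uniform[0.01, 0.15]
  (early-stage shallow-WGS signal levels; optionally stage-specific).
  Planted events default to arm-level gains on 2p/8q/9q/11q (c = 3) and
  losses on 6q/13q (c = 1), echoing recurrent prostate-cancer aberrations.
  Per-sample GC bias coefficient β ~ Normal(0, 0.6), giving the correction
  stage real bias to remove. PSA is log-normal with group means 19.34
  (cancer) and 3.43 ng/mL (non-cancer), matching reported screening-cohort
  means; stage probabilities (0.01, 0.53, 0.35, 0.11) follow the reported
  stage composition; Gleason/ISUP grades are sampled independently of the
  fragmentomic signal (grade was reported to carry little score signal).
  Default depth is 10⁵ fragments/sample, a desk-scale choice — real
  sequencing depth for such assays is far higher.
- **Not emulated.** Read-level error, duplicates, nucleosome positioning,
  end motifs, inter-individual fragmentation variation beyond the GC and
  size-shift knobs. Passing tests therefore demonstrate the pipeline's
  statistical machinery, not clinical performance on real plasma.

Everything derives deterministically from one cohort seed through
`numpy.random.SeedSequence` spawning.

## Classifier

1. **Selection.** Per-feature two-sample Welch t-test (the pooled-variance
   form is available via `equal_var=True`), two-sided, keep p < 0.01
   unadjusted. Features constant overall are excluded; a feature with zero
   variance in both groups but differing means is a perfect separator and
   is kept. If nothing passes (possible on null cohorts), the single
   smallest-p feature is used so every fold still yields a score.
2. **Base learners.** One gradient-boosted tree model (XGBoost, `hist`,
   single-thread) per feature family, tuned by a seeded random search of
   S configurations (default 20) over depth 2–6, learning rate 0.01–0.3
   (log-uniform), 50–500 rounds, row/column subsampling 0.5–1.0, scored by
   k-fold (default 5) inner-CV log-loss. The winner is refit on all
   samples; its inner-CV predictions supply out-of-fold (OOF)
   probabilities, so every training sample is scored by models that never
   saw it. A degenerate single-class inner fold triggers one seeded
   redraw, then an error.
3. **Stacker.** Elastic-net logistic regression on the two OOF base
   scores; grid over mixing α ∈ {0, 0.25, 0.5, 0.75, 1} and a log-spaced
   inverse-penalty path (default 8 values, 10⁻²–10²), selected by
   inner-CV log-loss. Training the stacker on in-sample base scores would
   make it degenerate — OOF inputs are the standard stacked-generalization
   construction.
4. **Integrated model.** XGBoost on exactly (cnv_score, fsc_score, PSA)
   with fixed hyperparameters: log-loss objective, max_depth 3, gamma 1,
   L1 alpha 0.5, subsample 0.75, colsample_bytree 0.7, eta 0.01, up to
   1000 rounds, early stopping with patience 20 on a seeded 20%
   class-stratified holdout. Missing PSA is an error; there is no
   imputation.
5. **LOOCV.** Selection, both base searches, the stacker and the
   integrated model are re-trained inside every leave-one-out fold; the
   held-out sample is scored by that fold's models only. A test verifies
   fold models are a function of the other n−1 samples alone (junk
   features for the held-out sample flow only through prediction).
6. **Threshold.** Candidate cut-points are midpoints between adjacent
   distinct sorted scores of the subcohort (non-cancer, PSA ≥ 4 ng/mL)
   plus a +∞ sentinel; the chosen threshold is the smallest candidate
   whose subcohort specificity (fraction of subcohort scores strictly
   below it; classification is positive iff score ≥ threshold, ties
   positive) reaches the 98% target. With fewer than 50 subcohort samples
   only specificity 1.0 is attainable, and the threshold lands above the
   subcohort maximum. The threshold of 0.7294 reported for the original
   training cohort is carried as an informational constant only — it is a
   data-derived value and is never asserted against synthetic cohorts.

Search breadth (S, inner k, penalty-path length) is compute budget, not a
study condition: tests and worked examples use reduced values, and the
pipeline's statistical properties (null calibration, signal recovery,
leakage-freedom) are asserted under those reduced settings.

## Evaluation

- **AUC** by the rank (Mann–Whitney) formulation — P(score_cancer >
  score_non-cancer) + ½ P(tie) — which equals the trapezoidal area under
  the empirical ROC; tested against an all-pairs brute-force oracle.
- **Confusion metrics** (sensitivity, specificity, PPV, NPV, accuracy) at
  a threshold, rule "positive iff score ≥ threshold". F1 =
  2·P·S/(P+S) with the (0,0) corner defined as 0.
- **Calibration** by logistic recalibration of outcome on
  logit(predicted), probabilities clipped to [10⁻⁶, 1−10⁻⁶]. The reported
  `slope` is the free-slope coefficient (ideal 1); the reported
  `intercept` is calibration-in-the-large, i.e. the intercept with slope
  fixed at 1 (ideal 0); the free fit's intercept is exposed as
  `intercept_free`. The two intercept conventions coincide only at
  slope 1 — when outcomes are generated with slope b ≠ 1, only the free
  fit recovers the generating intercept, which is how the recovery tests
  are framed.
- **Permutation importance**: with the integrated model fixed, one
  feature column is shuffled across samples (2000 times by default) and
  ΔAUC = mean original AUC − mean shuffled AUC is reported in percentage
  points. Because a permutation commutes with any per-column monotone
  transform and AUC is rank-invariant, pre-standardizing the features
  (with PSA log-transformed) provably cannot change ΔAUC; columns are
  shuffled on their native scale. The three ΔAUC values satisfy no
  conservation law and are not forced to sum to anything.
- **Paired bootstrap F1 comparison**: 2000 resamples of sample indices,
  F1 difference per replicate, two-sided p = 2·min(P(diff ≤ 0),
  P(diff ≥ 0)) with add-one smoothing (never exactly 0); replicates with
  no positive labels are skipped, > 10% skipped is an error.
- **Subgroups**: the PSA grey zone is the closed interval [4, 10] ng/mL
  (both ends inclusive — the boundary rule is this package's documented
  choice); assay metrics and PSA-used-as-a-score metrics are reported side
  by side. Per-stage sensitivity tables report detected/total with
  percentages to one decimal, matching the field's reporting style.

## Numerical and degenerate-input conventions

- Ties at the decision threshold classify positive.
- LOWESS fitted values floored at ε = max(10⁻⁶, 10⁻⁶·median);
  median-normalized depths floored at 10⁻³ before log2.
- z-scores use the population standard deviation; zero variance →
  all-zero z with a degeneracy flag.
- All stochastic components consume seeds derived from a single master
  seed via `SeedSequence` (string tokens hashed by CRC32); XGBoost runs
  single-threaded `hist` for bit-reproducibility.
- Matrix TSVs serialize floats at full round-trip precision
  (`%.17g` / `float_precision="round_trip"`); human-readable percentages
  are shown to one decimal.

## Problem sizes used by the test suite and acceptance script

Chosen for single-CPU desk-scale runs, as the package's own defaults for
its bundled verification: signal recovery uses 40 + 40 samples at 10⁵
fragments/sample on the full hg19 autosomes; null calibration uses 20
seeds of 16 + 16 samples at 5×10³ fragments on a two-chromosome genome;
the acceptance script trains on 100 cancer + 450 non-cancer samples at
2×10⁴ fragments on eight autosomes, giving a thresholding subcohort of
~130 non-cancer samples with PSA ≥ 4 ng/mL.

## Known limitations

- The panel of normals replaces the external reference baseline of the
  published tooling; absolute log2 levels therefore depend on the panel's
  composition.
- The simulator's fragment-length law is a two-component truncated
  normal; real cfDNA shows nucleosomal multi-modality.
- Reported clinical performance numbers (AUCs near 0.9 on patient
  cohorts) are properties of data this package cannot access; the bundled
  checks establish correctness of the machinery, null calibration and
  signal recovery on synthetic cohorts only.
- SHAP attribution and figure plotting are out of scope; reports are
  numeric tables and JSON.
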