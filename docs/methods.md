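# Methods

This note documents the statistical procedures implemented in `mitofusion`,
the synthetic data model used to validate them, the numerical conventions,
and the limits of what the tests demonstrate.

## Labels and curation

Mitotoxicity labels are ternary: `toxic`, `nontoxic`, and `inconclusive`.
The inconclusive state models MMP-assay calls masked by excessive
cytotoxicity — one cannot tell whether mitochondrial dysfunction caused the
cell death — and such compounds are excluded from training so the models
learn mitochondrial toxicity rather than general cytotoxicity.

Structures are standardized in a fixed order: sanitization and
functional-group normalization, largest-organic-fragment selection, charge
neutralization, tautomer canonicalization (RDKit `rdMolStandardize`).
Compound identity is the InChIKey (or InChI, configurable) of the
standardized structure, never of the raw input. When merged records
disagree, label precedence is `toxic > inconclusive > nontoxic`: a single
mitotoxic observation makes the compound toxic (evidence of toxicity under
*some* condition exists), and an inconclusive observation must not silently
become nontoxic, because inconclusive compounds are removed rather than
used as negatives. Unparseable structures are skipped with a warning —
curation runs over heterogeneous sources should not abort on one bad
SMILES. Tautomer-canonicalization failures fall back to the pre-tautomer
form with a warning (tautomer enumerators have known pathological inputs).

## Consensus morphological profiles

Input is a well-level table keyed by (plate, well) with a compound id (or
DMSO flag), a dose, and named features including
`Cells_Number_Object_Number`. The aggregation is:

1. **Plate-control subtraction.** For each plate and feature, subtract the
   mean over that plate's DMSO wells. This removes plate-level additive
   batch effects and leaves within-plate compound contrasts untouched.
2. **Replicate collapse.** Median per compound × dose.
3. **Dose collapse.** Retain dose levels within one sample SD of the mean
   dose and take the per-feature median across the retained dose-level
   profiles; append the median retained concentration as the
   `concentration` feature. Whose mean/SD defines retention is a switch
   (`per-compound`, the default, or `global`); with a shared dose grid the
   two coincide. Sample (n−1) SDs are used throughout because replicate
   and dose counts are small. At least one dose is always retained: the
   sample SD is never smaller than the smallest deviation from the mean.
4. **Cytotoxicity exclusion.** Threshold `mean − 1.5·SD` of the cell-count
   feature over the assembled cohort; profiles below it are flagged
   `cytotoxic` and excluded from modeling. The threshold is cohort-relative
   because source-repository-wide statistics are generally unavailable; a
   `fixed_threshold` mode accepts an externally published cutoff instead.

## Feature selection

Features are z-scored with training-set statistics (zero-variance features
dropped with a warning) and scored with three tests against the binary
label: two-sample KS, two-sided Mann–Whitney U (direction = sign of the
difference of class medians), and point-biserial correlation (Pearson r
against the 0/1 label with a t-distribution p). Five candidate lists are
formed — MWU top-k per direction, PBS top-k per sign, unsigned KS top-k —
each ranked by ascending p with ties broken by larger effect size (KS
statistic, |median difference|, |r|), then feature name, for determinism.
`union` mode deduplicates the union of the five lists (at most 5k
features); `intersection` mode intersects the three tests' candidate sets.
Union is the default: with k=25 it reproduces the "≤125 candidates →
~110 selected" arithmetic of external-style selection. Selection is by
rank, not significance, so no multiple-testing correction applies.

## Neighbor similarities and applicability domain

* **Tanimoto similarity** of two bit vectors is |a∧b|/|a∨b|, defined as 0
  (with a warning) when both vectors are empty. **Structural distance** of
  a query to a reference set is the median of the k=5 smallest Tanimoto
  distances (all references when fewer than k exist). The nearest-neighbor
  reading is used throughout: an applicability-domain measure must grow as
  the query leaves the neighborhood of the reference set.
* **Morphological similarity** is the absolute pooled median of the k=15
  most positive and k=15 most negative Pearson correlations between the
  query's selected-feature profile and the reference profiles. "Most
  positive/negative" is a rank statement (the largest and smallest values),
  and each correlation enters the pool at most once, so with fewer than 30
  references all correlations are pooled. Zero-variance profiles yield
  undefined correlations for the affected pairs; they are skipped with a
  warning. Profiles are z-scored before correlation (Pearson is
  scale-invariant; this only fixes the feature weighting).
* **Class separation** resamples the majority class to the minority size
  (seeded, without replacement), computes intra-class (vs the other toxic
  compounds, self excluded by index) and inter-class (vs the resampled
  nontoxic compounds) similarity per toxic compound in both spaces, and
  compares the two lists with an independent two-sample t test (Student by
  default, Welch by flag).

## Stump screens and grouped PPV

Random-forest Gini importance dilutes across correlated features, so
individual-feature predictivity is screened with depth-one decision trees.
The threshold minimizes weighted Gini impurity over all midpoints between
adjacent distinct sorted values; Gini ties resolve to the smaller
threshold. The positive leaf is the side with the larger toxic fraction
(ties to the `>` side), and the reported PPV is the training
(resubstitution) TP/(TP+FP) — the stumps are descriptive feature screens,
not validated classifiers. Constant features yield a flagged degenerate
stump with undefined PPV. Mean PPV over stumps with PPV > 0 is summarized
per compartment × channel × feature-group cell of the Cell Painting name
grammar `Compartment_FeatureGroup_[Parameters]_Channel`; names with
unknown compartments are kept but stay out of the grouped summary.

## Models, thresholds, evaluation

Random Forests use 100 trees, `max_features=sqrt`, `min_samples_split=2`,
`min_samples_leaf=1`, and no class weights — imbalance is handled entirely
by threshold tuning. The 100-tree default sits on the plateau visible in
the `grid_search_trees` sweep (21–301 trees, step 5, out-of-fold balanced
accuracy on fixed folds).

**Youden threshold.** Over candidate cuts (every distinct predicted
probability; midpoints give identical confusion tables; plus an
all-negative cut), choose the cut maximizing J = TPR − FPR, with ties —
detected up to 1e-12 to absorb float rounding of the rational TPR/FPR
values — resolved toward the larger threshold (fewer positive calls, the
conservative choice). A prediction is positive when probability ≥
threshold. Constant probability vectors are degenerate (J = 0 everywhere)
and flagged.

**Fusion.** Early fusion concatenates the selected CP features, selected GE
features, and all fingerprint bits (modality-prefixed names). Late fusion
averages the three single-modality probability vectors; its Youden
threshold is re-optimized on the averaged out-of-fold probabilities, since
the fused probability is the decision variable.

**Nested CV.** Stratified 4-fold outer splitting; per outer fold, feature
selection (CP and GE only; fingerprint bits pass through) runs on the
outer-training portion, the threshold comes from stratified 4-fold
out-of-fold probabilities *within* that portion, and metrics are computed
on the untouched outer-test fold at that threshold. Fifty repeats give 200
test folds, aggregated by the median. Every feature-selection and
threshold-selection call is recorded in an audit log with the compound ids
it saw, so the absence of test-set leakage is machine-checkable. Seeds fan
out per repeat from the master seed: repeats differ, runs reproduce.

**External evaluation.** After verifying that no compound id is shared
between train and test (a violation raises a leakage error listing the
offenders), selection runs on the full training set, the threshold comes
from 4-fold out-of-fold training probabilities, the model is refit on all
training data, and the test set is predicted once at the fixed threshold.
Per-compound output includes structural and morphological distances to the
toxic and to the nontoxic training references separately, so predictions
can be weighed by their applicability domain.

**Metrics.** Confusion counts plus F1 and precision of the minority
(mitotoxic) class, sensitivity, specificity, balanced accuracy, AUROC,
AUCPR (average precision), and MCC. Degenerate denominators follow the
zero-division-to-zero convention for precision/F1/MCC; AUROC/AUCPR are
NaN-flagged for single-class label sets.

## Synthetic data model

The generator reproduces the features of the real inputs that the pipeline
logic depends on, with a single seed fanning out to per-stage child
sequences (bit-identical datasets per configuration).

* **Cohort.** Defaults: 404 compounds, 16% toxic, 22 inconclusive drawn
  from a 10% cytotoxic subset — chosen to match a screening cohort in
  which roughly one in six compounds disrupts MMP and a twentieth of the
  cohort is excessively cytotoxic.
* **Morphology wells.** 384-well plates (auto-sized count) with 16
  scattered DMSO wells each; three log-spaced doses (0.3–10, assay
  concentration units) × three replicates per compound. A well value is
  `plate offset (SD 0.5) + compound effect + well noise (SD 0.3)`.
  Compound effects are unit-variance Gaussians with block-diagonal
  correlation (blocks of 20 features, within-block r = 0.5), mirroring the
  heavy redundancy of real Cell Painting features that motivates the stump
  screens. Planted features (30 of 1,729 by default, sign-balanced) are
  shifted by the configured effect size for signal-carrying toxic
  compounds, scaled linearly with log-dose and normalized so the
  *consensus* shift equals the requested Cohen's d.
* **Cell count.** Feature 0 is `Cells_Number_Object_Number`. Healthy
  compounds draw from N(0,1); cytotoxic compounds sit at −3 SD with a
  small (0.3 SD) residual spread. The depression is modeled as
  near-deterministic — a kill effect, not a shifted copy of the healthy
  distribution — because an additive 3-SD shift with full unit variance
  would overlap the 1.5-SD exclusion threshold far too much to represent
  the clearly separated low-cell-count mode the filter is designed for.
* **GE features.** Compound-level signed enrichment scores, standard
  normal under the null (they stand for signed −log10-p-like statistics),
  with the analogous planted shift.
* **Fingerprints.** Each compound belongs to one of 25 scaffolds; its bit
  vector is the scaffold's 40 core bits plus 15 compound-specific random
  bits, giving high within-scaffold and low between-scaffold Tanimoto
  similarity. Optionally a fraction of toxic compounds is placed in
  toxic-exclusive scaffolds (`fp_signal_fraction`, default 0.3), which is
  what makes structure informative.
* **Signal placement.** `cp_signal_fraction` (from the head of the toxic
  list) and `ge_signal_fraction` / `fp_signal_fraction` (from the tail)
  control which toxic compounds carry each modality's signal; fractions of
  0.5 plant complementary, disjoint signals — the regime in which late
  fusion should, and in the tests does, beat every single modality.

What the generator does **not** emulate: real feature marginals (skewness,
heavy tails, bimodality), dose–response saturation, plate spatial gradients
and edge effects, correlated assay noise between CP and GE for the same
compound, and real chemistry (fingerprint bits are abstract, not Morgan
hashes of actual structures). Passing tests therefore demonstrate that the
*procedures* are implemented correctly and behave as designed under known
signal — not that the reported effect sizes or model performance transfer
to any particular experimental dataset.

## Problem sizes used in the shipped analyses

The test suite and `scripts/acceptance.py` scale the cohort rather than the
logic: the acceptance script uses a 648-compound cohort at full feature
dimensionality (1,729 CP / 4,438 GE / 2,048 bits) split ~60/40 into train
and external test, 3 nested-CV repeats (12 test folds), and the full
21–301 tree grid; the fusion-benefit analysis uses 10 generator seeds at
300 compounds with 200 CP features. These sizes were chosen so a complete
run stays in the minutes range on one CPU while every estimate rests on
enough folds and seeds to be stable.

## Known limitations

* Stump PPVs are resubstitution estimates and upward-biased; they rank
  features, they do not validate them.
* The cohort-relative cytotoxicity threshold shifts with cohort
  composition; for cross-study comparability use the fixed-threshold mode.
* Youden tuning targets balanced sensitivity/specificity; if the
  application weighs false negatives differently, the threshold rule —
  not the probabilities — should change.
* The intersection selection mode can return very small (even empty)
  feature sets when the three tests disagree; union is the recommended
  default.
* Late fusion averages probabilities unweighted; no stacking or weighted
  ensemble is provided.
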