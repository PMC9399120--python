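# mitofusion

Multi-modal fusion models for detecting mitochondrial toxicants by combining
**Cell Painting** morphological profiles, **L1000-derived gene-expression
(GE) enrichment features**, and **Morgan fingerprints**.

Mitochondrial membrane-potential (MMP) disruption is a key safety endpoint
in drug discovery, but models built on chemical structure alone generalize
poorly outside the chemical space of their training compounds. This package
implements a pipeline that fuses biological readouts (high-content imaging
morphology, transcriptomic enrichment scores) with structural fingerprints
so that a compound can be flagged by what it *does to cells*, not only by
what it *looks like* — which is what lets the models extrapolate to new
chemical space. It is aimed at computational toxicologists and
cheminformaticians working with compound-level profile tables.

## What the pipeline does

1. **Curation** (`mitofusion.chem`): SMILES standardization (sanitize,
   normalize, largest fragment, neutralize charges, canonical tautomer),
   InChI/InChIKey identity merging, and label resolution with a
   *toxic-if-ever* rule (`toxic > inconclusive > nontoxic`). Compounds
   flagged "inconclusive" (excessive cytotoxicity masking the MMP call) are
   excluded from model training.
2. **Consensus profiles** (`mitofusion.profiles`): per plate, the DMSO
   neutral-control mean is subtracted from every well; replicate wells are
   collapsed by per-compound-per-dose medians; dose levels within one SD of
   the compound's mean dose are retained and collapsed by a second median;
   the retained median concentration becomes an extra feature. Compounds
   whose `Cells_Number_Object_Number` consensus value falls more than 1.5 SD
   below the cohort mean are excluded as excessively cytotoxic.
3. **Feature selection** (`mitofusion.feature_selection`): each standardized
   feature is scored against the binary label with a two-sample
   Kolmogorov–Smirnov test, a two-sided Mann–Whitney U test, and the
   point-biserial correlation; the top-*k* features per test (split by
   direction for the signed tests) are combined by union or intersection.
4. **Neighbor distances** (`mitofusion.similarity`): structural distance of
   a compound to a reference set is the median of its 5 nearest-neighbor
   Tanimoto distances,

   `structural_distance = median(x_1 … x_5)`, `x_k` = smallest Tanimoto
   distances `1 − |a ∧ b| / |a ∨ b|`;

   morphological similarity pools the 15 most positive and 15 most negative
   pairwise Pearson correlations over the selected features,

   `morphological_similarity = |median(a_1 … a_15, b_1 … b_15)|`,
   `morphological_distance = 1 − morphological_similarity`.

   These quantify the applicability domain and the intra- vs inter-class
   separation of mitotoxic compounds in morphological space.
5. **Interpretability** (`mitofusion.interpret`): depth-one decision trees
   (stumps) per feature give a training positive predictive value
   PPV = TP/(TP+FP), summarized by the Cell Painting name grammar
   (compartment × channel × feature group), plus CP–GE Pearson correlation
   tables.
6. **Modeling** (`mitofusion.modeling`): Random Forests (100 trees,
   `max_features=sqrt`, no class weights) over five variants — each single
   modality, early fusion (feature concatenation), and late fusion (mean of
   the three models' probabilities). Class imbalance is handled by tuning
   the probability cutoff to maximize **Youden's J = TPR − FPR** on
   out-of-fold predictions only. Performance is estimated with 4-fold
   nested cross-validation repeated 50 times (200 test folds) and with an
   external-test protocol (select + tune on train, refit on all training
   data, predict the disjoint test set at the fixed threshold).

A synthetic-data generator (`mitofusion.synthetic`) emulates the statistical
structure of the inputs — 384-well plate layouts with DMSO controls,
block-correlated morphology backgrounds with planted class shifts scaling
with log-dose, a cytotoxic subset with depressed cell counts feeding the
inconclusive labels, signed GE enrichment scores, and scaffold-clustered
fingerprints — so every stage is testable end-to-end with known ground
truth.

## Worked example

```python
import pandas as pd
from mitofusion import synthetic, profiles, feature_selection as fs, modeling

cfg = synthetic.SyntheticConfig(n_compounds=200, n_cp_features=300,
                                n_ge_features=120, n_inconclusive=8, seed=42)
ds = synthetic.generate(cfg)

# consensus morphology profiles + cytotoxicity exclusion
wells = profiles.subtract_plate_control(ds.well_table)
pset = profiles.filter_low_cellcount(profiles.consensus(wells))
print(f"{len(pset.retained)} profiles retained, "
      f"{len(pset.excluded)} excluded as cytotoxic "
      f"(threshold {pset.excluded.attrs['threshold']:.2f})")

labels = ds.labels.set_index("compound_id")["label"]
kept = pset.retained.index[
    labels.reindex(pset.retained.index) != "inconclusive"]
y = labels.loc[kept]

# three-test feature selection (external mode: top 25 per test, union)
cp = pset.retained.loc[kept].drop(columns=["concentration"])
report = fs.select_features(cp, y == "toxic", k_per_test=25)
planted = set(ds.truth["planted_cp_features"])
print(f"{len(report.selected)} morphology features selected; "
      f"{len(planted & set(report.selected))}/{len(planted)} planted recovered")

# late-fusion Random Forest under repeated nested CV
fp = pd.DataFrame(ds.fingerprints.bits,
                  index=ds.fingerprints.compound_ids).loc[kept]
fp.columns = [f"bit_{i}" for i in fp.columns]
tables = {"cp": pset.retained.loc[kept], "ge": ds.ge_table.loc[kept],
          "fp": fp}
cv = modeling.nested_cv(tables, y, "late", modeling.ModelConfig(seed=0),
                        n_repeats=2, k_per_test=40)
print(f"late fusion nested CV ({len(cv.fold_metrics)} folds): "
      f"median BA {cv.aggregate['balanced_accuracy']:.3f}, "
      f"F1 {cv.aggregate['f1_minority']:.3f}, "
      f"AUROC {cv.aggregate['auroc']:.3f}")
```

Output:

```
175 profiles retained, 25 excluded as cytotoxic (threshold -2.21)
52 morphology features selected; 30/30 planted recovered
late fusion nested CV (8 folds): median BA 0.986, F1 0.933, AUROC 0.998
```

The cytotoxicity filter removed the compounds whose cell count collapsed;
feature selection recovered every planted discriminative feature from the
300-feature background; and the late-fusion model, thresholded by Youden's
J from out-of-fold probabilities, separates the ~16%-prevalence mitotoxic
class almost perfectly on this planted-signal dataset.

The same steps are scriptable from a shell — see `mitofusion --help`
(`generate`, `curate`, `profiles`, `select-features`, `train`,
`evaluate-external`, `distances`, `interpret`).

## Documentation

`docs/methods.md` describes the statistical model behind the generator, all
tunable parameters, numerical conventions (tie-breaking, degenerate inputs),
and known limitations.
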