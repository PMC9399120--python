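"""Random-Forest fusion models with Youden-tuned decision thresholds.

Five model variants are supported: one per feature space (Cell Painting
consensus profiles, GE enrichment scores, Morgan fingerprints), early-stage
fusion (feature concatenation), and late-stage fusion (unweighted average of
the three models' predicted probabilities).  Class imbalance is handled by
tuning the probability cutoff to maximize Youden's J = TPR - FPR on
out-of-fold predictions, never on test data.  Performance estimation uses
repeated stratified nested cross-validation; external evaluation refits on
the full training set with a threshold from its own out-of-fold predictions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from . import feature_selection as fs
from . import similarity
from .errors import ContractViolation, LeakageError, SizingError

logger = logging.getLogger(__name__)

MODALITIES = ("cp", "ge", "fp")
FUSION_MODES = ("single_cp", "single_ge", "single_fp", "early", "late")
#: modalities that undergo univariate feature selection (fingerprint bits
#: are used as-is)
SELECTED_MODALITIES = ("cp", "ge")

METRIC_NAMES = ("f1_minority", "precision_minority", "sensitivity",
                "specificity", "balanced_accuracy", "auroc", "aucpr", "mcc")


@dataclass(frozen=True)
class ModelConfig:
    """Random-Forest settings; the defaults are the pipeline's baseline."""

    n_trees: int = 100
    min_samples_split: int = 2
    min_samples_leaf: int = 1
    max_features_rule: str = "sqrt"
    class_weighting: str | None = None
    seed: int = 0


@dataclass
class ThresholdResult:
    threshold: float
    j: float
    degenerate: bool = False


@dataclass
class EvaluationReport:
    fusion: str
    fold_metrics: pd.DataFrame
    aggregate: dict
    config: ModelConfig
    audit: list = field(default_factory=list)
    test_fold_ids: list = field(default_factory=list)
    predictions: pd.DataFrame | None = None
    threshold: float | None = None
    selected_features: dict | None = None


def _as_binary(labels) -> pd.Series:
    s = pd.Series(labels)
    if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
        if (s == "inconclusive").any():
            raise ContractViolation(
                "inconclusive compounds must be removed before modeling")
        bad = set(s.unique()) - {"toxic", "nontoxic"}
        if bad:
            raise ContractViolation(f"unknown labels: {sorted(bad)}")
        s = s == "toxic"
    return s.astype(bool)


def youden_threshold(probabilities, labels) -> ThresholdResult:
    """Probability cutoff maximizing Youden's J over all candidate cuts.

    A prediction is positive when probability >= threshold; candidates are
    the distinct probability values (midpoints between adjacent values give
    identical confusion tables) plus an all-negative cut above the maximum.
    Ties in J resolve toward the larger threshold (fewer positives).  When
    all probabilities are equal, J = 0 everywhere: the common value is
    returned with ``degenerate=True``.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(_as_binary(labels))
    if y.all() or not y.any():
        raise ContractViolation("both classes required to tune a threshold")
    u = np.unique(p)[::-1]  # descending
    if len(u) == 1:
        return ThresholdResult(threshold=float(u[0]), j=0.0, degenerate=True)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    # counts per distinct probability, accumulated from the top
    pos_at = np.array([(y & (p == t)).sum() for t in u], dtype=float)
    tot_at = np.array([(p == t).sum() for t in u], dtype=float)
    tp = np.cumsum(pos_at)
    fp = np.cumsum(tot_at - pos_at)
    j = tp / n_pos - fp / n_neg
    # all-negative option (threshold above the largest probability)
    thresholds = np.concatenate(([u[0] + 1.0], u))
    js = np.concatenate(([0.0], j))
    best_j = js.max()
    # ties in J (up to float rounding of the rational TPR/FPR values)
    # resolve toward the larger threshold, i.e. fewer positive calls
    best_t = thresholds[js >= best_j - 1e-12].max()
    return ThresholdResult(threshold=float(best_t), j=float(best_j))


def compute_metrics(labels, predictions, probabilities=None) -> dict:
    """Confusion counts and the eight evaluation metrics.

    The minority (positive) class is the mitotoxic one.  AUROC/AUCPR are
    NaN-flagged when probabilities are absent or the labels are
    single-class.
    """
    y = np.asarray(_as_binary(labels))
    yhat = np.asarray(predictions).astype(bool)
    if len(y) == 0 or len(y) != len(yhat):
        raise ContractViolation("labels and predictions must be aligned "
                                "and non-empty")
    tp = int((y & yhat).sum())
    fp = int((~y & yhat).sum())
    fn = int((y & ~yhat).sum())
    tn = int((~y & ~yhat).sum())

    def ratio(a, b):
        return a / b if b else float("nan")

    sens = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    prec = tp / (tp + fp) if (tp + fp) else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    mcc_den = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = ((tp * tn - fp * fn) / mcc_den) if mcc_den else 0.0
    auroc = aucpr = float("nan")
    if probabilities is not None and 0 < y.sum() < len(y):
        probs = np.asarray(probabilities, dtype=float)
        auroc = float(roc_auc_score(y, probs))
        aucpr = float(average_precision_score(y, probs))
    ba = (sens + spec) / 2.0
    return {"tp": tp, "fp": fp, "tn": tn, "fn": fn,
            "f1_minority": f1, "precision_minority": prec,
            "sensitivity": sens, "specificity": spec,
            "balanced_accuracy": ba, "auroc": auroc, "aucpr": aucpr,
            "mcc": mcc}


def fuse_early(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Column-wise concatenation with modality-prefixed feature names."""
    if not tables:
        raise ContractViolation("no modalities to fuse")
    keys = list(tables)
    index = tables[keys[0]].index
    for k in keys[1:]:
        if not tables[k].index.equals(index):
            raise ContractViolation(
                f"modality {k!r} has mismatched compound keys/order")
    parts = [tables[k].add_prefix(f"{k}__") for k in keys]
    return pd.concat(parts, axis=1)


def fuse_late(probabilities: dict[str, pd.Series] | list) -> np.ndarray:
    """Unweighted mean of per-modality predicted probabilities."""
    if isinstance(probabilities, dict):
        vectors = list(probabilities.values())
        keys = list(probabilities)
        if all(isinstance(v, pd.Series) for v in vectors):
            idx = vectors[0].index
            for k, v in zip(keys[1:], vectors[1:]):
                if not v.index.equals(idx):
                    raise ContractViolation(
                        f"probability vector {k!r} is misaligned")
    else:
        vectors = list(probabilities)
    if not vectors:
        raise ContractViolation("no probability vectors to fuse")
    arrs = [np.asarray(v, dtype=float) for v in vectors]
    n = len(arrs[0])
    if any(len(a) != n for a in arrs):
        raise ContractViolation("probability vectors differ in length")
    return np.mean(arrs, axis=0)


# --------------------------------------------------------------------------
# internal plumbing


class _FittedSpaces:
    """Per-modality feature selection + standardization fit on training data.

    Fingerprint bits pass through unchanged; CP and GE tables are z-scored
    with training statistics and restricted to the selected features.
    """

    @classmethod
    def fit(cls, tables, labels, train_ids, k_per_test, selection_mode):
        obj = cls.__new__(cls)
        obj.tables = tables
        obj.selected = {}
        obj.stats = {}
        for mod, table in tables.items():
            train = table.loc[train_ids]
            if mod in SELECTED_MODALITIES:
                mean = train.mean()
                sd = train.std(ddof=1)
                keep = sd.index[(sd > 0) & np.isfinite(sd)]
                z = (train[keep] - mean[keep]) / sd[keep]
                report = fs.select(fs.test_table(z, labels.loc[train_ids]),
                                   k_per_test, selection_mode)
                obj.selected[mod] = report.selected
                obj.stats[mod] = (mean, sd)
            else:
                obj.selected[mod] = list(table.columns)
        return obj

    def transform(self, mod: str, ids) -> pd.DataFrame:
        table = self.tables[mod].loc[ids]
        cols = self.selected[mod]
        if mod in self.stats:
            mean, sd = self.stats[mod]
            return (table[cols] - mean[cols]) / sd[cols]
        return table[cols]

    def design(self, fusion: str, ids) -> pd.DataFrame:
        if fusion == "early":
            return fuse_early({m: self.transform(m, ids)
                               for m in MODALITIES})
        mod = fusion.removeprefix("single_")
        return self.transform(mod, ids)


def _required_modalities(fusion: str) -> tuple[str, ...]:
    if fusion not in FUSION_MODES:
        raise ContractViolation(
            f"fusion must be one of {FUSION_MODES}, got {fusion!r}")
    if fusion in ("early", "late"):
        return MODALITIES
    return (fusion.removeprefix("single_"),)


def _check_tables(tables: dict, labels: pd.Series, fusion: str) -> dict:
    need = _required_modalities(fusion)
    missing = [m for m in need if m not in tables]
    if missing:
        raise ContractViolation(
            f"fusion {fusion!r} requires modalities {missing}")
    out = {}
    for mod in need:
        table = tables[mod]
        absent = labels.index.difference(table.index)
        if len(absent):
            raise ContractViolation(
                f"modality {mod!r} lacks compounds: {list(absent[:5])}")
        out[mod] = table
    return out


def _rf(config: ModelConfig, seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=config.n_trees,
        min_samples_split=config.min_samples_split,
        min_samples_leaf=config.min_samples_leaf,
        max_features=config.max_features_rule,
        class_weight=config.class_weighting,
        random_state=int(seed), n_jobs=1)


def _proba(clf: RandomForestClassifier, X) -> np.ndarray:
    idx = list(clf.classes_).index(True)
    return clf.predict_proba(X)[:, idx]


def _oof_probabilities(spaces: _FittedSpaces, fusion: str, ids, y: pd.Series,
                       config: ModelConfig, n_folds: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Out-of-fold probabilities on the given compounds (per fusion mode)."""
    ids = pd.Index(ids)
    yv = y.loc[ids].to_numpy()
    _check_stratifiable(yv, n_folds)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                          random_state=int(rng.integers(2**31)))
    mods = MODALITIES if fusion == "late" else (None,)
    oof = {m: np.full(len(ids), np.nan) for m in mods}
    for tr, te in skf.split(np.zeros(len(ids)), yv):
        for m in mods:
            sub_fusion = f"single_{m}" if m else fusion
            X_tr = spaces.design(sub_fusion, ids[tr])
            X_te = spaces.design(sub_fusion, ids[te])
            clf = _rf(config, rng.integers(2**31)).fit(X_tr, yv[tr])
            oof[m][te] = _proba(clf, X_te)
    if fusion == "late":
        return fuse_late([oof[m] for m in MODALITIES])
    return oof[None]


def _fit_predict(spaces: _FittedSpaces, fusion: str, train_ids, test_ids,
                 y_train: pd.Series, config: ModelConfig,
                 rng: np.random.Generator) -> np.ndarray:
    """Fit final model(s) on the training compounds, return test probs."""
    yv = y_train.loc[train_ids].to_numpy()
    if fusion == "late":
        probs = []
        for m in MODALITIES:
            clf = _rf(config, rng.integers(2**31)).fit(
                spaces.design(f"single_{m}", train_ids), yv)
            probs.append(_proba(clf, spaces.design(f"single_{m}", test_ids)))
        return fuse_late(probs)
    clf = _rf(config, rng.integers(2**31)).fit(
        spaces.design(fusion, train_ids), yv)
    return _proba(clf, spaces.design(fusion, test_ids))


def _check_stratifiable(y: np.ndarray, n_folds: int) -> None:
    pos, neg = int(y.sum()), int(len(y) - y.sum())
    if min(pos, neg) < n_folds:
        raise SizingError(
            f"stratified {n_folds}-fold split impossible with "
            f"{pos} positives / {neg} negatives")


# --------------------------------------------------------------------------
# public estimation procedures


def nested_cv(tables: dict[str, pd.DataFrame], labels, fusion: str,
              config: ModelConfig = ModelConfig(), n_outer: int = 4,
              n_inner: int = 4, n_repeats: int = 50, k_per_test: int = 40,
              selection_mode: str = "union") -> EvaluationReport:
    """Repeated stratified nested cross-validation for one fusion mode.

    Per repeat and outer fold: feature selection runs on the outer-training
    portion only; the decision threshold comes from inner out-of-fold
    probabilities on that same portion (maximizing Youden's J); metrics are
    computed on the untouched outer-test portion at that threshold.  With
    the defaults (4 outer folds x 50 repeats) the report carries one row per
    each of the 200 test folds, aggregated by the median.
    """
    y = _as_binary(labels)
    tables = _check_tables(tables, y, fusion)
    _check_stratifiable(y.to_numpy(), n_outer)
    ss = np.random.SeedSequence(config.seed)
    audit, rows, test_fold_ids = [], [], []
    ids = y.index.to_numpy()
    for rep, child in enumerate(ss.spawn(n_repeats)):
        rng = np.random.default_rng(child)
        outer = StratifiedKFold(n_splits=n_outer, shuffle=True,
                                random_state=int(rng.integers(2**31)))
        for fold, (tr, te) in enumerate(
                outer.split(np.zeros(len(ids)), y.to_numpy())):
            train_ids, test_ids = ids[tr], ids[te]
            audit.append({"stage": "feature_selection", "repeat": rep,
                          "fold": fold,
                          "compound_ids": frozenset(train_ids)})
            spaces = _FittedSpaces.fit(tables, y, train_ids, k_per_test,
                                       selection_mode)
            oof = _oof_probabilities(spaces, fusion, train_ids, y, config,
                                     n_inner, rng)
            audit.append({"stage": "threshold_selection", "repeat": rep,
                          "fold": fold,
                          "compound_ids": frozenset(train_ids)})
            thr = youden_threshold(oof, y.loc[train_ids])
            probs = _fit_predict(spaces, fusion, train_ids, test_ids, y,
                                 config, rng)
            m = compute_metrics(y.loc[test_ids], probs >= thr.threshold,
                                probs)
            m.update({"repeat": rep, "fold": fold,
                      "threshold": thr.threshold})
            rows.append(m)
            test_fold_ids.append(frozenset(test_ids))
    fold_metrics = pd.DataFrame(rows)
    aggregate = {k: float(fold_metrics[k].median()) for k in METRIC_NAMES}
    return EvaluationReport(fusion=fusion, fold_metrics=fold_metrics,
                            aggregate=aggregate, config=config, audit=audit,
                            test_fold_ids=test_fold_ids)


def external_evaluate(train_tables: dict, train_labels, test_tables: dict,
                      test_labels, fusion: str,
                      config: ModelConfig = ModelConfig(),
                      k_per_test: int = 25, selection_mode: str = "union",
                      n_folds: int = 4,
                      neighbor_params: similarity.NeighborParams =
                      similarity.NeighborParams()) -> EvaluationReport:
    """Train on the full training cohort and evaluate an external test set.

    Feature selection runs on the full training set; the probability
    threshold comes from stratified out-of-fold training predictions; the
    final model is refit on all training data and applied to the test set
    at that fixed threshold.  Train/test identifier overlap raises a
    :class:`LeakageError`.  Per-compound predictions include
    applicability-domain distances (structural and morphological) to each
    training class when both the fingerprint and CP modalities are present.
    """
    y_train = _as_binary(train_labels)
    y_test = _as_binary(test_labels)
    shared = y_train.index.intersection(y_test.index)
    if len(shared):
        raise LeakageError(
            f"{len(shared)} compound ids shared between train and test",
            offenders=list(shared))
    tables = _check_tables(train_tables, y_train, fusion)
    test_tables = _check_tables(test_tables, y_test, fusion)
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss)
    train_ids = y_train.index.to_numpy()
    test_ids = y_test.index.to_numpy()

    audit = [{"stage": "feature_selection", "repeat": 0, "fold": -1,
              "compound_ids": frozenset(train_ids)}]
    spaces = _FittedSpaces.fit(tables, y_train, train_ids, k_per_test,
                               selection_mode)
    oof = _oof_probabilities(spaces, fusion, train_ids, y_train, config,
                             n_folds, rng)
    audit.append({"stage": "threshold_selection", "repeat": 0, "fold": -1,
                  "compound_ids": frozenset(train_ids)})
    thr = youden_threshold(oof, y_train)

    # refit on the entire training set; predict the external compounds
    # (selection and standardization statistics stay those of the train set)
    spaces.tables = {m: pd.concat([tables[m], test_tables[m]])
                     for m in tables}
    probs = _fit_predict(spaces, fusion, train_ids, test_ids, y_train,
                         config, rng)
    preds = probs >= thr.threshold
    metrics = compute_metrics(y_test, preds, probs)
    metrics.update({"repeat": 0, "fold": -1, "threshold": thr.threshold})

    predictions = pd.DataFrame({
        "compound_id": test_ids,
        "probability": probs,
        "prediction": np.where(preds, "toxic", "nontoxic"),
        "label": np.where(y_test.to_numpy(), "toxic", "nontoxic"),
    }).set_index("compound_id")
    if "fp" in tables and "cp" in tables:
        dist = similarity.distance_records(
            spaces.transform("cp", test_ids),
            test_tables["fp"].loc[test_ids].to_numpy(),
            spaces.transform("cp", train_ids),
            tables["fp"].loc[train_ids].to_numpy(),
            y_train.to_numpy(), params=neighbor_params)
        wide = dist.pivot(index="compound_id", columns="class_used",
                          values=["structural_distance",
                                  "morphological_distance"])
        wide.columns = [f"{a}_to_{b}" for a, b in wide.columns]
        predictions = predictions.join(wide)

    fold_metrics = pd.DataFrame([metrics])
    aggregate = {k: float(fold_metrics[k].median()) for k in METRIC_NAMES}
    return EvaluationReport(fusion=fusion, fold_metrics=fold_metrics,
                            aggregate=aggregate, config=config, audit=audit,
                            test_fold_ids=[frozenset(test_ids)],
                            predictions=predictions,
                            threshold=thr.threshold,
                            selected_features=spaces.selected)


def grid_search_trees(table: pd.DataFrame, labels,
                      config: ModelConfig = ModelConfig(),
                      grid=None, n_folds: int = 4) -> pd.DataFrame:
    """Out-of-fold balanced accuracy per forest size over a tree-count grid.

    The default grid runs from 21 to 301 trees in steps of 5; fold
    assignments are held fixed across grid points so rows are comparable.
    The table is returned for inspection — choosing the 100-tree baseline
    stays the caller's decision.
    """
    if grid is None:
        grid = range(21, 302, 5)
    y = _as_binary(labels).to_numpy()
    _check_stratifiable(y, n_folds)
    X = table.to_numpy(dtype=float)
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                          random_state=int(rng.integers(2**31)))
    splits = list(skf.split(X, y))
    seeds = rng.integers(2**31, size=len(splits))
    rows = []
    for n_trees in grid:
        preds = np.zeros(len(y), dtype=bool)
        cfg = ModelConfig(n_trees=int(n_trees),
                          min_samples_split=config.min_samples_split,
                          min_samples_leaf=config.min_samples_leaf,
                          max_features_rule=config.max_features_rule,
                          class_weighting=config.class_weighting,
                          seed=config.seed)
        for (tr, te), s in zip(splits, seeds):
            clf = _rf(cfg, s).fit(X[tr], y[tr])
            preds[te] = clf.predict(X[te])
        m = compute_metrics(y, preds)
        rows.append({"n_trees": int(n_trees),
                     "balanced_accuracy": m["balanced_accuracy"]})
    return pd.DataFrame(rows)
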