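"""Youden thresholds, metrics, fusion, nested CV, external evaluation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import (balanced_accuracy_score, f1_score,
                             matthews_corrcoef, precision_score,
                             recall_score)

from mitofusion import modeling
from mitofusion.errors import ContractViolation, LeakageError, SizingError


def youden_oracle(probs, labels):
    """Enumerate all distinct probabilities, midpoints, and an all-negative
    cut; return the largest threshold among the J maximizers."""
    probs = np.asarray(probs, float)
    labels = np.asarray(labels, bool)
    u = np.unique(probs)
    candidates = list(u) + [(a + b) / 2 for a, b in zip(u, u[1:])]
    candidates.append(u.max() + 1.0)
    best = None
    for t in candidates:
        pred = probs >= t
        tpr = (pred & labels).sum() / labels.sum()
        fpr = (pred & ~labels).sum() / (~labels).sum()
        j = tpr - fpr
        if best is None or j > best[0] + 1e-12 or (
                abs(j - best[0]) <= 1e-12 and t > best[1]):
            best = (j, t)
    return best[1], best[0]


class TestYoudenThreshold:
    def test_perfect_separation(self):
        r = modeling.youden_threshold([0.9, 0.6, 0.55, 0.1],
                                      [1, 1, 0, 0])
        assert 0.55 < r.threshold <= 0.6
        assert r.j == pytest.approx(1.0)

    def test_tie_resolves_to_larger_threshold(self):
        r = modeling.youden_threshold([0.9, 0.8, 0.4, 0.2], [1, 0, 1, 0])
        assert r.j == pytest.approx(0.5)
        assert r.threshold == pytest.approx(0.9)

    def test_constant_probabilities_flagged_degenerate(self):
        r = modeling.youden_threshold([0.5, 0.5, 0.5], [1, 0, 1])
        assert r.degenerate
        assert r.threshold == pytest.approx(0.5)
        assert r.j == 0.0

    def test_single_class_rejected(self):
        with pytest.raises(ContractViolation):
            modeling.youden_threshold([0.2, 0.8], [1, 1])

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            n = int(rng.integers(4, 60))
            probs = rng.choice([0.1, 0.25, 0.5, 0.7, 0.9], size=n)
            labels = rng.random(n) < 0.35
            if labels.all() or not labels.any():
                continue
            if len(np.unique(probs)) == 1:
                continue
            r = modeling.youden_threshold(probs, labels)
            t, j = youden_oracle(probs, labels)
            assert r.j == pytest.approx(j)
            assert r.threshold == pytest.approx(t)


class TestComputeMetrics:
    def test_external_sensitivity_arithmetic(self):
        labels = [1] * 47 + [0] * 197
        preds = [1] * 37 + [0] * 10 + [0] * 197
        m = modeling.compute_metrics(labels, preds)
        assert m["sensitivity"] == pytest.approx(37 / 47)
        assert round(m["sensitivity"], 2) == 0.79

    def test_hand_computed_confusion(self):
        labels = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        preds = [1, 1, 1, 0, 1, 0, 0, 0, 0, 0]
        m = modeling.compute_metrics(labels, preds)
        assert (m["tp"], m["fp"], m["fn"], m["tn"]) == (3, 1, 1, 5)
        assert m["f1_minority"] == pytest.approx(0.75)
        assert m["balanced_accuracy"] == pytest.approx((0.75 + 5 / 6) / 2)

    def test_perfect_predictions(self):
        labels = [1, 0, 1, 0]
        m = modeling.compute_metrics(labels, labels, [0.9, 0.1, 0.8, 0.2])
        for key in ("f1_minority", "balanced_accuracy", "mcc", "auroc",
                    "aucpr"):
            assert m[key] == pytest.approx(1.0)

    def test_identities_against_sklearn_on_random_instances(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            n = int(rng.integers(6, 80))
            y = rng.random(n) < 0.3
            if y.all() or not y.any():
                continue
            pred = rng.random(n) < 0.4
            m = modeling.compute_metrics(y, pred)
            assert m["f1_minority"] == pytest.approx(
                f1_score(y, pred, zero_division=0))
            assert m["precision_minority"] == pytest.approx(
                precision_score(y, pred, zero_division=0))
            assert m["sensitivity"] == pytest.approx(recall_score(y, pred))
            assert m["balanced_accuracy"] == pytest.approx(
                balanced_accuracy_score(y, pred))
            assert m["mcc"] == pytest.approx(matthews_corrcoef(y, pred))
            assert m["balanced_accuracy"] == pytest.approx(
                (m["sensitivity"] + m["specificity"]) / 2)


class TestFusion:
    def _tables(self, n=6):
        idx = pd.Index([f"C{i}" for i in range(n)], name="compound_id")
        rng = np.random.default_rng(19)
        return {
            "cp": pd.DataFrame(rng.normal(size=(n, 11)), index=idx),
            "ge": pd.DataFrame(rng.normal(size=(n, 10)), index=idx),
            "fp": pd.DataFrame(rng.integers(0, 2, (n, 20)), index=idx),
        }

    def test_early_fusion_column_arithmetic(self):
        fused = modeling.fuse_early(self._tables())
        assert fused.shape[1] == 11 + 10 + 20
        assert fused.columns[0].startswith("cp__")

    def test_early_fusion_rejects_shuffled_keys(self):
        tables = self._tables()
        tables["ge"] = tables["ge"].iloc[::-1]
        with pytest.raises(ContractViolation):
            modeling.fuse_early(tables)

    def test_early_fusion_rejects_empty(self):
        with pytest.raises(ContractViolation):
            modeling.fuse_early({})

    def test_late_fusion_average(self):
        assert modeling.fuse_late([[1.0], [1.0], [1.0]])[0] == 1.0
        assert modeling.fuse_late([[0.9], [0.3], [0.0]])[0] == \
            pytest.approx(0.4)

    def test_late_fusion_permutation_invariant(self):
        a, b, c = [0.2, 0.9], [0.4, 0.1], [0.6, 0.5]
        np.testing.assert_allclose(modeling.fuse_late([a, b, c]),
                                   modeling.fuse_late([c, a, b]))

    def test_late_fusion_misalignment_rejected(self):
        idx1 = pd.Index(["a", "b"])
        idx2 = pd.Index(["a", "c"])
        with pytest.raises(ContractViolation):
            modeling.fuse_late({"cp": pd.Series([0.1, 0.2], index=idx1),
                                "ge": pd.Series([0.1, 0.2], index=idx2)})
        with pytest.raises(ContractViolation):
            modeling.fuse_late([[0.1, 0.2], [0.1]])


class TestNestedCV:
    def test_one_repeat_emits_four_fold_rows(self, small_tables):
        tables, labels = small_tables
        report = modeling.nested_cv(tables, labels, "single_cp",
                                    modeling.ModelConfig(seed=1),
                                    n_repeats=1, k_per_test=10)
        assert len(report.fold_metrics) == 4
        assert set(modeling.METRIC_NAMES) <= set(report.fold_metrics.columns)

    def test_stratification_impossible_raises(self):
        idx = pd.Index([f"C{i}" for i in range(8)])
        tables = {"cp": pd.DataFrame(np.random.default_rng(0)
                                     .normal(size=(8, 5)), index=idx)}
        labels = pd.Series(["toxic"] * 2 + ["nontoxic"] * 6, index=idx)
        with pytest.raises(SizingError):
            modeling.nested_cv(tables, labels, "single_cp", n_repeats=1)

    def test_inconclusive_labels_rejected(self, small_tables):
        tables, labels = small_tables
        bad = labels.copy()
        bad.iloc[0] = "inconclusive"
        with pytest.raises(ContractViolation):
            modeling.nested_cv(tables, bad, "single_cp", n_repeats=1)

    def test_planted_cp_signal_beats_uninformative_fingerprints(
            self, small_tables):
        # structural scaffolds are label-independent in the small dataset
        tables, labels = small_tables
        cp = modeling.nested_cv(tables, labels, "single_cp",
                                modeling.ModelConfig(seed=2), n_repeats=1,
                                k_per_test=10)
        fp = modeling.nested_cv(tables, labels, "single_fp",
                                modeling.ModelConfig(seed=2), n_repeats=1,
                                k_per_test=10)
        assert cp.aggregate["balanced_accuracy"] > \
            fp.aggregate["balanced_accuracy"]


class TestExternalEvaluate:
    def test_train_test_overlap_is_leakage(self, small_tables):
        tables, labels = small_tables
        with pytest.raises(LeakageError):
            modeling.external_evaluate(tables, labels, tables, labels,
                                       "single_cp")

    def test_predictions_carry_distances(self, small_tables):
        tables, labels = small_tables
        ids = labels.index
        train_ids, test_ids = ids[:80], ids[80:]
        tr = {m: t.loc[train_ids] for m, t in tables.items()}
        te = {m: t.loc[test_ids] for m, t in tables.items()}
        report = modeling.external_evaluate(
            tr, labels.loc[train_ids], te, labels.loc[test_ids], "late",
            modeling.ModelConfig(seed=3), k_per_test=10)
        preds = report.predictions
        assert len(preds) == len(test_ids)
        for col in ("structural_distance_to_toxic",
                    "structural_distance_to_nontoxic",
                    "morphological_distance_to_toxic",
                    "morphological_distance_to_nontoxic"):
            assert preds[col].between(0, 1).all()
        assert 0.0 <= report.threshold <= 1.0
        assert report.selected_features["cp"]


class TestGridSearchTrees:
    def _data(self):
        rng = np.random.default_rng(23)
        idx = pd.Index([f"C{i}" for i in range(60)])
        y = pd.Series(rng.random(60) < 0.3, index=idx)
        y.iloc[:8] = True
        x = pd.DataFrame(rng.normal(size=(60, 10)), index=idx)
        x.iloc[:, 0] += y.to_numpy() * 1.5
        return x, y

    def test_default_grid_has_57_rows(self):
        x, y = self._data()
        table = modeling.grid_search_trees(x, y)
        assert len(table) == 57
        assert table["n_trees"].iloc[0] == 21
        assert table["n_trees"].iloc[-1] == 301

    def test_same_seed_reproduces_table(self):
        x, y = self._data()
        cfg = modeling.ModelConfig(seed=4)
        a = modeling.grid_search_trees(x, y, cfg, grid=[21, 51, 101])
        b = modeling.grid_search_trees(x, y, cfg, grid=[21, 51, 101])
        pd.testing.assert_frame_equal(a, b)
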