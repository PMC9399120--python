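"""Three-test univariate feature selection against the binary toxicity label.

Each feature of a modality is scored with a two-sample Kolmogorov–Smirnov
test, a two-sided Mann–Whitney U test, and the point-biserial correlation.
Candidates are the top-k features per test — split by direction for the two
signed scores (MWU direction from the difference of class medians, PBS from
the sign of r) — and the selected set is either the union of the five
candidate lists or the intersection across the three tests.  Selection is by
rank, not by a significance cutoff, so no multiple-testing correction is
applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractViolation

logger = logging.getLogger(__name__)

MODES = ("union", "intersection")


@dataclass
class FeatureTestResult:
    feature: str
    ks_statistic: float
    ks_p: float
    mwu_u: float
    mwu_p: float
    mwu_direction: int      # sign of median(toxic) - median(nontoxic)
    median_diff: float
    pbs_r: float
    pbs_p: float


@dataclass
class SelectionReport:
    results: pd.DataFrame           # one row per tested feature
    selected: list[str]
    mode: str
    k_per_test: int
    candidates: dict = field(default_factory=dict)  # per-list feature names

    def to_json_dict(self) -> dict:
        return {"selected": self.selected, "mode": self.mode,
                "k_per_test": self.k_per_test}


def zscore(table: pd.DataFrame,
           reference: pd.DataFrame | None = None) -> pd.DataFrame:
    """Standardize each feature by the reference mean and (sample) SD.

    Zero-variance reference features are dropped with a warning; the
    reference defaults to the table itself.
    """
    if reference is None:
        reference = table
    missing = [c for c in table.columns if c not in reference.columns]
    if missing:
        raise ContractViolation(
            f"reference lacks columns of the table: {missing[:5]}")
    mean = reference[table.columns].mean()
    sd = reference[table.columns].std(ddof=1)
    bad = sd.index[(sd == 0) | ~np.isfinite(sd)]
    if len(bad):
        logger.warning("dropping %d zero-variance features", len(bad))
    keep = [c for c in table.columns if c not in set(bad)]
    return (table[keep] - mean[keep]) / sd[keep]


def _check_classes(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ContractViolation(
            "both classes must be present to test a feature")
    return labels


def test_feature(values, labels) -> FeatureTestResult:
    """Score one feature against the binary label with the three tests."""
    values = np.asarray(values, dtype=float)
    labels = _check_classes(labels)
    tox, non = values[labels], values[~labels]
    ks = stats.ks_2samp(tox, non)
    mwu = stats.mannwhitneyu(tox, non, alternative="two-sided")
    pbs = stats.pointbiserialr(labels.astype(int), values)
    med_diff = float(np.median(tox) - np.median(non))
    return FeatureTestResult(
        feature="", ks_statistic=float(ks.statistic), ks_p=float(ks.pvalue),
        mwu_u=float(mwu.statistic), mwu_p=float(mwu.pvalue),
        mwu_direction=int(np.sign(med_diff)), median_diff=med_diff,
        pbs_r=float(pbs.statistic), pbs_p=float(pbs.pvalue))


def test_table(table: pd.DataFrame, labels) -> pd.DataFrame:
    """Vectorized three-test scoring of every column of a feature table.

    Returns one row per feature with the same statistics as
    :func:`test_feature`.
    """
    labels = _check_classes(labels)
    x = table.to_numpy(dtype=float)
    tox, non = x[labels], x[~labels]
    ks = stats.ks_2samp(tox, non, axis=0)
    mwu = stats.mannwhitneyu(tox, non, alternative="two-sided", axis=0)
    med_diff = np.median(tox, axis=0) - np.median(non, axis=0)
    # point-biserial = Pearson r of feature vs 0/1 label
    y = labels.astype(float)
    yc = y - y.mean()
    xc = x - x.mean(axis=0)
    denom = np.sqrt((xc ** 2).sum(axis=0)) * np.sqrt((yc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * yc[:, None]).sum(axis=0) / denom
        n = len(y)
        t = r * np.sqrt((n - 2) / np.clip(1.0 - r ** 2, 1e-300, None))
    pbs_p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    pbs_p = np.where(np.isfinite(r), pbs_p, np.nan)
    return pd.DataFrame({
        "feature": table.columns,
        "ks_statistic": np.atleast_1d(ks.statistic),
        "ks_p": np.atleast_1d(ks.pvalue),
        "mwu_u": np.atleast_1d(mwu.statistic),
        "mwu_p": np.atleast_1d(mwu.pvalue),
        "mwu_direction": np.sign(med_diff).astype(int),
        "median_diff": med_diff,
        "pbs_r": r,
        "pbs_p": pbs_p,
    })


def _top_k(results: pd.DataFrame, p_col: str, effect_col: str,
           k: int, mask=None) -> list[str]:
    """Top-k features by ascending p; ties broken by larger |effect|,
    then lexicographic feature name."""
    sub = results if mask is None else results.loc[mask]
    sub = sub.dropna(subset=[p_col])
    order = sub.assign(_abs_eff=sub[effect_col].abs()).sort_values(
        by=[p_col, "_abs_eff", "feature"],
        ascending=[True, False, True], kind="mergesort")
    return order["feature"].head(k).tolist()


def select(results: pd.DataFrame, k_per_test: int,
           mode: str = "union") -> SelectionReport:
    """Combine per-test top-k candidate lists into the selected feature set.

    Five candidate lists are formed: MWU top-k per direction, PBS top-k per
    sign, and the unsigned KS top-k.  ``mode="union"`` deduplicates their
    union (the external-evaluation behaviour, e.g. k=25 yielding at most 125
    features); ``mode="intersection"`` intersects the three tests' candidate
    sets (signed lists pooled per test).
    """
    if mode not in MODES:
        raise ContractViolation(f"mode must be one of {MODES}, got {mode!r}")
    if k_per_test < 1:
        raise ContractViolation("k_per_test must be >= 1")
    if k_per_test > len(results):
        logger.warning("k_per_test=%d exceeds %d tested features; using all",
                       k_per_test, len(results))
        k_per_test = len(results)

    cands = {
        "mwu_pos": _top_k(results, "mwu_p", "median_diff", k_per_test,
                          results["mwu_direction"] > 0),
        "mwu_neg": _top_k(results, "mwu_p", "median_diff", k_per_test,
                          results["mwu_direction"] < 0),
        "pbs_pos": _top_k(results, "pbs_p", "pbs_r", k_per_test,
                          results["pbs_r"] > 0),
        "pbs_neg": _top_k(results, "pbs_p", "pbs_r", k_per_test,
                          results["pbs_r"] < 0),
        "ks": _top_k(results, "ks_p", "ks_statistic", k_per_test),
    }
    if mode == "union":
        chosen = set().union(*map(set, cands.values()))
    else:
        by_test = [set(cands["mwu_pos"]) | set(cands["mwu_neg"]),
                   set(cands["pbs_pos"]) | set(cands["pbs_neg"]),
                   set(cands["ks"])]
        chosen = set.intersection(*by_test)

    # deterministic output order: by best p across the three tests, then name
    best_p = results[["ks_p", "mwu_p", "pbs_p"]].min(axis=1)
    ranked = results.assign(_best_p=best_p).sort_values(
        by=["_best_p", "feature"], kind="mergesort")
    selected = [f for f in ranked["feature"] if f in chosen]
    return SelectionReport(results=results, selected=selected, mode=mode,
                           k_per_test=k_per_test, candidates=cands)


def select_features(table: pd.DataFrame, labels, k_per_test: int = 25,
                    mode: str = "union",
                    reference: pd.DataFrame | None = None) -> SelectionReport:
    """Standardize, score, and select in one call (per modality)."""
    z = zscore(table, reference)
    return select(test_table(z, labels), k_per_test, mode)
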