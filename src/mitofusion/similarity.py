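"""Neighbor-based structural and morphological similarities and distances.

Structural distance of a query to a reference set is the median of its five
nearest-neighbor Tanimoto distances (Tanimoto distance = 1 - similarity).
Morphological similarity is the absolute value of the pooled median of the
15 most positive and 15 most negative pairwise Pearson correlations between
the query's selected-feature profile and the reference profiles;
morphological distance is one minus that similarity.  Both serve as
applicability-domain measures and as the intra- vs inter-class separation
statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractViolation

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NeighborParams:
    k_struct: int = 5
    k_pos: int = 15
    k_neg: int = 15

    def __post_init__(self):
        if min(self.k_struct, self.k_pos, self.k_neg) < 1:
            raise ContractViolation("all neighbor counts must be >= 1")


@dataclass
class SeparationResult:
    """Per-compound intra/inter similarities and the two-sample t tests."""

    intra_struct: np.ndarray
    inter_struct: np.ndarray
    intra_morph: np.ndarray
    inter_morph: np.ndarray
    t_struct: float
    p_struct: float
    t_morph: float
    p_morph: float
    n_per_class: int


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto similarity |a AND b| / |a OR b| of two bit vectors."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ContractViolation(
            f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        logger.warning("Tanimoto of two all-zero vectors defined as 0")
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def tanimoto_to_references(query: np.ndarray,
                           references: np.ndarray) -> np.ndarray:
    """Vectorized Tanimoto similarity of one query against many references."""
    q = np.asarray(query, dtype=bool)
    refs = np.asarray(references, dtype=bool)
    if refs.ndim != 2 or refs.shape[1] != q.shape[0]:
        raise ContractViolation("references must be (n, n_bits) of the "
                                "query's length")
    inter = np.logical_and(refs, q).sum(axis=1)
    union = np.logical_or(refs, q).sum(axis=1)
    out = np.zeros(len(refs), dtype=float)
    nz = union > 0
    out[nz] = inter[nz] / union[nz]
    if (~nz).any():
        logger.warning("Tanimoto with all-zero pair defined as 0")
    return out


def structural_distance(query: np.ndarray, references: np.ndarray,
                        k_struct: int = 5) -> float:
    """Median of the k nearest-neighbor Tanimoto distances to the references.

    Uses all references when fewer than ``k_struct`` are available.
    """
    refs = np.atleast_2d(np.asarray(references))
    if refs.shape[0] == 0:
        raise ContractViolation("empty reference set")
    dists = 1.0 - tanimoto_to_references(query, refs)
    k = min(k_struct, len(dists))
    nearest = np.partition(dists, k - 1)[:k]
    return float(np.median(nearest))


def _pearson_to_references(query: np.ndarray,
                           references: np.ndarray) -> np.ndarray:
    """Pearson correlation of the query profile with each reference profile.

    Zero-variance vectors yield NaN for the affected pairs (skipped with a
    warning by the callers).
    """
    q = np.asarray(query, dtype=float)
    refs = np.atleast_2d(np.asarray(references, dtype=float))
    qc = q - q.mean()
    rc = refs - refs.mean(axis=1, keepdims=True)
    qn = np.sqrt((qc ** 2).sum())
    rn = np.sqrt((rc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (rc @ qc) / (rn * qn)
    r[~np.isfinite(r)] = np.nan
    return r


def morphological_similarity(query: np.ndarray, references: np.ndarray,
                             k_pos: int = 15, k_neg: int = 15) -> float:
    """|pooled median| of the k most positive and k most negative Pearson
    correlations between the query and the reference profiles.

    Each correlation enters the pool at most once: with fewer than
    ``k_pos + k_neg`` references, all available correlations are used.
    """
    refs = np.atleast_2d(np.asarray(references))
    if refs.shape[0] == 0:
        raise ContractViolation("empty reference set")
    r = _pearson_to_references(query, refs)
    bad = np.isnan(r)
    if bad.any():
        logger.warning("skipping %d zero-variance correlation pairs",
                       int(bad.sum()))
        r = r[~bad]
    if r.size == 0:
        raise ContractViolation("no valid correlations to pool")
    order = np.argsort(r)
    idx = set(order[-k_pos:].tolist()) | set(order[:k_neg].tolist())
    pooled = r[sorted(idx)]
    return float(abs(np.median(pooled)))


def morphological_distance(query: np.ndarray, references: np.ndarray,
                           k_pos: int = 15, k_neg: int = 15) -> float:
    """1 - morphological similarity."""
    return 1.0 - morphological_similarity(query, references, k_pos, k_neg)


def _self_excluded(matrix: np.ndarray, i: int) -> np.ndarray:
    return np.delete(matrix, i, axis=0)


def class_separation(profiles: pd.DataFrame, fingerprints: np.ndarray,
                     labels, params: NeighborParams = NeighborParams(),
                     seed: int = 0, welch: bool = False) -> SeparationResult:
    """Intra- vs inter-class neighbor similarity in both spaces.

    The majority (nontoxic) class is resampled without replacement to the
    minority size.  For each toxic compound, intra-class similarity is
    computed against the other toxic compounds (self excluded) and
    inter-class similarity against the resampled nontoxic compounds, in
    structural space (median of the ``k_struct`` highest Tanimoto
    similarities) and morphological space (pooled-median Pearson rule).
    Student's t (equal variances) compares the paired value lists per space;
    ``welch=True`` switches to Welch's t.
    """
    labels = np.asarray(labels).astype(bool)
    if labels.sum() < 2 or (~labels).sum() < 2:
        raise ContractViolation(
            "class separation requires >= 2 compounds per class")
    x = profiles.to_numpy(dtype=float)
    fps = np.asarray(fingerprints)
    if not (len(x) == len(fps) == len(labels)):
        raise ContractViolation("profiles, fingerprints and labels must be "
                                "aligned")
    rng = np.random.default_rng(seed)
    tox_idx = np.flatnonzero(labels)
    non_idx = np.flatnonzero(~labels)
    n_min = min(len(tox_idx), len(non_idx))
    if len(non_idx) > n_min:
        non_idx = rng.choice(non_idx, size=n_min, replace=False)
    elif len(tox_idx) > n_min:
        tox_idx = rng.choice(tox_idx, size=n_min, replace=False)

    tox_fp, non_fp = fps[tox_idx], fps[non_idx]
    tox_x, non_x = x[tox_idx], x[non_idx]

    intra_s, inter_s, intra_m, inter_m = [], [], [], []
    for i in range(len(tox_idx)):
        other_fp = _self_excluded(tox_fp, i)
        other_x = _self_excluded(tox_x, i)
        # similarities: median of k nearest = 1 - structural_distance
        intra_s.append(1.0 - structural_distance(tox_fp[i], other_fp,
                                                 params.k_struct))
        inter_s.append(1.0 - structural_distance(tox_fp[i], non_fp,
                                                 params.k_struct))
        intra_m.append(morphological_similarity(tox_x[i], other_x,
                                                params.k_pos, params.k_neg))
        inter_m.append(morphological_similarity(tox_x[i], non_x,
                                                params.k_pos, params.k_neg))

    equal_var = not welch
    ts = stats.ttest_ind(intra_s, inter_s, equal_var=equal_var)
    tm = stats.ttest_ind(intra_m, inter_m, equal_var=equal_var)
    return SeparationResult(
        intra_struct=np.array(intra_s), inter_struct=np.array(inter_s),
        intra_morph=np.array(intra_m), inter_morph=np.array(inter_m),
        t_struct=float(ts.statistic), p_struct=float(ts.pvalue),
        t_morph=float(tm.statistic), p_morph=float(tm.pvalue),
        n_per_class=n_min)


def distance_records(query_profiles: pd.DataFrame, query_fps: np.ndarray,
                     train_profiles: pd.DataFrame, train_fps: np.ndarray,
                     train_labels,
                     params: NeighborParams = NeighborParams()
                     ) -> pd.DataFrame:
    """Applicability-domain distances of queries to each training class.

    For every query compound, reports structural and morphological distance
    to the toxic and to the nontoxic training references separately (the
    query's own label need not be known).
    """
    train_labels = np.asarray(train_labels).astype(bool)
    tx = train_profiles.to_numpy(dtype=float)
    tf = np.asarray(train_fps)
    rows = []
    for cid, qx, qf in zip(query_profiles.index,
                           query_profiles.to_numpy(dtype=float),
                           np.asarray(query_fps)):
        for cls, mask in (("toxic", train_labels),
                          ("nontoxic", ~train_labels)):
            if not mask.any():
                continue
            rows.append({
                "compound_id": cid,
                "class_used": cls,
                "structural_distance": structural_distance(
                    qf, tf[mask], params.k_struct),
                "morphological_distance": morphological_distance(
                    qx, tx[mask], params.k_pos, params.k_neg),
                "n_references": int(mask.sum()),
            })
    return pd.DataFrame(rows)
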