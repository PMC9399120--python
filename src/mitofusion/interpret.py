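"""Per-feature interpretability: decision-stump PPV and grouped summaries.

Random forests dilute Gini importance across correlated morphology features,
so individual-feature predictivity is screened instead with depth-one
decision trees (stumps): the Gini-optimal threshold per feature defines a
positive leaf whose training positive predictive value (PPV) measures how
well that single feature flags mitotoxic compounds.  PPVs are summarized by
the Cell Painting name grammar (compartment, feature group, channel), and
selected morphology features are correlated against selected gene-expression
features by Pearson correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractViolation

logger = logging.getLogger(__name__)

COMPARTMENTS = ("Cells", "Cytoplasm", "Nuclei")
FEATURE_GROUPS = ("Correlation", "Granularity", "Intensity",
                  "RadialDistribution", "Texture", "AreaShape", "Location",
                  "Number", "Neighbors")
CHANNELS = ("AGP", "DNA", "ER", "Mito", "RNA")


@dataclass(frozen=True)
class FeatureName:
    """Parsed Cell Painting feature name (Compartment_Group_Params_Channel)."""

    compartment: str
    feature_group: str
    channel: str            # "" when channel-free
    parameters: tuple
    raw: str

    def unparse(self) -> str:
        return self.raw


@dataclass
class StumpResult:
    feature: str
    threshold: float
    positive_leaf_side: str   # "<=" or ">"
    ppv: float                # NaN when the stump predicts no positives
    n_predicted_positive: int
    degenerate: bool = False


def parse_feature_name(name: str) -> FeatureName:
    """Parse an underscore-delimited Cell Painting feature name.

    Compartment is the first token, feature group the second, channel the
    last token when it is a recognized channel (else channel-free); the
    remaining tokens are parameters.  Unknown compartments are kept but
    logged, so such features simply stay ungrouped downstream.
    """
    tokens = name.split("_")
    if len(tokens) < 2:
        raise ContractViolation(
            f"feature name must have >= 2 underscore tokens: {name!r}")
    compartment, group = tokens[0], tokens[1]
    rest = tokens[2:]
    channel = ""
    if rest and rest[-1] in CHANNELS:
        channel = rest[-1]
        rest = rest[:-1]
    if compartment not in COMPARTMENTS:
        logger.warning("unknown compartment %r in feature %r; kept ungrouped",
                       compartment, name)
    return FeatureName(compartment=compartment, feature_group=group,
                       channel=channel, parameters=tuple(rest), raw=name)


def fit_stump(values, labels, feature: str = "") -> StumpResult:
    """Depth-one decision tree on a single feature.

    The threshold minimizes weighted Gini impurity over all midpoints
    between adjacent distinct sorted values (ties resolved toward the
    smaller threshold); the positive leaf is the side with the larger
    fraction of toxic compounds, and PPV is its training (resubstitution)
    TP / (TP + FP).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ContractViolation("both classes required to fit a stump")
    distinct = np.unique(values)
    if len(distinct) < 2:
        return StumpResult(feature=feature, threshold=float(distinct[0]),
                           positive_leaf_side="<=", ppv=float("nan"),
                           n_predicted_positive=0, degenerate=True)
    order = np.argsort(values, kind="mergesort")
    v, y = values[order], labels[order]
    n = len(v)
    n_pos = y.sum()
    cum_pos = np.cumsum(y)
    # candidate split after position i (0-based): left = v[:i+1]
    cut = np.flatnonzero(v[:-1] < v[1:])   # last index of each distinct run
    left_n = cut + 1.0
    right_n = n - left_n
    left_pos = cum_pos[cut].astype(float)
    right_pos = n_pos - left_pos

    def gini(pos, tot):
        p = pos / tot
        return 2.0 * p * (1.0 - p)

    impurity = (left_n * gini(left_pos, left_n)
                + right_n * gini(right_pos, right_n)) / n
    best = int(np.argmin(impurity))  # argmin returns first = smaller thresh
    threshold = float((v[cut[best]] + v[cut[best] + 1]) / 2.0)
    lp, ln = left_pos[best], left_n[best]
    rp, rn = right_pos[best], right_n[best]
    if lp / ln > rp / rn:
        side, tp, pred = "<=", lp, ln
    else:
        side, tp, pred = ">", rp, rn
    return StumpResult(feature=feature, threshold=threshold,
                       positive_leaf_side=side,
                       ppv=float(tp / pred) if pred else float("nan"),
                       n_predicted_positive=int(pred))


def fit_stumps(table: pd.DataFrame, labels) -> list[StumpResult]:
    return [fit_stump(table[c].to_numpy(), labels, feature=c)
            for c in table.columns]


def grouped_ppv(stumps: list[StumpResult]) -> pd.DataFrame:
    """Mean PPV over stumps with PPV > 0, per compartment/channel/group cell.

    Stumps whose names do not parse to a known compartment are left out of
    the summary; the per-cell count of contributing stumps is included.
    """
    rows = []
    for s in stumps:
        if not np.isfinite(s.ppv) or s.ppv <= 0:
            continue
        parsed = parse_feature_name(s.feature)
        if parsed.compartment not in COMPARTMENTS:
            continue
        rows.append({"compartment": parsed.compartment,
                     "channel": parsed.channel or "none",
                     "feature_group": parsed.feature_group,
                     "ppv": s.ppv})
    if not rows:
        return pd.DataFrame(columns=["compartment", "channel",
                                     "feature_group", "mean_ppv", "n"])
    df = pd.DataFrame(rows)
    out = (df.groupby(["compartment", "channel", "feature_group"])
           .agg(mean_ppv=("ppv", "mean"), n=("ppv", "size"))
           .reset_index())
    return out


def correlate_cp_ge(cp: pd.DataFrame, ge: pd.DataFrame,
                    compounds=None) -> pd.DataFrame:
    """Pearson correlation of every (CP feature, GE feature) pair.

    Computed over the shared compound subset (optionally restricted to
    ``compounds``, e.g. the known mitotoxic compounds).  Zero-variance
    columns are skipped with a warning.  Returns a long-format table with
    r, p, and -log10(p).
    """
    shared = cp.index.intersection(ge.index)
    if compounds is not None:
        shared = shared.intersection(pd.Index(compounds))
    if len(shared) < 3:
        raise ContractViolation(
            f"need >= 3 shared compounds, got {len(shared)}")
    cpx = cp.loc[shared]
    gex = ge.loc[shared]

    def nonconstant(df, tag):
        sd = df.std(ddof=1)
        bad = sd.index[(sd == 0) | ~np.isfinite(sd)]
        if len(bad):
            logger.warning("skipping %d zero-variance %s columns",
                           len(bad), tag)
        return df.drop(columns=bad)

    cpx = nonconstant(cpx, "CP")
    gex = nonconstant(gex, "GE")
    n = len(shared)
    a = (cpx - cpx.mean()) / cpx.std(ddof=1)
    b = (gex - gex.mean()) / gex.std(ddof=1)
    r = (a.to_numpy().T @ b.to_numpy()) / (n - 1)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.clip(1.0 - r ** 2, 1e-300, None))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    out = pd.DataFrame({
        "cp_feature": np.repeat(cpx.columns, len(gex.columns)),
        "ge_feature": np.tile(gex.columns, len(cpx.columns)),
        "r": r.ravel(),
        "p": p.ravel(),
    })
    with np.errstate(divide="ignore"):
        out["neg_log10_p"] = -np.log10(out["p"])
    return out
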