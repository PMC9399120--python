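"""Consensus morphological profiles from well-level Cell Painting tables.

The aggregation follows the standard consensus-profile recipe: per plate,
the mean over that plate's DMSO neutral-control wells is subtracted from
every perturbation well; per compound and dose, replicate wells are
collapsed by the median; across a compound's doses, only dose levels within
one standard deviation of the mean dose are retained and collapsed by a
second median; the retained median concentration is appended as a feature.
Compounds whose cell count falls more than 1.5 SD below the cohort mean are
flagged as excessively cytotoxic and excluded from downstream modeling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ContractViolation, NormalizationError

logger = logging.getLogger(__name__)

DMSO = "DMSO"
META_COLUMNS = ("plate", "well", "compound_id", "dose")
CONCENTRATION_FEATURE = "concentration"
CELL_COUNT_FEATURE = "Cells_Number_Object_Number"


@dataclass
class ProfileSet:
    """Consensus profiles plus the exclusion audit."""

    features: pd.DataFrame   # compound_id-indexed
    excluded: pd.DataFrame   # compound_id, reason, value

    @property
    def retained(self) -> pd.DataFrame:
        return self.features.loc[
            ~self.features.index.isin(self.excluded["compound_id"])]


def feature_columns(wells: pd.DataFrame) -> list[str]:
    return [c for c in wells.columns if c not in META_COLUMNS]


def subtract_plate_control(wells: pd.DataFrame) -> pd.DataFrame:
    """Subtract each plate's DMSO mean from every well on that plate."""
    feats = feature_columns(wells)
    if not feats:
        raise ContractViolation("well table has no feature columns")
    is_dmso = wells["compound_id"] == DMSO
    missing = sorted(set(wells["plate"]) - set(wells.loc[is_dmso, "plate"]))
    if missing:
        raise NormalizationError(
            f"plates without DMSO control wells: {missing}")
    dmso_means = (wells.loc[is_dmso].groupby("plate")[feats].mean())
    out = wells.copy()
    out[feats] = (wells[feats].to_numpy()
                  - dmso_means.reindex(wells["plate"]).to_numpy())
    return out


def _retained_doses(doses: np.ndarray, mean: float, sd: float) -> np.ndarray:
    """Doses within [mean - sd, mean + sd]; all retained when SD is 0/NaN."""
    if not np.isfinite(sd) or sd == 0:
        return np.ones(len(doses), dtype=bool)
    return (doses >= mean - sd) & (doses <= mean + sd)


def consensus(wells: pd.DataFrame,
              dose_stats: str = "per-compound") -> pd.DataFrame:
    """Collapse control-subtracted wells into one profile per compound.

    Stage 1 takes the per-compound-per-dose median across replicate wells;
    stage 2 keeps dose levels within one (sample) SD of the mean dose and
    takes the per-feature median across the retained dose-level profiles.
    The median retained concentration is appended as the
    ``concentration`` feature.

    ``dose_stats`` selects whose mean/SD defines dose retention:
    ``"per-compound"`` (each compound's own dose values, the default) or
    ``"global"`` (all compound wells in the table).
    """
    if dose_stats not in ("per-compound", "global"):
        raise ConfigurationError(
            f"dose_stats must be 'per-compound' or 'global', "
            f"got {dose_stats!r}")
    feats = feature_columns(wells)
    cpd = wells.loc[wells["compound_id"] != DMSO]
    if cpd.empty:
        raise ContractViolation("no compound wells to aggregate")
    # stage 1: replicate median per compound-dose
    per_dose = cpd.groupby(["compound_id", "dose"], sort=True)[feats].median()

    dose_frame = per_dose.index.to_frame(index=False)
    doses = dose_frame["dose"].astype(float)
    if dose_stats == "per-compound":
        grp = doses.groupby(dose_frame["compound_id"])
        mean = grp.transform("mean")
        sd = grp.transform("std").fillna(0.0)
    else:
        g = cpd["dose"].to_numpy(float)
        mean = pd.Series(g.mean(), index=doses.index)
        sd = pd.Series(g.std(ddof=1) if len(g) > 1 else 0.0,
                       index=doses.index)
    keep = ((sd == 0) | ((doses >= mean - sd) & (doses <= mean + sd)))
    keep = keep.to_numpy()
    # a compound can never lose all doses: the sample SD is at least the
    # smallest deviation from the mean, so >= 1 dose is always retained
    retained = per_dose.iloc[keep]
    cids = dose_frame["compound_id"].to_numpy()[keep]
    out = retained.groupby(cids).median()
    conc = pd.Series(doses.to_numpy()[keep]).groupby(cids).median()
    out = pd.concat([out, conc.rename(CONCENTRATION_FEATURE)], axis=1)
    out.index.name = "compound_id"
    return out


def filter_low_cellcount(profiles: pd.DataFrame,
                         cellcount_feature: str = CELL_COUNT_FEATURE,
                         n_sd: float = 1.5,
                         fixed_threshold: float | None = None) -> ProfileSet:
    """Flag excessively cytotoxic compounds by their consensus cell count.

    The threshold is ``mean - n_sd * SD`` of the named feature over all
    candidate profiles in the run; profiles below it are marked excluded
    with reason ``"cytotoxic"``.  ``fixed_threshold`` bypasses the cohort
    statistics (e.g. to reuse a threshold published for another cohort).
    """
    if cellcount_feature not in profiles.columns:
        raise ConfigurationError(
            f"cell-count feature {cellcount_feature!r} not in profiles")
    values = profiles[cellcount_feature].astype(float)
    if fixed_threshold is None:
        threshold = values.mean() - n_sd * values.std(ddof=1)
    else:
        threshold = fixed_threshold
    mask = values < threshold
    excluded = pd.DataFrame({
        "compound_id": profiles.index[mask],
        "reason": "cytotoxic",
        "value": values[mask].to_numpy(),
    })
    excluded.attrs["threshold"] = float(threshold)
    return ProfileSet(features=profiles, excluded=excluded)


def drop_blocklisted(profiles: pd.DataFrame,
                     blocklist: list[str]) -> pd.DataFrame:
    """Remove known-noisy features by name; absent names only warn."""
    present = [c for c in blocklist if c in profiles.columns]
    absent = [c for c in blocklist if c not in profiles.columns]
    if absent:
        logger.warning("blocklist names absent from table: %s", absent)
    if present:
        logger.info("removing %d blocklisted features", len(present))
    return profiles.drop(columns=present)
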