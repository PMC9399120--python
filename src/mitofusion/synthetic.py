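"""Synthetic multi-modal screening data with known ground truth.

Emulates the statistical structure of the three input modalities used by the
fusion pipeline: well-level Cell Painting morphology tables laid out on
384-well plates with DMSO neutral-control wells, compound-level signed
gene-expression (GE) enrichment scores, and scaffold-clustered binary
fingerprints — together with binary mitotoxicity labels carrying an
"inconclusive" state for excessively cytotoxic compounds.

Every random choice fans out from a single seed through named child
sequences, so identical configurations yield bit-identical datasets.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import FingerprintSet
from .errors import ConfigurationError, SizingError
from .profiles import CELL_COUNT_FEATURE

PLATE_ROWS = "ABCDEFGHIJKLMNOP"  # 16 rows x 24 columns = 384 wells
PLATE_COLS = 24
PLATE_SIZE = len(PLATE_ROWS) * PLATE_COLS

_COMPARTMENTS = ("Cells", "Cytoplasm", "Nuclei")
_GROUPS = ("Intensity", "Texture", "Granularity", "Correlation",
           "RadialDistribution", "AreaShape")
_CHANNELS = ("Mito", "DNA", "ER", "RNA", "AGP")

# background correlation structure of morphology features
_BLOCK_SIZE = 20
_BLOCK_R = 0.5
_WELL_NOISE_SD = 0.3
_PLATE_OFFSET_SD = 0.5
_CYTOTOXIC_RESIDUAL_SD = 0.3


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror the screening cohort the pipeline was designed around:
    ~400 compounds at ~16% mitotoxic prevalence, 1,729 morphology features,
    4,438 GE enrichment features, 2048-bit fingerprints, a small
    excessively-cytotoxic subset from which the inconclusive labels are
    drawn, and three log-spaced doses with three replicate wells each.
    """

    n_compounds: int = 404
    toxic_fraction: float = 0.16
    n_inconclusive: int = 22
    n_cp_features: int = 1729
    n_ge_features: int = 4438
    n_planted_cp: int = 30
    n_planted_ge: int = 30
    effect_size: float = 1.0
    n_plates: int | None = None  # auto-sized when None
    doses_per_compound: int = 3
    replicates_per_dose: int = 3
    dmso_wells_per_plate: int = 16
    cytotoxic_fraction: float = 0.10
    fp_bits: int = 2048
    n_scaffolds: int = 25
    seed: int = 0
    # Placement of the class signal within the toxic class.  The CP subset is
    # the first ceil(f * n_toxic) toxic compounds, the GE and fingerprint
    # subsets the last ceil(f * n_toxic); fractions of 0.5 therefore plant
    # complementary (disjoint) signals across modalities.
    cp_signal_fraction: float = 1.0
    ge_signal_fraction: float = 1.0
    fp_signal_fraction: float = 0.3
    # depression of the cell-count feature for cytotoxic compounds, in units
    # of that feature's compound-level SD
    cytotoxic_depression_sd: float = 3.0
    dose_min: float = 0.3
    dose_max: float = 10.0

    def validate(self) -> None:
        def positive(name):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be a positive count")

        for name in ("n_compounds", "n_cp_features", "n_ge_features",
                     "doses_per_compound", "replicates_per_dose",
                     "fp_bits", "n_scaffolds"):
            positive(name)
        for name in ("toxic_fraction", "cytotoxic_fraction",
                     "cp_signal_fraction", "ge_signal_fraction",
                     "fp_signal_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        for name in ("n_inconclusive", "n_planted_cp", "n_planted_ge"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.n_planted_cp > self.n_cp_features - 1:
            # feature 0 is the reserved cell-count feature
            raise ConfigurationError(
                "n_planted_cp must be <= n_cp_features - 1 "
                f"(one feature is reserved for {CELL_COUNT_FEATURE})")
        if self.n_planted_ge > self.n_ge_features:
            raise ConfigurationError("n_planted_ge must be <= n_ge_features")
        if self.n_inconclusive > self.n_cytotoxic:
            raise ConfigurationError(
                "n_inconclusive exceeds the cytotoxic subset "
                f"({self.n_inconclusive} > {self.n_cytotoxic}); inconclusive "
                "compounds are drawn from cytotoxic compounds")
        if self.dmso_wells_per_plate < 1:
            raise ConfigurationError(
                "dmso_wells_per_plate must be >= 1 "
                "(DMSO plate normalization is impossible without controls)")
        if self.dmso_wells_per_plate >= PLATE_SIZE:
            raise ConfigurationError(
                "dmso_wells_per_plate must leave room for compound wells")
        if self.effect_size < 0:
            raise ConfigurationError("effect_size must be non-negative")
        if self.cytotoxic_depression_sd < 0:
            raise ConfigurationError(
                "cytotoxic_depression_sd must be non-negative")
        if self.dose_min <= 0 or self.dose_max < self.dose_min:
            raise ConfigurationError(
                "doses require 0 < dose_min <= dose_max")
        if self.n_plates is not None and self.n_plates < 1:
            raise ConfigurationError("n_plates must be a positive count")
        if not 0 <= int(self.seed) < 2**31:
            raise ConfigurationError("seed must lie in [0, 2**31)")

    @property
    def n_toxic(self) -> int:
        return int(round(self.toxic_fraction * self.n_compounds))

    @property
    def n_cytotoxic(self) -> int:
        return int(round(self.cytotoxic_fraction * self.n_compounds))

    @property
    def wells_per_compound(self) -> int:
        return self.doses_per_compound * self.replicates_per_dose


@dataclass
class SyntheticDataset:
    """One generated dataset plus the ground truth used to plant it."""

    well_table: pd.DataFrame      # plate, well, compound_id, dose, features
    ge_table: pd.DataFrame        # compound_id-indexed GE enrichment scores
    fingerprints: FingerprintSet
    labels: pd.DataFrame          # compound_id, label
    truth: dict
    config: SyntheticConfig = field(repr=False, default=None)


def cp_feature_names(n: int) -> list[str]:
    """Morphology feature names following Compartment_Group_Params_Channel.

    Feature 0 is always the cell-count feature so the cytotoxicity filter
    can address it by name.
    """
    names = [CELL_COUNT_FEATURE]
    i = 0
    while len(names) < n:
        comp = _COMPARTMENTS[i % len(_COMPARTMENTS)]
        grp = _GROUPS[(i // len(_COMPARTMENTS)) % len(_GROUPS)]
        ch = _CHANNELS[i % len(_CHANNELS)]
        names.append(f"{comp}_{grp}_{i}_{ch}")
        i += 1
    return names


def _well_name(idx: int) -> str:
    return f"{PLATE_ROWS[idx // PLATE_COLS]}{idx % PLATE_COLS + 1:02d}"


def _compound_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"C{i:0{width}d}" for i in range(1, n + 1)]


def dose_levels(config: SyntheticConfig) -> np.ndarray:
    return np.geomspace(config.dose_min, config.dose_max,
                        config.doses_per_compound)


def make_plate_layout(config: SyntheticConfig,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Assign compound-dose replicates and DMSO controls to plate wells.

    Returns a table with columns (plate, well, compound_id, dose); DMSO
    wells carry compound_id "DMSO" and dose 0. Replicates of one
    compound-dose pair may span plates. Raises :class:`SizingError` when the
    requested plate count cannot hold all wells.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    ids = _compound_ids(config.n_compounds)
    doses = dose_levels(config)
    jobs = [(cid, d)
            for cid in ids
            for d in doses
            for _ in range(config.replicates_per_dose)]
    capacity = PLATE_SIZE - config.dmso_wells_per_plate
    n_plates = config.n_plates
    if n_plates is None:
        n_plates = math.ceil(len(jobs) / capacity)
    if len(jobs) > n_plates * capacity:
        raise SizingError(
            f"{len(jobs)} compound wells do not fit on {n_plates} plates "
            f"({capacity} non-control wells per plate)")
    order = rng.permutation(len(jobs))
    # DMSO wells evenly scattered across each plate
    dmso_pos = np.unique(np.linspace(
        0, PLATE_SIZE - 1, config.dmso_wells_per_plate).round().astype(int))
    rows = []
    j = 0
    for p in range(1, n_plates + 1):
        plate = f"P{p:03d}"
        free = [w for w in range(PLATE_SIZE) if w not in set(dmso_pos)]
        for w in dmso_pos:
            rows.append((plate, _well_name(w), "DMSO", 0.0))
        for w in free:
            if j >= len(jobs):
                break
            cid, d = jobs[order[j]]
            rows.append((plate, _well_name(w), cid, d))
            j += 1
    return pd.DataFrame(rows, columns=["plate", "well", "compound_id", "dose"])


def _dose_weights(config: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-dose multipliers for planted shifts, linear in log-dose.

    Scaled so that consensus aggregation over the doses retained by the
    within-one-SD rule recovers exactly the configured effect size.
    """
    doses = dose_levels(config)
    if len(doses) == 1:
        return doses, np.ones(1)
    mean, sd = doses.mean(), doses.std(ddof=1)
    retained = (doses >= mean - sd) & (doses <= mean + sd)
    if not retained.any():  # cannot happen for >=2 doses, kept defensive
        retained[:] = True
    logd = np.log10(doses)
    raw = logd - (logd.min() - 0.5)
    w = raw / np.median(raw[retained])
    return doses, w


def _correlated_background(rng: np.random.Generator, n_rows: int,
                           n_cols: int) -> np.ndarray:
    """Unit-variance Gaussians with block-wise correlation r=_BLOCK_R."""
    out = np.empty((n_rows, n_cols))
    a, b = math.sqrt(_BLOCK_R), math.sqrt(1.0 - _BLOCK_R)
    for start in range(0, n_cols, _BLOCK_SIZE):
        stop = min(start + _BLOCK_SIZE, n_cols)
        shared = rng.normal(size=(n_rows, 1))
        out[:, start:stop] = a * shared + b * rng.normal(
            size=(n_rows, stop - start))
    return out


def _scaffold_assignment(config: SyntheticConfig, rng: np.random.Generator,
                         fp_signal: np.ndarray) -> np.ndarray:
    """Scaffold index per compound; fp-signal compounds get pure scaffolds."""
    n = config.n_compounds
    assign = np.empty(n, dtype=int)
    sig_idx = np.flatnonzero(fp_signal)
    other_idx = np.flatnonzero(~fp_signal)
    if len(sig_idx) and config.n_scaffolds > 1:
        avg = max(1.0, n / config.n_scaffolds)
        n_pure = min(config.n_scaffolds - 1,
                     max(1, math.ceil(len(sig_idx) / avg)))
        assign[sig_idx] = np.arange(len(sig_idx)) % n_pure
        rest = rng.permutation(other_idx)
        assign[rest] = n_pure + np.arange(len(rest)) % (
            config.n_scaffolds - n_pure)
    else:
        perm = rng.permutation(n)
        assign[perm] = np.arange(n) % config.n_scaffolds
    return assign


def _fingerprints(config: SyntheticConfig, rng: np.random.Generator,
                  scaffold: np.ndarray) -> np.ndarray:
    core_n = max(1, min(40, config.fp_bits // 2))
    extra_n = max(1, min(15, config.fp_bits // 4))
    cores = [rng.choice(config.fp_bits, size=core_n, replace=False)
             for _ in range(config.n_scaffolds)]
    bits = np.zeros((config.n_compounds, config.fp_bits), dtype=np.uint8)
    for i in range(config.n_compounds):
        bits[i, cores[scaffold[i]]] = 1
        bits[i, rng.choice(config.fp_bits, size=extra_n, replace=False)] = 1
    return bits


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate one fully synthetic dataset under the configured conditions.

    Morphology wells are a correlated Gaussian background plus plate-level
    additive offsets; planted features are shifted by ``effect_size``
    (sign-balanced) for signal-carrying toxic compounds, scaled linearly
    with log-dose; cytotoxic compounds have the cell-count feature
    depressed; GE features are standard-normal signed enrichment scores
    with the analogous planted shift; fingerprints carry scaffold core bits
    plus per-compound random bits.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    (ss_layout, ss_assign, ss_fp, ss_cp, ss_ge, ss_noise) = ss.spawn(6)
    rng_assign = np.random.default_rng(ss_assign)

    n = config.n_compounds
    ids = np.array(_compound_ids(n))

    # ---- labels and ground-truth subsets -------------------------------
    perm = rng_assign.permutation(n)
    n_toxic = config.n_toxic
    toxic_order = perm[:n_toxic]          # toxic compounds, random order
    is_toxic = np.zeros(n, dtype=bool)
    is_toxic[toxic_order] = True

    def head_subset(frac):
        k = math.ceil(frac * n_toxic) if n_toxic else 0
        m = np.zeros(n, dtype=bool)
        m[toxic_order[:k]] = True
        return m

    def tail_subset(frac):
        k = math.ceil(frac * n_toxic) if n_toxic else 0
        m = np.zeros(n, dtype=bool)
        if k:
            m[toxic_order[n_toxic - k:]] = True
        return m

    cp_signal = head_subset(config.cp_signal_fraction)
    ge_signal = tail_subset(config.ge_signal_fraction)
    fp_signal = tail_subset(config.fp_signal_fraction)

    cytotoxic = np.zeros(n, dtype=bool)
    cyto_idx = rng_assign.choice(n, size=config.n_cytotoxic, replace=False)
    cytotoxic[cyto_idx] = True
    inconclusive = np.zeros(n, dtype=bool)
    if config.n_inconclusive:
        inc_idx = rng_assign.choice(cyto_idx, size=config.n_inconclusive,
                                    replace=False)
        inconclusive[inc_idx] = True

    label = np.where(is_toxic, "toxic", "nontoxic").astype(object)
    label[inconclusive] = "inconclusive"
    labels = pd.DataFrame({"compound_id": ids, "label": label})

    # ---- fingerprints ---------------------------------------------------
    rng_fp = np.random.default_rng(ss_fp)
    scaffold = _scaffold_assignment(config, rng_fp, fp_signal)
    bits = _fingerprints(config, rng_fp, scaffold)
    fingerprints = FingerprintSet(compound_ids=list(ids), bits=bits,
                                  radius=None, n_bits=config.fp_bits)

    # ---- Cell Painting wells -------------------------------------------
    rng_cp = np.random.default_rng(ss_cp)
    rng_noise = np.random.default_rng(ss_noise)
    feat_names = cp_feature_names(config.n_cp_features)
    planted_cp = rng_cp.choice(
        np.arange(1, config.n_cp_features), size=config.n_planted_cp,
        replace=False)
    cp_signs = np.ones(config.n_planted_cp)
    cp_signs[rng_cp.permutation(config.n_planted_cp)[
        :config.n_planted_cp // 2]] = -1.0

    base = _correlated_background(rng_cp, n, config.n_cp_features)
    # cell-count feature: healthy compounds ~N(0,1); cytotoxic compounds sit
    # a fixed number of SDs below with a small residual spread (a strong,
    # near-deterministic kill effect)
    base[:, 0] = rng_cp.normal(size=n)
    base[cytotoxic, 0] = (-config.cytotoxic_depression_sd
                          + _CYTOTOXIC_RESIDUAL_SD
                          * rng_cp.normal(size=int(cytotoxic.sum())))

    layout = make_plate_layout(config, np.random.default_rng(ss_layout))
    plates = layout["plate"].to_numpy()
    plate_codes, plate_uniques = pd.factorize(plates)
    offsets = rng_cp.normal(scale=_PLATE_OFFSET_SD,
                            size=(len(plate_uniques), config.n_cp_features))

    cid_to_idx = {c: i for i, c in enumerate(ids)}
    comp_idx = np.array([cid_to_idx.get(c, -1)
                         for c in layout["compound_id"]])
    is_cpd_well = comp_idx >= 0

    doses, weights = _dose_weights(config)
    dose_w = np.zeros(len(layout))
    dose_map = dict(zip(doses, weights))
    dose_w[is_cpd_well] = [dose_map[d]
                           for d in layout.loc[is_cpd_well, "dose"]]

    values = offsets[plate_codes] + rng_noise.normal(
        scale=_WELL_NOISE_SD, size=(len(layout), config.n_cp_features))
    values[is_cpd_well] += base[comp_idx[is_cpd_well]]
    if config.n_planted_cp and config.effect_size:
        sig_well = is_cpd_well & cp_signal[np.clip(comp_idx, 0, None)]
        shift = (dose_w[sig_well, None] * config.effect_size
                 * cp_signs[None, :])
        values[np.ix_(sig_well, planted_cp)] += shift

    well_table = pd.concat(
        [layout.reset_index(drop=True),
         pd.DataFrame(values, columns=feat_names)], axis=1)

    # ---- GE enrichment scores ------------------------------------------
    rng_ge = np.random.default_rng(ss_ge)
    ge_names = [f"GE_{i:04d}" for i in range(config.n_ge_features)]
    planted_ge = rng_ge.choice(config.n_ge_features,
                               size=config.n_planted_ge, replace=False)
    ge_signs = np.ones(config.n_planted_ge)
    ge_signs[rng_ge.permutation(config.n_planted_ge)[
        :config.n_planted_ge // 2]] = -1.0
    ge = rng_ge.normal(size=(n, config.n_ge_features))
    if config.n_planted_ge and config.effect_size:
        ge[np.ix_(ge_signal, planted_ge)] += (config.effect_size
                                              * ge_signs[None, :])
    ge_table = pd.DataFrame(ge, index=pd.Index(ids, name="compound_id"),
                            columns=ge_names)

    truth = {
        "planted_cp_features": [feat_names[i] for i in planted_cp],
        "planted_cp_signs": cp_signs.tolist(),
        "planted_ge_features": [ge_names[i] for i in planted_ge],
        "planted_ge_signs": ge_signs.tolist(),
        "scaffold": dict(zip(ids.tolist(), scaffold.tolist())),
        "cytotoxic": dict(zip(ids.tolist(),
                              cytotoxic.astype(bool).tolist())),
        "cp_signal_compounds": ids[cp_signal].tolist(),
        "ge_signal_compounds": ids[ge_signal].tolist(),
        "fp_signal_compounds": ids[fp_signal].tolist(),
        "doses": doses.tolist(),
        "dose_weights": weights.tolist(),
    }
    return SyntheticDataset(well_table=well_table, ge_table=ge_table,
                            fingerprints=fingerprints, labels=labels,
                            truth=truth, config=config)


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> None:
    """Write a dataset as plain-text CSV/JSON files under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ds.well_table.to_csv(out / "well_table.csv", index=False)
    ds.ge_table.to_csv(out / "ge_table.csv")
    bitstrings = ["".join(map(str, row)) for row in ds.fingerprints.bits]
    pd.DataFrame({"compound_id": ds.fingerprints.compound_ids,
                  "bits": bitstrings}).to_csv(out / "fingerprints.csv",
                                              index=False)
    ds.labels.to_csv(out / "labels.csv", index=False)
    with open(out / "truth.json", "w") as fh:
        json.dump(ds.truth, fh, indent=1)


def config_from_dict(d: dict) -> SyntheticConfig:
    """Build a config from a plain dict, rejecting unknown keys."""
    known = {f.name for f in fields(SyntheticConfig)}
    unknown = set(d) - known
    if unknown:
        raise ConfigurationError(
            f"unknown configuration fields: {sorted(unknown)}")
    return SyntheticConfig(**d)
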