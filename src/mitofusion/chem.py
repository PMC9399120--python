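"""Structure standardization, Morgan fingerprints, and label curation.

Standardization follows the conventional small-molecule cleanup sequence:
sanitization, functional-group normalization, largest-organic-fragment
selection, charge neutralization, and tautomer canonicalization, with the
canonical SMILES and a structure-derived InChI/InChIKey as output.  Compound
records from heterogeneous sources are merged on that identifier, and
conflicting toxicity calls are resolved with a toxic-if-ever rule.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator
from rdkit.Chem.MolStandardize import rdMolStandardize

from .errors import ContractViolation, StructureParseError

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

LABELS = ("toxic", "nontoxic", "inconclusive", "unlabeled")
#: precedence when merging conflicting observations: a single mitotoxic call
#: makes the compound toxic; inconclusive never silently becomes nontoxic
#: because inconclusive compounds are excluded from training.
_LABEL_PRECEDENCE = {"toxic": 3, "inconclusive": 2, "nontoxic": 1,
                     "unlabeled": 0}


@dataclass
class CompoundRecord:
    """One curated compound: structure identity, label, provenance."""

    raw_smiles: str
    standardized_smiles: str = ""
    identifier: str = ""  # InChI or InChIKey of the standardized structure
    label: str = "unlabeled"
    source_tags: set = field(default_factory=set)


@dataclass
class FingerprintSet:
    """Fixed-length binary vectors per compound.

    ``radius`` is ``None`` for synthetic bit vectors that were not derived
    from structures.
    """

    compound_ids: list
    bits: np.ndarray  # (n_compounds, n_bits) uint8
    radius: int | None = 2
    n_bits: int = 2048

    def __post_init__(self):
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.ndim != 2 or self.bits.shape[0] != len(self.compound_ids):
            raise ContractViolation(
                "bits must be a (n_compounds, n_bits) matrix")
        self.n_bits = self.bits.shape[1]

    def vector(self, compound_id) -> np.ndarray:
        return self.bits[self.compound_ids.index(compound_id)]

    def subset(self, compound_ids: Sequence) -> "FingerprintSet":
        idx = [self.compound_ids.index(c) for c in compound_ids]
        return FingerprintSet(list(compound_ids), self.bits[idx],
                              radius=self.radius, n_bits=self.n_bits)


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    if not smiles or not smiles.strip():
        raise StructureParseError("empty SMILES", offending=smiles)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureParseError(f"unparseable SMILES: {smiles!r}",
                                  offending=smiles)
    return mol


def standardize_structure(raw_smiles: str,
                          identifier_kind: str = "inchikey"
                          ) -> tuple[str, str]:
    """Standardize a SMILES and derive a canonical identifier.

    Applies, in order: sanitize + normalize functional groups, keep the
    largest organic fragment, neutralize charges, and canonicalize the
    tautomer.  Returns ``(canonical_smiles, identifier)`` where the
    identifier is the InChIKey (default) or InChI of the standardized
    structure.  Tautomer canonicalization failures fall back to the
    pre-tautomer form with a warning.
    """
    mol = _mol_from_smiles(raw_smiles)
    mol = rdMolStandardize.Cleanup(mol)  # sanitize + normalize groups
    mol = rdMolStandardize.LargestFragmentChooser().choose(mol)
    mol = rdMolStandardize.Uncharger().uncharge(mol)
    try:
        mol = rdMolStandardize.TautomerEnumerator().Canonicalize(mol)
    except Exception:  # pathological tautomer cases
        logger.warning("tautomer canonicalization failed for %r; "
                       "keeping pre-tautomer form", raw_smiles)
    smiles = Chem.MolToSmiles(mol)
    if identifier_kind == "inchikey":
        ident = Chem.MolToInchiKey(mol)
    elif identifier_kind == "inchi":
        ident = Chem.MolToInchi(mol)
    else:
        raise ContractViolation(
            f"identifier_kind must be 'inchikey' or 'inchi', "
            f"got {identifier_kind!r}")
    return smiles, ident


def morgan_fingerprint(smiles: str, radius: int = 2,
                       n_bits: int = 2048) -> np.ndarray:
    """Morgan (circular) fingerprint of a standardized structure."""
    mol = _mol_from_smiles(smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius,
                                                    fpSize=n_bits)
    return np.asarray(gen.GetFingerprint(mol), dtype=np.uint8)


def fingerprints_for(records: Iterable[CompoundRecord], radius: int = 2,
                     n_bits: int = 2048) -> FingerprintSet:
    recs = list(records)
    bits = np.vstack([morgan_fingerprint(r.standardized_smiles or
                                         r.raw_smiles, radius, n_bits)
                      for r in recs]) if recs else np.zeros((0, n_bits),
                                                            np.uint8)
    return FingerprintSet([r.identifier or r.raw_smiles for r in recs],
                          bits, radius=radius, n_bits=n_bits)


def resolve_labels(labels: Iterable[str]) -> str:
    """Resolve a multiset of observed labels to a single call.

    Toxic if mitotoxic at least once; otherwise inconclusive if any
    observation was inconclusive; otherwise nontoxic.
    """
    counts = Counter(labels)
    if not counts:
        raise ContractViolation("cannot resolve an empty label multiset")
    unknown = set(counts) - set(LABELS)
    if unknown:
        raise ContractViolation(f"unknown labels: {sorted(unknown)}")
    return max(counts, key=lambda lab: _LABEL_PRECEDENCE[lab])


def standardize_records(records: Iterable[CompoundRecord],
                        identifier_kind: str = "inchikey"
                        ) -> list[CompoundRecord]:
    """Standardize raw records; unparseable structures are skipped with a
    logged warning rather than aborting the curation run."""
    out = []
    for rec in records:
        try:
            smi, ident = standardize_structure(rec.raw_smiles,
                                               identifier_kind)
        except StructureParseError as exc:
            logger.warning("skipping unparseable structure %r: %s",
                           rec.raw_smiles, exc)
            continue
        rec.standardized_smiles = smi
        rec.identifier = ident
        out.append(rec)
    return out


def merge_by_identity(records: Iterable[CompoundRecord]
                      ) -> list[CompoundRecord]:
    """Deduplicate standardized records on their canonical identifier.

    Labels are merged with :func:`resolve_labels`; source tags are unioned.
    Output is sorted by identifier, so merging is invariant to the order of
    the input records.
    """
    merged: dict[str, list[CompoundRecord]] = {}
    for rec in records:
        if not rec.identifier:
            raise ContractViolation(
                "records must be standardized before merging")
        merged.setdefault(rec.identifier, []).append(rec)
    out = []
    for ident in sorted(merged):
        group = merged[ident]
        tags = set().union(*(r.source_tags for r in group))
        out.append(CompoundRecord(
            raw_smiles=group[0].raw_smiles,
            standardized_smiles=group[0].standardized_smiles,
            identifier=ident,
            label=resolve_labels(r.label for r in group),
            source_tags=tags))
    return out
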