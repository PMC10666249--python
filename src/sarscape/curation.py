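"""Bioactivity data curation.

Ingests ChEMBL-style activity exports (compound id, SMILES, IC50 value,
units, relation qualifier), applies the cleansing rules of the analysis
(drop records without SMILES or value, drop censored ``<``/``>`` records,
drop unparseable structures, deduplicate on canonical SMILES), converts
IC50 to pIC50 and assigns a three-level bioactivity class:

* active       pIC50 > 8        (group 1)
* intermediate 6 <= pIC50 <= 8  (group 2)
* inactive     pIC50 < 6        (group 3)
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

#: molar conversion factors for recognized concentration units
UNIT_TO_MOLAR: dict[str, float] = {"M": 1.0, "uM": 1e-6, "nM": 1e-9}


class Bioclass(str, Enum):
    ACTIVE = "active"
    INTERMEDIATE = "intermediate"
    INACTIVE = "inactive"


@dataclass(frozen=True)
class ActivityRecord:
    """One raw assay record as exported from an activity database."""

    record_id: str
    smiles: str | None = None
    value: float | None = None
    units: str | None = None
    relation: str | None = "="


@dataclass(frozen=True)
class CuratedCompound:
    """A cleansed compound with canonical structure, pIC50 and class."""

    record_id: str
    canonical_smiles: str
    pic50: float
    bioclass: Bioclass


class UnitError(ValueError):
    pass


def to_pic50(value: float, units: str) -> float:
    """Convert an IC50 magnitude in the given concentration unit to pIC50.

    pIC50 = -log10(IC50 in molar); larger means more potent.
    """
    if units not in UNIT_TO_MOLAR:
        raise UnitError(f"unrecognized concentration unit: {units!r}")
    if not (value > 0) or not math.isfinite(value):
        raise ValueError(f"IC50 value must be positive and finite, got {value!r}")
    return -math.log10(value * UNIT_TO_MOLAR[units])


def classify_bioactivity(pic50: float, active_inclusive: bool = False) -> Bioclass:
    """Assign the three-level bioactivity class from pIC50.

    ``active_inclusive`` flips the active boundary from strictly > 8 to >= 8.
    """
    if not math.isfinite(pic50):
        raise ValueError(f"pIC50 must be finite, got {pic50!r}")
    if pic50 >= 8 if active_inclusive else pic50 > 8:
        return Bioclass.ACTIVE
    if pic50 < 6:
        return Bioclass.INACTIVE
    return Bioclass.INTERMEDIATE


def canonicalize(smiles: str) -> str | None:
    """Canonical SMILES via RDKit, or None when the string does not parse."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


def clean_records(
    records: Iterable[ActivityRecord],
    active_inclusive: bool = False,
    aggregate_duplicates: bool = False,
) -> list[CuratedCompound]:
    """Apply the cleansing rules and return curated compounds.

    Records are rejected (with a logged reason) when the SMILES or the value
    is absent, the relation qualifier is censored (``<`` or ``>``), the
    SMILES does not parse, or the unit is not a recognized concentration
    unit. Duplicate structures (same canonical SMILES) collapse to one
    compound: by default the record with the lexicographically smallest
    record_id wins; with ``aggregate_duplicates`` the median pIC50 over the
    duplicates is used instead (id of the smallest-id member is kept).

    Output is sorted by record_id and is deterministic.
    """
    survivors: list[tuple[str, str, float]] = []  # (record_id, canonical, pic50)
    for rec in records:
        if rec.smiles is None or (isinstance(rec.smiles, float) and math.isnan(rec.smiles)) or rec.smiles == "":
            logger.info("reject %s: missing_smiles", rec.record_id)
            continue
        if rec.value is None or (isinstance(rec.value, float) and math.isnan(rec.value)):
            logger.info("reject %s: missing_value", rec.record_id)
            continue
        if rec.relation in ("<", ">"):
            logger.info("reject %s: censored_relation", rec.record_id)
            continue
        canonical = canonicalize(rec.smiles)
        if canonical is None:
            logger.info("reject %s: unparseable_smiles", rec.record_id)
            continue
        try:
            pic50 = to_pic50(rec.value, rec.units)
        except (UnitError, ValueError) as exc:
            logger.info("reject %s: %s", rec.record_id, exc)
            continue
        survivors.append((str(rec.record_id), canonical, pic50))

    by_smiles: dict[str, list[tuple[str, float]]] = {}
    for rid, canonical, pic50 in survivors:
        by_smiles.setdefault(canonical, []).append((rid, pic50))

    curated: list[CuratedCompound] = []
    for canonical, members in by_smiles.items():
        members.sort(key=lambda m: m[0])
        rid = members[0][0]
        if aggregate_duplicates:
            vals = sorted(p for _, p in members)
            mid = len(vals) // 2
            pic50 = vals[mid] if len(vals) % 2 else 0.5 * (vals[mid - 1] + vals[mid])
        else:
            pic50 = members[0][1]
        curated.append(
            CuratedCompound(
                record_id=rid,
                canonical_smiles=canonical,
                pic50=pic50,
                bioclass=classify_bioactivity(pic50, active_inclusive),
            )
        )
    curated.sort(key=lambda c: c.record_id)
    return curated


# ---------------------------------------------------------------------------
# I/O: ChEMBL-style activity export (CSV/TSV) and curated CSV

_EXPORT_COLUMNS = ["compound_id", "smiles", "standard_value", "standard_units", "standard_relation"]


def read_activity_export(path: str | Path, sep: str | None = None) -> list[ActivityRecord]:
    """Read a delimited activity export with the ChEMBL-style column names."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype={"compound_id": str, "smiles": str, "standard_relation": str})
    missing = [c for c in _EXPORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"activity export {path} lacks required columns: {missing}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            ActivityRecord(
                record_id=str(row.compound_id),
                smiles=None if pd.isna(row.smiles) else str(row.smiles),
                value=None if pd.isna(row.standard_value) else float(row.standard_value),
                units=None if pd.isna(row.standard_units) else str(row.standard_units),
                relation="=" if pd.isna(row.standard_relation) else str(row.standard_relation),
            )
        )
    return records


def curated_to_frame(compounds: Sequence[CuratedCompound]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "record_id": [c.record_id for c in compounds],
            "canonical_smiles": [c.canonical_smiles for c in compounds],
            "pic50": [c.pic50 for c in compounds],
            "bioclass": [c.bioclass.value for c in compounds],
        }
    )


def write_curated(compounds: Sequence[CuratedCompound], path: str | Path) -> None:
    curated_to_frame(compounds).to_csv(path, index=False)


def read_curated(path: str | Path) -> list[CuratedCompound]:
    df = pd.read_csv(path, dtype={"record_id": str})
    return [
        CuratedCompound(
            record_id=str(r.record_id),
            canonical_smiles=str(r.canonical_smiles),
            pic50=float(r.pic50),
            bioclass=Bioclass(r.bioclass),
        )
        for r in df.itertuples(index=False)
    ]
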