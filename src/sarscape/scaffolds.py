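"""Murcko scaffold and cyclic-skeleton analysis.

The Murcko scaffold of a molecule is its ring systems plus the linkers
connecting them, with terminal side chains removed; the cyclic skeleton
(generic framework) further replaces every atom by carbon and every bond
by a single bond, so it captures only the ring/linker shape. Acyclic
molecules have no scaffold and are reported as the empty string.

Diversity is summarised by the ratios Ns/N, Ncsk/N and Ncsk/Ns where N is
the number of compounds, Ns the number of distinct Murcko scaffolds and
Ncsk the number of distinct cyclic skeletons.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from .curation import CuratedCompound

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScaffoldRecord:
    compound_id: str
    murcko_smiles: str   # "" for acyclic molecules
    skeleton_smiles: str  # "" iff murcko is ""


@dataclass(frozen=True)
class ScaffoldDiversityReport:
    stratum: str
    n: int
    ns: int
    ncsk: int
    acyclic: int

    @property
    def ns_over_n(self) -> float:
        return self.ns / self.n

    @property
    def ncsk_over_n(self) -> float:
        return self.ncsk / self.n

    @property
    def ncsk_over_ns(self) -> float:
        return self.ncsk / self.ns if self.ns else float("nan")

    def rounded(self, ndigits: int = 3) -> dict[str, float]:
        return {
            "ns_over_n": round(self.ns_over_n, ndigits),
            "ncsk_over_n": round(self.ncsk_over_n, ndigits),
            "ncsk_over_ns": round(self.ncsk_over_ns, ndigits),
        }


def murcko_scaffold(smiles: str) -> str:
    """Canonical Murcko scaffold SMILES; empty string for acyclic input."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    if mol.GetRingInfo().NumRings() == 0:
        return ""
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    return Chem.MolToSmiles(scaffold)


def cyclic_skeleton(smiles: str) -> str:
    """Generic framework: Murcko scaffold with all atoms C, all bonds single."""
    murcko = murcko_scaffold(smiles)
    if not murcko:
        return ""
    generic = MurckoScaffold.MakeScaffoldGeneric(Chem.MolFromSmiles(murcko))
    return Chem.MolToSmiles(generic)


def scaffold_records(compounds: Sequence[CuratedCompound]) -> list[ScaffoldRecord]:
    return [
        ScaffoldRecord(
            compound_id=c.record_id,
            murcko_smiles=murcko_scaffold(c.canonical_smiles),
            skeleton_smiles=cyclic_skeleton(c.canonical_smiles),
        )
        for c in compounds
    ]


def scaffold_frequencies(records: Sequence[ScaffoldRecord]) -> tuple[list[tuple[str, int]], int]:
    """Ranked (scaffold, count) list plus the count of acyclic compounds.

    Descending by count; ties broken lexicographically by scaffold SMILES.
    Acyclic (empty-scaffold) compounds are excluded from the ranking.
    """
    counts = Counter(r.murcko_smiles for r in records if r.murcko_smiles)
    acyclic = sum(1 for r in records if not r.murcko_smiles)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked, acyclic


def diversity_report(
    compounds: Sequence[CuratedCompound],
    records: Sequence[ScaffoldRecord] | None = None,
    stratify_by_class: bool = True,
) -> list[ScaffoldDiversityReport]:
    """Scaffold diversity per stratum (complete set and, optionally, classes).

    Acyclic compounds count toward N but contribute no scaffold/skeleton.
    """
    if records is None:
        records = scaffold_records(compounds)
    by_id = {r.compound_id: r for r in records}

    def one(stratum: str, subset: Sequence[CuratedCompound]) -> ScaffoldDiversityReport:
        recs = [by_id[c.record_id] for c in subset]
        scaffolds = {r.murcko_smiles for r in recs if r.murcko_smiles}
        skeletons = {r.skeleton_smiles for r in recs if r.skeleton_smiles}
        return ScaffoldDiversityReport(
            stratum=stratum,
            n=len(subset),
            ns=len(scaffolds),
            ncsk=len(skeletons),
            acyclic=sum(1 for r in recs if not r.murcko_smiles),
        )

    out = [one("complete", compounds)]
    if stratify_by_class:
        for cls in ("active", "intermediate", "inactive"):
            subset = [c for c in compounds if c.bioclass.value == cls]
            if not subset:
                logger.warning("empty stratum %s omitted from diversity report", cls)
                continue
            out.append(one(cls, subset))
    return out


def diversity_frame(reports: Sequence[ScaffoldDiversityReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        rows.append(
            {
                "stratum": r.stratum,
                "n": r.n,
                "ns": r.ns,
                "ncsk": r.ncsk,
                **r.rounded(),
            }
        )
    return pd.DataFrame(rows)


def select_prevalent_subset(
    compounds: Sequence[CuratedCompound],
    records: Sequence[ScaffoldRecord] | None = None,
    min_freq: int = 10,
) -> tuple[list[CuratedCompound], list[str]]:
    """Compounds whose Murcko scaffold occurs at least ``min_freq`` times.

    Returns the subset (input order preserved) and the retained scaffold
    whitelist, ranked by frequency.
    """
    if records is None:
        records = scaffold_records(compounds)
    ranked, _ = scaffold_frequencies(records)
    whitelist = [s for s, cnt in ranked if cnt >= min_freq]
    allowed = set(whitelist)
    by_id = {r.compound_id: r for r in records}
    subset = [c for c in compounds if by_id[c.record_id].murcko_smiles in allowed]
    return subset, whitelist


def scaffold_activity_landscape(
    compounds: Sequence[CuratedCompound],
    records: Sequence[ScaffoldRecord] | None = None,
    active_threshold: float = 8.0,
) -> pd.DataFrame:
    """Per-scaffold activity summary with favorability.

    A scaffold is favorable iff any member's pIC50 strictly exceeds the
    active threshold.
    """
    if records is None:
        records = scaffold_records(compounds)
    by_id = {r.compound_id: r for r in records}
    groups: dict[str, list[float]] = {}
    for c in compounds:
        scaf = by_id[c.record_id].murcko_smiles
        if scaf:
            groups.setdefault(scaf, []).append(c.pic50)
    rows = []
    for scaf, vals in groups.items():
        arr = np.asarray(vals)
        rows.append(
            {
                "scaffold": scaf,
                "count": len(vals),
                "min_pic50": float(arr.min()),
                "median_pic50": float(np.median(arr)),
                "max_pic50": float(arr.max()),
                "favorable": bool(arr.max() > active_threshold),
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(["count", "scaffold"], ascending=[False, True]).reset_index(drop=True)
    return df


def write_whitelist(whitelist: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(whitelist) + ("\n" if whitelist else ""))


def read_whitelist(path: str | Path) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
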