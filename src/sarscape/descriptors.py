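"""Molecular descriptors and substructure fingerprints.

Three descriptor surfaces:

* :func:`physchem_profile` — the eight exploratory physicochemical
  descriptors (MW, LogP, nHA, nHD, nRot, TPSA, nHET, Aro).
* :func:`descriptor_matrix` — the large 2D descriptor block used for QSAR
  modelling (RDKit's full 2D descriptor list), sanitized so every retained
  column is finite across the dataset.
* :func:`fragment_fingerprint` — a 512-bit substructure-dictionary binary
  fingerprint with Tanimoto similarity, standing in for dictionary-based
  fragment fingerprints of desktop cheminformatics tools.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors

from .fragments import DICTIONARY_SIZE, load_dictionary

logger = logging.getLogger(__name__)

PHYSCHEM_NAMES = ["mw", "logp", "nha", "nhd", "nrot", "tpsa", "nhet", "aro"]


class SmilesParseError(ValueError):
    pass


def _mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparseable SMILES: {smiles!r}")
    # recanonicalize so additive descriptors (atom-contribution sums) are
    # bit-identical regardless of the input atom ordering
    return Chem.MolFromSmiles(Chem.MolToSmiles(mol))


@dataclass(frozen=True)
class PhyschemProfile:
    """Eight physicochemical descriptors of one molecule."""

    mw: float      # molecular weight, Da
    logp: float    # Crippen octanol-water partition coefficient
    nha: int       # H-bond acceptors
    nhd: int       # H-bond donors
    nrot: int      # rotatable bonds
    tpsa: float    # topological polar surface area, A^2
    nhet: int      # heteroatoms
    aro: int       # aromatic rings

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in PHYSCHEM_NAMES}


def physchem_profile(smiles: str) -> PhyschemProfile:
    """Compute the 8 exploratory descriptors for one SMILES."""
    mol = _mol(smiles)
    return PhyschemProfile(
        mw=Descriptors.MolWt(mol),
        logp=Crippen.MolLogP(mol),
        nha=Lipinski.NumHAcceptors(mol),
        nhd=Lipinski.NumHDonors(mol),
        nrot=Lipinski.NumRotatableBonds(mol),
        tpsa=rdMolDescriptors.CalcTPSA(mol),
        nhet=Lipinski.NumHeteroatoms(mol),
        aro=rdMolDescriptors.CalcNumAromaticRings(mol),
    )


def physchem_table(smiles_list: list[str], ids: list[str] | None = None) -> pd.DataFrame:
    """Eight-descriptor table, one row per molecule."""
    rows = [physchem_profile(s).as_dict() for s in smiles_list]
    index = ids if ids is not None else list(range(len(smiles_list)))
    return pd.DataFrame(rows, index=pd.Index(index, name="compound_id"))


def descriptor_matrix(
    smiles_list: list[str], ids: list[str] | None = None
) -> pd.DataFrame:
    """Large 2D descriptor block (rows = compounds, columns = descriptors).

    Columns containing any non-finite value across the dataset are dropped
    (and logged) rather than imputed; the remaining column order follows the
    descriptor registry and is deterministic.
    """
    index = ids if ids is not None else list(range(len(smiles_list)))
    rows = []
    for i, smiles in enumerate(smiles_list):
        try:
            mol = _mol(smiles)
        except SmilesParseError as exc:
            raise SmilesParseError(f"row {i} ({index[i]}): {exc}") from None
        rows.append(Descriptors.CalcMolDescriptors(mol))
    df = pd.DataFrame(rows, index=pd.Index(index, name="compound_id"))
    df = df.astype(float)
    finite = np.isfinite(df.to_numpy()).all(axis=0)
    dropped = [c for c, ok in zip(df.columns, finite) if not ok]
    if dropped:
        logger.info("dropping %d non-finite descriptor columns: %s", len(dropped), dropped[:10])
    return df.loc[:, df.columns[finite]]


@dataclass(frozen=True)
class BinaryFingerprint:
    """Fixed-length substructure-dictionary bit vector."""

    bits: frozenset[int]
    length: int = DICTIONARY_SIZE

    def __post_init__(self) -> None:
        if self.bits and (min(self.bits) < 0 or max(self.bits) >= self.length):
            raise ValueError("bit index outside fingerprint length")

    @property
    def popcount(self) -> int:
        return len(self.bits)

    def as_array(self) -> np.ndarray:
        arr = np.zeros(self.length, dtype=np.uint8)
        arr[list(self.bits)] = 1
        return arr


_DICTIONARY_CACHE: list | None = None


def _dictionary_mols() -> list:
    global _DICTIONARY_CACHE
    if _DICTIONARY_CACHE is None:
        _DICTIONARY_CACHE = [Chem.MolFromSmarts(s) for s in load_dictionary()]
    return _DICTIONARY_CACHE


def fragment_fingerprint(smiles: str) -> BinaryFingerprint:
    """512-bit dictionary fingerprint: bit i set iff fragment i matches."""
    mol = _mol(smiles)
    bits = frozenset(
        i for i, patt in enumerate(_dictionary_mols()) if mol.HasSubstructMatch(patt)
    )
    return BinaryFingerprint(bits=bits)


def tanimoto(fp1: BinaryFingerprint, fp2: BinaryFingerprint) -> float:
    """Tanimoto similarity |a AND b| / |a OR b|; 1.0 when both are empty."""
    if fp1.length != fp2.length:
        raise ValueError(f"fingerprint length mismatch: {fp1.length} != {fp2.length}")
    union = len(fp1.bits | fp2.bits)
    if union == 0:
        return 1.0
    return len(fp1.bits & fp2.bits) / union
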