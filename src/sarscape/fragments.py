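"""A 512-entry substructure fragment dictionary.

Substructure-dictionary fingerprints encode, for each molecule, which of a
fixed set of predefined fragments it contains. The dictionary used here is
built by a deterministic enumeration of element primitives, bonded pairs,
short linear paths, functional groups, ring systems and branching motifs,
padded/truncated to exactly 512 SMARTS patterns, and frozen as a packaged
text file so the bit assignment is stable across releases.

Because every bit is a plain substructure match, the fingerprint has the
superstructure property: any fragment bit set for a substructure is also
set for every molecule containing that substructure.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from rdkit import Chem

DICTIONARY_SIZE = 512
_DATA_FILE = "fragment_dictionary.smarts"

_FUNCTIONAL_GROUPS = [
    # carbonyl chemistry
    "[CX3]=[OX1]", "[CX3](=O)[OX2H1]", "[CX3](=O)[OX1-]", "[CX3](=O)O[#6]",
    "[CX3](=O)[NX3]", "[CX3H1]=O", "[CX3](=O)[#6]", "O=C([NX3])[NX3]",
    "[NX3][CX3](=O)O[#6]", "O=C1CCCN1", "O=C1CCCCN1",
    # nitrogen groups
    "[NX3;H2][#6]", "[NX3;H1]([#6])[#6]", "[NX3]([#6])([#6])[#6]",
    "[NX3+0](=O)=O", "[NX1]#[CX2]", "[NX2]=[NX2]", "[NX3][NX3]",
    "[NX2]=[CX3]", "NC(=N)N", "[#6]C(=N)N", "[NX3][OX2H1]", "[NX2]=[OX1]",
    "[nH]", "[NX4+]", "[NX3+]=[CX3]",
    # oxygen groups
    "[OX2H]", "[OX2H][CX4]", "[OX2H]c", "[OX2]([#6])[#6]", "[OX2H][CX3]=[OX1]",
    "[#6][OX2][#6]=O", "C1CO1", "[OX1-]",
    # sulfur / phosphorus
    "[SX2H]", "[SX2]([#6])[#6]", "[SX3]=[OX1]", "[SX4](=[OX1])(=[OX1])",
    "[SX4](=O)(=O)[NX3]", "[SX4](=O)(=O)[OX2H1]", "[#16X2][#16X2]", "s",
    "[PX4](=[OX1])", "[PX4](=O)([OX2])([OX2])", "P",
    # halogens on carbon
    "[#6]F", "[#6]Cl", "[#6]Br", "[#6]I", "cF", "cCl", "cBr", "cI",
    "C(F)(F)F", "[CX4](F)F",
    # misc pharmacophoric motifs
    "[#6]=[#6][CX3]=[OX1]", "[OX2H][#6][#6][NX3]", "[NX3][#6][CX3](=O)[OX2H1]",
    "[#6](=O)[#6][#6](=O)", "c-[NX3]", "c-[OX2H]", "c-[CX3]=[OX1]",
    "c[CX4]", "c-[SX2]", "c-[NX3](=O)=O", "cC#N",
    "C=C=C", "C#CC", "[OX2][CX4][OX2]", "[SX2][CX3]=[OX1]",
    "[NX3]S(=O)=O", "[#6]=[#7][#7]", "[OX2][NX2]=[#6]", "[F][CX4][F]",
]

_RINGS = [
    "C1CC1", "C1CCC1", "C1CCCC1", "C1CCCCC1", "C1CCCCCC1", "C1CCCCCCC1",
    "C1=CCCCC1", "C1=CCCC1", "c1ccccc1",
    "C1CCNC1", "C1CCNCC1", "C1CCOC1", "C1CCOCC1", "C1CCSC1", "C1CCSCC1",
    "C1CNCCN1", "C1COCCN1", "C1CCNCCC1", "N1CCNCC1", "C1OCCO1", "C1OCOC1",
    "c1cc[nH]c1", "c1ccoc1", "c1ccsc1", "c1cnc[nH]1", "c1cn[nH]c1",
    "c1ccncc1", "c1ccnnc1", "c1cncnc1", "c1cnncn1", "a1aaaa1", "a1aaaaa1",
    "c1ccc2ccccc2c1", "c1ccc2[nH]ccc2c1", "c1ccc2occc2c1", "c1ccc2sccc2c1",
    "c1ccc2ncccc12", "c1ccc2[nH]cnc2c1", "c1ccc2OCOc2c1",
    "C1CCc2ccccc2C1", "C1Cc2ccccc2C1", "C1CCC2CCCCC2C1", "O=c1cccc[nH]1",
    "[r3]", "[r4]", "[r5]", "[r6]", "[r7]", "[r8]", "[R2]",
]

_ATOM_PRIMITIVES = [
    "[#5]", "[#7]", "[#8]", "[#9]", "[#14]", "[#15]", "[#16]", "[#17]",
    "[#35]", "[#53]", "[F,Cl,Br,I]", "[+]", "[-]", "c", "n", "o",
    "[CX4]", "[CX3]", "[CX2]", "[NX3]", "[NX2]", "[NX1]", "[OX2]", "[OX1]",
    "[#6;R]", "[#7;R]", "[#8;R]", "[#16;R]",
]

_BONDED_PAIRS = [
    "C-C", "C=C", "C#C", "C-N", "C=N", "C#N", "C-O", "C=O", "C-S", "C=S",
    "C-P", "N-N", "N=N", "N-O", "N=O", "N-S", "O-S", "O-P", "S=O", "N-P",
    "cc", "cn", "co", "cs", "nn", "c:n:c", "n:c:n", "C=C-C=C", "C=C-C=O",
    "c-C", "c-N", "c-O", "c-S", "c-c",
]

_BRANCHING = [
    "C(C)C", "C(C)(C)C", "C(C)(C)(C)C", "C(N)N", "C(O)O", "N(C)C",
    "C(c)c", "c(c)(c)c", "C(F)F", "C(Cl)Cl",
]


def _carbon_chains() -> list[str]:
    return ["C" * n for n in range(2, 9)]


def _linear_paths() -> list[str]:
    """Canonical (lexicographically minimal vs reversal) element paths."""
    elems = ["C", "N", "O", "S"]
    out = []
    for length in (3, 4):
        seen = set()
        for idx in range(len(elems) ** length):
            seq, k = [], idx
            for _ in range(length):
                seq.append(elems[k % len(elems)])
                k //= len(elems)
            seq = tuple(seq)
            canon = min(seq, seq[::-1])
            if canon not in seen:
                seen.add(canon)
                out.append("".join(canon))
    return out


def _distance_patterns() -> list[str]:
    """Element pairs separated by one to three arbitrary atoms."""
    elems = ["#6", "#7", "#8", "#16", "#9", "#17", "#35"]
    out = []
    for gap in ("~*~", "~*~*~", "~*~*~*~"):
        for i, a in enumerate(elems):
            for b in elems[i:]:
                out.append(f"[{a}]{gap}[{b}]")
    aromatic = ["c", "n", "o", "s"]
    for i, a in enumerate(aromatic):
        for b in aromatic[i:]:
            out.append(f"{a}~a~{b}")
            out.append(f"{a}~a~a~{b}")
            out.append(f"{a}~a~a~a~{b}")
    elems_n = ["#7", "#8", "#16", "#9", "#17"]
    for i, a in enumerate(elems_n):
        for b in elems_n[i:]:
            out.append(f"[{a}]~*~*~*~*~[{b}]")
    return out


_HYBRID_PAIRS = [
    "[CX4][CX4]", "[CX4][CX3]", "[CX3][CX3]", "[CX4][NX3]", "[CX3][NX3]",
    "[CX4][OX2]", "[CX3][OX2]", "[CX4][SX2]", "[CX4]c", "[CX3]c",
    "[NX3]c", "[OX2]c", "[CX2][CX4]", "[CX2]c",
]


def build_default_dictionary() -> list[str]:
    """Deterministically enumerate the 512 SMARTS fragment dictionary."""
    raw = (
        _ATOM_PRIMITIVES
        + _BONDED_PAIRS
        + _carbon_chains()
        + _FUNCTIONAL_GROUPS
        + _RINGS
        + _BRANCHING
        + _HYBRID_PAIRS
        + _linear_paths()
        + _distance_patterns()
    )
    seen: set[str] = set()
    patterns: list[str] = []
    for smarts in raw:
        if smarts in seen:
            continue
        if Chem.MolFromSmarts(smarts) is None:  # pragma: no cover - all entries valid
            raise ValueError(f"invalid SMARTS in dictionary source: {smarts}")
        seen.add(smarts)
        patterns.append(smarts)
    if len(patterns) < DICTIONARY_SIZE:  # pragma: no cover
        raise ValueError(f"dictionary source too small: {len(patterns)} < {DICTIONARY_SIZE}")
    return patterns[:DICTIONARY_SIZE]


def load_dictionary() -> list[str]:
    """Load the frozen 512-SMARTS dictionary shipped with the package."""
    ref = resources.files("sarscape").joinpath("data").joinpath(_DATA_FILE)
    lines = [ln.strip() for ln in ref.read_text().splitlines()]
    patterns = [ln for ln in lines if ln and not ln.startswith("#")]
    if len(patterns) != DICTIONARY_SIZE:
        raise ValueError(f"frozen dictionary has {len(patterns)} entries, expected {DICTIONARY_SIZE}")
    return patterns


def write_dictionary(path: str | Path) -> None:
    """Regenerate the frozen dictionary file (maintenance helper)."""
    patterns = build_default_dictionary()
    Path(path).write_text(
        "# sarscape substructure fragment dictionary v1 (512 SMARTS, one per line)\n"
        + "\n".join(patterns)
        + "\n"
    )
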