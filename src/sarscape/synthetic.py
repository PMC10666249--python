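"""Synthetic bioactivity dataset generator.

Emits ChEMBL-style activity records with the statistical structure the
analysis pipeline assumes, so every stage is testable without external
downloads:

* a scaffold-frequency distribution where a few scaffold templates
  dominate (>= 10 members each) amid a long tail of singleton scaffolds;
* pIC50 values spanning roughly 4-10 with scaffold-dependent means
  (true pIC50 = scaffold base + substituent effects + Gaussian noise);
* optionally, exact three-class counts (classes assigned first, pIC50
  sampled inside the class interval);
* planted activity-cliff pairs: two decorations of the same template
  differing by one small substituent swap (high fragment-fingerprint
  similarity) and by an exact pIC50 gap.

Molecules are assembled by decorating scaffold template strings with a
small frozen vocabulary of substituent fragments; IC50 values are emitted
in nM as 10^(9 - pIC50), so the curation module is exercised on realistic
units. Everything is reproducible per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from rdkit import Chem

from .curation import ActivityRecord
from .descriptors import fragment_fingerprint, tanimoto
from .scaffolds import murcko_scaffold

# ---------------------------------------------------------------------------
# substituent vocabulary (frozen in data/substituents.csv)
#
# Each substituent has a "prefix" spelling (prepended to a template, bonds
# into its first atom) and a "suffix" spelling (appended inside a branch,
# bonds out of a ring atom), plus a signed activity effect in pIC50 units.

_SUBSTITUENT_FILE = "substituents.csv"
_VOCAB_CACHE: pd.DataFrame | None = None


def load_substituents() -> pd.DataFrame:
    """The frozen R-group vocabulary: name, prefix/suffix SMILES, effect."""
    global _VOCAB_CACHE
    if _VOCAB_CACHE is None:
        ref = resources.files("sarscape").joinpath("data").joinpath(_SUBSTITUENT_FILE)
        with resources.as_file(ref) as path:
            _VOCAB_CACHE = pd.read_csv(path, keep_default_na=False)
    return _VOCAB_CACHE


# Nine prevalent scaffold templates with two decoration slots {a} (prefix)
# and {b} (branch). Ring systems are pairwise distinct so each template
# maps to its own Murcko scaffold.
PREVALENT_TEMPLATES: list[str] = [
    "{a}C1Cc2ccccc2CN1C(=O)C{b}",            # tetrahydroisoquinoline amide
    "{a}C(=O)N1CCCC1C(=O)O{b}",              # N-acyl proline
    "{a}C1CCC(=O)N(C{b})c2ccccc21",          # benzazepinone
    "{a}C1CCN(C{b})CC1",                     # piperidine
    "{a}c1ccc(C{b})cc1",                     # benzene
    "{a}c1ccc(C{b})nc1",                     # pyridine
    "{a}c1ccc2c(c1)c(C{b})c[nH]2",           # indole
    "{a}c1ccc2cc(C{b})ccc2c1",               # naphthalene
    "{a}c1ccc(N2CCN(C{b})CC2)cc1",           # phenylpiperazine
]

# ring and linker fragments for the long diverse scaffold tail
_TAIL_RINGS = [
    "c1ccccc1", "c1ccncc1", "c1ccoc1", "c1ccsc1", "c1cc[nH]c1",
    "c1cncnc1", "C1CCCCC1", "C1CCCC1", "C1CCNCC1", "C1CCOCC1",
    "C1CNCCN1", "c1ccc2ccccc2c1",
]
_TAIL_LINKERS = ["", "C", "CC", "O", "OC", "N", "C(=O)", "C(=O)N", "S", "CN", "CCC", "OCC"]


def assemble(template: str, a: str = "", b: str = "") -> str:
    """Decorate a two-slot template and return canonical SMILES."""
    smiles = template.replace("{a}", a)
    smiles = smiles.replace("{b}", b)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"template {template!r} with a={a!r}, b={b!r} is not chemically valid")
    return Chem.MolToSmiles(mol)


@dataclass
class CliffSpec:
    template_index: int
    delta_pic50: float
    count: int = 1


@dataclass
class SyntheticConfig:
    """Study conditions for the generator.

    Defaults emulate the shape of a curated ACE-inhibitor extraction: nine
    dominant scaffolds (10-40 members each, 168 compounds total) over a
    long tail of rare scaffolds, pIC50 spanning ~4-10 with scaffold-
    dependent means, and a handful of planted activity cliffs.
    """

    scaffold_templates: list[str] = field(default_factory=lambda: list(PREVALENT_TEMPLATES))
    per_scaffold_counts: list[int] = field(
        default_factory=lambda: [40, 25, 22, 18, 16, 14, 12, 11, 10]
    )
    base_pic50: list[float] = field(
        default_factory=lambda: [8.8, 7.9, 7.2, 6.8, 6.5, 6.2, 5.8, 5.3, 4.8]
    )
    substituent_effects: dict[str, float] | None = None  # None -> frozen vocabulary values
    noise_sd: float = 0.1
    cliff_specs: list[CliffSpec] = field(default_factory=list)
    tail_scaffold_counts: list[int] = field(default_factory=list)  # members per tail scaffold
    class_targets: tuple[int, int, int] | None = None  # (active, intermediate, inactive)
    seed: int = 42

    def __post_init__(self) -> None:
        if len(self.per_scaffold_counts) != len(self.scaffold_templates):
            raise ValueError("per_scaffold_counts must match scaffold_templates")
        if len(self.base_pic50) != len(self.scaffold_templates):
            raise ValueError("base_pic50 must match scaffold_templates")
        if any(c <= 0 for c in self.per_scaffold_counts):
            raise ValueError("per-scaffold counts must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if any(c.delta_pic50 <= 0 for c in self.cliff_specs):
            raise ValueError("cliff delta_pic50 must be positive")


def _effects(config: SyntheticConfig) -> dict[str, float]:
    if config.substituent_effects is not None:
        return dict(config.substituent_effects)
    vocab = load_substituents()
    return dict(zip(vocab["name"], vocab["effect"].astype(float)))


def _decorations(rng: np.random.Generator, count: int) -> list[tuple[str, str]]:
    """Deterministically sample ``count`` distinct (a, b) substituent pairs."""
    vocab = load_substituents()
    names = list(vocab["name"])
    combos = [(na, nb) for na in names for nb in names]
    if count > len(combos):
        raise ValueError(f"template supports at most {len(combos)} distinct decorations")
    order = rng.permutation(len(combos))
    return [combos[i] for i in order[:count]]


def _vocab_maps() -> tuple[dict[str, str], dict[str, str]]:
    vocab = load_substituents()
    prefix = dict(zip(vocab["name"], vocab["prefix"]))
    suffix = dict(zip(vocab["name"], vocab["suffix"]))
    return prefix, suffix


@dataclass
class _Slot:
    """One molecule under construction."""

    smiles: str
    scaffold_key: str      # template string or tail core id
    scaffold_base: float
    effect_sum: float
    substituents: str
    cliff_pair: int = -1   # pair id, -1 when not planted
    forced_pic50: float | None = None
    forced_class: str | None = None


def plant_cliff_pair(
    template: str,
    delta_pic50: float,
    base_pic50: float = 7.5,
    branch_name: str = "fluoro",
    pair_id: int = 0,
) -> tuple[_Slot, _Slot]:
    """Two decorations of one template differing by a methyl->chloro swap
    (one heavy atom, but visible to the fragment dictionary so similarity
    stays below 1) and by exactly ``delta_pic50`` in true activity."""
    if delta_pic50 <= 0:
        raise ValueError("delta_pic50 must be positive")
    if "{a}" not in template:
        raise ValueError(f"template lacks an attachment slot: {template!r}")
    prefix, suffix = _vocab_maps()
    b = suffix[branch_name]
    hi = assemble(template, prefix["methyl"], b)
    lo = assemble(template, prefix["chloro"], b)
    if hi == lo:
        raise ValueError("cliff pair collapsed to one structure")
    mk = lambda s, p: _Slot(
        smiles=s, scaffold_key=template, scaffold_base=base_pic50, effect_sum=0.0,
        substituents=f"cliff:{branch_name}", cliff_pair=pair_id, forced_pic50=p,
    )
    return mk(hi, base_pic50 + delta_pic50 / 2), mk(lo, base_pic50 - delta_pic50 / 2)


def _build_slots(config: SyntheticConfig, rng: np.random.Generator) -> list[_Slot]:
    prefix, suffix = _vocab_maps()
    effects = _effects(config)
    slots: list[_Slot] = []
    used_smiles: set[str] = set()
    used_scaffolds: set[str] = set()

    # planted cliffs first (they consume template decorations deterministically)
    pair_id = 0
    cliff_budget: dict[int, int] = {}
    for spec in config.cliff_specs:
        base = config.base_pic50[spec.template_index]
        vocab_names = list(load_substituents()["name"])
        for k in range(spec.count):
            branch = vocab_names[(3 + k) % len(vocab_names)]
            hi, lo = plant_cliff_pair(
                config.scaffold_templates[spec.template_index],
                spec.delta_pic50,
                base_pic50=base,
                branch_name=branch,
                pair_id=pair_id,
            )
            pair_id += 1
            for s in (hi, lo):
                if s.smiles in used_smiles:
                    raise ValueError("cliff pair collides with an existing structure")
                used_smiles.add(s.smiles)
                slots.append(s)
            cliff_budget[spec.template_index] = cliff_budget.get(spec.template_index, 0) + 2

    # prevalent templates
    for t, (template, count, base) in enumerate(
        zip(config.scaffold_templates, config.per_scaffold_counts, config.base_pic50)
    ):
        remaining = count - cliff_budget.get(t, 0)
        if remaining < 0:
            raise ValueError(f"template {t} has more cliff members than its count")
        decorations = _decorations(rng, count + 16)  # head room for collisions
        taken = 0
        for na, nb in decorations:
            if taken == remaining:
                break
            smiles = assemble(template, prefix[na], suffix[nb])
            if smiles in used_smiles:
                continue
            used_smiles.add(smiles)
            slots.append(
                _Slot(
                    smiles=smiles,
                    scaffold_key=template,
                    scaffold_base=base,
                    effect_sum=effects.get(na, 0.0) + effects.get(nb, 0.0),
                    substituents=f"{na}+{nb}",
                )
            )
            taken += 1
        if taken < remaining:
            raise ValueError(f"could not realize {remaining} distinct members of template {t}")
        used_scaffolds.add(murcko_scaffold(assemble(template)))

    # long diverse tail
    if config.tail_scaffold_counts:
        cores = []
        for ra in _TAIL_RINGS:
            for rb in _TAIL_RINGS:
                for ln in _TAIL_LINKERS:
                    cores.append(ra + ln + rb)
        order = rng.permutation(len(cores))
        vocab_names = list(load_substituents()["name"])
        core_iter = iter(order)
        for tail_count in config.tail_scaffold_counts:
            # find the next core with a fresh scaffold
            while True:
                try:
                    core = cores[next(core_iter)]
                except StopIteration:  # pragma: no cover - vocabulary is ample
                    raise ValueError("exhausted tail scaffold cores") from None
                mol = Chem.MolFromSmiles(core)
                if mol is None:
                    continue
                scaf = murcko_scaffold(core)
                if scaf and scaf not in used_scaffolds:
                    used_scaffolds.add(scaf)
                    break
            base = float(rng.uniform(4.5, 9.5))
            placed = 0
            for na in vocab_names:
                if placed == tail_count:
                    break
                smiles = assemble("{a}" + core, prefix[na])
                if smiles in used_smiles:
                    continue
                used_smiles.add(smiles)
                slots.append(
                    _Slot(
                        smiles=smiles,
                        scaffold_key=core,
                        scaffold_base=base,
                        effect_sum=effects.get(na, 0.0),
                        substituents=na,
                    )
                )
                placed += 1
            if placed < tail_count:
                raise ValueError(f"could not realize {tail_count} members on tail core {core}")
    return slots


_CLASS_INTERVALS = {
    "active": (8.10, 9.95),
    "intermediate": (6.05, 7.95),
    "inactive": (4.05, 5.95),
}


def _assign_forced_classes(
    slots: list[_Slot], targets: tuple[int, int, int], rng: np.random.Generator
) -> None:
    """Assign classes with exact counts, ordered by scaffold potency, and
    sample pIC50 inside the class interval (rank-matched so scaffold means
    stay ordered)."""
    n_act, n_int, n_ina = targets
    free = [s for s in slots if s.forced_pic50 is None]
    planted_act = sum(1 for s in slots if s.forced_pic50 is not None and s.forced_pic50 > 8)
    planted_ina = sum(1 for s in slots if s.forced_pic50 is not None and s.forced_pic50 < 6)
    planted_int = sum(1 for s in slots if s.forced_pic50 is not None) - planted_act - planted_ina
    need = {
        "active": n_act - planted_act,
        "intermediate": n_int - planted_int,
        "inactive": n_ina - planted_ina,
    }
    if any(v < 0 for v in need.values()):
        raise ValueError("planted cliffs exceed the class targets")
    if sum(need.values()) != len(free):
        raise ValueError(
            f"class targets {targets} do not sum to the dataset size ({len(slots)})"
        )
    score = np.array([s.scaffold_base + s.effect_sum for s in free]) + rng.normal(
        0, 0.8, size=len(free)
    )
    order = np.argsort(-score, kind="stable")
    boundaries = [("active", need["active"]), ("intermediate", need["intermediate"]),
                  ("inactive", need["inactive"])]
    pos = 0
    for cls, count in boundaries:
        lo, hi = _CLASS_INTERVALS[cls]
        members = order[pos : pos + count]
        pos += count
        draws = np.sort(rng.uniform(lo, hi, size=count))[::-1]  # high pIC50 to high score
        for rank, idx in enumerate(sorted(members, key=lambda i: -score[i])):
            free[idx].forced_pic50 = float(draws[rank])
            free[idx].forced_class = cls


def generate_dataset(config: SyntheticConfig) -> tuple[list[ActivityRecord], pd.DataFrame]:
    """Generate activity records and the ground-truth table.

    True pIC50 is scaffold base + substituent effects + N(0, noise_sd),
    except for planted cliff members (exact values) and class-forced
    datasets (sampled inside the class interval). IC50 is emitted in nM as
    10^(9 - pIC50).
    """
    rng = np.random.default_rng(config.seed)
    slots = _build_slots(config, rng)
    if config.class_targets is not None:
        _assign_forced_classes(slots, config.class_targets, rng)

    records: list[ActivityRecord] = []
    truth_rows = []
    width = max(4, len(str(len(slots))))
    for i, slot in enumerate(slots):
        if slot.forced_pic50 is not None:
            pic50 = slot.forced_pic50
        else:
            pic50 = slot.scaffold_base + slot.effect_sum + float(rng.normal(0, config.noise_sd))
        rid = f"SYN-{i:0{width}d}"
        records.append(
            ActivityRecord(
                record_id=rid,
                smiles=slot.smiles,
                value=10 ** (9.0 - pic50),
                units="nM",
                relation="=",
            )
        )
        truth_rows.append(
            {
                "record_id": rid,
                "smiles": slot.smiles,
                "scaffold_key": slot.scaffold_key,
                "scaffold_base": slot.scaffold_base,
                "effect_sum": slot.effect_sum,
                "substituents": slot.substituents,
                "true_pic50": pic50,
                "cliff_pair": slot.cliff_pair,
            }
        )
    truth = pd.DataFrame(truth_rows)

    # publish realized similarity and planted SALI for cliff pairs
    truth["planted_sali"] = np.nan
    truth["pair_similarity"] = np.nan
    for pid in sorted(truth.loc[truth.cliff_pair >= 0, "cliff_pair"].unique()):
        pair = truth.index[truth.cliff_pair == pid]
        fa = fragment_fingerprint(truth.loc[pair[0], "smiles"])
        fb = fragment_fingerprint(truth.loc[pair[1], "smiles"])
        sim = tanimoto(fa, fb)
        delta = abs(truth.loc[pair[0], "true_pic50"] - truth.loc[pair[1], "true_pic50"])
        sali = delta / (1 - sim) if sim < 1 else np.inf
        truth.loc[pair, "pair_similarity"] = sim
        truth.loc[pair, "planted_sali"] = sali
    return records, truth


def emulate_study_shape(seed: int = 42) -> tuple[list[ActivityRecord], pd.DataFrame]:
    """A 549-compound dataset with exact class counts 148/247/154.

    Nine prevalent scaffolds (frequencies 40..10, 168 compounds) over a
    long tail of 254 rare scaffolds, with four planted activity cliffs
    (pIC50 gap 4.0) inside favorable prevalent scaffolds. Class membership
    is assigned first (exactly 148 active / 247 intermediate / 154
    inactive) and pIC50 is sampled inside the class interval, scaffold-
    rank matched; the output is intended to be verified through the
    curation module.
    """
    tail = [3] * 24 + [2] * 79 + [1] * 151  # 381 compounds, 254 scaffolds
    config = SyntheticConfig(
        cliff_specs=[
            CliffSpec(template_index=1, delta_pic50=4.0, count=2),
            CliffSpec(template_index=2, delta_pic50=4.0, count=1),
            CliffSpec(template_index=4, delta_pic50=4.0, count=1),
        ],
        tail_scaffold_counts=tail,
        class_targets=(148, 247, 154),
        seed=seed,
    )
    return generate_dataset(config)


def write_activity_export(records: list[ActivityRecord], path) -> None:
    """Write records as the ChEMBL-style CSV the curation reader consumes."""
    pd.DataFrame(
        {
            "compound_id": [r.record_id for r in records],
            "smiles": [r.smiles for r in records],
            "standard_value": [r.value for r in records],
            "standard_units": [r.units for r in records],
            "standard_relation": [r.relation for r in records],
        }
    ).to_csv(path, index=False)
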