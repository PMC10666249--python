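"""Structure-Activity Landscape Index (SALI) and activity-cliff networks.

For a pair of compounds m1, m2 with activities A_m1, A_m2 (pIC50) and
fingerprint similarity sim(m1, m2), the landscape index is

    SALI = |A_m1 - A_m2| / (1 - sim(m1, m2))

Large SALI marks activity cliffs: structurally similar pairs with very
different potencies. Identical structures (sim = 1) make the quotient
singular; such pairs are reported at a configurable ceiling and flagged
as capped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx

from .curation import CuratedCompound
from .descriptors import BinaryFingerprint, tanimoto

DEFAULT_SALI_CAP = 1e6
DEFAULT_SIM_FLOOR = 0.8


@dataclass(frozen=True)
class SALIEdge:
    """Undirected compound pair with similarity, activity delta and SALI."""

    id_a: str
    id_b: str
    similarity: float
    delta_activity: float
    sali: float
    capped: bool = False
    cliff: bool = False

    def __post_init__(self) -> None:
        if self.id_a >= self.id_b:
            raise ValueError("SALIEdge requires id_a < id_b (canonical ordering)")


def sali_value(a1: float, a2: float, sim: float, cap: float = DEFAULT_SALI_CAP) -> tuple[float, bool]:
    """SALI of one pair; returns (value, capped).

    sim = 1 with different activities is reported as the cap with
    ``capped=True``; sim = 1 with equal activities is 0.
    """
    if not 0.0 <= sim <= 1.0:
        raise ValueError(f"similarity must be in [0, 1], got {sim}")
    delta = abs(a1 - a2)
    if sim == 1.0:
        return (0.0, False) if delta == 0.0 else (cap, True)
    return delta / (1.0 - sim), False


def sali_matrix(
    compounds: Sequence[CuratedCompound],
    fingerprints: Mapping[str, BinaryFingerprint],
    sim_floor: float = 0.0,
    cap: float = DEFAULT_SALI_CAP,
) -> list[SALIEdge]:
    """All-pairs SALI edges for pairs with similarity >= sim_floor."""
    for c in compounds:
        if c.record_id not in fingerprints:
            raise KeyError(f"missing fingerprint for compound {c.record_id}")
    edges: list[SALIEdge] = []
    ordered = sorted(compounds, key=lambda c: c.record_id)
    for i, ca in enumerate(ordered):
        for cb in ordered[i + 1 :]:
            sim = tanimoto(fingerprints[ca.record_id], fingerprints[cb.record_id])
            if sim < sim_floor:
                continue
            value, capped = sali_value(ca.pic50, cb.pic50, sim, cap)
            edges.append(
                SALIEdge(
                    id_a=ca.record_id,
                    id_b=cb.record_id,
                    similarity=sim,
                    delta_activity=abs(ca.pic50 - cb.pic50),
                    sali=value,
                    capped=capped,
                )
            )
    return edges


def detect_cliffs(
    edges: Sequence[SALIEdge], mode: str = "top_fraction", param: float = 0.01
) -> list[SALIEdge]:
    """Flag activity-cliff edges.

    ``sali_threshold`` mode flags edges with SALI >= param; ``top_fraction``
    flags the ceil(param * |edges|) largest by SALI (ties broken toward the
    lower canonical pair id).
    """
    if param <= 0:
        raise ValueError("param must be positive")
    if mode == "sali_threshold":
        return [replace(e, cliff=e.sali >= param) for e in edges]
    if mode == "top_fraction":
        if not edges:
            raise ValueError("top_fraction mode requires a nonempty edge list")
        k = math.ceil(param * len(edges))
        ranked = sorted(edges, key=lambda e: (-e.sali, e.id_a, e.id_b))
        flagged = {(e.id_a, e.id_b) for e in ranked[:k]}
        return [replace(e, cliff=(e.id_a, e.id_b) in flagged) for e in edges]
    raise ValueError(f"unknown cliff-detection mode: {mode!r}")


def build_network(
    compounds: Sequence[CuratedCompound],
    edges: Sequence[SALIEdge],
    scaffold_freq: Mapping[str, int] | None = None,
) -> nx.Graph:
    """Cliff network: nodes annotated with pIC50 (and scaffold frequency),
    edges with similarity/delta/SALI/cliff flag."""
    g = nx.Graph()
    ids = set()
    for c in compounds:
        attrs = {"pic50": c.pic50, "bioclass": c.bioclass.value}
        if scaffold_freq is not None:
            attrs["scaffold_freq"] = int(scaffold_freq.get(c.record_id, 0))
        g.add_node(c.record_id, **attrs)
        ids.add(c.record_id)
    for e in edges:
        if e.id_a not in ids or e.id_b not in ids:
            raise KeyError(f"edge endpoint not among nodes: ({e.id_a}, {e.id_b})")
        g.add_edge(
            e.id_a,
            e.id_b,
            similarity=e.similarity,
            delta=e.delta_activity,
            sali=e.sali,
            capped=e.capped,
            cliff=e.cliff,
        )
    return g


def neighbor_network(network: nx.Graph, compound_id: str) -> nx.Graph:
    """Induced star of a compound: the node, its neighbors, incident edges."""
    if compound_id not in network:
        raise KeyError(f"unknown compound id: {compound_id}")
    nodes = [compound_id, *network.neighbors(compound_id)]
    star = nx.Graph()
    for n in nodes:
        star.add_node(n, **network.nodes[n])
    for nbr in network.neighbors(compound_id):
        star.add_edge(compound_id, nbr, **network.edges[compound_id, nbr])
    return star


def export_network(network: nx.Graph, path: str | Path, fmt: str = "graphml") -> None:
    """Write the network as GraphML or an edge-list CSV (with node table)."""
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(network, path)
    elif fmt == "edgelist":
        lines = ["id_a,id_b,similarity,delta,sali,capped,cliff"]
        for a, b, d in sorted(network.edges(data=True)):
            lines.append(
                f"{a},{b},{d['similarity']!r},{d['delta']!r},{d['sali']!r},"
                f"{str(d['capped']).lower()},{str(d['cliff']).lower()}"
            )
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown format: {fmt!r}")


def read_network(path: str | Path) -> nx.Graph:
    return nx.read_graphml(Path(path))
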