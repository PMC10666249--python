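import itertools

import pytest
from hypothesis import given, settings, strategies as st

from sarscape.curation import Bioclass, CuratedCompound
from sarscape.descriptors import BinaryFingerprint, tanimoto
from sarscape.sali import (
    SALIEdge,
    build_network,
    detect_cliffs,
    export_network,
    neighbor_network,
    read_network,
    sali_matrix,
    sali_value,
)


def compound(rid, pic50):
    cls = Bioclass.ACTIVE if pic50 > 8 else Bioclass.INACTIVE if pic50 < 6 else Bioclass.INTERMEDIATE
    return CuratedCompound(rid, "CCO", pic50, cls)


def fp(*bits):
    return BinaryFingerprint(frozenset(bits))


class TestSaliValue:
    @pytest.mark.parametrize(
        "a1,a2,sim,expected",
        [(9, 5, 0.9, 40.0), (7, 7, 0.5, 0.0), (8, 4.05, 0.95, 79.0)],
    )
    def test_closed_form(self, a1, a2, sim, expected):
        value, capped = sali_value(a1, a2, sim)
        assert not capped
        assert value == pytest.approx(expected, abs=1e-9)

    def test_identical_structures(self):
        assert sali_value(7, 7, 1.0) == (0.0, False)
        value, capped = sali_value(9, 5, 1.0)
        assert capped and value == 1e6

    def test_domain_error(self):
        with pytest.raises(ValueError):
            sali_value(9, 5, 1.2)
        with pytest.raises(ValueError):
            sali_value(9, 5, -0.1)

    @settings(deadline=None)
    @given(
        st.floats(0, 14), st.floats(0, 14),
        st.floats(0, 0.999, allow_nan=False),
    )
    def test_symmetry(self, a1, a2, sim):
        assert sali_value(a1, a2, sim) == sali_value(a2, a1, sim)

    def test_monotonicity(self):
        # increasing similarity at fixed delta increases SALI
        v = [sali_value(9, 5, s)[0] for s in (0.0, 0.5, 0.9, 0.99)]
        assert v == sorted(v) and len(set(v)) == 4
        # increasing delta at fixed similarity increases SALI
        w = [sali_value(5 + d, 5, 0.5)[0] for d in (0.5, 1, 2, 4)]
        assert w == sorted(w) and len(set(w)) == 4


class TestSaliMatrix:
    def setup_method(self):
        self.comps = [compound(r, p) for r, p in [("a", 9.0), ("b", 5.0), ("c", 7.0), ("d", 7.5)]]
        self.fps = {"a": fp(1, 2, 3), "b": fp(1, 2, 4), "c": fp(9), "d": fp(1, 2, 3)}

    def test_full_matrix_size(self):
        edges = sali_matrix(self.comps, self.fps, sim_floor=0.0)
        assert len(edges) == 6  # n(n-1)/2

    def test_floor_above_one_empty(self):
        assert sali_matrix(self.comps, self.fps, sim_floor=1.01) == []

    def test_floor_nesting(self):
        loose = {(e.id_a, e.id_b) for e in sali_matrix(self.comps, self.fps, sim_floor=0.1)}
        tight = {(e.id_a, e.id_b) for e in sali_matrix(self.comps, self.fps, sim_floor=0.5)}
        assert tight <= loose

    def test_matches_brute_force_oracle(self):
        edges = {(e.id_a, e.id_b): e for e in sali_matrix(self.comps, self.fps)}
        for ca, cb in itertools.combinations(sorted(self.comps, key=lambda c: c.record_id), 2):
            sim = tanimoto(self.fps[ca.record_id], self.fps[cb.record_id])
            e = edges[(ca.record_id, cb.record_id)]
            assert e.similarity == pytest.approx(sim)
            assert e.delta_activity == pytest.approx(abs(ca.pic50 - cb.pic50))
            if sim < 1:
                assert e.sali == pytest.approx(abs(ca.pic50 - cb.pic50) / (1 - sim))
            else:
                assert e.capped == (ca.pic50 != cb.pic50)

    def test_missing_fingerprint(self):
        with pytest.raises(KeyError, match="d"):
            sali_matrix(self.comps, {"a": fp(1), "b": fp(1), "c": fp(1)})


def edge(a, b, sali, sim=0.9):
    return SALIEdge(a, b, sim, sali * (1 - sim), sali)


class TestDetectCliffs:
    def test_threshold_mode(self):
        edges = [edge("a", "b", 40.0), edge("a", "c", 2.0), edge("b", "c", 0.5)]
        flagged = detect_cliffs(edges, "sali_threshold", 10.0)
        assert [e.cliff for e in flagged] == [True, False, False]

    def test_top_fraction_all(self):
        edges = [edge("a", "b", 40.0), edge("a", "c", 2.0)]
        assert all(e.cliff for e in detect_cliffs(edges, "top_fraction", 1.0))

    def test_top_fraction_picks_largest(self):
        edges = [edge("a", "b", 1.0), edge("a", "c", 99.0), edge("b", "c", 5.0)]
        flagged = {(e.id_a, e.id_b): e.cliff for e in detect_cliffs(edges, "top_fraction", 0.3)}
        assert flagged == {("a", "b"): False, ("a", "c"): True, ("b", "c"): False}

    def test_bad_param(self):
        with pytest.raises(ValueError):
            detect_cliffs([edge("a", "b", 1.0)], "sali_threshold", 0)
        with pytest.raises(ValueError):
            detect_cliffs([], "top_fraction", 0.5)


class TestNetwork:
    def setup_method(self):
        self.comps = [compound(r, p) for r, p in [("a", 9.0), ("b", 5.0), ("c", 7.0), ("z", 6.0)]]
        self.edges = [edge("a", "b", 40.0), edge("a", "c", 2.0)]
        self.net = build_network(self.comps, detect_cliffs(self.edges, "sali_threshold", 10))

    def test_neighbor_star(self):
        star = neighbor_network(self.net, "a")
        assert set(star.nodes) == {"a", "b", "c"}
        assert star.number_of_edges() == 2
        assert star.nodes["a"]["pic50"] == 9.0

    def test_isolated_node(self):
        star = neighbor_network(self.net, "z")
        assert list(star.nodes) == ["z"] and star.number_of_edges() == 0

    def test_union_of_stars_restores_network(self):
        import networkx as nx

        union = nx.Graph()
        for node in self.net.nodes:
            union = nx.compose(union, neighbor_network(self.net, node))
        assert set(union.nodes) == set(self.net.nodes)
        assert set(union.edges) == set(self.net.edges)

    def test_unknown_id(self):
        with pytest.raises(KeyError):
            neighbor_network(self.net, "ghost")

    def test_graphml_round_trip(self, tmp_path):
        path = tmp_path / "net.graphml"
        export_network(self.net, path)
        back = read_network(path)
        assert set(back.nodes) == set(self.net.nodes)
        for a, b in self.net.edges:
            for key in ("similarity", "sali", "cliff", "capped"):
                assert back.edges[a, b][key] == self.net.edges[a, b][key]

    def test_empty_network_export(self, tmp_path):
        import networkx as nx

        export_network(nx.Graph(), tmp_path / "empty.graphml")
        assert read_network(tmp_path / "empty.graphml").number_of_nodes() == 0

    def test_capped_edge_serialized_with_flag(self, tmp_path):
        comps = [compound("a", 9.0), compound("b", 5.0)]
        fps = {"a": fp(1, 2), "b": fp(1, 2)}
        edges = sali_matrix(comps, fps)
        net = build_network(comps, edges)
        path = tmp_path / "capped.csv"
        export_network(net, path, fmt="edgelist")
        text = path.read_text()
        assert "true" in text and "1000000.0" in text
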