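import numpy as np
import pytest

from conftest import make_connectome, random_connectome
from mesoconn.connectome import (
    LEFT,
    RIGHT,
    Arc,
    ConnectionRecord,
    Connectome,
    adjacency_matrix,
    build_connectome,
    condense,
    connectome_from_adjacency,
    extrinsic_io_counts,
    read_records_csv,
    remove_isolated,
    write_records_csv,
)
from mesoconn.ontology import UnknownRegionError, load_hierarchy


def rec(s, t, w=1, lat="ipsilateral", **kw):
    return ConnectionRecord(source=s, target=t, weight_code=w, laterality=lat, **kw)


class TestRecords:
    def test_validation(self):
        with pytest.raises(ValueError):
            rec("A", "B", lat="bilateralish")
        with pytest.raises(ValueError):
            rec("A", "B", w=12)
        with pytest.raises(ValueError):
            ConnectionRecord(source="A", target="B", transport="sideways")

    def test_csv_round_trip(self, tmp_path):
        records = [rec("A", "B", 3, tracer="PHA-L", reference="smith91"),
                   rec("B", "C", 7, lat="contralateral")]
        p = tmp_path / "records.csv"
        write_records_csv(records, p)
        assert read_records_csv(p) == records

    def test_csv_rejects_unknown_laterality(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("source,target,laterality,weight\nA,B,sideways,3\n")
        with pytest.raises(ValueError):
            read_records_csv(p)


class TestBuild:
    def test_max_aggregation(self):
        c = build_connectome([rec("A", "B", 3), rec("A", "B", 5)], ["A", "B"])
        arc = c.arcs[("A", "B")]
        assert arc.weight == 5 and arc.n_studies == 2

    def test_subtree_aggregation(self):
        h = load_hierarchy({"id": "root", "children": [
            {"id": "P", "children": [{"id": "c"}]}, {"id": "B"}]})
        c = build_connectome([rec("c", "B", 4)], ["P", "B"], hierarchy=h)
        assert c.has_arc("P", "B")

    def test_contralateral_filtered_in_unilateral(self):
        c = build_connectome([rec("A", "B", lat="contralateral")], ["A", "B"])
        assert c.n_arcs == 0

    def test_bilateral_mirror_and_crossing(self):
        c = build_connectome(
            [rec("A", "B", 2), rec("A", "B", 5, lat="contralateral")],
            ["A", "B"], side="bilateral")
        assert c.n_nodes == 4
        assert c.has_arc(LEFT + "A", LEFT + "B") and c.has_arc(RIGHT + "A", RIGHT + "B")
        assert c.has_arc(LEFT + "A", RIGHT + "B") and c.has_arc(RIGHT + "A", LEFT + "B")

    def test_bilateral_mirror_symmetric_automorphism(self):
        records = [rec("A", "B", 3), rec("B", "C", 2),
                   rec("C", "A", 4, lat="contralateral")]
        c = build_connectome(records, ["A", "B", "C"], side="bilateral")

        def swap(n):
            return RIGHT + n[len(LEFT):] if n.startswith(LEFT) else LEFT + n[len(RIGHT):]

        swapped = {(swap(s), swap(t)) for (s, t) in c.arcs}
        assert swapped == set(c.arcs)

    def test_documented_absent_and_self_projection_dropped(self):
        h = load_hierarchy({"id": "root", "children": [
            {"id": "P", "children": [{"id": "c1"}, {"id": "c2"}]}, {"id": "B"}]})
        # c1->c2 resolves to P->P (self-projection) and P->B is weight 0
        c = build_connectome(
            [rec("c1", "c2", 5), rec("P", "B", 0)], ["P", "B"], hierarchy=h)
        assert c.n_arcs == 0

    def test_unresolvable_record(self):
        with pytest.raises(UnknownRegionError):
            build_connectome([rec("X", "B")], ["A", "B"])

    def test_empty_records(self):
        c = build_connectome([], ["A", "B"])
        assert c.n_nodes == 2 and c.n_arcs == 0


class TestCondense:
    def test_chain_collapses_to_empty(self):
        c = make_connectome("ABC", [("A", "B"), ("B", "C")])
        assert condense(c).n_nodes == 0

    def test_cycle_unchanged(self, three_cycle):
        out = condense(three_cycle)
        assert out.nodes == three_cycle.nodes and out.arcs.keys() == three_cycle.arcs.keys()

    def test_pendant_removed(self, three_cycle):
        c = make_connectome("ABCD", [("A", "B"), ("B", "C"), ("C", "A"), ("A", "D")])
        out = condense(c)
        assert out.nodes == ["A", "B", "C"]

    def test_every_survivor_has_io(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            c = condense(random_connectome(rng, 12, 0.12))
            di, do = c.in_degree(), c.out_degree()
            assert all(di[n] >= 1 and do[n] >= 1 for n in c.nodes)


def test_remove_isolated():
    c = make_connectome("ABCDEFG", [("A", "B"), ("C", "D")])
    out = remove_isolated(c)
    assert out.nodes == ["A", "B", "C", "D"]
    c2 = make_connectome("AB", [("A", "B")])
    assert remove_isolated(c2).nodes == ["A", "B"]


class TestAdjacency:
    def test_empty(self):
        assert adjacency_matrix(Connectome(nodes=[])).shape == (0, 0)

    def test_single_arc(self):
        c = make_connectome("AB", [("A", "B")], weights=[4])
        m = adjacency_matrix(c)
        assert m[0, 1] == 4 and (m == -1).sum() == 3

    def test_cycle_structure(self, three_cycle):
        m = adjacency_matrix(three_cycle)
        present = m >= 0
        assert present.sum() == 3
        assert (present.sum(axis=0) == 1).all() and (present.sum(axis=1) == 1).all()

    def test_round_trip(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            c = random_connectome(rng, 8, 0.3)
            back = connectome_from_adjacency(adjacency_matrix(c), c.nodes)
            assert back.nodes == c.nodes
            assert {k: a.weight for k, a in back.arcs.items()} == \
                   {k: a.weight for k, a in c.arcs.items()}


class TestExtrinsicIO:
    @pytest.fixture
    def world(self):
        h = load_hierarchy({"id": "root", "children": [
            {"id": "amy", "children": [
                {"id": "P", "children": [{"id": "c1"}, {"id": "c2"}]},
                {"id": "Q"}]},
            {"id": "X"}, {"id": "Y"}]})
        return h, ["P", "Q"]

    def test_hand_counts(self, world):
        h, intrinsic = world
        records = [
            rec("X", "P"),                          # direct ipsi input to P
            rec("X", "c1", lat="contralateral"),    # subtree contra input to P
            rec("P", "X"),                          # direct ipsi output of P
            rec("c2", "Y"),                         # subtree ipsi output of P
            rec("P", "Q"),                          # intrinsic: never counted
        ]
        df = extrinsic_io_counts(records, intrinsic, h)
        p = df.loc["P"]
        assert p["Dii"] == 1 and p["Dic"] == 0 and p["Dis"] == 1
        assert p["Sii"] == 1 and p["Sic"] == 1 and p["Sis"] == 2
        assert p["Doi"] == 1 and p["Dos"] == 1
        assert p["Soi"] == 2 and p["Sos"] == 2
        assert (df.loc["Q"] == 0).all()

    def test_sum_identities(self, world):
        h, intrinsic = world
        rng = np.random.default_rng(3)
        regions = ["P", "Q", "c1", "c2", "X", "Y"]
        records = []
        for _ in range(60):
            s, t = rng.choice(regions, size=2, replace=False)
            lat = "contralateral" if rng.random() < 0.4 else "ipsilateral"
            records.append(rec(str(s), str(t), lat=lat))
        df = extrinsic_io_counts(records, intrinsic, h)
        assert (df["Dis"] == df["Dic"] + df["Dii"]).all()
        assert (df["Sis"] >= df["Dis"]).all()
        assert (df["Sos"] >= df["Dos"]).all()
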