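from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from _oracles import naive_motif_census
from conftest import make_connectome, random_connectome
from mesoconn.connectome import Arc, Connectome
from mesoconn.motifs import (
    _canonical,
    _code_of,
    count_motifs,
    enumerate_motif_classes,
    motif_participation,
    motif_significance,
)
from mesoconn.nulls import erdos_renyi


def reciprocal_complete(nodes):
    return make_connectome(
        nodes, [(a, b) for a in nodes for b in nodes if a != b])


class TestEnumeration:
    @pytest.mark.parametrize("k,expected", [(2, 2), (3, 13), (4, 199)])
    def test_class_counts(self, k, expected):
        assert len(enumerate_motif_classes(k)) == expected

    def test_unsupported_k(self):
        with pytest.raises(ValueError):
            enumerate_motif_classes(5)

    def test_ordering_by_arc_count(self):
        for k in (3, 4):
            arcs = [mc.arc_count for mc in enumerate_motif_classes(k)]
            assert arcs == sorted(arcs)

    def test_triad_anchor_classes(self):
        """Pinned triad ids: named classes keep their conventional labels."""
        by_id = {mc.motif_id: mc for mc in enumerate_motif_classes(3)}
        assert [by_id[f"3-{i:02d}"].arc_count for i in range(1, 14)] == \
            [2, 2, 2, 3, 3, 3, 3, 4, 4, 4, 4, 5, 6]
        cycle = _canonical(3, _code_of(3, {(0, 1), (1, 2), (2, 0)}))
        assert by_id["3-07"].canonical_code == cycle
        two_mutual = _canonical(3, _code_of(3, {(0, 1), (1, 0), (1, 2), (2, 1)}))
        assert by_id["3-09"].canonical_code == two_mutual
        cyc_mutual = _canonical(3, _code_of(3, {(0, 1), (1, 0), (1, 2), (2, 0)}))
        assert by_id["3-10"].canonical_code == cyc_mutual
        full = _canonical(3, _code_of(3, {(i, j) for i in range(3)
                                          for j in range(3) if i != j}))
        assert by_id["3-13"].canonical_code == full

    def test_stable_across_calls(self):
        a = enumerate_motif_classes(4)
        b = enumerate_motif_classes(4)
        assert a == b


class TestCensus:
    def test_directed_cycle(self, three_cycle):
        counts = count_motifs(three_cycle, 3)
        assert counts["3-07"] == 1 and sum(counts.values()) == 1

    def test_reciprocal_triad(self, complete3):
        counts = count_motifs(complete3, 3)
        assert counts["3-13"] == 1 and sum(counts.values()) == 1

    def test_reciprocal_k4_triads(self):
        c = reciprocal_complete("ABCD")
        counts = count_motifs(c, 3)
        assert counts["3-13"] == 4 and sum(counts.values()) == 4
        counts4 = count_motifs(c, 4)
        assert counts4["4-199"] == 1 and sum(counts4.values()) == 1

    def test_total_equals_connected_subset_scan(self, fixture8):
        _, c = fixture8
        for k in (3, 4):
            counts = count_motifs(c, k)
            g = c.to_networkx()
            n_connected = sum(
                1 for subset in combinations(c.nodes, k)
                if g.subgraph(subset).number_of_edges() > 0
                and nx.is_weakly_connected(g.subgraph(subset)))
            assert sum(counts.values()) == n_connected

    def test_census_invariant_under_relabeling(self, fixture8):
        _, c = fixture8
        rng = np.random.default_rng(0)
        perm = rng.permutation(c.n_nodes)
        mapping = {c.nodes[i]: c.nodes[perm[i]] for i in range(c.n_nodes)}
        relabeled = Connectome(
            nodes=list(c.nodes),
            arcs={(mapping[s], mapping[t]): Arc(1) for (s, t) in c.arcs})
        assert count_motifs(c, 3) == count_motifs(relabeled, 3)
        assert count_motifs(c, 4) == count_motifs(relabeled, 4)

    def test_matches_naive_oracle_on_fixture(self, fixture8):
        _, c = fixture8
        for k in (3, 4):
            assert count_motifs(c, k) == naive_motif_census(
                c, k, enumerate_motif_classes(k))


class TestParticipation:
    def test_reciprocal_triad(self, complete3):
        assert motif_participation(complete3, "3-13") == {"A": 1, "B": 1, "C": 1}

    def test_reciprocal_k4(self):
        c = reciprocal_complete("ABCD")
        assert motif_participation(c, "3-13") == dict.fromkeys("ABCD", 3)

    def test_double_counting_identity(self, fixture8):
        _, c = fixture8
        counts = count_motifs(c, 3)
        for mid in ("3-02", "3-07", "3-13"):
            part = motif_participation(c, mid)
            assert sum(part.values()) == 3 * counts[mid]

    def test_unknown_id(self, complete3):
        with pytest.raises(ValueError):
            motif_participation(complete3, "3-99")


class TestSignificance:
    def test_saturated_graph_degenerate_ensemble(self, complete3):
        stats = {s.motif_id: s for s in motif_significance(
            complete3, 3, n_rand=20, seed=0)}
        s = stats["3-13"]
        assert s.rand_sd == 0 and s.z == 0 and s.p == 1.0

    def test_er_self_consistency(self):
        """Rewired nulls of an ER graph should rarely flag any class."""
        c = erdos_renyi(20, 80, seed=5)
        stats = motif_significance(c, 3, n_rand=200, swap_multiplier=10, seed=1)
        calm = sum(1 for s in stats if abs(s.z) < 3)
        assert calm >= 11

    def test_deterministic(self, fixture8):
        _, c = fixture8
        a = motif_significance(c, 3, n_rand=10, seed=2)
        b = motif_significance(c, 3, n_rand=10, seed=2)
        assert a == b
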