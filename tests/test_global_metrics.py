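import numpy as np
import pytest

from conftest import make_connectome, random_connectome
from mesoconn.connectome import Connectome
from mesoconn.global_metrics import (
    average_path_length,
    delta_error_from_valencies,
    exhaustive_modularity,
    global_summary,
    modularity_partition,
    powerlaw_delta_error,
    small_worldness,
)
from mesoconn.nulls import erdos_renyi, watts_strogatz_directed


class TestSummary:
    def test_condensed_regime_closed_forms(self):
        c = erdos_renyi(49, 464, seed=0)
        gm = global_summary(c, n_rand=0)
        assert gm.avg_valency == pytest.approx(18.939, abs=5e-4)
        assert gm.line_density == pytest.approx(19.728, abs=5e-4)

    def test_three_cycle_hand_values(self, three_cycle):
        gm = global_summary(three_cycle, n_rand=0)
        assert gm.avg_path_length == pytest.approx(1.5)
        assert gm.heterogeneity == 0.0
        assert gm.avg_cluster_coefficient == pytest.approx(1.0)
        assert gm.reachable_pair_fraction == 1.0

    def test_complete_digraph(self, complete3):
        gm = global_summary(complete3, n_rand=0)
        assert gm.line_density == pytest.approx(100.0)
        assert gm.avg_path_length == pytest.approx(1.0)

    def test_single_node_path_missing(self):
        gm = global_summary(Connectome(nodes=["A"]), n_rand=0)
        assert gm.avg_path_length is None

    def test_closed_forms_any_graph(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            c = random_connectome(rng, 12, 0.25)
            gm = global_summary(c, n_rand=0)
            n, e = c.n_nodes, c.n_arcs
            assert gm.avg_valency == pytest.approx(2 * e / n)
            assert gm.line_density == pytest.approx(100 * e / (n * (n - 1)))

    def test_strongly_connected_path_bound(self, three_cycle, complete3):
        assert average_path_length(three_cycle)[0] > 1
        assert average_path_length(complete3)[0] == 1.0


class TestSmallWorldness:
    def test_er_self_comparison_near_one(self):
        c = erdos_renyi(40, 240, seed=3)
        # ensemble spread of S taken from independent ER draws
        ss = [small_worldness(erdos_renyi(40, 240, seed=100 + i), n_rand=20, seed=i)
              for i in range(12)]
        s = small_worldness(c, n_rand=20, seed=50)
        assert abs(s - 1) < max(3 * np.std(ss), 0.1)

    def test_lattice_exceeds_one(self):
        c = watts_strogatz_directed(50, 200, p_rewire=0.0, seed=0)
        assert small_worldness(c, n_rand=20, seed=1) > 1

    def test_deterministic(self, three_cycle):
        a = small_worldness(three_cycle, n_rand=1, seed=5)
        b = small_worldness(three_cycle, n_rand=1, seed=5)
        assert a == b


class TestPowerlawDelta:
    def test_exact_power_law_fits_perfectly(self):
        # integer counts 64, 16, 4, 1 follow k^-2 exactly
        vals = np.repeat([1, 2, 4, 8], [64, 16, 4, 1])
        assert delta_error_from_valencies(vals) < 1e-6

    def test_regular_graph_undefined(self, three_cycle):
        assert powerlaw_delta_error(three_cycle) is None

    def test_geometric_decay_worse_than_power_law(self):
        ks = np.arange(1, 9)
        geom = 0.5 ** ks
        geom /= geom.sum()
        power = ks ** -2.0
        power /= power.sum()
        n = 100_000
        v_geom = np.repeat(ks, np.round(geom * n).astype(int))
        v_pow = np.repeat(ks, np.round(power * n).astype(int))
        assert delta_error_from_valencies(v_geom) > delta_error_from_valencies(v_pow)


class TestModularity:
    def test_two_disjoint_cycles(self):
        c = make_connectome("ABCDEF", [("A", "B"), ("B", "C"), ("C", "A"),
                                       ("D", "E"), ("E", "F"), ("F", "D")])
        part, q = modularity_partition(c, seed=0)
        assert q == pytest.approx(0.5)
        assert len(set(part.values())) == 2
        assert part["A"] == part["B"] == part["C"]

    def test_complete_digraph_trivial_optimum(self, complete3):
        _, q = modularity_partition(complete3, seed=0)
        _, q_best = exhaustive_modularity(complete3)
        assert q == pytest.approx(q_best, abs=1e-12)
        assert q_best == pytest.approx(0.0, abs=1e-12)

    def test_deterministic(self):
        rng = np.random.default_rng(1)
        c = random_connectome(rng, 15, 0.2)
        assert modularity_partition(c, seed=3) == modularity_partition(c, seed=3)

    def test_never_below_trivial(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            c = random_connectome(rng, 8, 0.3)
            if c.n_arcs == 0:
                continue
            _, q = modularity_partition(c, seed=0)
            assert q >= -1e-12

    def test_heuristic_matches_exhaustive_on_small_graphs(self):
        """Louvain recovers the exact optimum on nearly all tiny graphs."""
        rng = np.random.default_rng(7)
        hits = total = 0
        while total < 100:
            c = random_connectome(rng, 6, 0.35)
            if c.n_arcs < 2:
                continue
            total += 1
            _, q = modularity_partition(c, seed=total)
            _, q_best = exhaustive_modularity(c)
            hits += q >= q_best - 1e-9
        assert hits >= 95
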