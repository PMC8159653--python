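import math

import numpy as np
import pytest

from netprox.datasets import load_reported_proximity
from netprox.genesets import GeneSet
from netprox.graph_core import PPINetwork, shortest_paths_from
from netprox.proximity import (
    closest_distance,
    kernel_distance,
    mean_shortest_distance,
    proximity_table,
    separation_score,
    within_set_distance,
)

from conftest import floyd_warshall, random_graph


def gs(*symbols):
    return GeneSet.from_symbols("s", symbols)


@pytest.fixture
def oracle_abc(path_abc):
    return shortest_paths_from(path_abc, path_abc.nodes)


class TestMeanShortestDistance:
    def test_endpoints_of_path(self, oracle_abc):
        d, dropped = mean_shortest_distance(oracle_abc, gs("a"), gs("c"))
        assert d == 2.0 and dropped == 0

    def test_identical_singletons(self, oracle_abc):
        d, _ = mean_shortest_distance(oracle_abc, gs("a"), gs("a"))
        assert d == 0.0

    def test_overlapping_pairs_enumeration(self, oracle_abc):
        # pairs (a,b)=1 (a,c)=2 (b,b)=0 (b,c)=1 -> mean 1.0
        d, _ = mean_shortest_distance(oracle_abc, gs("a", "b"), gs("b", "c"))
        assert d == 1.0

    def test_unreachable_pairs_dropped(self, path_abc_plus_d):
        oracle = shortest_paths_from(path_abc_plus_d, path_abc_plus_d.nodes)
        d, dropped = mean_shortest_distance(oracle, gs("a", "d"), gs("c"))
        assert d == 2.0 and dropped == 1

    def test_all_unreachable_is_error(self, path_abc_plus_d):
        oracle = shortest_paths_from(path_abc_plus_d, path_abc_plus_d.nodes)
        with pytest.raises(ValueError, match="no finite"):
            mean_shortest_distance(oracle, gs("d"), gs("a"))

    def test_unmapped_set_is_error(self, oracle_abc):
        with pytest.raises(ValueError, match="zero network nodes"):
            mean_shortest_distance(oracle_abc, gs("zzz"), gs("a"))


class TestClosestDistance:
    def test_by_hand_minima(self, oracle_abc):
        # a->min(1,2)=1, b->0, b->0, c->min(2,1)=1 over 4 terms
        d, _ = closest_distance(oracle_abc, gs("a", "b"), gs("b", "c"))
        assert d == 0.5

    def test_equal_sets_zero(self, oracle_abc):
        d, _ = closest_distance(oracle_abc, gs("a", "c"), gs("a", "c"))
        assert d == 0.0

    def test_singletons(self, oracle_abc):
        d, _ = closest_distance(oracle_abc, gs("a"), gs("c"))
        assert d == 2.0


class TestKernelDistance:
    def test_identical_singletons(self, oracle_abc):
        # -(1/2)(ln e^-1 + ln e^-1) = 1
        assert kernel_distance(oracle_abc, gs("a"), gs("a")) == pytest.approx(1.0)

    def test_distance_two_singletons(self, oracle_abc):
        # -(1/2)(ln e^-3 + ln e^-3) = 3
        assert kernel_distance(oracle_abc, gs("a"), gs("c")) == pytest.approx(3.0)

    def test_mixed_set(self, oracle_abc):
        expected = -(
            math.log((math.e**-1 + math.e**-3) / 2)
            + math.log(math.e**-1)
            + math.log(math.e**-3)
        ) / 3
        got = kernel_distance(oracle_abc, gs("a"), gs("a", "c"))
        assert got == pytest.approx(expected)
        assert got == pytest.approx(1.855, abs=5e-4)

    def test_fully_unreachable_node_is_error(self, path_abc_plus_d):
        oracle = shortest_paths_from(path_abc_plus_d, path_abc_plus_d.nodes)
        with pytest.raises(ValueError, match="D"):
            kernel_distance(oracle, gs("d"), gs("a", "b"))


class TestSeparationScore:
    def test_equal_sets_zero(self):
        assert separation_score(1.3, 1.3, 1.3) == 0.0

    def test_reported_row_arithmetic(self):
        # published row: d_S 2.68 with within-mean 4.77 gives -2.09
        assert separation_score(2.68, 4.77, 4.77) == pytest.approx(-2.09)

    def test_path_within_set_convention(self, oracle_abc):
        d_s, _ = mean_shortest_distance(oracle_abc, gs("a", "b"), gs("b", "c"))
        d_aa, _ = within_set_distance(oracle_abc, gs("a", "b"))
        d_bb, _ = within_set_distance(oracle_abc, gs("b", "c"))
        assert (d_aa, d_bb) == (0.5, 0.5)
        assert separation_score(d_s, d_aa, d_bb) == 0.5

    def test_nonfinite_is_error(self):
        with pytest.raises(ValueError):
            separation_score(float("nan"), 1.0, 1.0)


class TestWithinSetConventions:
    def test_nearest_singleton_is_zero(self, oracle_abc):
        d, _ = within_set_distance(oracle_abc, gs("a"), convention="nearest")
        assert d == 0.0

    def test_nearest_excludes_self(self, oracle_abc):
        d, _ = within_set_distance(oracle_abc, gs("a", "c"), convention="nearest")
        assert d == 2.0  # allpairs would give (0+2+2+0)/4 = 1

    def test_allpairs_includes_self(self, oracle_abc):
        d, _ = within_set_distance(oracle_abc, gs("a", "c"))
        assert d == 1.0


class TestProximityTable:
    def test_equal_target_and_key_sets_do_not_interfere(self, path_abc):
        rows = proximity_table(
            path_abc, {"M1": gs("a", "b", "c")}, gs("a", "b", "c")
        )
        assert rows[0].S_P == pytest.approx(0.0)
        assert rows[0].interferes is False

    def test_unmappable_ingredient_skipped(self, path_abc):
        rows = proximity_table(
            path_abc, {"M1": gs("a"), "M2": gs("zzz")}, gs("c")
        )
        assert [r.ingredient_id for r in rows] == ["M1"]

    def test_empty_key_set_is_error(self, path_abc):
        with pytest.raises(ValueError):
            proximity_table(path_abc, {"M1": gs("a")}, gs("zzz"))

    def test_row_invariants_and_sorting(self):
        rng = np.random.default_rng(3)
        net = random_graph(rng, 30, 0.12, connected=True)
        nodes = sorted(net.nodes)
        targets = {
            f"M{i}": GeneSet.from_symbols(
                f"M{i}", rng.choice(nodes, size=4, replace=False)
            )
            for i in range(6)
        }
        key = GeneSet.from_symbols("K", rng.choice(nodes, size=5, replace=False))
        rows = proximity_table(net, targets, key)
        assert len(rows) == 6
        sps = [r.S_P for r in rows]
        assert sps == sorted(sps)
        for r in rows:
            assert r.d_C <= r.d_S + 1e-12
            assert r.S_P == pytest.approx(r.d_S - (r.d_AA + r.d_BB) / 2)
            assert r.interferes == (r.S_P < 0)
            assert r.n_A >= 1 and r.n_B >= 1


class TestReportedTableFixture:
    def test_refilter_reproduces_interference_count(self):
        df = load_reported_proximity()
        assert (df["S_P"] < 0).sum() == 17

    def test_distance_orderings(self):
        df = load_reported_proximity()
        assert (df["d_C"] <= df["d_S"]).all()
        assert (df["d_K"] > df["d_S"]).all()


class TestAgainstBruteForce:
    """Direct formula evaluation on Floyd–Warshall distances, graphs <= 8."""

    @pytest.mark.parametrize("seed", range(8))
    def test_all_three_distances(self, seed):
        rng = np.random.default_rng(100 + seed)
        net = random_graph(rng, 8, 0.3, connected=True)
        nodes = sorted(net.nodes)
        a = [nodes[i] for i in rng.choice(8, size=3, replace=False)]
        b = [nodes[i] for i in rng.choice(8, size=4, replace=False)]
        fw = floyd_warshall(net)
        oracle = shortest_paths_from(net, net.nodes)
        A, B = gs(*a), gs(*b)
        an = sorted(GeneSet.from_symbols("", a).members)
        bn = sorted(GeneSet.from_symbols("", b).members)

        exp_s = np.mean([fw[(x, y)] for x in an for y in bn])
        assert mean_shortest_distance(oracle, A, B)[0] == pytest.approx(exp_s)

        exp_c = (
            sum(min(fw[(x, y)] for y in bn) for x in an)
            + sum(min(fw[(x, y)] for x in an) for y in bn)
        ) / (len(an) + len(bn))
        assert closest_distance(oracle, A, B)[0] == pytest.approx(exp_c)

        exp_k = -(
            sum(
                math.log(sum(math.exp(-(fw[(x, y)] + 1)) for y in bn) / len(bn))
                for x in an
            )
            + sum(
                math.log(sum(math.exp(-(fw[(x, y)] + 1)) for x in an) / len(an))
                for y in bn
            )
        ) / (len(an) + len(bn))
        assert kernel_distance(oracle, A, B) == pytest.approx(exp_k)

    @pytest.mark.parametrize("seed", range(6))
    def test_symmetry_in_set_roles(self, seed):
        rng = np.random.default_rng(200 + seed)
        net = random_graph(rng, 10, 0.3, connected=True)
        nodes = sorted(net.nodes)
        a = gs(*(nodes[i] for i in rng.choice(10, size=3, replace=False)))
        b = gs(*(nodes[i] for i in rng.choice(10, size=3, replace=False)))
        oracle = shortest_paths_from(net, net.nodes)
        assert mean_shortest_distance(oracle, a, b)[0] == pytest.approx(
            mean_shortest_distance(oracle, b, a)[0]
        )
        assert closest_distance(oracle, a, b)[0] == pytest.approx(
            closest_distance(oracle, b, a)[0]
        )
        assert kernel_distance(oracle, a, b) == pytest.approx(
            kernel_distance(oracle, b, a)
        )

    @pytest.mark.parametrize("seed", range(6))
    def test_adding_key_member_to_targets_never_increases_closest(self, seed):
        rng = np.random.default_rng(300 + seed)
        net = random_graph(rng, 12, 0.25, connected=True)
        nodes = sorted(net.nodes)
        oracle = shortest_paths_from(net, net.nodes)
        a_syms = [nodes[i] for i in rng.choice(12, size=3, replace=False)]
        b_syms = [nodes[i] for i in rng.choice(12, size=4, replace=False)]
        A, B = gs(*a_syms), gs(*b_syms)
        before, _ = closest_distance(oracle, A, B)
        extra = next(s for s in sorted(B.members) if s not in A.members)
        after, _ = closest_distance(oracle, gs(*a_syms, extra), B)
        assert after <= before + 1e-12
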