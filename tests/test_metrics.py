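"""Partition-quality criteria and dismantling diagnostics."""

import math
from fractions import Fraction

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eachnet.graphcore import Partition
from eachnet.metrics import (
    community_diameter,
    dismantle_curve,
    modularity,
    nmi,
    normalized_susceptibility,
    partition_density,
)

from conftest import random_graph


def _partition(groups):
    return Partition.from_communities(groups)


class TestNMI:
    def test_identical_partitions_score_one(self):
        p = _partition([{"1", "2"}, {"3"}])
        assert nmi(p, p) == pytest.approx(1.0)

    def test_maximally_crossed_partitions_score_zero(self):
        p1 = _partition([{"1", "2"}, {"3", "4"}])
        p2 = _partition([{"1", "3"}, {"2", "4"}])
        assert nmi(p1, p2) == pytest.approx(0.0)

    def test_two_trivial_partitions_score_one_by_convention(self):
        p = _partition([{"1", "2", "3"}])
        assert nmi(p, p) == 1.0

    def test_differing_vertex_sets_rejected(self):
        with pytest.raises(ValueError):
            nmi(_partition([{"1"}]), _partition([{"2"}]))

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_symmetric_relabel_invariant_and_bounded(self, seed):
        import random

        rng = random.Random(seed)
        n = rng.randint(2, 30)
        verts = [f"v{i}" for i in range(n)]
        a = {v: rng.randint(1, 4) for v in verts}
        b = {v: rng.randint(1, 4) for v in verts}
        p1, p2 = Partition(a), Partition(b)
        v12, v21 = nmi(p1, p2), nmi(p2, p1)
        assert v12 == pytest.approx(v21)
        assert -1e-12 <= v12 <= 1 + 1e-12
        relabeled = Partition({v: chr(64 + c) for v, c in a.items()})
        assert nmi(relabeled, p2) == pytest.approx(v12)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_sklearn_reference(self, seed):
        """Independent cross-check against scikit-learn's arithmetic-mean NMI,
        which the confusion-matrix formula is algebraically equal to."""
        import random

        from sklearn.metrics import normalized_mutual_info_score

        rng = random.Random(seed)
        verts = [f"v{i}" for i in range(40)]
        a = {v: rng.randint(1, 5) for v in verts}
        b = {v: rng.randint(1, 3) for v in verts}
        ours = nmi(Partition(a), Partition(b))
        ref = normalized_mutual_info_score(
            [a[v] for v in verts], [b[v] for v in verts], average_method="arithmetic"
        )
        assert ours == pytest.approx(ref, abs=1e-10)


class TestModularity:
    def test_single_community_is_zero(self, two_triangle_bridge):
        g, _ = two_triangle_bridge
        assert modularity(g, _partition([set(g.nodes)])) == pytest.approx(0.0)

    def test_bridge_graph_planted_split(self, two_triangle_bridge):
        g, truth = two_triangle_bridge
        assert modularity(g, truth) == pytest.approx(5 / 14)

    def test_karate_factions(self, karate):
        g, truth = karate
        assert modularity(g, truth) == pytest.approx(0.3715, abs=5e-5)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_networkx_reference(self, seed):
        import random

        g = random_graph(seed, n_max=30)
        if g.number_of_edges() == 0:
            return
        rng = random.Random(seed)
        assign = {v: rng.randint(1, 3) for v in g}
        p = Partition(assign)
        ref = nx.algorithms.community.modularity(g, p.communities())
        assert modularity(g, p) == pytest.approx(ref)

    def test_edgeless_graph_rejected(self):
        g = nx.Graph()
        g.add_nodes_from("ab")
        with pytest.raises(ValueError):
            modularity(g, _partition([{"a"}, {"b"}]))


class TestPartitionDensity:
    def test_tree_communities_give_zero(self, path4):
        assert partition_density(path4, _partition([set("abcd")])) == 0.0

    def test_bridge_graph_planted_split(self, two_triangle_bridge):
        g, truth = two_triangle_bridge
        assert partition_density(g, truth) == pytest.approx(6 / 7)

    def test_clique_cover_gives_one(self):
        g = nx.relabel_nodes(nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(3)), str)
        p = _partition(nx.connected_components(g))
        assert partition_density(g, p) == pytest.approx(1.0)

    def test_pair_communities_contribute_nothing(self):
        g = nx.Graph([("a", "b"), ("c", "d")])
        assert partition_density(g, _partition([{"a", "b"}, {"c", "d"}])) == 0.0


class TestCommunityDiameter:
    def test_singleton_and_triangle(self, two_triangle_bridge):
        g, _ = two_triangle_bridge
        assert community_diameter(g, {"1"}) == 0
        assert community_diameter(g, {"1", "2", "3"}) == 1

    def test_path_community(self, path4):
        assert community_diameter(path4, set("abcd")) == 3

    def test_disconnected_community_is_infinite(self, two_triangle_bridge):
        g, _ = two_triangle_bridge
        assert community_diameter(g, {"1", "5"}) == math.inf


class TestSusceptibility:
    @pytest.mark.parametrize("sizes,n,expected", [
        ([10], 10, 0.0),
        ([5, 3, 2], 10, 1.3),
        ([4, 4, 2], 10, 2.0),   # one maximal instance excluded, the other kept
        ([1] * 6, 6, 5 / 6),
    ])
    def test_closed_forms(self, sizes, n, expected):
        assert normalized_susceptibility(sizes, n) == pytest.approx(expected)

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError):
            normalized_susceptibility([3, 3], 7)


class TestDismantleCurve:
    def test_connected_graph_starts_at_full_giant_component(self, karate):
        g, _ = karate
        curve = dismantle_curve(g, kind="antitriangle")
        assert curve[0].f == 0 and curve[0].rgc == 1.0 and curve[0].s_tilde == 0.0

    def test_final_point_is_all_singletons(self, two_triangle_bridge):
        g, _ = two_triangle_bridge
        n = g.number_of_nodes()
        curve = dismantle_curve(g, kind="betweenness")
        last = curve[-1]
        assert last.f == 1 and last.rgc == pytest.approx(1 / n)
        assert last.s_tilde == pytest.approx((n - 1) / n)

    def test_bridge_goes_first_under_recomputed_antitriangle(self, two_triangle_bridge):
        g, _ = two_triangle_bridge
        curve = dismantle_curve(g, kind="antitriangle", recompute=True)
        assert curve[1].f == Fraction(1, 7) and curve[1].rgc == pytest.approx(0.5)

    @pytest.mark.parametrize("kind,recompute", [
        ("antitriangle", False),
        ("betweenness", False),
        ("clustering_coefficient", True),
    ])
    def test_rgc_non_increasing_and_curve_length(self, karate, kind, recompute):
        g, _ = karate
        curve = dismantle_curve(g, kind=kind, recompute=recompute)
        assert len(curve) == g.number_of_edges() + 1
        for a, b in zip(curve, curve[1:]):
            assert b.rgc <= a.rgc + 1e-12
            assert b.f > a.f
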