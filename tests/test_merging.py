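"""Cohesiveness, essential-protein overlap and the merge procedure."""

import numpy as np
import pytest

from prorankplus import (
    Complex,
    ComplexSet,
    MergeParams,
    PPINetwork,
    ProteinClassification,
    cohesiveness,
    essential_overlap,
    expand_by_cohesiveness,
    merge_all,
    merge_by_cohesiveness,
)
from oracles import brute_cohesiveness, random_edges


def _cx(members, essentials=None):
    members = frozenset(members)
    essentials = frozenset(essentials) if essentials is not None else members
    return Complex(members=members, essential_members=essentials)


def _all_essential(net):
    return ProteinClassification({u: "essential" for u in net.nodes})


class TestCohesiveness:
    def test_isolated_triangle(self, triangle):
        assert cohesiveness(triangle, {"A", "B", "C"}, penalty=2.0) == pytest.approx(0.6)

    def test_triangle_with_external_edge(self):
        net = PPINetwork.from_edges(
            [("A", "B"), ("B", "C"), ("A", "C"), ("C", "X")]
        )
        assert cohesiveness(net, {"A", "B", "C"}, penalty=2.0) == pytest.approx(0.5)

    def test_whole_component_no_penalty_is_one(self, two_shared_triangles):
        assert cohesiveness(
            two_shared_triangles, two_shared_triangles.nodes, penalty=0.0
        ) == pytest.approx(1.0)

    def test_weighted_edges_counted_by_weight(self):
        net = PPINetwork.from_edges(
            [("A", "B", 0.5), ("B", "C", 0.25), ("C", "X", 0.75)], weighted=True
        )
        # w_in = 0.75, w_out = 0.75, p = 2
        assert cohesiveness(net, {"A", "B", "C"}, 2.0) == pytest.approx(0.75 / 3.5)

    def test_empty_set_is_error(self, triangle):
        with pytest.raises(ValueError):
            cohesiveness(triangle, set())

    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            edges = random_edges(rng, 10, 0.3, weighted=True)
            net = PPINetwork.from_edges(edges, weighted=True)
            nodes = sorted(net.nodes)
            if not nodes:
                continue
            members = set(rng.choice(nodes, size=min(4, len(nodes)), replace=False))
            assert cohesiveness(net, members, 2.0) == pytest.approx(
                brute_cohesiveness(edges, members, 2.0)
            )


class TestEssentialOverlap:
    def test_identical_sets(self):
        assert essential_overlap(_cx("abc"), _cx("abc")) == 1.0

    def test_disjoint_sets(self):
        assert essential_overlap(_cx("ab"), _cx("cd")) == 0.0

    def test_min_denominator_containment(self):
        assert essential_overlap(_cx("abcd"), _cx("abcd", "cd")) == 1.0

    def test_jaccard_mode(self):
        c1, c2 = _cx("abc"), _cx("abd")
        assert essential_overlap(c1, c2, mode="jaccard") == pytest.approx(2 / 4)

    def test_empty_essentials_give_zero(self):
        c1 = Complex(frozenset("abc"), essential_members=frozenset())
        assert essential_overlap(c1, _cx("abc")) == 0.0


class TestMergeByCohesiveness:
    def test_two_shared_triangles_merge_to_component(self, two_shared_triangles):
        cls = _all_essential(two_shared_triangles)
        merged = merge_by_cohesiveness(
            two_shared_triangles, _cx("abc"), _cx("cde"), cls, penalty=0.0
        )
        assert merged.members == frozenset("abcde")
        assert cohesiveness(two_shared_triangles, merged.members, 0.0) == 1.0

    def test_self_merge_only_grows(self, k4):
        cls = _all_essential(k4)
        merged = merge_by_cohesiveness(k4, _cx("abcd"), _cx("abcd"), cls)
        assert merged.members >= frozenset("abcd")

    def test_pendant_admission_matches_decision_rule(self):
        """A pendant vertex joins iff it does not lower cohesiveness."""
        # dense core {a,b,c,d} with pendant x on d: adding x removes the
        # boundary edge (w_out 1 -> 0) while w_in grows, so x is admitted.
        core = [("a", "b"), ("a", "c"), ("a", "d"), ("b", "c"), ("b", "d"), ("c", "d")]
        net = PPINetwork.from_edges(core + [("d", "x")])
        before = cohesiveness(net, set("abcd"), 2.0)
        after = cohesiveness(net, set("abcdx"), 2.0)
        assert after >= before
        expanded, _ = expand_by_cohesiveness(net, set("abcd"), 2.0)
        assert expanded == frozenset("abcdx")

    def test_hub_attachment_rejected_when_cohesiveness_drops(self):
        # x carries many outgoing edges; absorbing it lowers cohesiveness.
        core = [("a", "b"), ("a", "c"), ("b", "c")]
        spokes = [("c", "x")] + [("x", f"y{i}") for i in range(6)]
        net = PPINetwork.from_edges(core + spokes)
        assert cohesiveness(net, set("abcx"), 2.0) < cohesiveness(net, set("abc"), 2.0)
        expanded, _ = expand_by_cohesiveness(net, set("abc"), 2.0)
        assert "x" not in expanded

    def test_expansion_matches_oracle_scan_on_small_graphs(self):
        """Replay the documented scan with the brute-force cohesiveness
        oracle and require the same final member set."""
        rng = np.random.default_rng(31)
        for _ in range(25):
            edges = random_edges(rng, 8, 0.4, weighted=True)
            net = PPINetwork.from_edges(edges, weighted=True)
            nodes = sorted(net.nodes)
            if len(nodes) < 4:
                continue
            start = set(rng.choice(nodes, size=3, replace=False))
            adj = {u: set() for u in nodes}
            for a, b, _w in edges:
                adj[a].add(b)
                adj[b].add(a)
            expect = set(start)
            coh = brute_cohesiveness(edges, expect, 2.0)
            for prot in sorted(start):
                for nb in sorted(adj[prot]):
                    if nb in expect:
                        continue
                    cand = brute_cohesiveness(edges, expect | {nb}, 2.0)
                    if cand >= coh:
                        expect.add(nb)
                        coh = cand
            got, trajectory = expand_by_cohesiveness(net, start, 2.0)
            assert got == frozenset(expect)
            assert trajectory == sorted(trajectory)  # never decreases


class TestMergeAll:
    def test_low_overlap_is_fixpoint(self, two_shared_triangles):
        cls = _all_essential(two_shared_triangles)
        cs = ComplexSet([_cx("abc"), _cx("cde")])
        out = merge_all(two_shared_triangles, cs, cls)
        assert set(out.member_sets()) == set(cs.member_sets())
        assert len(out) == len(cs)

    def test_identical_complexes_merge(self, k4):
        cls = _all_essential(k4)
        cs = ComplexSet([_cx("abcd"), _cx("abcd")])
        out = merge_all(k4, cs, cls)
        assert len(out) == 1

    def test_three_complexes_with_shared_core_collapse(self):
        """Complexes sharing one essential core merge transitively into
        their union (matching exhaustive merging to fixpoint)."""
        from conftest import clique_edges

        net = PPINetwork.from_edges(
            clique_edges(["a", "b", "c", "d", "e", "f"])
        )
        cls = _all_essential(net)
        cs = ComplexSet(
            [_cx("abcd", "ab"), _cx("abce", "ab"), _cx("abdf", "ab")]
        )
        out = merge_all(net, cs, cls, MergeParams(threshold=0.75))
        assert len(out) == 1
        assert out[0].members == frozenset("abcdef")
        # fixpoint: no remaining pair above the threshold
        for i in range(len(out)):
            for j in range(i + 1, len(out)):
                assert essential_overlap(out[i], out[j]) <= 0.75

    def test_deterministic(self):
        rng = np.random.default_rng(41)
        edges = random_edges(rng, 14, 0.3, weighted=True)
        net = PPINetwork.from_edges(edges, weighted=True)
        nodes = sorted(net.nodes)
        complexes = []
        for _ in range(6):
            members = set(rng.choice(nodes, size=4, replace=False))
            complexes.append(_cx(members))
        cls = _all_essential(net)
        cs = ComplexSet(complexes)
        out1 = merge_all(net, cs, cls)
        out2 = merge_all(net, ComplexSet(list(complexes)), cls)
        assert out1.member_sets() == out2.member_sets()

    def test_strict_threshold_comparison(self, k4):
        """Overlap exactly at the threshold does not merge."""
        cls = _all_essential(k4)
        # |E1 ∩ E2| / min(|E1|, |E2|) = 3/4 exactly
        cs = ComplexSet([_cx("abcd", "abcd"), _cx("abcx", "abcx")])
        out = merge_all(k4, cs, cls, MergeParams(threshold=0.75))
        assert len(out) == 2

    def test_output_sizes_at_least_three(self, k4):
        cls = _all_essential(k4)
        cs = ComplexSet([_cx("abc"), _cx("ab", "ab")])
        out = merge_all(k4, cs, cls)
        assert all(len(c) >= 3 for c in out)
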