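import numpy as np
import pytest
from skbio import DistanceMatrix

from spotclust.trees import (
    cophenetic_matrix,
    is_ultrametric,
    midpoint_root,
    neighbor_joining,
    nnls_ultrametric,
    node_heights,
    read_newick,
    tree_fit_diagnostic,
    upgma,
    write_newick,
)
from tests.conftest import random_additive_tree, random_clock_tree


def tip_distances(t, order):
    return t.tip_tip_distances().filter(order).data


class TestUpgma:
    def test_exact_recovery_of_ultrametric_input(self):
        d = DistanceMatrix(
            np.array([[0, 2, 6], [2, 0, 6], [6, 6, 0.0]]), ["A", "B", "C"]
        )
        t = upgma(d)
        assert np.allclose(tip_distances(t, ["A", "B", "C"]), d.data)
        h = node_heights(t)
        assert sorted(round(v, 6) for n, v in h.items() if not n.is_tip()) == [1.0, 3.0]

    def test_equal_distances_merge_at_single_height(self):
        d = DistanceMatrix(np.full((4, 4), 0.8) - 0.8 * np.eye(4), list("ABCD"))
        t = upgma(d)
        assert is_ultrametric(t)
        hs = {round(v, 9) for n, v in node_heights(t).items() if not n.is_tip()}
        assert hs == {0.4}

    def test_round_trip_random_clock_trees(self, rng):
        for _ in range(20):
            true = random_clock_tree(rng, int(rng.integers(4, 9)))
            order = [x.name for x in true.tips()]
            d = true.tip_tip_distances().filter(order)
            rebuilt = upgma(d)
            assert np.allclose(tip_distances(rebuilt, order), d.data, atol=1e-10)

    def test_nan_rejected(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.nan
        with pytest.raises(ValueError):
            upgma(DistanceMatrix(d, list("ABC"), validate=False))


class TestNeighborJoining:
    def test_known_four_taxon_tree_recovered(self):
        # tree ((A:1,B:2):5,(C:3,D:4)) -> additive distances
        d = np.array(
            [
                [0, 3, 9, 10],
                [3, 0, 10, 11],
                [9, 10, 0, 7],
                [10, 11, 7, 0.0],
            ]
        )
        dm = DistanceMatrix(d, list("ABCD"))
        # four-point condition: AB|CD is the closest pair-split
        assert d[0, 1] + d[2, 3] < d[0, 2] + d[1, 3]
        t = neighbor_joining(dm)
        assert np.allclose(tip_distances(t, list("ABCD")), d, atol=1e-10)
        from spotclust.treecmp import bipartition_sets

        splits = bipartition_sets(t)
        assert frozenset({frozenset("AB"), frozenset("CD")}) in splits

    def test_star_distances_give_zero_internal_branches(self):
        d = DistanceMatrix(np.full((4, 4), 2.0) - 2.0 * np.eye(4), list("ABCD"))
        t = neighbor_joining(d)
        internal = [n.length for n in t.traverse(include_self=False) if not n.is_tip()]
        assert all(abs(x) < 1e-12 for x in internal)

    def test_random_additive_matrices_reproduced(self, rng):
        for _ in range(20):
            true = random_additive_tree(rng, int(rng.integers(4, 10)))
            order = [x.name for x in true.tips()]
            d = true.tip_tip_distances().filter(order)
            t = neighbor_joining(d)
            assert np.abs(tip_distances(t, order) - d.data).max() < 1e-8

    def test_too_few_objects_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(np.array([[0, 1], [1, 0.0]]), ["A", "B"]))


def leaf_depths(rooted):
    return {x.name: x.accumulate_to_ancestor(rooted) for x in rooted.tips()}


class TestMidpointRoot:
    def test_two_leaf_tree_split_evenly(self):
        t = read_newick("(A:2,B:3);")
        depths = leaf_depths(midpoint_root(t))
        assert depths == pytest.approx({"A": 2.5, "B": 2.5})

    def test_root_lies_on_diameter_path(self, rng):
        for _ in range(10):
            t = random_additive_tree(rng, 7)
            order = [x.name for x in t.tips()]
            d = t.tip_tip_distances().filter(order).data
            i, j = np.unravel_index(np.argmax(d), d.shape)
            depths = leaf_depths(midpoint_root(t))
            # both diameter endpoints at exactly half the diameter
            assert depths[order[i]] == pytest.approx(d[i, j] / 2)
            assert depths[order[j]] == pytest.approx(d[i, j] / 2)

    def test_rerooting_preserves_cophenetic_distances(self, rng):
        t = random_additive_tree(rng, 8)
        order = [x.name for x in t.tips()]
        before = t.tip_tip_distances().filter(order).data
        after = midpoint_root(t).tip_tip_distances().filter(order).data
        assert np.allclose(before, after, atol=1e-10)


class TestCophenetic:
    def test_read_off_small_tree(self):
        t = read_newick("((A:1,B:1):2,C:3);")
        d = cophenetic_matrix(t).filter(["A", "B", "C"]).data
        assert np.allclose(d, [[0, 2, 6], [2, 0, 6], [6, 6, 0]])

    def test_matches_brute_force_path_sums(self, rng):
        for _ in range(10):
            t = random_additive_tree(rng, 6)
            d = cophenetic_matrix(t)
            tips = {x.name: x for x in t.tips()}
            for a in d.ids:
                for b in d.ids:
                    if a == b:
                        continue
                    lca = tips[a].lowest_common_ancestor([tips[a], tips[b]])
                    want = tips[a].accumulate_to_ancestor(lca) + tips[
                        b
                    ].accumulate_to_ancestor(lca)
                    assert d[a, b] == pytest.approx(want, abs=1e-10)

    def test_ultrametric_tree_gives_ultrametric_matrix(self, rng):
        t = random_clock_tree(rng, 6)
        d = cophenetic_matrix(t).data
        n = d.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    trip = sorted([d[i, j], d[i, k], d[j, k]])
                    assert trip[1] == pytest.approx(trip[2], abs=1e-9)


class TestNnlsUltrametric:
    def test_fixed_point_on_ultrametric_input(self, rng):
        t = random_clock_tree(rng, 7)
        order = [x.name for x in t.tips()]
        u = nnls_ultrametric(t)
        assert is_ultrametric(u)
        assert np.allclose(
            tip_distances(u, order), tip_distances(t, order), atol=1e-8
        )

    def test_three_leaf_closed_form(self):
        # D_AB = 2, D_AC = 4.5, D_BC = 5.5 -> h(AB) = 1, h(root) = (4.5+5.5)/4
        t = read_newick("((A:0.5,B:1.5):1,C:3);")
        u = nnls_ultrametric(t)
        d = tip_distances(u, ["A", "B", "C"])
        assert d[0, 1] == pytest.approx(2.0, abs=1e-8)
        assert d[0, 2] == pytest.approx(5.0, abs=1e-8)
        assert d[1, 2] == pytest.approx(5.0, abs=1e-8)

    @staticmethod
    def _objective(tree, heights, d0, order):
        """sum_{i<j} (D0_ij - 2 h(mrca(i,j)))^2 for given node heights."""
        pos = {name: k for k, name in enumerate(order)}
        tips = {x.name: x for x in tree.tips()}
        total = 0.0
        for a in range(len(order)):
            for b in range(a + 1, len(order)):
                ta, tb = tips[order[a]], tips[order[b]]
                mrca = tree.lowest_common_ancestor([ta, tb])
                total += (d0[pos[order[a]], pos[order[b]]] - 2 * heights[mrca]) ** 2
        return total

    def test_local_optimality_against_random_feasible_heights(self, rng):
        t = random_additive_tree(rng, 6)
        rooted = midpoint_root(t)
        order = [x.name for x in rooted.tips()]
        d0 = tip_distances(rooted, order)
        u = nnls_ultrametric(rooted)
        h = node_heights(u)
        best = self._objective(u, h, d0, order)
        internal = [n for n in u.postorder() if not n.is_tip()]
        for _ in range(1000):
            pert = {n: max(h[n] + rng.normal(0, 0.05), 0.0) for n in internal}
            for n in internal:  # enforce monotonicity bottom-up
                for c in n.children:
                    if not c.is_tip():
                        pert[n] = max(pert[n], pert[c])
            pert.update({n: 0.0 for n in u.tips()})
            cand = self._objective(u, pert, d0, order)
            assert cand >= best - 1e-9


class TestFitDiagnostic:
    def test_perfect_fit_on_own_distances(self, rng):
        t = random_additive_tree(rng, 6)
        d = t.tip_tip_distances()
        rep = tree_fit_diagnostic(t, d)
        assert rep["correlation"] == pytest.approx(1.0)
        assert rep["stress"] == pytest.approx(0.0, abs=1e-12)

    def test_upgma_beats_nj_on_ultrametric_data(self, rng):
        t = random_clock_tree(rng, 6)
        d = t.tip_tip_distances()
        s_upgma = tree_fit_diagnostic(upgma(d), d)["stress"]
        s_nj = tree_fit_diagnostic(neighbor_joining(d), d)["stress"]
        assert s_upgma <= s_nj + 1e-12

    def test_stress_matches_brute_force(self, rng):
        t = random_additive_tree(rng, 5)
        order = [x.name for x in t.tips()]
        noisy = t.tip_tip_distances().filter(order).data + rng.uniform(
            0, 0.2, (5, 5)
        )
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 0)
        d = DistanceMatrix(noisy, order)
        rep = tree_fit_diagnostic(t, d)
        dt = t.tip_tip_distances().filter(order).data
        num = den = 0.0
        for i in range(5):
            for j in range(i + 1, 5):
                num += (dt[i, j] - noisy[i, j]) ** 2
                den += noisy[i, j] ** 2
        assert rep["stress"] == pytest.approx(np.sqrt(num / den), abs=1e-12)


class TestNewickIO:
    def test_small_tree_parses(self):
        t = read_newick("((A:1,B:1):2,C:3);")
        assert sorted(x.name for x in t.tips()) == ["A", "B", "C"]
        assert cophenetic_matrix(t)["A", "C"] == 6

    def test_round_trip_fuzzed_corpus(self, rng):
        for _ in range(15):
            t = random_additive_tree(rng, int(rng.integers(3, 9)))
            text = write_newick(t)
            t2 = read_newick(text)
            assert write_newick(t2) == text

    def test_malformed_newick_rejected(self):
        with pytest.raises(Exception):
            read_newick("((A:1,B:1:2,C:3);")
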