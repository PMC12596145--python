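"""Tree distances, Mantel, PCoA, Procrustes and PROTEST."""

import io
import itertools

import networkx as nx
import numpy as np
import pytest
from scipy.spatial import procrustes as scipy_procrustes
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import mantel as skbio_mantel
from skbio.stats.ordination import pcoa as skbio_pcoa

from oracles import exhaustive_mantel_p, exhaustive_protest_p
from phylogeoscan import (euclidean_tree_distance, least_squares_distance,
                          mantel_test, mean_patristic_matrix, newick_read,
                          newick_write, patristic_matrix, pcoa, procrustes_m2,
                          protest, robinson_foulds)
from phylogeoscan.compare import read_matrix_csv, write_matrix_csv
from phylogeoscan.simulate import make_additive_tree_matrix


def random_dm(n, seed, ids=None):
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n, 3))
    return DistanceMatrix(squareform(pdist(pts), checks=False),
                          ids=ids or [f"t{i}" for i in range(n)])


class TestPatristic:
    def test_two_and_four_leaf_path_sums(self):
        assert patristic_matrix(newick_read("(A:1,B:2);"))["A", "B"] == 3
        dm = patristic_matrix(newick_read("((A:1,B:1):1,(C:1,D:1):1);"))
        assert dm["A", "C"] == 4 and dm["A", "B"] == 2

    def test_missing_length_error_and_zero_flag(self):
        t = newick_read("((A:1,B:1),C:1);")
        with pytest.raises(ValueError, match="branch length"):
            patristic_matrix(t)
        assert patristic_matrix(t, missing_as_zero=True)["A", "C"] == 2

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_graph_shortest_path_oracle(self, seed):
        tree, _ = make_additive_tree_matrix(7, rng_seed=seed)
        g = nx.Graph()
        for node in tree.traverse(include_self=True):
            for child in node.children:
                g.add_edge(id(node), id(child), weight=child.length)
        tips = {t.name: id(t) for t in tree.tips()}
        dm = patristic_matrix(tree)
        for a, b in itertools.combinations(sorted(tips), 2):
            expected = nx.shortest_path_length(g, tips[a], tips[b], weight="weight")
            assert dm[a, b] == pytest.approx(expected, abs=1e-12)


class TestRobinsonFoulds:
    def test_identical_topologies_zero(self):
        t = newick_read("((A,B),(C,D),E);")
        assert robinson_foulds(t, newick_read("((A,B),(C,D),E);")) == 0

    def test_conflicting_quartets(self):
        t1 = newick_read("((A,B),(C,D));")
        t2 = newick_read("((A,C),(B,D));")
        assert robinson_foulds(t1, t2) == 2
        assert robinson_foulds(t1, t2, normalized=True) == 1.0

    def test_binary_vs_star_counts_internal_edges(self):
        binary = newick_read("((A,B),(C,D),E);")  # 2 internal edges on 5 taxa
        star = newick_read("(A,B,C,D,E);")
        assert robinson_foulds(binary, star) == 2
        assert robinson_foulds(star, star, normalized=True) == 0.0

    def test_leaf_set_mismatch(self):
        with pytest.raises(ValueError, match="leaf sets differ"):
            robinson_foulds(newick_read("((A,B),C);"), newick_read("((A,B),D);"))

    @pytest.mark.parametrize("seeds", [(0, 1, 2), (3, 4, 5), (6, 7, 8)])
    def test_metric_axioms_on_random_six_leaf_trees(self, seeds):
        trees = [make_additive_tree_matrix(6, rng_seed=s)[0] for s in seeds]
        a, b, c = trees
        assert robinson_foulds(a, a) == 0
        assert robinson_foulds(a, b) == robinson_foulds(b, a)
        assert (robinson_foulds(a, c)
                <= robinson_foulds(a, b) + robinson_foulds(b, c))

    @pytest.mark.parametrize("s1,s2", [(0, 1), (2, 3), (4, 5)])
    def test_agrees_with_dendropy(self, s1, s2):
        import dendropy

        t1, _ = make_additive_tree_matrix(8, rng_seed=s1)
        t2, _ = make_additive_tree_matrix(8, rng_seed=s2)
        tns = dendropy.TaxonNamespace()
        d1 = dendropy.Tree.get(data=newick_write(t1), schema="newick", taxon_namespace=tns)
        d2 = dendropy.Tree.get(data=newick_write(t2), schema="newick", taxon_namespace=tns)
        d1.encode_bipartitions(); d2.encode_bipartitions()
        expected = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
        assert robinson_foulds(t1, t2) == expected


class TestLsdAndEuclidean:
    def test_identical_trees_zero_for_all_three(self):
        t1, _ = make_additive_tree_matrix(6, rng_seed=9)
        t2 = t1.copy()
        assert least_squares_distance(t1, t2) == pytest.approx(0, abs=1e-9)
        assert euclidean_tree_distance(t1, t2) == pytest.approx(0, abs=1e-9)
        assert robinson_foulds(t1, t2) == 0

    def test_single_pair_difference(self):
        assert least_squares_distance(newick_read("(A:1,B:1);"),
                                      newick_read("(A:2,B:2);")) == 2.0

    def test_euclidean_default_equals_lsd_and_clade_option(self):
        t1, _ = make_additive_tree_matrix(6, rng_seed=10)
        t2, _ = make_additive_tree_matrix(6, rng_seed=11)
        assert euclidean_tree_distance(t1, t2) == least_squares_distance(t1, t2)
        q1 = newick_read("((A:1,B:1):1,(C:1,D:1):1);")
        q2 = newick_read("((A:1,C:1):1,(B:1,D:1):1);")
        assert euclidean_tree_distance(q1, q2, "clades") == pytest.approx(np.sqrt(2))

    def test_leaf_order_permutation_invariance(self):
        t1 = newick_read("((A:1,B:2):1,(C:1,D:2):1);")
        t1_shuffled = newick_read("((D:2,C:1):1,(B:2,A:1):1);")
        t2, _ = make_additive_tree_matrix(4, rng_seed=1)
        t2 = newick_read(newick_write(t2).replace("L00", "A").replace("L01", "B")
                         .replace("L02", "C").replace("L03", "D"))
        assert least_squares_distance(t1, t2) == pytest.approx(
            least_squares_distance(t1_shuffled, t2))


class TestMantel:
    def test_perfect_correlation_minimal_p(self):
        m = random_dm(8, 0)
        res = mantel_test(m, m, permutations=99, rng_seed=1)
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 100)

    def test_affine_invariance_of_pearson(self):
        m = random_dm(7, 3)
        m2 = DistanceMatrix(2.5 * m.data + (1 - np.eye(7)), ids=m.ids)
        res = mantel_test(m, m2, permutations=49, rng_seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_statistic_matches_skbio(self):
        m1, m2 = random_dm(9, 4), random_dm(9, 5)
        mine = mantel_test(m1, m2, permutations=9, rng_seed=0)
        ref_r, _, _ = skbio_mantel(m1, m2, permutations=9)
        assert mine.statistic == pytest.approx(ref_r)
        spearman = mantel_test(m1, m2, permutations=9, rng_seed=0, method="spearman")
        ref_s, _, _ = skbio_mantel(m1, m2, method="spearman", permutations=9)
        assert spearman.statistic == pytest.approx(ref_s)

    def test_exhaustive_permutation_oracle_n4(self):
        m1, m2 = random_dm(4, 7), random_dm(4, 8)
        res = mantel_test(m1, m2, all_permutations=True)
        obs, p = exhaustive_mantel_p(m1.data, m2.data)
        assert res.statistic == pytest.approx(obs)
        assert res.p_value == pytest.approx(p)
        assert res.permutations == 24

    def test_degenerate_constant_matrix_flagged(self):
        const = DistanceMatrix(1 - np.eye(5), ids=list("abcde"))
        res = mantel_test(const, random_dm(5, 1, ids=list("abcde")), permutations=9)
        assert res.degenerate and np.isnan(res.statistic)

    def test_invariant_to_simultaneous_relabeling(self):
        m1, m2 = random_dm(6, 12), random_dm(6, 13)
        perm = ["t3", "t0", "t5", "t1", "t4", "t2"]
        r = mantel_test(m1, m2, permutations=1, rng_seed=0).statistic
        r_perm = mantel_test(m1.filter(perm), m2.filter(perm),
                             permutations=1, rng_seed=0).statistic
        assert r == pytest.approx(r_perm)

    def test_seed_reproducibility(self):
        m1, m2 = random_dm(8, 20), random_dm(8, 21)
        a = mantel_test(m1, m2, permutations=99, rng_seed=5)
        b = mantel_test(m1, m2, permutations=99, rng_seed=5)
        assert (a.statistic, a.p_value) == (b.statistic, b.p_value)


class TestPcoa:
    def test_three_points_on_a_line(self):
        pts = np.array([0.0, 1.0, 3.0])
        dm = DistanceMatrix(np.abs(pts[:, None] - pts[None, :]), ids=list("abc"))
        X = pcoa(dm, k=2)
        assert X.shape[1] == 1  # a line has one positive axis
        rec = squareform(pdist(X), checks=False)
        assert np.allclose(rec, dm.data, atol=1e-10)

    def test_recovers_euclidean_configuration(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(10, 2))
        dm = DistanceMatrix(squareform(pdist(pts), checks=False),
                            ids=[str(i) for i in range(10)])
        X = pcoa(dm, k=2)
        assert np.allclose(squareform(pdist(X), checks=False), dm.data, atol=1e-8)

    def test_zero_matrix_gives_zero_configuration(self):
        dm = DistanceMatrix(np.zeros((4, 4)), ids=list("abcd"))
        assert np.allclose(pcoa(dm, k=2), 0)

    def test_k_bounds(self):
        dm = random_dm(5, 3)
        with pytest.raises(ValueError):
            pcoa(dm, k=5)

    def test_agrees_with_skbio_pcoa_distances(self):
        dm = random_dm(8, 30)
        X = pcoa(dm, k=3)
        ref = skbio_pcoa(dm, number_of_dimensions=3).samples.values
        assert np.allclose(squareform(pdist(X), checks=False),
                           squareform(pdist(ref), checks=False), atol=1e-8)


class TestProcrustes:
    def test_rigid_motion_and_scaling_give_zero(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(9, 2))
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        Y = 3.2 * X @ R + np.array([5.0, -2.0])
        assert procrustes_m2(X, Y) == pytest.approx(0, abs=1e-12)
        assert procrustes_m2(X, X) == pytest.approx(0, abs=1e-12)

    def test_matches_scipy_disparity(self):
        rng = np.random.default_rng(7)
        X, Y = rng.normal(size=(8, 3)), rng.normal(size=(8, 3))
        _, _, disparity = scipy_procrustes(X, Y)
        assert procrustes_m2(X, Y) == pytest.approx(disparity, abs=1e-10)

    def test_reflection_disallowed_matches_rotation_grid_oracle(self):
        X = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        Y = X @ np.diag([1.0, -1.0])  # reflected copy
        m2 = procrustes_m2(X, Y, allow_reflection=False)

        def norm(Z):
            Z = Z - Z.mean(0)
            return Z / np.linalg.norm(Z)
        Xn, Yn = norm(X), norm(Y)
        best = -np.inf
        for theta in np.linspace(0, 2 * np.pi, 400_000, endpoint=False):
            R = np.array([[np.cos(theta), -np.sin(theta)],
                          [np.sin(theta), np.cos(theta)]])
            best = max(best, np.sum(Xn * (Yn @ R)))
        assert m2 == pytest.approx(1 - best**2, abs=1e-6)
        assert procrustes_m2(X, Y, allow_reflection=True) == pytest.approx(0, abs=1e-12)

    def test_zero_variance_configuration_rejected(self):
        with pytest.raises(ValueError, match="zero total variance"):
            procrustes_m2(np.ones((4, 2)), np.random.default_rng(0).normal(size=(4, 2)))


class TestProtest:
    def test_identical_matrices_statistic_one(self):
        m = random_dm(8, 40)
        res = protest(m, m, permutations=99, rng_seed=0)
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 100)

    def test_exhaustive_permutation_oracle_n4(self):
        m1, m2 = random_dm(4, 41), random_dm(4, 42)
        res = protest(m1, m2, k=3, all_permutations=True)
        obs, p = exhaustive_protest_p(m1.data, m2.data, k=3)
        assert res.statistic == pytest.approx(obs)
        assert res.p_value == pytest.approx(p)

    def test_seed_reproducibility(self):
        m1, m2 = random_dm(9, 50), random_dm(9, 51)
        a = protest(m1, m2, permutations=99, rng_seed=3)
        b = protest(m1, m2, permutations=99, rng_seed=3)
        assert (a.statistic, a.p_value) == (b.statistic, b.p_value)


class TestMeanPatristic:
    def test_mean_over_replicates(self):
        t1 = newick_read("(A:1,B:1,C:1);")
        t2 = newick_read("(A:3,B:1,C:1);")
        dm = mean_patristic_matrix([t1, t2])
        assert dm["A", "B"] == 3.0  # mean of 2 and 4


class TestMatrixCsv:
    def test_round_trip(self, tmp_path):
        dm = random_dm(5, 60)
        p = tmp_path / "m.csv"
        write_matrix_csv(dm, p)
        back = read_matrix_csv(p)
        assert back.ids == dm.ids
        assert np.allclose(back.data, dm.data)
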