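"""Bruvo distances against a brute-force oracle; trees and networks."""

import itertools

import numpy as np
import pytest
from skbio import DistanceMatrix

from mlgpop.distance import (
    allele_sharing,
    bruvo_allele,
    bruvo_locus,
    bruvo_matrix,
    bruvo_pair,
    geographic_distance_matrix,
    n_diff_loci,
    nj_tree,
    spanning_network,
)
from .conftest import make_coll, make_geno, random_collection


# --- independent brute-force oracle (no shared code with the package) ---

def oracle_bruvo(ra, rb):
    """Bruvo distance from first principles: per locus, minimum over all
    permutations of one side of the mean per-allele 1 - 2^-|dx|."""
    vals = []
    for j in range(ra.shape[0]):
        a, b = ra[j], rb[j]
        if a[0] == 0 or b[0] == 0:
            continue
        best = min(
            np.mean([1.0 - 2.0 ** (-abs(int(x) - int(y))) for x, y in zip(a, perm)])
            for perm in itertools.permutations(b)
        )
        vals.append(best)
    return float(np.mean(vals))


class TestBruvoClosedForms:
    def test_allele_values(self):
        assert bruvo_allele(10, 10) == 0.0
        assert bruvo_allele(10, 11) == 0.5
        assert bruvo_allele(10, 12) == 0.75
        assert bruvo_allele(10, 13) == 0.875
        assert abs(bruvo_allele(10, 40) - 1.0) < 1e-9

    def test_locus_matching_minimum(self):
        # (10,12) vs (11,12): identity matching (0.5+0)/2 = 0.25,
        # crossed (0.75+0.5)/2 = 0.625 -> min 0.25
        assert bruvo_locus((10, 12), (11, 12)) == pytest.approx(0.25, abs=1e-15)

    def test_locus_symmetric(self):
        assert bruvo_locus((10, 15), (12, 13)) == bruvo_locus((12, 13), (10, 15))

    def test_pair_excludes_missing_loci(self):
        ra = np.array([[10, 12], [0, 0], [20, 20]])
        rb = np.array([[10, 12], [15, 15], [21, 20]])
        # only loci 0 and 2 compared: (0 + 0.25) / 2
        assert bruvo_pair(ra, rb) == pytest.approx(0.125, abs=1e-15)

    def test_pair_with_no_comparable_loci_raises(self):
        ra = np.array([[0, 0], [10, 10]])
        rb = np.array([[10, 10], [0, 0]])
        with pytest.raises(ValueError):
            bruvo_pair(ra, rb)


class TestBruvoMatrixOracle:
    def test_matches_brute_force(self, rng):
        coll = random_collection(rng, n=12, n_loci=17)
        dm = bruvo_matrix(coll)
        rep = coll.repeat_array()
        for i, j in itertools.combinations(range(12), 2):
            assert dm[coll.ids[i], coll.ids[j]] == pytest.approx(
                oracle_bruvo(rep[i], rep[j]), abs=1e-12
            )

    def test_matches_brute_force_with_missing(self, rng):
        coll = random_collection(rng, n=8, n_loci=10, missing_rate=0.15)
        dm = bruvo_matrix(coll)
        rep = coll.repeat_array()
        for i, j in itertools.combinations(range(8), 2):
            assert dm[coll.ids[i], coll.ids[j]] == pytest.approx(
                oracle_bruvo(rep[i], rep[j]), abs=1e-12
            )

    def test_metric_properties(self, rng):
        coll = random_collection(rng, n=6, n_loci=5)
        d = bruvo_matrix(coll).data
        assert np.allclose(d, d.T)
        assert np.all(np.diag(d) == 0)
        assert np.all(d >= 0) and np.all(d <= 1)

    def test_identical_genotypes_distance_zero(self):
        coll = make_coll(
            [("a", [(20, 24), (30, 30)], {}), ("b", [(24, 20), (30, 30)], {}),
             ("c", [(20, 24), (30, 32)], {})]
        )
        dm = bruvo_matrix(coll)
        assert dm["a", "b"] == 0.0
        assert dm["a", "c"] > 0


class TestAlleleSharing:
    def test_hand_computed(self):
        a = make_geno("a", [(100, 102), (98, 98), (96, 94)])
        b = make_geno("b", [(100, 100), (98, 98), (90, 92)])
        # locus1 shares 1 (100), locus2 shares 2, locus3 shares 0 -> 3/6
        share, excl = allele_sharing(a, b)
        assert share == pytest.approx(0.5, abs=1e-15)
        assert excl == 0

    def test_missing_loci_excluded(self):
        a = make_geno("a", [(100, 102), (0, 0)])
        b = make_geno("b", [(100, 102), (98, 98)])
        share, excl = allele_sharing(a, b)
        assert share == 1.0
        assert excl == 1

    def test_starter_rule_arithmetic_exact(self):
        # 17 loci, 2 loci fully different: shared 30 of 34 alleles
        pairs_a = [(100 + 2 * j, 102 + 2 * j) for j in range(17)]
        pairs_b = [list(p) for p in pairs_a]
        pairs_b[0] = (400, 402)
        pairs_b[1] = (404, 406)
        share, _ = allele_sharing(make_geno("a", pairs_a), make_geno("b", pairs_b))
        assert share == 30 / 34

    def test_n_diff_loci(self):
        a = make_geno("a", [(100, 102), (98, 98), (0, 0)])
        b = make_geno("b", [(102, 100), (98, 96), (94, 94)])
        assert n_diff_loci(a, b) == 1  # locus2 only; missing locus skipped


class TestNJTree:
    def test_three_taxon_closed_form(self):
        # additive 3-taxon distances have the unique closed-form solution
        # edge_a = (d_ab + d_ac - d_bc)/2, etc.
        d = np.array([[0, 3, 8.0], [3, 0, 9.0], [8, 9, 0]])
        t = nj_tree(DistanceMatrix(d, ids=list("abc")), midpoint=False)
        edge = {tip.name: tip.length for tip in t.tips()}
        assert edge["a"] == pytest.approx((3 + 8 - 9) / 2)
        assert edge["b"] == pytest.approx((3 + 9 - 8) / 2)
        assert edge["c"] == pytest.approx((8 + 9 - 3) / 2)

    def test_additive_matrix_topology_recovery(self):
        # quartet ((a,b),(c,d)) with internal edge 4
        t_ab, t_cd, internal = 1.0, 2.0, 4.0
        d = np.zeros((4, 4))
        lens = {"a": t_ab, "b": t_ab, "c": t_cd, "d": t_cd}
        ids = ["a", "b", "c", "d"]
        for i, j in itertools.combinations(range(4), 2):
            x, y = ids[i], ids[j]
            same = {x, y} in ({"a", "b"}, {"c", "d"})
            d[i, j] = d[j, i] = lens[x] + lens[y] + (0 if same else internal)
        t = nj_tree(DistanceMatrix(d, ids=ids), midpoint=False)
        # a and b must be sisters: their deepest common ancestor excludes c, d
        lca = t.lca(["a", "b"])
        assert {tip.name for tip in lca.tips()} == {"a", "b"}

    def test_midpoint_root_balances_depths(self):
        d = np.array([[0, 3, 8.0], [3, 0, 9.0], [8, 9, 0]])
        t = nj_tree(DistanceMatrix(d, ids=list("abc")))
        depths = {tip.name: t.find(tip.name).accumulate_to_ancestor(t) for tip in t.tips()}
        # midpoint: the two ends of the longest path (b-c, length 9) sit at 4.5
        assert max(depths.values()) == pytest.approx(4.5)

    def test_requires_three_labels(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(np.array([[0, 1.0], [1, 0]]), ids=list("ab")))


class TestSpanningNetwork:
    def test_matches_exhaustive_minimum(self, rng):
        # compare total weight against brute force over all spanning trees
        import networkx as nx

        n = 6
        w = rng.random((n, n))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        ids = [f"n{i}" for i in range(n)]
        g = spanning_network(DistanceMatrix(w, ids=ids))
        total = sum(d["distance"] for _, _, d in g.edges(data=True))
        complete = nx.Graph()
        for i, j in itertools.combinations(range(n), 2):
            complete.add_edge(ids[i], ids[j], weight=w[i, j])
        def spans_all(tree):
            h = nx.Graph(list(tree))
            return h.number_of_nodes() == n and nx.is_connected(h)

        best = min(
            sum(w[ids.index(a), ids.index(b)] for a, b in tree)
            for tree in itertools.combinations(complete.edges, n - 1)
            if spans_all(tree)
        )
        assert total == pytest.approx(best, abs=1e-12)
        assert g.number_of_edges() == n - 1
        assert nx.is_connected(g)

    def test_deterministic_under_ties(self):
        # all-equal distances: tie-break must give a reproducible tree
        d = np.ones((4, 4)) - np.eye(4)
        dm = DistanceMatrix(d, ids=list("dcba"))
        g1 = spanning_network(dm)
        g2 = spanning_network(DistanceMatrix(d, ids=list("dcba")))
        assert sorted(g1.edges) == sorted(g2.edges)

    def test_multiplicity_attribute(self):
        d = np.array([[0, 1.0], [1, 0]])
        g = spanning_network(DistanceMatrix(d, ids=["a", "b"]), {"a": 5})
        assert g.nodes["a"]["multiplicity"] == 5
        assert g.nodes["b"]["multiplicity"] == 1


class TestGeographicDistance:
    def test_known_city_pair(self):
        import pandas as pd

        # Paris <-> Bordeaux great-circle distance ~ 499 km
        df = pd.DataFrame(
            {"latitude": [48.8566, 44.8378], "longitude": [2.3522, -0.5792]},
            index=["paris", "bordeaux"],
        )
        dm = geographic_distance_matrix(df)
        assert dm["paris", "bordeaux"] == pytest.approx(499, abs=5)

    def test_zero_on_diagonal_and_symmetric(self):
        import pandas as pd

        df = pd.DataFrame(
            {"latitude": [44.8, 45.0, 44.9], "longitude": [-0.6, -0.7, -0.5]},
            index=list("abc"),
        )
        dm = geographic_distance_matrix(df)
        assert dm["a", "a"] == 0
        assert dm["a", "b"] == dm["b", "a"]
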