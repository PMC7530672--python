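"""AMOVA / Fst / Mantel oracles: closed-form toys, an independent
one-level AMOVA implementation, and estimator invariants."""

import itertools

import numpy as np
import pytest
from skbio import DistanceMatrix

from mlgpop.distance import bruvo_matrix
from mlgpop.structure import (
    amova,
    balanced_fst,
    mantel,
    pairwise_fst,
    phi_pt,
    pop_summary,
    weir_cockerham_theta,
)
from .conftest import make_coll, random_collection


def fixed_difference_coll(n_per=4):
    """Two populations, each fixed homozygous for a private allele."""
    rows = []
    for i in range(n_per):
        rows.append((f"p1_{i}", [(100, 100), (200, 200)], {"pop": "P1"}))
        rows.append((f"p2_{i}", [(120, 120), (220, 220)], {"pop": "P2"}))
    return make_coll(rows)


def one_level_amova_oracle(D, codes):
    """Independent one-level AMOVA from squared distances (Excoffier):
    SSD(total) = sum_{i<j} d2 / N; SSD(within) likewise per group;
    sigma_w = SSD_w / (N - g); sigma_a = (MSD_a - sigma_w) / n0 with
    n0 = (N - sum n_i^2 / N) / (g - 1).  Phi = sigma_a / (sigma_a + sigma_w).
    """
    N = len(codes)
    groups = sorted(set(codes))
    g = len(groups)
    ssd_total = sum(D[i, j] for i, j in itertools.combinations(range(N), 2)) / N
    ssd_within = 0.0
    for lab in groups:
        idx = [i for i in range(N) if codes[i] == lab]
        ssd_within += sum(D[i, j] for i, j in itertools.combinations(idx, 2)) / len(idx)
    ssd_among = ssd_total - ssd_within
    sizes = [codes.count(lab) for lab in groups]
    n0 = (N - sum(s * s for s in sizes) / N) / (g - 1)
    sigma_w = ssd_within / (N - g)
    sigma_a = (ssd_among / (g - 1) - sigma_w) / n0
    return sigma_a, sigma_w, sigma_a / (sigma_a + sigma_w)


class TestAmovaToys:
    def test_phi_one_for_fixed_difference(self):
        res = amova(fixed_difference_coll(), ["pop"], n_perm=99, seed=1)
        assert res.levels[0]["phi"] == pytest.approx(1.0, abs=1e-12)
        # permutations reproducing the original split (prob 2*4!4!/8!)
        # tie the observed Phi, so p is small but above the 1/(B+1) floor
        assert 1 / 100 <= res.levels[0]["p_value"] <= 0.1

    def test_phi_one_for_fixed_difference_bruvo(self):
        res = amova(fixed_difference_coll(), ["pop"], n_perm=0, distance="bruvo")
        assert res.levels[0]["phi"] == pytest.approx(1.0, abs=1e-12)

    def test_bruvo_mode_matches_independent_oracle(self, rng):
        coll = random_collection(
            rng, n=11, n_loci=6, meta_fn=lambda i: {"pop": f"P{i % 3}"}
        )
        D = bruvo_matrix(coll).data
        codes = list(coll.labels("pop"))
        sig_a, sig_w, phi = one_level_amova_oracle(D, codes)
        res = amova(coll, ["pop"], n_perm=0, distance="bruvo")
        assert res.levels[0]["sigma2"] == pytest.approx(sig_a, abs=1e-10)
        assert res.levels[-1]["sigma2"] == pytest.approx(sig_w, abs=1e-10)
        assert res.levels[0]["phi"] == pytest.approx(phi, abs=1e-10)

    def test_copies_mode_matches_distance_oracle_per_locus(self):
        # one locus, complete data: the one-hot copy features reproduce
        # the mismatch-count distance, so the two-level decomposition's
        # SS must match the oracle run on copy distances
        coll = make_coll(
            [
                ("a", [(100, 102)], {"pop": "P1"}),
                ("b", [(100, 100)], {"pop": "P1"}),
                ("c", [(104, 106)], {"pop": "P2"}),
                ("d", [(104, 104)], {"pop": "P2"}),
                ("e", [(100, 104)], {"pop": "P2"}),
            ]
        )
        res = amova(coll, ["pop"], n_perm=0)
        # squared distance between copies = 0 if same allele else 1
        copies = [a for g in coll for a in g.alleles[0]]
        D = np.array([[0.0 if x == y else 1.0 for y in copies] for x in copies])
        N = len(copies)
        # within-individual: SSD over copy pairs / df (= copies - individuals)
        ssd_ind = sum(D[i, i + 1] / 2 for i in range(0, N, 2))
        assert res.within_individual[1] == pytest.approx(ssd_ind / (N // 2), abs=1e-10)

    def test_nested_hierarchy_runs_and_sums(self, rng):
        coll = random_collection(
            rng,
            n=24,
            n_loci=5,
            meta_fn=lambda i: {"app": f"A{i // 12}", "estate": f"E{i // 6}"},
        )
        res = amova(coll, ["app", "estate"], n_perm=49, seed=0)
        names = [l["name"] for l in res.levels]
        assert names == ["app", "estate", "individual"]
        assert res.within_individual is not None
        for l in res.levels:
            assert l["p_value"] is not None
            assert 0 < l["p_value"] <= 1

    def test_selfing_gives_large_individual_phi(self):
        # all-homozygous individuals with polymorphism between them:
        # within-individual variance 0 -> Phi for individuals = 1
        rows = [
            (f"i{k}", [(100 + 4 * k, 100 + 4 * k), (200, 200)], {"pop": f"P{k % 2}"})
            for k in range(8)
        ]
        res = amova(make_coll(rows), ["pop"], n_perm=0)
        assert res.levels[-1]["phi"] == pytest.approx(1.0, abs=1e-12)

    def test_not_nested_raises(self):
        rows = [
            ("a", [(100, 100)], {"app": "A1", "estate": "E1"}),
            ("b", [(102, 102)], {"app": "A2", "estate": "E1"}),
            ("c", [(104, 104)], {"app": "A1", "estate": "E2"}),
            ("d", [(104, 104)], {"app": "A2", "estate": "E2"}),
        ]
        with pytest.raises(ValueError, match="not nested"):
            amova(make_coll(rows), ["app", "estate"], n_perm=0)

    def test_single_group_raises(self):
        rows = [("a", [(100, 100)], {"pop": "P"}), ("b", [(102, 102)], {"pop": "P"})]
        with pytest.raises(ValueError, match="single group"):
            amova(make_coll(rows), ["pop"], n_perm=0)

    def test_permutation_p_reproducible(self, rng):
        coll = random_collection(rng, n=12, n_loci=4, meta_fn=lambda i: {"pop": f"P{i % 2}"})
        a = amova(coll, ["pop"], n_perm=99, seed=5)
        b = amova(coll, ["pop"], n_perm=99, seed=5)
        assert a.levels[0]["p_value"] == b.levels[0]["p_value"]


class TestPairwiseFst:
    def test_fixed_difference_phi_pt_one(self):
        coll = fixed_difference_coll()
        assert phi_pt(coll, coll.labels("pop")) == pytest.approx(1.0, abs=1e-12)

    def test_fixed_difference_wc_one(self):
        coll = fixed_difference_coll()
        assert weir_cockerham_theta(coll, "pop") == pytest.approx(1.0, abs=1e-12)

    def test_matrix_shape_and_significance(self, rng):
        coll = random_collection(
            rng, n=18, n_loci=6, meta_fn=lambda i: {"pop": f"P{i % 3}"}
        )
        fst, p = pairwise_fst(coll, "pop", n_perm=49, seed=0)
        assert list(fst.ids) == ["P0", "P1", "P2"]
        assert np.allclose(fst.data, fst.data.T)
        iu = np.triu_indices(3, 1)
        assert np.all(p[iu] >= 1 / 50)

    def test_small_groups_excluded(self, rng):
        coll = random_collection(
            rng, n=9, n_loci=4, meta_fn=lambda i: {"pop": "solo" if i == 8 else f"P{i % 2}"}
        )
        fst, _ = pairwise_fst(coll, "pop", n_perm=0)
        assert "solo" not in fst.ids

    def test_wc_close_to_zero_for_split_pool(self, rng):
        # one panmictic pool randomly split in two: theta ~ 0
        coll = random_collection(
            rng, n=40, n_loci=10, meta_fn=lambda i: {"pop": f"P{i % 2}"}
        )
        fst, _ = pairwise_fst(coll, "pop", n_perm=0, estimator="weir_cockerham")
        assert fst["P0", "P1"] < 0.03

    def test_unknown_estimator(self, rng):
        coll = random_collection(rng, n=8, n_loci=3, meta_fn=lambda i: {"pop": f"P{i % 2}"})
        with pytest.raises(ValueError):
            pairwise_fst(coll, "pop", n_perm=0, estimator="nei")


class TestMantel:
    @staticmethod
    def correlated_pair(rng, n=6, noise=0.0):
        base = rng.random((n, n))
        base = (base + base.T) / 2
        np.fill_diagonal(base, 0)
        pert = rng.random((n, n)) * noise
        pert = (pert + pert.T) / 2
        np.fill_diagonal(pert, 0)
        ids = [f"x{i}" for i in range(n)]
        return DistanceMatrix(base, ids=ids), DistanceMatrix(2 * base + pert, ids=ids)

    def test_perfect_correlation(self, rng):
        d1, d2 = self.correlated_pair(rng)
        r, p = mantel(d1, d2, n_perm=199, seed=0)
        assert r == pytest.approx(1.0, abs=1e-12)
        assert p <= 0.05

    def test_exhaustive_includes_identity(self, rng):
        d1, d2 = self.correlated_pair(rng, n=4)
        r, p = mantel(d1, d2, exhaustive=True)
        assert r == pytest.approx(1.0, abs=1e-12)
        # identity permutation always ties the observed statistic
        assert p >= 1 / 24

    def test_label_mismatch(self, rng):
        d1, _ = self.correlated_pair(rng, n=4)
        d3 = DistanceMatrix(np.zeros((4, 4)), ids=["a", "b", "c", "d"])
        with pytest.raises(ValueError):
            mantel(d1, d3)

    def test_label_order_irrelevant(self, rng):
        d1, d2 = self.correlated_pair(rng, n=5, noise=1.0)
        perm = [3, 1, 4, 0, 2]
        d2_shuffled = DistanceMatrix(
            d2.data[np.ix_(perm, perm)], ids=[d2.ids[i] for i in perm]
        )
        r1, _ = mantel(d1, d2, n_perm=9, seed=0)
        r2, _ = mantel(d1, d2_shuffled, n_perm=9, seed=0)
        assert r1 == pytest.approx(r2, abs=1e-12)


class TestPopSummary:
    def test_hand_computed(self):
        coll = make_coll(
            [
                ("a", [(100, 100)], {"pop": "P"}),
                ("b", [(100, 102)], {"pop": "P"}),
                ("c", [(104, 104)], {"pop": "Q"}),
                ("d", [(104, 106)], {"pop": "Q"}),
            ]
        )
        s = pop_summary(coll, "pop")
        # P: Ho = 1/2; genes AAAB: He = 4/3 * (1 - (9+1)/16) = 0.5
        assert s["P"]["Ho"] == pytest.approx(0.5, abs=1e-12)
        assert s["P"]["He"] == pytest.approx(0.5, abs=1e-12)
        assert s["P"]["Fis"] == pytest.approx(0.0, abs=1e-12)
        assert s["P"]["allelic_richness"] == pytest.approx(2.0, abs=1e-12)

    def test_rarefy_to_too_large(self):
        coll = make_coll(
            [("a", [(100, 100)], {"pop": "P"}), ("b", [(104, 104)], {"pop": "Q"})]
        )
        with pytest.raises(ValueError):
            pop_summary(coll, "pop", rarefy_to=4)


class TestBalancedFst:
    def _coll(self, rng):
        def meta(i):
            return {
                "compartment": "grape" if i % 2 == 0 else "cellar",
                "estate": f"E{i % 4}",
            }

        return random_collection(rng, n=32, n_loci=6, meta_fn=meta)

    def test_reproducible_and_shaped(self, rng):
        coll = self._coll(rng)
        m1, s1, v1 = balanced_fst(coll, cap=3, n_reps=5, seed=9)
        m2, s2, v2 = balanced_fst(coll, cap=3, n_reps=5, seed=9)
        assert m1 == m2 and s1 == s2
        assert np.array_equal(v1, v2)
        assert len(v1) == 5

    def test_empty_side_raises(self, rng):
        coll = random_collection(
            rng, n=8, n_loci=3,
            meta_fn=lambda i: {"compartment": "grape", "estate": "E1"},
        )
        with pytest.raises(ValueError):
            balanced_fst(coll, n_reps=2)

    def test_cap_validation(self, rng):
        with pytest.raises(ValueError):
            balanced_fst(self._coll(rng), cap=1)
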