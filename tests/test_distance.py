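"""Distances, NJ, PCoA, AMOVA, Mantel, and Delta-K post-processing."""

import itertools

import numpy as np
import pandas as pd
import pytest
import skbio

from msatpop.core import CoordinateSet, GenotypeTable, allele_frequencies
from msatpop.distance import (
    DistanceMatrix,
    amova,
    evanno_delta_k,
    geographic_distances,
    mantel,
    nei_distance,
    nj_tree,
    pcoa,
    squared_genotypic_distance,
)

from conftest import make_random_table


def dm_from(values, labels=None, metric="test"):
    values = np.asarray(values, dtype=float)
    labels = labels or [f"t{i}" for i in range(values.shape[0])]
    return DistanceMatrix(labels=labels, values=values, metric=metric)


class TestNeiDistance:
    def test_identical_populations_zero(self):
        rng = np.random.default_rng(0)
        t = make_random_table(rng, n_pops=1, n_per_pop=8, n_loci=3)
        # duplicate the population so both share identical frequency vectors
        t2 = GenotypeTable(
            ids=t.ids + [f"{i}b" for i in t.ids], loci=t.loci,
            alleles=np.concatenate([t.alleles, t.alleles]),
            pops=["P1"] * t.n_individuals + ["P2"] * t.n_individuals)
        d = nei_distance(allele_frequencies(t2))
        assert d.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_single_locus_capped(self):
        alleles = np.array([[[1, 1]], [[1, 1]], [[2, 2]], [[2, 2]]])
        t = GenotypeTable(ids=list("abcd"), loci=["L1"], alleles=alleles,
                          pops=["P1", "P1", "P2", "P2"])
        d = nei_distance(allele_frequencies(t), cap=10.0)
        assert d.values[0, 1] == 10.0
        assert ("P1", "P2") in d.capped

    def test_hand_instance_three_pops_two_loci(self):
        """D matches the summed-J formula expanded by hand."""
        freqs = allele_frequencies(_three_pop_table())
        d = nei_distance(freqs)
        p = {  # population x locus frequency vectors on the union support
            "P1": [np.array([0.5, 0.5, 0.0]), np.array([1.0, 0.0])],
            "P2": [np.array([0.25, 0.75, 0.0]), np.array([0.5, 0.5])],
            "P3": [np.array([0.0, 0.5, 0.5]), np.array([0.0, 1.0])],
        }
        for a, b in itertools.combinations(["P1", "P2", "P3"], 2):
            jx = sum(float(v @ v) for v in p[a])
            jy = sum(float(v @ v) for v in p[b])
            jxy = sum(float(v @ w) for v, w in zip(p[a], p[b]))
            expected = -np.log(jxy / np.sqrt(jx * jy))
            i, j = d.labels.index(a), d.labels.index(b)
            assert d.values[i, j] == pytest.approx(expected, abs=1e-12)


def _three_pop_table():
    rows = {
        "P1": [([1, 2], [10, 10]), ([1, 2], [10, 10])],
        "P2": [([1, 2], [10, 11]), ([2, 2], [10, 11])],
        "P3": [([2, 3], [11, 11]), ([2, 3], [11, 11])],
    }
    ids, pops, alleles = [], [], []
    k = 0
    for pop, geno in rows.items():
        for g in geno:
            ids.append(f"i{k}")
            pops.append(pop)
            alleles.append(g)
            k += 1
    return GenotypeTable(ids=ids, loci=["L1", "L2"],
                         alleles=np.asarray(alleles), pops=pops)


class TestNeighbourJoining:
    def test_three_taxa_closed_form(self):
        d = dm_from([[0, 3, 5], [3, 0, 6], [5, 6, 0]], list("ABC"))
        tree = skbio.TreeNode.read([nj_tree(d)])
        # branch lengths solve the three-point equations
        assert tree.find("A").length == pytest.approx((3 + 5 - 6) / 2)
        assert tree.find("B").length == pytest.approx((3 + 6 - 5) / 2)
        assert tree.find("C").length == pytest.approx((5 + 6 - 3) / 2)

    def test_additive_matrix_recovered_exactly(self):
        # generate an additive matrix from a known 5-taxon tree
        dist = {("A", "B"): 5, ("A", "C"): 9, ("A", "D"): 10, ("A", "E"): 9,
                ("B", "C"): 10, ("B", "D"): 11, ("B", "E"): 10,
                ("C", "D"): 9, ("C", "E"): 12, ("D", "E"): 13}
        labels = list("ABCDE")
        D = np.zeros((5, 5))
        for (a, b), v in dist.items():
            i, j = labels.index(a), labels.index(b)
            D[i, j] = D[j, i] = v
        tree = skbio.TreeNode.read([nj_tree(dm_from(D, labels))])
        for a, b in itertools.combinations(labels, 2):
            got = tree.find(a).distance(tree.find(b))
            assert got == pytest.approx(dist[(a, b)], abs=1e-9)

    def test_matches_skbio_on_random_metric(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(7, 4))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = [f"t{i}" for i in range(7)]
        mine = skbio.TreeNode.read([nj_tree(dm_from(D, labels))])
        ref = skbio.tree.nj(skbio.DistanceMatrix(D, labels))
        assert mine.compare_rfd(ref) == 0

    def test_region_structure_clusters_together(self, island_table):
        table, truth = island_table
        d = nei_distance(allele_frequencies(table))
        tree = skbio.TreeNode.read([nj_tree(d)])
        hn = {p for p, r in truth["regions"].items() if r == "HN"}
        # the HN populations form one clade on the unrooted tree:
        # some edge bipartitions the taxa into HN vs the rest
        tips = {t.name for t in tree.tips()}
        found = False
        for node in tree.non_tips(include_self=True):
            clade = {t.name for t in node.tips()}
            if clade == hn or (tips - clade) == hn:
                found = True
                break
        assert found

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            dm_from([[0, 1], [2, 0]])


class TestPCoA:
    def test_two_points(self):
        res = pcoa(dm_from([[0, 4], [4, 0]], ["a", "b"]))
        assert res.coordinates.shape[1] == 1
        np.testing.assert_allclose(np.sort(res.coordinates[:, 0]), [-2, 2],
                                   atol=1e-10)

    def test_euclidean_reconstruction(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(8, 3))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        res = pcoa(dm_from(D))
        rec = np.sqrt(((res.coordinates[:, None]
                        - res.coordinates[None]) ** 2).sum(-1))
        np.testing.assert_allclose(rec, D, atol=1e-8)

    def test_eigenvalue_sum_equals_centered_trace(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(6, 2))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        res = pcoa(dm_from(D))
        a = -0.5 * D**2
        c = np.eye(6) - np.ones((6, 6)) / 6
        g = c @ a @ c
        assert res.eigenvalues.sum() == pytest.approx(np.trace(g), abs=1e-9)

    def test_two_groups_separate_on_axis_one(self, island_table):
        table, truth = island_table
        d = nei_distance(allele_frequencies(table))
        res = pcoa(d)
        axis1 = dict(zip(res.labels, res.coordinates[:, 0]))
        hn = [axis1[p] for p, r in truth["regions"].items() if r == "HN"]
        ic = [axis1[p] for p, r in truth["regions"].items() if r == "IC"]
        # complete separation of the two groups along the leading axis
        assert max(hn) < min(ic) or max(ic) < min(hn)


class TestSquaredGenotypicDistance:
    def test_canonical_values(self):
        genotypes = [(1, 1), (1, 2), (2, 3), (3, 4), (2, 2)]
        expected = {  # Smouse-Peakall codominant distances
            (0, 1): 1, (1, 2): 1, (1, 3): 2, (0, 4): 4, (0, 2): 3,
        }
        t = GenotypeTable(ids=[f"i{k}" for k in range(5)], loci=["L1"],
                          alleles=np.asarray(genotypes)[:, None, :],
                          pops=["P"] * 5)
        d = squared_genotypic_distance(t)
        for (i, j), v in expected.items():
            assert d.values[i, j] == pytest.approx(v)


class TestAMOVA:
    def test_panmictic_pool_mostly_within(self):
        rng = np.random.default_rng(10)
        pct_within = []
        for seed in range(5):
            r = np.random.default_rng(seed)
            # all "populations" drawn from one pool of frequencies
            alleles = r.choice(np.arange(1, 6), size=(30, 3, 2))
            t = GenotypeTable(ids=[f"i{k}" for k in range(30)],
                              loci=["L1", "L2", "L3"], alleles=alleles,
                              pops=["A"] * 10 + ["B"] * 10 + ["C"] * 10)
            res = amova(t, permutations=99, seed=seed)
            pct_within.append(res.percentages["within_populations"])
        assert np.mean(pct_within) > 90

    def test_fixed_disjoint_regions(self):
        alleles = np.zeros((8, 2, 2), dtype=int)
        alleles[:4] = 1
        alleles[4:] = 5
        t = GenotypeTable(ids=[f"i{k}" for k in range(8)], loci=["L1", "L2"],
                          alleles=alleles, pops=["A"] * 2 + ["B"] * 2
                          + ["C"] * 2 + ["D"] * 2,
                          regions={"A": "R1", "B": "R1", "C": "R2", "D": "R2"})
        res = amova(t, permutations=99, seed=1)
        assert res.components["within_populations"] == pytest.approx(0.0)
        assert res.percentages["among_regions"] == pytest.approx(100.0)

    def test_brute_force_moment_equations(self):
        """Components equal the hand-expanded sums-of-squares computation."""
        rng = np.random.default_rng(5)
        t = make_random_table(rng, n_pops=3, n_per_pop=4, n_loci=2,
                              regions={"P1": "R1", "P2": "R1", "P3": "R2"})
        res = amova(t, permutations=99, seed=0)
        d2 = squared_genotypic_distance(t).values
        pops = np.asarray(t.pops)
        regions = np.asarray([t.regions[p] for p in t.pops])
        N = 12

        def ss_within(groups):
            ss = 0.0
            for g in np.unique(groups):
                idx = np.flatnonzero(groups == g)
                for a, b in itertools.combinations(idx, 2):
                    ss += d2[a, b] / len(idx)
            return ss

        ss_tot = sum(d2[a, b] for a, b in itertools.combinations(range(N), 2)) / N
        ss_wp = ss_within(pops)
        ss_wr = ss_within(regions)
        assert res.sums_of_squares["within_populations"] == pytest.approx(ss_wp)
        assert res.sums_of_squares["among_regions"] == pytest.approx(ss_tot - ss_wr)
        # moment equations, expanded for this balanced-within-region design
        a_r, b_p = 2, 3
        df_wp, df_ap, df_ar = N - b_p, b_p - a_r, a_r - 1
        ms_wp = ss_wp / df_wp
        ms_ap = (ss_wr - ss_wp) / df_ap
        ms_ar = (ss_tot - ss_wr) / df_ar
        n_sizes = {"P1": 4, "P2": 4, "P3": 4}
        n_r = {"R1": 8, "R2": 4}
        sum_np2_over_nr = (4**2 + 4**2) / 8 + 4**2 / 4
        n1 = (N - sum_np2_over_nr) / (b_p - a_r)
        n2 = (sum_np2_over_nr - (3 * 4**2) / N) / (a_r - 1)
        n3 = (N - (8**2 + 4**2) / N) / (a_r - 1)
        sig_c = ms_wp
        sig_b = (ms_ap - sig_c) / n1
        sig_a = (ms_ar - sig_c - n2 * sig_b) / n3
        assert res.components["within_populations"] == pytest.approx(sig_c)
        assert res.components["among_populations_within_regions"] == pytest.approx(sig_b)
        assert res.components["among_regions"] == pytest.approx(sig_a)

    def test_percentages_sum_and_p_range(self, island_table):
        table, _ = island_table
        res = amova(table, permutations=99, seed=3)
        assert sum(res.percentages.values()) == pytest.approx(100.0, abs=0.01)
        for p in res.p_values.values():
            assert 0 < p <= 1


class TestMantel:
    def test_perfect_affine_relation(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(6, 2))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        m1 = dm_from(D)
        m2 = dm_from(3.0 * D)  # zero diagonal preserved
        res = mantel(m1, m2, permutations=99, seed=1)
        assert res.r == pytest.approx(1.0)
        assert res.slope == pytest.approx(3.0)

    def test_r_matches_skbio(self):
        rng = np.random.default_rng(7)
        a = rng.random((7, 7))
        b = rng.random((7, 7))
        A = dm_from((a + a.T) / 2 * (1 - np.eye(7)))
        B = dm_from((b + b.T) / 2 * (1 - np.eye(7)))
        mine = mantel(A, B, permutations=99, seed=0)
        r_ref, _, _ = skbio.stats.distance.mantel(
            skbio.DistanceMatrix(A.values, A.labels),
            skbio.DistanceMatrix(B.values, B.labels),
            permutations=0)
        assert mine.r == pytest.approx(r_ref, abs=1e-12)

    def test_affine_invariance_of_r(self):
        rng = np.random.default_rng(8)
        a = rng.random((6, 6))
        b = rng.random((6, 6))
        A = dm_from((a + a.T) / 2 * (1 - np.eye(6)))
        B = dm_from((b + b.T) / 2 * (1 - np.eye(6)))
        r1 = mantel(A, B, permutations=99, seed=5).r
        B2 = dm_from(2.5 * B.values)
        r2 = mantel(A, B2, permutations=99, seed=5).r
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_constant_matrix_rejected(self):
        A = dm_from(np.ones((4, 4)) - np.eye(4))
        B = dm_from(np.arange(16).reshape(4, 4) * 0.0)
        with pytest.raises(ValueError):
            mantel(A, A, permutations=99, seed=0)
        del B


class TestGeographicDistances:
    def test_identical_points_zero(self):
        c = CoordinateSet(labels=["a", "b"], xy=[[10.0, 20.0], [10.0, 20.0]],
                          mode="geodetic")
        assert geographic_distances(c).values[0, 1] == 0.0

    def test_one_degree_latitude(self):
        c = CoordinateSet(labels=["a", "b"], xy=[[0.0, 0.0], [1.0, 0.0]],
                          mode="geodetic")
        assert geographic_distances(c).values[0, 1] == pytest.approx(111.2, abs=0.3)

    def test_antipodal_half_circumference(self):
        c = CoordinateSet(labels=["a", "b"], xy=[[0.0, 0.0], [0.0, 180.0]],
                          mode="geodetic")
        assert geographic_distances(c).values[0, 1] == pytest.approx(20015, abs=1)

    def test_planar_euclidean_metres(self):
        c = CoordinateSet(labels=["a", "b"], xy=[[0.0, 0.0], [3.0, 4.0]],
                          mode="planar")
        d = geographic_distances(c)
        assert d.values[0, 1] == 5.0 and d.metric == "euclidean_m"


class TestEvannoDeltaK:
    def test_linear_likelihood_gives_zero(self):
        lk = {k: [(-10.0 * k) + eps for eps in (0.0, 0.5, -0.5)]
              for k in range(1, 6)}
        out = evanno_delta_k(lk)
        interior = out["delta_K"].dropna()
        np.testing.assert_allclose(interior, 0.0, atol=1e-12)

    def test_kink_at_two_detected(self):
        lk = {1: [-100, -101], 2: [-50, -51], 3: [-45, -46], 4: [-40, -41]}
        out = evanno_delta_k(lk)
        assert out.attrs["best_K"] == 2

    def test_hand_computed_table(self):
        lk = {1: [-20.0, -22.0, -21.0],
              2: [-10.0, -12.0, -14.0],
              3: [-8.0, -9.0, -10.0]}
        out = evanno_delta_k(lk)
        reps = np.abs(np.array([-8.0, -9.0, -10.0])
                      - 2 * np.array([-10.0, -12.0, -14.0])
                      + np.array([-20.0, -22.0, -21.0]))
        expected = reps.mean() / np.std([-10.0, -12.0, -14.0], ddof=1)
        assert out.loc[2, "delta_K"] == pytest.approx(expected)

    def test_zero_sd_flagged_infinite(self):
        lk = {1: [-10, -11], 2: [-5.0, -5.0], 3: [-4, -3]}
        out = evanno_delta_k(lk)
        assert np.isinf(out.loc[2, "delta_K"])
        assert out.attrs["delta_K_infinite"]
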