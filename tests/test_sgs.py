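"""Kinship, distance classes, permutation envelopes, Sp, and curvature."""

import numpy as np
import pytest

from msatpop.core import CoordinateSet, GenotypeTable
from msatpop.sgs import (
    KinshipMatrix,
    default_breaks,
    distance_classes,
    pairwise_kinship,
    permutation_envelope,
    residual_curvature,
    sgs_analysis,
    sp_statistic,
)


def grid_coords(ids, spacing=1.0):
    n = len(ids)
    side = int(np.ceil(np.sqrt(n)))
    xy = np.array([[spacing * (k % side), spacing * (k // side)]
                   for k in range(n)], dtype=float)
    return CoordinateSet(labels=ids, xy=xy, mode="planar")


class TestLoiselleKinship:
    def test_hand_expanded_formula(self):
        """Vectorised estimator equals the formula expanded term by term."""
        alleles = np.array([
            [[1, 2], [5, 5]],
            [[1, 1], [5, 6]],
            [[2, 2], [6, 6]],
            [[1, 2], [5, 6]],
        ])
        t = GenotypeTable(ids=list("abcd"), loci=["L1", "L2"],
                          alleles=alleles, pops=["P"] * 4)
        coords = grid_coords(t.ids)
        km = pairwise_kinship(t, "P", coords)

        # naive re-computation
        def naive(i, j):
            num = den = 0.0
            for locus in range(2):
                calls = alleles[:, locus, :]
                copies = calls.ravel()
                vals, cnt = np.unique(copies, return_counts=True)
                p = cnt / cnt.sum()
                nl = len(copies)
                x = {a: ((calls == a).sum(axis=1) / 2.0) for a in vals}
                for a_idx, a in enumerate(vals):
                    num += (x[a][i] - p[a_idx]) * (x[a][j] - p[a_idx])
                num += np.sum(p * (1 - p)) / (nl - 1)
                den += np.sum(p * (1 - p))
            return num / den

        for i in range(4):
            for j in range(i + 1, 4):
                assert km.kinship[i, j] == pytest.approx(naive(i, j), abs=1e-12)

    def test_identical_genotypes_positive_kinship(self):
        rng = np.random.default_rng(0)
        n = 20
        alleles = rng.choice(np.arange(1, 7), size=(n, 4, 2))
        alleles[1] = alleles[0]  # a clone pair in a large sample
        t = GenotypeTable(ids=[f"i{k}" for k in range(n)],
                          loci=[f"L{j}" for j in range(4)],
                          alleles=alleles, pops=["P"] * n)
        km = pairwise_kinship(t, "P", grid_coords(t.ids))
        assert km.kinship[0, 1] > 0
        assert km.kinship[0, 1] > np.nanmean(km.kinship)

    def test_monomorphic_population_rejected(self):
        alleles = np.ones((4, 2, 2), dtype=int)
        t = GenotypeTable(ids=list("abcd"), loci=["L1", "L2"],
                          alleles=alleles, pops=["P"] * 4)
        with pytest.raises(ValueError, match="monomorphic"):
            pairwise_kinship(t, "P", grid_coords(t.ids))

    def test_geodetic_coordinates_rejected(self):
        alleles = np.array([[[1, 2]], [[1, 1]]])
        t = GenotypeTable(ids=["a", "b"], loci=["L1"], alleles=alleles,
                          pops=["P"] * 2)
        coords = CoordinateSet(labels=["a", "b"],
                               xy=np.array([[10.0, 100.0], [11.0, 101.0]]),
                               mode="geodetic")
        with pytest.raises(ValueError, match="planar"):
            pairwise_kinship(t, "P", coords)


class TestDistanceClasses:
    def _km(self, dists, F=None):
        n = len(dists) + 1
        # star layout: individual 0 at origin, others on the x axis
        D = np.zeros((n, n))
        for k, d in enumerate(dists, start=1):
            D[0, k] = D[k, 0] = d
        for a in range(1, n):
            for b in range(a + 1, n):
                D[a, b] = D[b, a] = abs(dists[a - 1] - dists[b - 1]) + 1e-6
        K = np.full((n, n), 0.0) if F is None else F
        np.fill_diagonal(K, np.nan)
        return KinshipMatrix(ids=[f"i{k}" for k in range(n)], kinship=K,
                             distance=D)

    def test_paper_break_scheme(self):
        breaks = default_breaks(250.0)
        assert list(breaks[:8]) == [5, 10, 15, 20, 30, 40, 50, 100]
        assert breaks[-1] == 250.0

    def test_simple_binning(self):
        F = np.zeros((4, 4))
        D = np.zeros((4, 4))
        pairs = {(0, 1): 3.0, (0, 2): 4.0, (0, 3): 12.0,
                 (1, 2): 70.0, (1, 3): 70.0, (2, 3): 70.0}
        for (a, b), d in pairs.items():
            D[a, b] = D[b, a] = d
        np.fill_diagonal(F, np.nan)
        km = KinshipMatrix(ids=list("abcd"), kinship=F, distance=D)
        classes = distance_classes(km, scheme=[5, 10, 15, 100])
        by_bounds = {(r.low, r.high): r.n_pairs for r in classes.itertuples()}
        assert by_bounds[(0.0, 5.0)] == 2
        assert by_bounds[(10.0, 15.0)] == 1
        assert by_bounds[(15.0, 100.0)] == 3

    def test_balanced_quantiles_equalise_counts(self):
        rng = np.random.default_rng(1)
        n = 15  # 105 pairs
        xy = rng.uniform(0, 100, size=(n, 2))
        D = np.sqrt(((xy[:, None] - xy[None]) ** 2).sum(-1))
        F = rng.normal(0, 0.01, size=(n, n))
        F = (F + F.T) / 2
        np.fill_diagonal(F, np.nan)
        km = KinshipMatrix(ids=[f"i{k}" for k in range(n)], kinship=F,
                           distance=D)
        classes = distance_classes(km, scheme="balanced:5")
        counts = classes["n_pairs"].to_numpy()
        assert counts.sum() == 105
        assert counts.max() - counts.min() <= 2

    def test_class_means_average_to_global_mean(self):
        rng = np.random.default_rng(2)
        n = 12
        xy = rng.uniform(0, 50, size=(n, 2))
        D = np.sqrt(((xy[:, None] - xy[None]) ** 2).sum(-1))
        F = rng.normal(0, 0.05, size=(n, n))
        F = (F + F.T) / 2
        np.fill_diagonal(F, np.nan)
        km = KinshipMatrix(ids=[f"i{k}" for k in range(n)], kinship=F,
                           distance=D)
        classes = distance_classes(km)
        weighted = np.average(classes["mean_F"], weights=classes["n_pairs"])
        iu = np.triu_indices(n, 1)
        assert weighted == pytest.approx(np.nanmean(F[iu]), abs=1e-12)


class TestPermutationEnvelope:
    def test_null_data_mostly_inside_envelope(self, spatial_data):
        table, coords, _ = spatial_data
        km = pairwise_kinship(table, "SP1", coords)
        rng = np.random.default_rng(3)
        # destroy structure by shuffling coordinates once
        perm = rng.permutation(km.n)
        null_km = KinshipMatrix(ids=km.ids, kinship=km.kinship,
                                distance=km.distance[np.ix_(perm, perm)])
        env = permutation_envelope(null_km, n_perm=199, seed=4)
        assert env["significant"].mean() < 0.3

    def test_structured_data_first_class_above_envelope(self, spatial_data):
        table, coords, _ = spatial_data
        km = pairwise_kinship(table, "SP1", coords)
        env = permutation_envelope(km, n_perm=199, seed=5)
        first = env.iloc[0]
        assert first["mean_F"] > first["env_high"]

    def test_envelopes_narrow_with_more_pairs(self, spatial_data):
        table, coords, _ = spatial_data
        km = pairwise_kinship(table, "SP1", coords)
        env = permutation_envelope(km, n_perm=199, seed=6)
        width = env["env_high"] - env["env_low"]
        small = env["n_pairs"] < env["n_pairs"].median()
        assert width[small].mean() > width[~small].mean()


class TestSpStatistic:
    def test_published_worked_examples(self):
        # Sp = -b / (1 - F(d1)) on printed slope and first-class kinship;
        # the inputs are rounded to 3-4 significant digits, so agreement is
        # to one unit in the last printed place
        assert -(-0.0339) / (1 - 0.162) == pytest.approx(0.0404, abs=1e-4)
        assert -(-0.0075) / (1 - 0.025) == pytest.approx(0.0077, abs=1e-4)

    def test_zero_slope_gives_zero_sp(self):
        rng = np.random.default_rng(4)
        n = 16
        xy = rng.uniform(0, 80, size=(n, 2))
        D = np.sqrt(((xy[:, None] - xy[None]) ** 2).sum(-1))
        F = np.full((n, n), 0.02)
        np.fill_diagonal(F, np.nan)
        km = KinshipMatrix(ids=[f"i{k}" for k in range(n)], kinship=F,
                           distance=D)
        out = sp_statistic(km, n_perm=99, seed=0)
        assert out["b"] == pytest.approx(0.0, abs=1e-12)
        assert out["sp"] == pytest.approx(0.0, abs=1e-12)

    def test_sp_identity_holds_exactly(self, spatial_data):
        table, coords, _ = spatial_data
        res = sgs_analysis(table, "SP1", coords, n_perm=99, seed=1)
        assert res.sp == pytest.approx(-res.b / (1 - res.f_d1), abs=1e-12)

    def test_coordinate_rescaling_leaves_slope_and_sp_unchanged(self,
                                                                spatial_data):
        """Doubling all coordinates shifts ln(d) by a constant only."""
        table, coords, _ = spatial_data
        km = pairwise_kinship(table, "SP1", coords)
        out1 = sp_statistic(km, n_perm=99, seed=2)
        km2 = KinshipMatrix(ids=km.ids, kinship=km.kinship,
                            distance=2.0 * km.distance)
        # same class scheme in rescaled units keeps class membership
        breaks1 = distance_classes(km)["high"].to_numpy()
        out2 = sp_statistic(km2, scheme=2.0 * breaks1, n_perm=99, seed=2)
        assert out2["b"] == pytest.approx(out1["b"], abs=1e-12)
        assert out2["f_d1"] == pytest.approx(out1["f_d1"], abs=1e-12)
        assert out2["sp"] == pytest.approx(out1["sp"], abs=1e-12)

    def test_single_distance_rejected(self):
        F = np.full((12, 12), 0.01)
        np.fill_diagonal(F, np.nan)
        D = np.ones((12, 12)) * 5.0
        np.fill_diagonal(D, 0.0)
        km = KinshipMatrix(ids=[f"i{k}" for k in range(12)], kinship=F,
                           distance=D)
        with pytest.raises(ValueError, match="distinct"):
            sp_statistic(km, n_perm=99, seed=0)


class TestResidualCurvature:
    def test_pure_quadratic_residual_closed_form(self):
        """f(d) = 0.1 [ln d]^2 with d1 = e gives k = 2c = 0.2."""
        # craft class means: F(d) = linear part + 0.1 (ln d)^2 so that the
        # residual from the pair regression is exactly the quadratic term
        n = 40
        rng = np.random.default_rng(5)
        # distances chosen so class mean distances hit chosen values incl. e
        targets = np.array([np.e, 10.0, 25.0, 60.0, 140.0])
        ids, xy = [], []
        for c, d in enumerate(targets):
            for k in range(4):
                ids.append(f"c{c}_{k}")
        slope, intercept = -0.01, 0.05
        m = len(ids)
        D = np.zeros((m, m))
        F = np.full((m, m), np.nan)
        # place every pair within one class at exactly the class distance
        # by constructing the pair lists directly
        pair_class = {}
        for a in range(m):
            for b in range(a + 1, m):
                ca, cb = a // 4, b // 4
                d = targets[min(ca, cb)]
                D[a, b] = D[b, a] = d
                val = intercept + slope * np.log(d) + 0.1 * np.log(d) ** 2
                F[a, b] = F[b, a] = val
        km = KinshipMatrix(ids=ids, kinship=F, distance=D)
        out = residual_curvature(km, scheme=targets + 0.5)
        a0, b1, c2, d3 = out["cubic"]
        assert d3 == pytest.approx(0.0, abs=1e-9)
        assert c2 == pytest.approx(0.1, abs=1e-9)
        assert out["d1"] == pytest.approx(np.e)
        assert out["k"] == pytest.approx(0.2, abs=1e-8)
        assert out["verdict"] == "seed_restricted"

    def test_negative_curvature_verdict(self):
        targets = np.array([np.e, 10.0, 25.0, 60.0, 140.0])
        m = 20
        ids = [f"i{k}" for k in range(m)]
        D = np.zeros((m, m))
        F = np.full((m, m), np.nan)
        for a in range(m):
            for b in range(a + 1, m):
                d = targets[min(a // 4, b // 4)]
                D[a, b] = D[b, a] = d
                F[a, b] = F[b, a] = 0.05 - 0.01 * np.log(d) - 0.05 * np.log(d) ** 2
        km = KinshipMatrix(ids=ids, kinship=F, distance=D)
        out = residual_curvature(km, scheme=targets + 0.5)
        assert out["k"] < 0
        assert out["verdict"] == "pollen_restricted_or_neutral"

    def test_too_few_classes_rejected(self):
        m = 8
        ids = [f"i{k}" for k in range(m)]
        D = np.zeros((m, m))
        F = np.full((m, m), np.nan)
        for a in range(m):
            for b in range(a + 1, m):
                d = [3.0, 12.0][min(a // 4, b // 4)]
                D[a, b] = D[b, a] = d
                F[a, b] = F[b, a] = 0.01
        km = KinshipMatrix(ids=ids, kinship=F, distance=D)
        with pytest.raises(ValueError):
            residual_curvature(km, scheme=[5.0, 15.0])


class TestEndToEnd:
    def test_designed_asymmetry_recovered(self, spatial_data):
        """sigma_s = 2 m << sigma_p = 60 m must yield a concave residual."""
        table, coords, truth = spatial_data
        assert truth["sigma_seed"] < truth["sigma_pollen"]
        res = sgs_analysis(table, "SP1", coords, n_perm=99, seed=9)
        assert res.b < 0  # kinship decays with log distance
        assert res.verdict == "seed_restricted"
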