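"""Fingerprint profiles, clade clustering, group-distance comparison, and
covariate correlation mapping."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from varconn import synth
from varconn.profiles import (clade_mean_maps, compare_group_distances,
                              covariate_correlation, covariate_correlation_map,
                              hierarchical_cluster, parcel_profiles,
                              roi_covariate_correlation)


class TestParcelProfiles:
    def test_constant_map(self, small_atlas):
        maps = np.full((2,) + small_atlas.labels.shape, 4.2)
        prof = parcel_profiles(maps, small_atlas.labels, mask=small_atlas.gray_mask)
        assert np.allclose(prof.to_numpy(), 4.2)

    def test_two_parcel_hand_means(self):
        labels = np.zeros((2, 2, 1), int)
        labels[0, :, 0] = 1
        labels[1, :, 0] = 2
        m = np.array([[[1.0], [3.0]], [[10.0], [20.0]]])[None]
        prof = parcel_profiles(m, labels)
        assert prof.loc[0, 1] == pytest.approx(2.0)
        assert prof.loc[0, 2] == pytest.approx(15.0)

    def test_excluded_labels_dropped(self, small_atlas):
        maps = np.zeros((1,) + small_atlas.labels.shape)
        prof = parcel_profiles(maps, small_atlas.labels, excluded_labels=(1, 3))
        assert 1 not in prof.columns and 3 not in prof.columns
        assert 2 in prof.columns

    def test_empty_parcel_warns_and_drops(self, small_atlas):
        maps = np.zeros((1,) + small_atlas.labels.shape)
        mask = small_atlas.labels == 2          # everything else empty
        with pytest.warns(UserWarning, match="empty"):
            prof = parcel_profiles(maps, small_atlas.labels, mask=mask)
        assert list(prof.columns) == [2]


def brute_force_complete_linkage(D):
    """Exhaustive complete-linkage agglomeration; returns merge heights."""
    clusters = [{i} for i in range(len(D))]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = max(D[a][b] for a in clusters[i] for b in clusters[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        heights.append(d)
        clusters[i] = clusters[i] | clusters[j]
        del clusters[j]
    return heights


class TestHierarchicalCluster:
    def test_matches_brute_force_on_4_points(self, rng):
        profiles = rng.standard_normal((4, 6))
        res = hierarchical_cluster(profiles)
        expected = brute_force_complete_linkage(res.dissimilarity)
        assert np.allclose(sorted(res.linkage_matrix[:, 2]), sorted(expected),
                           atol=1e-12)

    def test_duplicate_subject_merges_first_at_zero(self, rng):
        p = rng.standard_normal((5, 8))
        p[3] = p[1]
        res = hierarchical_cluster(p)
        assert res.linkage_matrix[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert {int(res.linkage_matrix[0, 0]), int(res.linkage_matrix[0, 1])} == {1, 3}

    def test_planted_clades_recovered(self, rng):
        from sklearn.metrics import adjusted_rand_score

        templates = rng.standard_normal((3, 10)) * 4
        truth = np.repeat([0, 1, 2], 7)
        profiles = templates[truth] + 0.3 * rng.standard_normal((21, 10))
        res = hierarchical_cluster(profiles)
        assert adjusted_rand_score(truth, res.cut(3)) > 0.9

    def test_monotone_merge_heights(self, rng):
        res = hierarchical_cluster(rng.standard_normal((12, 9)))
        h = res.linkage_matrix[:, 2]
        assert (np.diff(h) >= -1e-12).all()
        assert res.dissimilarity.min() >= 0 and res.dissimilarity.max() <= 2

    def test_input_order_invariance(self, rng):
        from sklearn.metrics import adjusted_rand_score

        p = rng.standard_normal((15, 8))
        res1 = hierarchical_cluster(p)
        order = rng.permutation(15)
        res2 = hierarchical_cluster(p[order])
        c1 = res1.cut(4)[order]
        c2 = res2.cut(4)
        assert adjusted_rand_score(c1, c2) == 1.0

    def test_scaling_and_offset_invariance(self, rng):
        p = rng.standard_normal((6, 10))
        d1 = hierarchical_cluster(p).dissimilarity
        p2 = p.copy()
        p2[2] = p2[2] * 3.0 + 7.0             # Pearson-invariant changes
        d2 = hierarchical_cluster(p2).dissimilarity
        assert np.allclose(d1, d2, atol=1e-12)

    def test_zero_variance_profile_errors(self):
        p = np.vstack([np.ones(5), np.arange(5.0), np.arange(5.0) ** 2])
        with pytest.raises(ValueError, match="zero-variance"):
            hierarchical_cluster(p)


class TestCladeMeans:
    def test_singleton_identity_and_duplicates(self, rng):
        maps = rng.standard_normal((3, 4, 4, 2))
        maps[2] = maps[1]
        out = clade_mean_maps(maps, [0, 1, 1])
        assert np.array_equal(out[0], maps[0])
        assert np.allclose(out[1], maps[1])


class TestGroupDistances:
    def _dmat(self, rng, n, scale=1.0):
        x = rng.standard_normal((n, 8))
        d = 1 - np.corrcoef(x)
        np.fill_diagonal(d, 0.0)
        return (d + d.T) / 2 * scale

    def test_swap_negates_t(self, rng):
        db, ds = self._dmat(rng, 10), self._dmat(rng, 12)
        a = compare_group_distances(db, ds)
        b = compare_group_distances(ds, db)
        assert a["t"] == pytest.approx(-b["t"], abs=1e-12)

    def test_scaled_distances_detected(self, rng):
        base = self._dmat(rng, 20)
        out = compare_group_distances(base * 1.5, self._dmat(rng, 20))
        assert out["t"] > 0 and out["p"] < 0.05
        assert out["naive_nonindependent_pairs"]

    def test_null_calibration(self, rng):
        """Identical distance distributions: primary-scheme p > 0.05 in
        the large majority of null replicates. The per-subject means share
        pairwise entries, so the scheme is mildly anticonservative by
        construction; coverage sits a few points below the nominal 95%."""
        cover = 0
        n_rep = 200
        for _ in range(n_rep):
            out = compare_group_distances(self._dmat(rng, 12), self._dmat(rng, 14))
            cover += out["p"] > 0.05
        assert cover / n_rep >= 0.84

    def test_small_group_errors(self, rng):
        with pytest.raises(ValueError):
            compare_group_distances(np.zeros((2, 2)), self._dmat(rng, 5))


class TestCovariateCorrelation:
    def test_perfect_linear_readout(self, rng):
        cov = rng.uniform(8, 20, 12)
        values = rng.standard_normal((12, 20))
        values[:, 5] = 2.0 * cov - 3.0
        r, p, df = covariate_correlation_map(values, cov)
        assert r[5] == pytest.approx(1.0)
        assert p[5] == pytest.approx(0.0, abs=1e-12)
        assert df == 10

    def test_constant_covariate_errors(self, rng):
        with pytest.raises(ValueError, match="nonconstant"):
            covariate_correlation_map(rng.standard_normal((8, 4)), np.ones(8))

    def test_roi_variant_matches_scipy(self, rng):
        values = rng.standard_normal((15, 10))
        cov = rng.uniform(0, 1, 15)
        r, p = roi_covariate_correlation(values, cov, np.arange(4))
        ref = stats.pearsonr(values[:, :4].mean(1), cov)
        assert r == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    @pytest.mark.parametrize("null", ["gaussian", "permutation"])
    def test_planted_effect_survives_correction(self, null, rng, small_atlas):
        mask = small_atlas.gray_mask
        n = 20
        cov = rng.uniform(8, 20, n)
        values = rng.standard_normal((n, int(mask.sum())))
        target = small_atlas.labels[mask] == 3
        values[:, target] += 0.8 * (cov - cov.mean())[:, None]
        res = covariate_correlation(values, cov, mask, 3.0, voxel_p=0.001,
                                    n_iter=500, rng_seed=0, null=null)
        hit = (res["clusters"] > 0) & (small_atlas.labels == 3)
        assert hit.any()
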