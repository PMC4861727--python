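"""Group inference: t-maps, cluster adjacency, Monte Carlo nulls, partial r."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from voxdc import groupstats
from voxdc.groupstats import (
    alphasim_threshold,
    cluster_report,
    extract_region_z,
    label_clusters,
    neighbor_offsets,
    null_fwe_rate,
    partial_correlation,
    two_sample_t,
)


def bfs_oracle(binary, offsets):
    """Breadth-first connected components, independent of the implementation."""
    from collections import deque

    labels = np.zeros(binary.shape, dtype=int)
    nxt = 0
    for start in map(tuple, np.argwhere(binary)):
        if labels[start]:
            continue
        nxt += 1
        q = deque([start])
        labels[start] = nxt
        while q:
            v = q.popleft()
            for o in offsets:
                w = tuple(np.add(v, o))
                if all(0 <= w[i] < binary.shape[i] for i in range(3)):
                    if binary[w] and not labels[w]:
                        labels[w] = nxt
                        q.append(w)
    return labels


def make_maps(rng, n, shape, effect=None):
    maps = [rng.normal(size=shape) for _ in range(n)]
    if effect is not None:
        maps = [m + effect for m in maps]
    return maps


class TestTwoSampleT:
    def test_identical_groups_give_zero(self, rng):
        m = rng.normal(size=(4, 4, 4))
        mask = np.ones((4, 4, 4), dtype=bool)
        with pytest.warns(UserWarning, match="zero pooled variance"):
            t = two_sample_t([m, m], [m, m], mask)
        assert not t.data.any()

    def test_pooled_t_hand_oracle(self):
        """A=[1,2,3], B=[4,5,6]: pooled t = -3/sqrt(2/3) = -3.6742, df=4."""
        mask = np.ones((1, 1, 1), dtype=bool)
        A = [np.full((1, 1, 1), v) for v in (1.0, 2.0, 3.0)]
        B = [np.full((1, 1, 1), v) for v in (4.0, 5.0, 6.0)]
        t = two_sample_t(A, B, mask)
        assert t.data[0, 0, 0] == pytest.approx(-3.67423461, abs=1e-6)
        assert t.df == 4

    def test_matches_scipy(self, rng):
        mask = np.ones((3, 3, 3), dtype=bool)
        A = make_maps(rng, 8, (3, 3, 3))
        B = make_maps(rng, 6, (3, 3, 3), effect=0.5)
        t = two_sample_t(A, B, mask)
        ref = stats.ttest_ind(np.stack([m[mask] for m in A]),
                              np.stack([m[mask] for m in B]), axis=0)
        np.testing.assert_allclose(t.data[mask], ref.statistic, atol=1e-10)

    def test_swapping_groups_negates(self, rng):
        mask = np.ones((3, 3, 3), dtype=bool)
        A = make_maps(rng, 5, (3, 3, 3))
        B = make_maps(rng, 5, (3, 3, 3), effect=0.3)
        np.testing.assert_allclose(
            two_sample_t(A, B, mask).data, -two_sample_t(B, A, mask).data, atol=1e-12
        )

    def test_single_subject_group_rejected(self, rng):
        mask = np.ones((2, 2, 2), dtype=bool)
        with pytest.raises(ValueError, match="2 subjects"):
            two_sample_t(make_maps(rng, 1, (2, 2, 2)), make_maps(rng, 3, (2, 2, 2)), mask)


class TestNeighborOffsets:
    def test_rmm5_on_3mm_grid_gives_18_connectivity(self):
        offs = neighbor_offsets(5.0, (3.0, 3.0, 3.0))
        assert len(offs) == 18
        dists = np.linalg.norm(offs * 3.0, axis=1)
        assert dists.max() <= 5.0
        # corners at sqrt(27) = 5.196 mm are excluded
        assert not any((np.abs(o) == 1).all() for o in offs)

    def test_rmm3_gives_face_connectivity(self):
        assert len(neighbor_offsets(3.0, (3.0, 3.0, 3.0))) == 6

    def test_rmm52_includes_corners(self):
        assert len(neighbor_offsets(5.2, (3.0, 3.0, 3.0))) == 26

    def test_rmm_below_voxel_size_empty_then_label_errors(self):
        assert len(neighbor_offsets(2.9, (3.0, 3.0, 3.0))) == 0
        with pytest.raises(ValueError, match="no neighbors"):
            label_clusters(np.ones((3, 3, 3), bool), 2.9, (3.0, 3.0, 3.0))


class TestLabelClusters:
    def test_single_voxel_single_cluster(self):
        b = np.zeros((5, 5, 5), dtype=bool)
        b[2, 2, 2] = True
        labels, sizes = label_clusters(b, 5.0, (3, 3, 3))
        assert list(sizes) == [1] and labels[2, 2, 2] == 1

    def test_diagonal_pair_split_by_rmm(self):
        """(1,1,1) offset is 5.196 mm on a 3 mm grid: split at rmm=5, joined at 5.2."""
        b = np.zeros((4, 4, 4), dtype=bool)
        b[1, 1, 1] = b[2, 2, 2] = True
        _, sizes5 = label_clusters(b, 5.0, (3, 3, 3))
        _, sizes52 = label_clusters(b, 5.2, (3, 3, 3))
        assert list(sizes5) == [1, 1]
        assert list(sizes52) == [2]

    def test_empty_input_zero_clusters(self):
        labels, sizes = label_clusters(np.zeros((3, 3, 3), bool), 5.0, (3, 3, 3))
        assert sizes.size == 0 and not labels.any()

    def test_agrees_with_bfs_oracle_on_random_grids(self):
        rng = np.random.default_rng(3)
        offsets = neighbor_offsets(5.0, (3.0, 3.0, 3.0))
        for _ in range(50):
            b = rng.uniform(size=(12, 12, 12)) < 0.25
            labels, sizes = label_clusters(b, 5.0, (3.0, 3.0, 3.0))
            oracle = bfs_oracle(b, offsets)
            assert labels.max() == oracle.max()
            # identical partitions: labels agree up to renaming
            for lab in range(1, labels.max() + 1):
                sel = labels == lab
                assert len(np.unique(oracle[sel])) == 1
            np.testing.assert_array_equal(labels > 0, oracle > 0)

    def test_deterministic_ordering_by_size_then_index(self):
        b = np.zeros((10, 4, 4), dtype=bool)
        b[0:2, 0, 0] = True  # size 2, earliest
        b[5:9, 0, 0] = True  # size 4
        labels, sizes = label_clusters(b, 3.0, (3, 3, 3))
        assert list(sizes) == [4, 2]
        assert labels[5, 0, 0] == 1 and labels[0, 0, 0] == 2


class TestAlphaSim:
    def test_alpha_one_forces_extent_one(self):
        dist = alphasim_threshold(
            (12, 12, 12), (3, 3, 3), 4.0, 0.01, 5.0, 1.0, 20, seed=0
        )
        assert dist.extent_threshold_voxels == 1

    def test_unsmoothed_suprathreshold_count_is_binomial(self):
        """fwhm=0: mean suprathreshold voxels ~ Binomial(n_vox, voxel_p)."""
        shape, p, iters = (16, 16, 16), 0.01, 200
        rng = np.random.default_rng(5)
        zthr = stats.norm.ppf(1 - p)
        counts = []
        for _ in range(iters):
            x = rng.standard_normal(shape, dtype=np.float32)
            x = (x - x.mean()) / x.std()
            counts.append((x >= zthr).sum())
        n_vox = np.prod(shape)
        mean_expected = p * n_vox
        sd = np.sqrt(n_vox * p * (1 - p) / iters)
        assert abs(np.mean(counts) - mean_expected) < 3 * sd

    def test_deterministic_given_seed(self):
        kw = dict(fwhm_mm=4.0, voxel_p=0.05, rmm_mm=5.0, alpha=0.05,
                  n_iterations=30, seed=9)
        a = alphasim_threshold((14, 14, 14), (3, 3, 3), **kw)
        b = alphasim_threshold((14, 14, 14), (3, 3, 3), **kw)
        np.testing.assert_array_equal(a.max_cluster_sizes, b.max_cluster_sizes)

    def test_threshold_monotone_in_alpha(self):
        dist = alphasim_threshold(
            (16, 16, 16), (3, 3, 3), 4.0, 0.01, 5.0, 0.1, 300, seed=2
        )
        thr = [dist.threshold_for_alpha(a) for a in (0.5, 0.1, 0.05, 0.01)]
        assert thr == sorted(thr)

    def test_threshold_monotone_in_voxel_p_and_fwhm(self):
        common = dict(rmm_mm=5.0, alpha=0.05, n_iterations=300)
        loose = alphasim_threshold((16, 16, 16), (3, 3, 3), 4.0, 0.05, seed=4, **common)
        strict = alphasim_threshold((16, 16, 16), (3, 3, 3), 4.0, 0.01, seed=4, **common)
        assert strict.extent_threshold_voxels <= loose.extent_threshold_voxels
        rough = alphasim_threshold((16, 16, 16), (3, 3, 3), 0.0, 0.01, seed=4, **common)
        smooth = alphasim_threshold((16, 16, 16), (3, 3, 3), 6.0, 0.01, seed=4, **common)
        assert smooth.extent_threshold_voxels >= rough.extent_threshold_voxels

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            alphasim_threshold((8, 8, 8), (3, 3, 3), 4.0, 1.5, 5.0, 0.05, 10, 0)
        with pytest.raises(ValueError):
            alphasim_threshold((8, 8, 8), (3, 3, 3), 4.0, 0.01, 5.0, 0.0, 10, 0)

    def test_oversized_kernel_rejected(self):
        with pytest.raises(ValueError, match="kernel"):
            alphasim_threshold((8, 8, 8), (3, 3, 3), 100.0, 0.01, 5.0, 0.05, 10, 0)


class TestClusterReport:
    def _tmap(self, data, df=28):
        t = groupstats.TMap(data=data, df=df, n_a=15, n_b=15)
        return t

    def test_zero_tmap_gives_empty_table(self):
        table = cluster_report(
            self._tmap(np.zeros((6, 6, 6))), 0.01, 5, 5.0, (3, 3, 3), np.eye(4)
        )
        assert table.empty

    def test_synthetic_blob_reported_with_volume(self):
        data = np.zeros((10, 10, 10))
        blob = np.zeros_like(data, dtype=bool)
        blob[3:7, 3:8, 4] = True  # 20 contiguous voxels
        data[blob] = 6.0
        data[5, 5, 4] = 7.5  # peak
        table = cluster_report(self._tmap(data), 0.01, 18, 5.0, (3, 3, 3), np.eye(4))
        assert len(table) == 1
        row = table.iloc[0]
        assert row.extent_voxels == 20
        assert row.volume_mm3 == pytest.approx(540.0)  # 20 x 27 mm^3
        assert row.peak_t == pytest.approx(7.5)
        assert (row.peak_x, row.peak_y, row.peak_z) == (5, 5, 4)

    def test_blob_below_extent_threshold_dropped(self):
        data = np.zeros((10, 10, 10))
        data[3:7, 3:8, 4] = 6.0  # 20 voxels < threshold 21
        table = cluster_report(self._tmap(data), 0.01, 21, 5.0, (3, 3, 3), np.eye(4))
        assert table.empty

    def test_negation_equivariance(self, rng):
        data = rng.normal(size=(12, 12, 12)) * 2.5
        a = cluster_report(self._tmap(data), 0.05, 2, 5.0, (3, 3, 3), np.eye(4))
        b = cluster_report(self._tmap(-data), 0.05, 2, 5.0, (3, 3, 3), np.eye(4))
        assert len(a) == len(b)
        swap = {"+": "-", "-": "+"}
        assert list(b["sign"]) == [swap[s] for s in a["sign"]]
        pd.testing.assert_frame_equal(
            a.drop(columns=["sign", "peak_t"]),
            b.drop(columns=["sign", "peak_t"]),
        )
        np.testing.assert_allclose(a["peak_t"], -b["peak_t"])

    def test_world_coordinates_use_affine(self):
        data = np.zeros((6, 6, 6))
        data[2, 3, 4] = 9.0
        aff = np.diag([3.0, 3.0, 3.0, 1.0])
        aff[:3, 3] = [-7.5, -7.5, -7.5]
        table = cluster_report(self._tmap(data), 0.01, 1, 5.0, (3, 3, 3), aff)
        row = table.iloc[0]
        assert (row.peak_x, row.peak_y, row.peak_z) == (-1.5, 1.5, 4.5)


class TestPartialCorrelation:
    def test_zero_covariates_reduce_to_pearson(self, rng):
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        r, p, n = partial_correlation(x, y, np.zeros((30, 1)))
        ref_r, ref_p = stats.pearsonr(x, y)
        assert r == pytest.approx(ref_r, abs=1e-10)
        assert n == 30

    def test_identity_gives_r_one(self, rng):
        x = rng.normal(size=20)
        cov = rng.normal(size=(20, 2))
        r, p, _ = partial_correlation(x, x.copy(), cov)
        assert r == pytest.approx(1.0, abs=1e-8)

    def test_residual_oracle(self):
        """Explicit OLS residual arithmetic on a 6-point example."""
        x = np.array([1.0, 2, 3, 4, 5, 6])
        y = np.array([2.0, 1, 4, 3, 6, 5])
        c = np.array([1.0, 1, 2, 2, 3, 3])
        X = np.column_stack([np.ones(6), c])
        rx = x - X @ np.linalg.lstsq(X, x, rcond=None)[0]
        ry = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        expected = float(np.dot(rx, ry) / np.linalg.norm(rx) / np.linalg.norm(ry))
        r, p, n = partial_correlation(x, y, c)
        assert r == pytest.approx(expected, abs=1e-12)
        # the within-level residuals are perfectly anticorrelated here
        assert expected == pytest.approx(-1.0, abs=1e-12)
        assert p < 1e-6 and n == 6

    def test_independent_covariates_barely_change_r(self):
        """|partial r - plain r| < 0.05 at n=200 over 100 simulations."""
        rng = np.random.default_rng(11)
        deltas = []
        for _ in range(100):
            x = rng.normal(size=200)
            y = 0.4 * x + rng.normal(size=200)
            cov = rng.normal(size=(200, 2))
            r_partial, _, _ = partial_correlation(x, y, cov)
            r_plain = stats.pearsonr(x, y)[0]
            deltas.append(abs(r_partial - r_plain))
        assert max(deltas) < 0.05

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="n_covariates"):
            partial_correlation(np.arange(4.0), np.arange(4.0), rng.normal(size=(4, 1)))

    def test_constant_residuals_rejected(self):
        x = np.ones(10)
        with pytest.raises(ValueError, match="constant"):
            partial_correlation(x, np.arange(10.0), np.zeros((10, 1)))


class TestExtractRegionZ:
    def test_single_voxel_region(self, rng):
        maps = [rng.normal(size=(4, 4, 4)) for _ in range(3)]
        region = np.zeros((4, 4, 4), dtype=bool)
        region[1, 2, 3] = True
        out = extract_region_z(maps, region)
        np.testing.assert_allclose(out, [m[1, 2, 3] for m in maps])

    def test_uniform_map_gives_constant(self):
        maps = [np.full((3, 3, 3), c) for c in (0.5, -1.0)]
        region = np.ones((3, 3, 3), dtype=bool)
        np.testing.assert_allclose(extract_region_z(maps, region), [0.5, -1.0])

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            extract_region_z([np.zeros((2, 2, 2))], np.zeros((2, 2, 2), bool))


class TestFweControl:
    def test_extent_rule_controls_fwe_on_small_grid(self):
        """Null FWE of the derived rule stays near alpha (binomial CI)."""
        dist = alphasim_threshold(
            (16, 16, 16), (3, 3, 3), 4.0, 0.01, 5.0, 0.05, 500, seed=31
        )
        rate = null_fwe_rate(dist, dist.extent_threshold_voxels, 300, seed=77)
        assert rate <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / 300)
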