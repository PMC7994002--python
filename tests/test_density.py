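"""Heat maps, per-label density stats, DBSCAN label scoring, k-NN distances."""

import numpy as np
import pandas as pd
import pytest

import atlasforge as af
from atlasforge import ClusterParams, LabelVolume
from atlasforge.density import blob_labels, dbscan_min_samples


def brute_force_dbscan(points, eps, min_samples):
    """Direct density-reachability implementation for <= a few hundred points."""
    n = len(points)
    d = np.linalg.norm(points[:, None] - points[None], axis=2)
    neighbors = [np.flatnonzero(d[i] <= eps) for i in range(n)]
    core = [len(neighbors[i]) >= min_samples for i in range(n)]
    labels = np.full(n, -1)
    cid = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        stack = [i]
        labels[i] = cid
        while stack:
            j = stack.pop()
            if not core[j]:
                continue
            for k in neighbors[j]:
                if labels[k] == -1:
                    labels[k] = cid
                    stack.append(k)
        cid += 1
    return labels


class TestHeatmap:
    def test_single_blob_at_origin(self):
        hm = af.nuclei_heatmap(np.array([[0.0, 0, 0, 3]]), 1.0, (4, 4, 4))
        assert hm.counts[0, 0, 0] == 1 and hm.total == 1

    def test_two_blobs_same_voxel(self):
        blobs = np.array([[2.2, 2, 2, 3], [1.8, 2, 2, 3]])
        hm = af.nuclei_heatmap(blobs, 1.0, (4, 4, 4))
        assert hm.counts[2, 2, 2] == 2

    def test_conservation_of_in_bounds_blobs(self, rng):
        blobs = np.column_stack([rng.uniform(0, 15, (300, 3)), np.full(300, 3.0)])
        hm = af.nuclei_heatmap(blobs, 1.0, (16, 16, 16))
        assert hm.total == 300

    def test_out_of_bounds_dropped_and_counted(self):
        blobs = np.array([[20.0, 2, 2, 3], [2.0, 2, 2, 3]])
        hm = af.nuclei_heatmap(blobs, 1.0, (4, 4, 4))
        assert hm.total == 1 and hm.n_out_of_bounds == 1

    def test_scaling_to_downsampled_grid(self):
        blobs = np.array([[10.0, 10, 10, 3]])
        hm = af.nuclei_heatmap(blobs, 0.5, (8, 8, 8))
        assert hm.counts[5, 5, 5] == 1


class TestPerLabelStats:
    def test_uniform_heatmap_arithmetic(self):
        labels = np.zeros((10, 10, 10), np.int32)
        labels[:, :, :] = 0
        labels.ravel()[:1000] = 1
        hm = af.nuclei_heatmap(np.empty((0, 4)), 1.0, (10, 10, 10))
        hm.counts[labels == 1] = 1
        df = af.per_label_stats(hm, LabelVolume(labels, spacing=(20.0, 1.0, 1.0)))
        row = df.iloc[0]
        assert row["count"] == 1000
        assert row["volume_mm3"] == pytest.approx(1000 * 20 * 1e-9)
        assert row["density_cv"] == 0.0
        assert row["density_per_mm3"] == pytest.approx(1000 / (1000 * 20 * 1e-9))

    def test_counts_partition_over_labels(self, rng):
        labels = rng.integers(0, 4, (12, 12, 12)).astype(np.int32)
        blobs = np.column_stack([rng.uniform(0, 11, (200, 3)), np.full(200, 3.0)])
        hm = af.nuclei_heatmap(blobs, 1.0, (12, 12, 12))
        df = af.per_label_stats(hm, LabelVolume(labels))
        assert df["count"].sum() == hm.counts[labels != 0].sum()

    def test_matches_brute_force_masked_sums(self, rng):
        labels = rng.integers(0, 3, (10, 10, 10)).astype(np.int32)
        blobs = np.column_stack([rng.uniform(0, 9, (150, 3)), np.full(150, 3.0)])
        hm = af.nuclei_heatmap(blobs, 1.0, (10, 10, 10))
        df = af.per_label_stats(hm, LabelVolume(labels)).set_index("label_id")
        for lid in (1, 2):
            sel = labels == lid
            assert df.loc[lid, "count"] == hm.counts[sel].sum()
            vals = hm.counts[sel]
            if vals.mean() > 0:
                assert df.loc[lid, "density_cv"] == pytest.approx(vals.std() / vals.mean())


class TestClustering:
    def test_min_samples_rule(self):
        assert dbscan_min_samples(3) == 6
        assert ClusterParams().min_samples == 6
        assert ClusterParams().eps == 20.0

    def test_tight_group_clusters(self):
        labels = np.ones((30, 30, 30), np.int32)
        pts = np.column_stack([np.full(10, 15.0), np.linspace(10, 19, 10), np.full(10, 15.0)])
        blobs = np.column_stack([pts, np.full(10, 3.0)])
        df = af.cluster_label_nuclei(blobs, LabelVolume(labels), params=ClusterParams(eps=20))
        assert df.iloc[0]["n_clusters"] == 1 and df.iloc[0]["n_noise"] == 0

    def test_sparse_points_below_core_threshold_are_noise(self):
        labels = np.ones((100, 100, 100), np.int32)
        pts = np.array([[10, 10, 10], [90, 10, 10], [10, 90, 10], [10, 10, 90], [90, 90, 90]], float)
        blobs = np.column_stack([pts, np.full(5, 3.0)])
        df = af.cluster_label_nuclei(blobs, LabelVolume(labels), params=ClusterParams(eps=20))
        assert df.iloc[0]["n_clusters"] == 0 and df.iloc[0]["n_noise"] == 5

    def test_matches_brute_force_dbscan(self, rng):
        labels = np.ones((64, 64, 64), np.int32)
        pts = rng.uniform(0, 63, (150, 3))
        blobs = np.column_stack([pts, np.full(150, 3.0)])
        params = ClusterParams(eps=8.0, min_samples=6)
        df = af.cluster_label_nuclei(blobs, LabelVolume(labels), params=params)
        oracle = brute_force_dbscan(pts, 8.0, 6)
        assert df.iloc[0]["n_noise"] == int((oracle == -1).sum())
        assert df.iloc[0]["n_clusters"] == len(set(oracle[oracle >= 0]))

    def test_labels_without_nuclei_report_zero(self):
        labels = np.zeros((8, 8, 8), np.int32)
        labels[:4] = 1
        labels[4:] = 2
        blobs = np.array([[1.0, 1, 1, 3]] * 7)
        df = af.cluster_label_nuclei(blobs, LabelVolume(labels)).set_index("label_id")
        assert df.loc[2, "n_nuclei"] == 0
        assert df.loc[2, "n_clusters"] == 0 and df.loc[2, "n_noise"] == 0

    def test_noise_invariant_to_label_permutation(self, rng):
        labels = rng.integers(1, 4, (32, 32, 32)).astype(np.int32)
        blobs = np.column_stack([rng.uniform(0, 31, (120, 3)), np.full(120, 3.0)])
        df1 = af.cluster_label_nuclei(blobs, LabelVolume(labels))
        perm = np.array([0, 3, 1, 2])
        df2 = af.cluster_label_nuclei(blobs, LabelVolume(perm[labels].astype(np.int32)))
        assert df1["n_noise"].sum() == df2["n_noise"].sum()

    def test_boundary_blob_rule_matches_counting(self, rng):
        labels = np.zeros((16, 16, 16), np.int32)
        labels[:8] = 1
        labels[8:] = 2
        blobs = np.column_stack([rng.uniform(0, 15, (50, 3)), np.full(50, 3.0)])
        by_label = blob_labels(blobs, LabelVolume(labels))
        hm = af.nuclei_heatmap(blobs, 1.0, (16, 16, 16))
        df = af.per_label_stats(hm, LabelVolume(labels)).set_index("label_id")
        for lid in (1, 2):
            assert (by_label == lid).sum() == df.loc[lid, "count"]


class TestMisalignmentNoise:
    @staticmethod
    def clumped_blobs(rng, z_range, n_clumps, z_clip, clump_size=8, spread=1.5, shape=64):
        centers = np.column_stack([
            rng.uniform(*z_range, n_clumps),
            rng.uniform(8, shape - 8, n_clumps),
            rng.uniform(8, shape - 8, n_clumps),
        ])
        pts = np.concatenate([
            c + rng.normal(0, spread, (clump_size, 3)) for c in centers
        ])
        pts[:, 0] = np.clip(pts[:, 0], *z_clip)
        return np.column_stack([pts, np.full(len(pts), 3.0)])

    def test_shifted_boundary_increases_noise(self, rng):
        # region 1 (z < 32): dense clumps incl. some near the boundary;
        # region 2: empty. Shifting the label boundary into region 1 splits
        # the near-boundary clumps into sub-core pockets -> more noise.
        shape = 64
        true_labels = np.zeros((shape,) * 3, np.int32)
        true_labels[:32] = 1
        true_labels[32:] = 2
        shifted = np.zeros_like(true_labels)
        shifted[:28] = 1
        shifted[28:] = 2
        blobs = np.concatenate([
            self.clumped_blobs(rng, (6, 20), 10, z_clip=(2, 24)),
            # clumps straddling the shifted boundary but inside region 1
            self.clumped_blobs(rng, (26.5, 27.5), 6, z_clip=(23, 31), spread=1.2),
        ])
        params = ClusterParams(eps=6.0, min_samples=6)
        noise_true = af.cluster_label_nuclei(blobs, LabelVolume(true_labels), params=params)["n_noise"].sum()
        noise_shift = af.cluster_label_nuclei(blobs, LabelVolume(shifted), params=params)["n_noise"].sum()
        assert noise_shift > noise_true


class TestKnn:
    def test_lattice_distances_exact(self):
        g = np.arange(0, 20, 4.0)
        pts = np.array(np.meshgrid(g, g, g, indexing="ij")).reshape(3, -1).T
        # every lattice point has at least 3 face neighbors at distance d
        for k in (1, 2, 3):
            np.testing.assert_allclose(af.knn_elbow_distances(pts, k=k), 4.0)
        # for k = 6 the 27 interior points still sit at exactly d; boundary
        # points fall back to diagonal neighbors at d*sqrt(2)
        d6 = af.knn_elbow_distances(pts, k=6)
        np.testing.assert_allclose(d6[:27], 4.0)
        assert set(np.round(np.unique(d6), 6)) <= {4.0, np.round(4 * np.sqrt(2), 6)}

    def test_sorted_output_and_brute_force(self, rng):
        pts = rng.uniform(0, 30, (60, 3))
        d = af.knn_elbow_distances(pts, k=5, spacing=(2.0, 1.0, 1.0))
        assert (np.diff(d) >= 0).all()
        sp = np.array([2.0, 1.0, 1.0])
        scaled = pts * sp
        pairwise = np.linalg.norm(scaled[:, None] - scaled[None], axis=2)
        kth = np.sort(np.sort(pairwise, axis=1)[:, 5])
        np.testing.assert_allclose(d, kth, rtol=1e-9)

    def test_too_few_points_errors(self):
        with pytest.raises(ValueError):
            af.knn_elbow_distances(np.zeros((4, 3)), k=5)
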