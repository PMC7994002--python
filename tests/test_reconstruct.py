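"""Lateral extension, plane expansion, rotation, mirroring, shears, stripping."""

import numpy as np
import pytest
from scipy import ndimage

import atlasforge as af
from atlasforge import ExtensionParams, LabelVolume, Mask, MirrorParams, Volume
from atlasforge.edges import anatomical_edge_map
from atlasforge.morph import ball_dilation
from atlasforge.reconstruct import mirror_plane_source


def labels_on_planes(n, lo, hi, shape=(16, 16)):
    data = np.zeros((n, *shape), np.int32)
    data[lo:hi, 4:12, 4:12] = 1
    return LabelVolume(data)


class TestFindExtensionStart:
    def test_first_labeled_plane_of_contiguous_run(self):
        assert af.find_extension_start(labels_on_planes(60, 10, 50)) == 10

    def test_override_returned_verbatim(self):
        assert af.find_extension_start(labels_on_planes(60, 10, 50), override=13) == 13

    def test_isolated_plane_skipped(self):
        lv = labels_on_planes(60, 10, 50)
        lv.data[5, 4:12, 4:12] = 2  # discontiguous lateral-most labeled plane
        assert af.find_extension_start(lv) == 10

    def test_no_labels_errors(self):
        with pytest.raises(ValueError):
            af.find_extension_start(LabelVolume(np.zeros((5, 4, 4), np.int32)))


@pytest.fixture(scope="module")
def taper_fixture():
    """Clean atlas with 20% of lateral planes unlabeled, for extension tests."""
    params = af.AtlasFixtureParams(
        shape=(96, 96, 96), n_regions=8, seed=5, jitter=0,
        fragmented_label=False, unlabeled_fraction=0.2,
    )
    return af.make_synthetic_atlas(params)


class TestExtendLabels:
    def test_no_unlabeled_planes_is_identity(self, small_atlas_clean):
        vol, true, _ = small_atlas_clean
        em = anatomical_edge_map(vol, true, af.EdgeMapParams(gaussian_sigma=2))
        start = af.find_extension_start(true)
        out = af.extend_labels_lateral(vol, true, start, em)
        np.testing.assert_array_equal(out.data, true.data)

    def test_identical_planes_fixed_point_without_refit(self):
        # constant histology planes + erosion 0: resize and in-paint are
        # identities, so every extended plane equals the start plane
        plane = np.zeros((32, 32))
        plane[8:24, 8:24] = 100.0
        vol = Volume(np.broadcast_to(plane, (10, 32, 32)).copy())
        labels = np.zeros((10, 32, 32), np.int32)
        lab_plane = np.zeros((32, 32), np.int32)
        lab_plane[8:24, 8:16] = 1
        lab_plane[8:24, 16:24] = 2
        labels[4:] = lab_plane
        lv = LabelVolume(labels)
        em = anatomical_edge_map(vol, lv, af.EdgeMapParams(gaussian_sigma=2))
        out = af.extend_labels_lateral(
            vol, lv, 4, em, ExtensionParams(erosion_base=0, min_object_px=10)
        )
        for p in range(4):
            np.testing.assert_array_equal(out.data[p], lab_plane)

    def test_tapering_fixture_recovers_ground_truth(self, taper_fixture):
        vol, true, deg = taper_fixture
        ep = ExtensionParams(erosion_base=3)
        start = af.find_extension_start(deg, params=ep)
        em = anatomical_edge_map(vol, deg, af.EdgeMapParams(gaussian_sigma=2))
        out = af.extend_labels_lateral(vol, deg, start, em, ep)
        # no label IDs beyond those present at the start plane
        assert set(np.unique(out.data)) <= set(np.unique(deg.data))
        dscs = []
        for p in range(start - 1, -1, -1):
            t, e = true.data[p], out.data[p]
            if not (e != 0).any():
                continue  # plane below the cleaned-foreground size floor
            ids, counts = np.unique(t[t != 0], return_counts=True)
            per = [
                2 * ((t == i) & (e == i)).sum() / ((t == i).sum() + (e == i).sum())
                for i in ids
            ]
            dscs.append(np.average(per, weights=counts))
        assert len(dscs) > 5
        assert np.mean(dscs) >= 0.85
        # the most central label tapers away before the final extended plane
        final = out.data[np.flatnonzero([p.any() for p in out.data])[0]]
        assert 1 not in final

    def test_unlabeled_start_plane_errors(self, taper_fixture):
        vol, _, deg = taper_fixture
        em = Mask(np.zeros(vol.shape, bool))
        with pytest.raises(ValueError):
            af.extend_labels_lateral(vol, deg, 0, em)


class TestExpandCompressedPlanes:
    def _pair(self):
        vol = Volume(np.zeros((4, 32, 32)))
        vol.data[:, 4:28, 4:28] = 100.0
        labels = np.zeros((4, 32, 32), np.int32)
        labels[:, 10:22, 4:28] = 1  # compressed along rows
        return vol, LabelVolume(labels)

    def test_labels_stretched_to_foreground_bbox(self):
        vol, labels = self._pair()
        out = af.expand_compressed_planes(vol, labels, (1, 3), ExtensionParams(min_object_px=10))
        for p in (1, 2):
            rows = np.flatnonzero(out.data[p].any(axis=1))
            assert rows.min() == 4 and rows.max() == 27
        np.testing.assert_array_equal(out.data[0], labels.data[0])

    def test_already_matching_bbox_unchanged(self):
        vol, labels = self._pair()
        labels.data[:, 4:28, 4:28] = 1
        out = af.expand_compressed_planes(vol, labels, (0, 4), ExtensionParams(min_object_px=10))
        np.testing.assert_array_equal(out.data, labels.data)

    def test_small_disconnected_blob_ignored(self):
        vol, labels = self._pair()
        vol.data[1, 30:32, 0:2] = 100.0  # tiny ventral blob, not the largest comp
        out = af.expand_compressed_planes(vol, labels, (1, 2), ExtensionParams(min_object_px=1))
        rows = np.flatnonzero(out.data[1].any(axis=1))
        assert rows.max() == 27  # stretched to the main component only


class TestRotate:
    def test_zero_degrees_is_identity(self, rng):
        vol = Volume(rng.random((8, 8, 8)))
        out = af.rotate_to_midline(vol, [(1, 0.0)])
        np.testing.assert_array_equal(out.data, vol.data)

    def test_right_angle_exact(self):
        data = np.zeros((4, 6, 6))
        data[:, 1, 2] = 7.0
        out = af.rotate_to_midline(Volume(data), [(0, 90.0)])
        # rot90 in the (row, col) plane maps (r, c) -> (n_col - 1 - c, r)
        assert (out.data[:, 3, 1] == 7.0).all()
        assert out.data.sum() == data.sum()

    def test_small_rotation_round_trip_dsc(self):
        labels = np.zeros((8, 40, 40), np.int32)
        labels[:, 12:28, 15:25] = 1
        lv = LabelVolume(labels)
        back = af.rotate_to_midline(af.rotate_to_midline(lv, [(0, 3.0)]), [(0, -3.0)])
        assert af.dice(Mask(labels != 0), Mask(back.data != 0)) >= 0.95
        assert set(np.unique(back.data)) <= {0, 1}


class TestMirror:
    def test_half_mirror_is_full_symmetry(self, rng):
        vol = Volume(rng.random((10, 6, 6)))
        labels = LabelVolume(rng.integers(0, 3, (10, 6, 6)).astype(np.int32))
        mv, ml = af.mirror_across_midline(vol, labels, MirrorParams(mirror_fraction=0.5))
        for i in range(10):
            np.testing.assert_array_equal(mv.data[i], mv.data[9 - i])
            np.testing.assert_array_equal(ml.data[i], ml.data[9 - i])

    def test_labeled_count_doubles(self, rng):
        labels = np.zeros((10, 6, 6), np.int32)
        labels[:5] = rng.integers(0, 3, (5, 6, 6))
        vol = Volume(rng.random((10, 6, 6)))
        _, ml = af.mirror_across_midline(vol, LabelVolume(labels), MirrorParams(mirror_fraction=0.5))
        assert (ml.data != 0).sum() == 2 * (labels != 0).sum()

    def test_documented_index_map_at_48_percent(self, rng):
        n = 100
        vol = Volume(rng.random((n, 4, 4)))
        labels = LabelVolume(rng.integers(0, 5, (n, 4, 4)).astype(np.int32))
        mv, ml = af.mirror_across_midline(vol, labels, MirrorParams(mirror_fraction=0.48))
        m = 48
        for j in range(m, n):
            src = mirror_plane_source(j, m)
            assert src == max(2 * m - 1 - j, 0)
            np.testing.assert_array_equal(mv.data[j], vol.data[src])
        np.testing.assert_array_equal(mv.data[:m], vol.data[:m])

    def test_mirroring_twice_idempotent(self, rng):
        vol = Volume(rng.random((20, 5, 5)))
        labels = LabelVolume(rng.integers(0, 3, (20, 5, 5)).astype(np.int32))
        p = MirrorParams(mirror_fraction=0.4)
        v1, l1 = af.mirror_across_midline(vol, labels, p)
        v2, l2 = af.mirror_across_midline(v1, l1, p)
        np.testing.assert_array_equal(v1.data, v2.data)
        np.testing.assert_array_equal(l1.data, l2.data)

    def test_negate_mirrored_ids(self, rng):
        labels = np.zeros((6, 4, 4), np.int32)
        labels[:3] = 2
        vol = Volume(np.ones((6, 4, 4)))
        _, ml = af.mirror_across_midline(
            vol, LabelVolume(labels), MirrorParams(mirror_fraction=0.5, negate_mirrored_ids=True)
        )
        assert (ml.data[3:] == -2).all()


class TestPiecewiseAffine:
    def _block(self):
        data = np.zeros((12, 12, 12))
        data[2:10, 2:6, 2:10] = np.arange(8 * 4 * 8).reshape(8, 4, 8) + 1.0
        return Volume(data)

    def test_zero_shift_identity(self):
        vol = self._block()
        roi = (slice(0, 12), slice(0, 12), slice(0, 12))
        out = af.piecewise_affine_shear(vol, roi, shear_axis=0, shift_axis=2, max_shift=0)
        np.testing.assert_array_equal(out.data, vol.data)

    def test_attachment_face_fixed(self):
        vol = self._block()
        roi = (slice(0, 12), slice(0, 12), slice(0, 12))
        out = af.piecewise_affine_shear(
            vol, roi, shear_axis=0, shift_axis=2, max_shift=4, attach_axis=1
        )
        np.testing.assert_array_equal(out.data[:, 0, :], vol.data[:, 0, :])

    def test_foreground_conserved_without_clipping(self):
        vol = self._block()
        roi = (slice(0, 12), slice(0, 12), slice(0, 12))
        out = af.piecewise_affine_shear(vol, roi, shear_axis=0, shift_axis=2, max_shift=2)
        assert (out.data > 0).sum() == (vol.data > 0).sum()
        assert out.data.sum() == vol.data.sum()

    def test_excessive_shift_errors(self):
        vol = self._block()
        roi = (slice(0, 12), slice(0, 12), slice(0, 12))
        with pytest.raises(ValueError):
            af.piecewise_affine_shear(vol, roi, shear_axis=0, shift_axis=2, max_shift=12)


class TestStripNonCns:
    def _pair(self):
        vol = Volume(np.full((20, 20, 20), 50.0))
        labels = np.zeros((20, 20, 20), np.int32)
        labels[8:12, 8:12, 8:12] = 1
        return vol, LabelVolume(labels)

    def test_distant_intensity_removed_near_retained(self):
        vol, labels = self._pair()
        sv, sl = af.strip_non_cns(vol, labels, pad=5, dilate=2)
        keep = ball_dilation(sl.data != 0, 2)
        assert (sv.data[~keep] == 0).all()
        assert (sv.data[keep] == 50.0).all()

    def test_crop_box_is_padded_bbox_clamped(self):
        vol, labels = self._pair()
        sv, sl = af.strip_non_cns(vol, labels, pad=5, dilate=2)
        assert sv.shape == (14, 14, 14)  # bbox 8..12 padded by 5, within bounds
        sv2, _ = af.strip_non_cns(vol, labels, pad=50, dilate=2)
        assert sv2.shape == (20, 20, 20)

    def test_empty_labels_error(self):
        vol, _ = self._pair()
        with pytest.raises(ValueError):
            af.strip_non_cns(vol, LabelVolume(np.zeros((20, 20, 20), np.int32)))

    def test_pairing_preserved(self):
        vol, labels = self._pair()
        sv, sl = af.strip_non_cns(vol, labels)
        assert sv.shape == sl.shape
        assert sv.spacing == sl.spacing
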