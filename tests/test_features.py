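"""Volume filter, masked smoothing, intensity statistics, outer regions, morphology."""

import numpy as np
import pytest
from scipy import ndimage, signal

import spheroidquant as sq
from spheroidquant.features import (
    IntensityStats,
    filter_nuclei_by_volume,
    masked_gaussian_smooth,
    nucleus_intensity_stats,
    nucleus_morphology,
    outer_region_mask,
)
from spheroidquant.volumes import LabelVolume, VoxelSpacing

from conftest import truth_by_id

UNIT = VoxelSpacing(1.0, 1.0, 1.0)


def _cuboid_labels():
    """Nuclei of exactly {250, 300, 1500, 3000, 3200} µm³ at 1 µm spacing."""
    sizes = {1: (5, 5, 10), 2: (5, 6, 10), 3: (10, 10, 15), 4: (10, 15, 20), 5: (10, 16, 20)}
    lab = np.zeros((30, 30, 130), dtype=np.int32)
    x0 = 0
    for nid, (a, b, c) in sizes.items():
        lab[:a, :b, x0:x0 + c] = nid
        x0 += c + 5
    return LabelVolume(labels=lab, spacing=UNIT)


class TestVolumeFilter:
    def test_boundary_exactness(self):
        filtered, excluded = filter_nuclei_by_volume(_cuboid_labels(), 300, 3000)
        assert set(np.unique(filtered.labels)) == {0, 2, 3, 4}
        reasons = {e.id: e.reason for e in excluded}
        assert reasons == {1: "small", 5: "large"}
        volumes = {e.id: e.volume_um3 for e in excluded}
        assert volumes == {1: 250.0, 5: 3200.0}

    def test_partition_is_exact(self):
        labels = _cuboid_labels()
        filtered, excluded = filter_nuclei_by_volume(labels, 300, 3000)
        kept = set(np.unique(filtered.labels)) - {0}
        dropped = {e.id for e in excluded}
        assert kept | dropped == set(np.unique(labels.labels)) - {0}
        assert kept & dropped == set()

    def test_all_in_range_is_identity(self):
        labels = _cuboid_labels()
        filtered, excluded = filter_nuclei_by_volume(labels, 1, 1e9)
        assert excluded == []
        np.testing.assert_array_equal(filtered.labels, labels.labels)

    def test_emptied_mask_errors(self):
        lab = np.zeros((10, 10, 10), dtype=np.int32)
        lab[:5, :5, :4] = 1  # 100 µm³
        with pytest.raises(ValueError, match="removed all"):
            filter_nuclei_by_volume(LabelVolume(labels=lab, spacing=UNIT), 300, 3000)

    def test_no_nuclei_errors(self):
        with pytest.raises(ValueError, match="no nuclei"):
            filter_nuclei_by_volume(
                LabelVolume(labels=np.zeros((5, 5, 5), dtype=np.int32), spacing=UNIT)
            )


class TestMaskedGaussianSmooth:
    def test_constant_foreground_fixed_point(self):
        img = np.full((12, 12, 12), 42.0)
        out = masked_gaussian_smooth(img, threshold=10.0, sigma=1.5)
        assert np.max(np.abs(out - 42.0)) < 1e-6 * 42.0

    def test_all_background_maps_to_zero(self):
        img = np.full((10, 10, 10), 3.0)
        out = masked_gaussian_smooth(img, threshold=5.0, sigma=1.0)
        assert np.all(out == 0.0)

    def test_bright_cube_against_bruteforce_convolution(self):
        img = np.zeros((15, 15, 15))
        img[5:10, 5:10, 5:10] = 100.0
        out = masked_gaussian_smooth(img, threshold=10.0, sigma=1.0)
        # independent oracle: dense normalized convolution with an explicit
        # truncated Gaussian kernel (radius 4 sigma, matching the smoother)
        r = 4
        x = np.arange(-r, r + 1)
        g1 = np.exp(-x**2 / 2.0)
        g1 /= g1.sum()
        kern = g1[:, None, None] * g1[None, :, None] * g1[None, None, :]
        fg = (img > 10.0).astype(float)
        num = signal.convolve(img * fg, kern, mode="same", method="direct")
        den = signal.convolve(fg, kern, mode="same", method="direct")
        ok = den > 0
        expect = np.where(ok, num / np.where(ok, den, 1.0), 0.0)
        np.testing.assert_allclose(out, expect, atol=1e-9)
        # interior stays near the cube value, no long-range spill
        assert np.all(out[6:9, 6:9, 6:9] >= 90.0)
        assert np.all(out[6:9, 6:9, 6:9] <= 100.0 + 1e-9)
        far = out.copy()
        far[1:14, 1:14, 1:14] = 0.0
        assert np.all(far <= 1.0)


class TestIntensityStats:
    def test_constant_nucleus(self):
        lab = np.zeros((5, 5, 5), dtype=np.int32)
        lab[1:4, 1:4, 1:4] = 3
        img = np.where(lab == 3, 7.0, 99.0)
        st = nucleus_intensity_stats(img, lab, 3)
        assert (st.mean, st.median, st.max, st.p95, st.sd) == (7, 7, 7, 7, 0)

    def test_percentile_interpolation(self):
        lab = np.zeros((4, 5, 5), dtype=np.int32)
        lab[:, :, :] = 0
        vals = np.arange(1, 101, dtype=np.float64)
        lab.ravel()[:100] = 1
        img = np.zeros(lab.shape)
        img.ravel()[:100] = vals
        st = nucleus_intensity_stats(img, lab, 1)
        assert st.p95 == pytest.approx(95.05)
        assert st.median == pytest.approx(50.5)
        assert st.sd == pytest.approx(np.std(vals, ddof=0))

    def test_invariant_to_relabeling_others(self):
        rng = np.random.default_rng(0)
        lab = np.zeros((8, 8, 8), dtype=np.int32)
        lab[:3, :3, :3] = 1
        lab[5:, 5:, 5:] = 2
        img = rng.random(lab.shape)
        st1 = nucleus_intensity_stats(img, lab, 1)
        lab2 = lab.copy()
        lab2[lab2 == 2] = 17
        assert nucleus_intensity_stats(img, lab2, 1) == st1

    def test_missing_id_errors(self):
        lab = np.ones((3, 3, 3), dtype=np.int32)
        with pytest.raises(ValueError, match="not present"):
            nucleus_intensity_stats(np.zeros_like(lab, dtype=float), lab, 9)

    def test_stats_invariants(self):
        rng = np.random.default_rng(1)
        st = IntensityStats.from_values(rng.random(500) * 100)
        assert st.median <= st.max
        assert st.p95 <= st.max
        assert st.sd >= 0


class TestOuterRegion:
    def test_single_voxel_l1_ball(self):
        lab = np.zeros((11, 11, 11), dtype=np.int32)
        lab[5, 5, 5] = 1
        outer = outer_region_mask(lab, 1, n_dilations=4)
        # brute force: L1 ball of radius 4 in 3D minus the center voxel
        zz, yy, xx = np.indices(lab.shape)
        l1 = np.abs(zz - 5) + np.abs(yy - 5) + np.abs(xx - 5)
        assert outer.sum() == ((l1 <= 4).sum() - 1) == 128
        np.testing.assert_array_equal(outer, (l1 <= 4) & (l1 > 0))

    def test_fully_enclosed_nucleus_empty_outer(self):
        lab = np.zeros((13, 13, 13), dtype=np.int32)
        lab[6, 6, 6] = 1
        shell = np.zeros_like(lab, dtype=bool)
        zz, yy, xx = np.indices(lab.shape)
        l1 = np.abs(zz - 6) + np.abs(yy - 6) + np.abs(xx - 6)
        shell[(l1 >= 1) & (l1 <= 5)] = True
        lab[shell] = 2
        assert outer_region_mask(lab, 1, n_dilations=4).sum() == 0

    def test_never_intersects_any_nucleus(self, train_scene):
        lab = train_scene.labels.labels
        for nid in train_scene.truth["id"].head(5):
            outer = outer_region_mask(lab, int(nid), 4)
            assert not np.any(outer & (lab > 0))


class TestMorphology:
    def test_cube_is_isotropic(self):
        lab = np.zeros((14, 14, 14), dtype=np.int32)
        lab[2:12, 2:12, 2:12] = 1
        vol, centroid, axes, elong = nucleus_morphology(LabelVolume(labels=lab, spacing=UNIT), 1)
        assert vol == 1000.0
        assert elong == pytest.approx(1.0, abs=1e-6)
        assert centroid == pytest.approx((6.5, 6.5, 6.5), abs=0.5)

    def test_ellipsoid_axis_recovery(self):
        zz, yy, xx = np.indices((25, 25, 25), dtype=float)
        q = ((zz - 12) / 10) ** 2 + ((yy - 12) / 4) ** 2 + ((xx - 12) / 4) ** 2
        lab = (q <= 1).astype(np.int32)
        _, _, axes, elong = nucleus_morphology(LabelVolume(labels=lab, spacing=UNIT), 1)
        assert elong == pytest.approx(2.5, rel=0.10)
        assert axes[0] == pytest.approx(20.0, rel=0.10)

    def test_missing_id(self):
        lab = LabelVolume(labels=np.ones((3, 3, 3), dtype=np.int32), spacing=UNIT)
        with pytest.raises(ValueError, match="not present"):
            nucleus_morphology(lab, 4)


class TestBuildCellTable:
    def test_one_record_per_surviving_nucleus(self, clean_scene, clean_records, default_config):
        truth = clean_scene.truth
        vv = clean_scene.labels.spacing.voxel_volume_um3
        counts = dict(zip(*np.unique(clean_scene.labels.labels, return_counts=True)))
        expected = [
            int(i) for i in truth["id"]
            if default_config.volume_min_um3 <= counts[i] * vv <= default_config.volume_max_um3
        ]
        assert [r.id for r in clean_records] == sorted(expected)

    def test_volumes_match_truth_exactly(self, clean_scene, clean_records):
        truth = truth_by_id(clean_scene)
        for r in clean_records:
            assert r.volume_um3 == truth.loc[r.id, "volume_um3"]

    def test_marker_contrast_visible(self, clean_scene, clean_records):
        truth = truth_by_id(clean_scene)
        pos = [r for r in clean_records if truth.loc[r.id, "ki67_pos"]]
        neg = [r for r in clean_records if not truth.loc[r.id, "ki67_pos"]]
        assert pos and neg
        assert min(r.stat("ki67", "raw", "nucleus").mean for r in pos) > max(
            r.stat("ki67", "raw", "nucleus").mean for r in neg
        )

    def test_shape_mismatch_errors(self, clean_scene, default_config):
        small = LabelVolume(labels=np.ones((4, 4, 4), dtype=np.int32), spacing=UNIT)
        with pytest.raises(ValueError, match="shape"):
            sq.build_cell_table(clean_scene.image, small, default_config)
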