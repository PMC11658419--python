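"""Spheroid mask closure, morphometry, distances, equi-volumetric shells."""

import numpy as np
import pytest
from scipy import ndimage, stats

import spheroidquant as sq
from spheroidquant.features import IntensityStats, NucleusRecord
from spheroidquant.morphometry import (
    SpheroidGeometry,
    build_spheroid_mask,
    largest_equivalent_xy_diameter,
    nuclei_density,
    partition_shells,
    shell_statistics,
    void_fraction,
)
from spheroidquant.volumes import LabelVolume, VoxelSpacing

from conftest import digital_ball

UNIT = VoxelSpacing(1.0, 1.0, 1.0)


def _as_labels(mask):
    return LabelVolume(labels=mask.astype(np.int32), spacing=UNIT)


class TestBuildSpheroidMask:
    def test_closure_near_identity_on_ball(self):
        ball = digital_ball(30)
        mask = build_spheroid_mask(_as_labels(ball), n_iter=40)
        change = abs(int(mask.sum()) - int(ball.sum())) / ball.sum()
        assert change < 0.01

    def test_keeps_largest_component_and_connected(self):
        lab = np.zeros((10, 10, 120), dtype=np.int32)
        lab[5, 5, 5] = 1
        lab[5, 5, 110] = 2
        lab[5, 6, 5] = 3  # second voxel makes the left aggregate larger
        mask = build_spheroid_mask(lab, n_iter=3)
        comp, n = ndimage.label(mask, structure=ndimage.generate_binary_structure(3, 1))
        assert n == 1
        assert mask[5, 5, 5] and not mask[5, 5, 110]

    def test_mask_contains_main_aggregate_nuclei(self, train_scene):
        mask = build_spheroid_mask(train_scene.labels, n_iter=40)
        lab = train_scene.labels.labels
        comp, n = ndimage.label(mask, structure=ndimage.generate_binary_structure(3, 1))
        assert n == 1
        assert np.all(mask[lab > 0])

    def test_monotone_in_input(self):
        ball = digital_ball(15)
        mask1 = build_spheroid_mask(_as_labels(ball), n_iter=10)
        ball2 = ball.astype(np.int32)
        c = ball.shape[0] // 2
        ball2[c, c, c] = 2  # extra nucleus inside the existing mask
        mask2 = build_spheroid_mask(ball2, n_iter=10)
        assert np.all(mask2[mask1])

    def test_empty_labels_error(self):
        with pytest.raises(ValueError, match="empty"):
            build_spheroid_mask(np.zeros((5, 5, 5), dtype=np.int32), 4)


class TestVoidAndDensity:
    def test_full_tiling_zero_void(self):
        mask = np.ones((4, 4, 4), dtype=bool)
        assert void_fraction(mask, np.ones((4, 4, 4), dtype=np.int32)) == 0.0

    def test_arithmetic(self):
        mask = np.zeros((20, 20, 20), dtype=bool)
        mask[:10, :20, :20] = True  # 4000 voxels
        lab = np.zeros_like(mask, dtype=np.int32)
        lab[:10, :10, :10] = 1  # 1000 voxels
        assert void_fraction(mask, lab) == 0.75

    def test_bounds_and_translation_invariance(self, train_scene):
        mask = build_spheroid_mask(train_scene.labels, n_iter=40)
        lab = train_scene.labels.labels
        vf = void_fraction(mask, lab)
        assert 0 <= vf < 1
        shifted_mask = np.roll(mask, 3, axis=2)
        shifted_lab = np.roll(lab, 3, axis=2)
        assert void_fraction(shifted_mask, shifted_lab) == vf

    def test_density(self):
        assert nuclei_density(100, 1e6) == 1e-4
        assert nuclei_density(100, 2e6) == 0.5e-4
        assert nuclei_density(0, 1e6) == 0.0
        with pytest.raises(ValueError):
            nuclei_density(1, 0.0)


class TestEquivalentDiameter:
    def test_ball_diameter(self):
        ball = digital_ball(50)
        d = largest_equivalent_xy_diameter(ball, UNIT)
        assert d == pytest.approx(100.0, rel=0.02)

    def test_single_voxel_closed_form(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = True
        assert largest_equivalent_xy_diameter(mask, UNIT) == pytest.approx(2 / np.sqrt(np.pi))

    def test_translation_invariance(self):
        ball = digital_ball(10, margin=6)
        d1 = largest_equivalent_xy_diameter(ball, UNIT)
        d2 = largest_equivalent_xy_diameter(np.roll(ball, 4, axis=1), UNIT)
        assert d1 == d2


class TestDistances:
    def test_center_point(self):
        ball = digital_ball(30)
        geom = SpheroidGeometry(ball, UNIT)
        c = (np.asarray(ball.shape) - 1) / 2
        d_center, d_hull, inside = geom.distances(c)
        assert inside
        assert d_center == pytest.approx(0.0, abs=1e-9)
        assert d_hull == pytest.approx(30.0, abs=1.0)

    def test_sum_property_interior_points(self):
        R = 30
        ball = digital_ball(R)
        geom = SpheroidGeometry(ball, UNIT)
        c = (np.asarray(ball.shape) - 1) / 2
        rng = np.random.default_rng(11)
        checked = 0
        while checked < 100:
            p = rng.uniform(0, ball.shape[0] - 1, 3)
            if not ball[tuple(np.round(p).astype(int))]:
                continue
            d_center, d_hull, inside = geom.distances(p)
            assert inside
            assert abs(d_center + d_hull - R) <= 2.0
            checked += 1

    def test_outside_centroid_flagged(self):
        ball = digital_ball(5, margin=4)
        geom = SpheroidGeometry(ball, UNIT)
        d_center, d_hull, inside = geom.distances((0.0, 0.0, 0.0))
        assert not inside and d_hull == 0.0


def _ball_partition(radius=60):
    ball = digital_ball(radius)
    return ball, partition_shells(ball, UNIT, 3)


class TestShells:
    def test_equal_thirds_on_ball(self):
        _, part = _ball_partition(60)
        for f in part.achieved_fractions:
            assert f == pytest.approx(1 / 3, abs=0.05 / 3)

    def test_exact_tiling_and_disjoint(self):
        ball, part = _ball_partition(30)
        total = np.zeros_like(ball, dtype=int)
        for m in part.masks:
            total += m.astype(int)
        assert np.array_equal(total > 0, ball)
        assert total.max() == 1

    def test_inner_shell_connected_and_nested(self):
        ball, part = _ball_partition(30)
        outer, middle, inner = part.masks
        comp, n = ndimage.label(inner, structure=ndimage.generate_binary_structure(3, 1))
        assert n == 1
        e2 = middle | inner
        assert np.all(e2[inner])
        assert np.all(ball[e2])

    def test_too_small_mask_errors(self):
        tiny = np.zeros((4, 4, 4), dtype=bool)
        tiny[1, 1, 1] = True
        with pytest.raises(ValueError, match="fractions"):
            partition_shells(tiny, UNIT, 3)


def _point_record(rid, z, y, x, volume=500.0):
    return NucleusRecord(
        id=rid, volume_um3=volume, centroid_um=(float(z), float(y), float(x)),
        axis_lengths_um=(10, 5, 4), elongation=1.5, stats={},
    )


class TestShellStatistics:
    def test_uniform_points_split_evenly(self):
        ball, part = _ball_partition(40)
        rng = np.random.default_rng(5)
        records = []
        rid = 0
        while rid < 300:
            p = rng.uniform(0, ball.shape[0] - 1, 3)
            if not ball[tuple(np.round(p).astype(int))]:
                continue
            rid += 1
            records.append(_point_record(rid, *p))
        table = shell_statistics(part, records)
        counts = table["n_nuclei"].to_numpy()
        expected = 300 * np.asarray(part.achieved_fractions)
        chi2 = float(((counts - expected) ** 2 / expected).sum())
        assert chi2 < stats.chi2.ppf(0.99, df=2)

    def test_rim_marker_all_in_outer_shell(self):
        ball, part = _ball_partition(30)
        c = (ball.shape[0] - 1) / 2
        rim = [_point_record(1, c, c, c + 28), _point_record(2, c, c + 28, c)]
        core = [_point_record(3, c, c, c)]
        table = shell_statistics(part, rim + core, marker_flags={"ki67": [True, True, False]})
        pct = dict(zip(table["shell"], table["pct_ki67"]))
        assert pct["outer"] == 100.0 and pct["middle"] == 0.0 and pct["inner"] == 0.0

    def test_marker_percentages_sum_to_100(self, train_scene, train_records, default_config):
        mask = build_spheroid_mask(train_scene.labels, n_iter=40)
        part = partition_shells(mask, train_scene.labels.spacing, 3)
        truth = train_scene.truth.set_index("id")
        flags = {"ki67": [bool(truth.loc[r.id, "ki67_pos"]) for r in train_records]}
        table = shell_statistics(part, train_records, marker_flags=flags)
        assert table["pct_ki67"].sum() == pytest.approx(100.0, abs=1e-9)
        assert (table["n_nuclei"].sum()) == len(train_records)
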