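"""Whole-spheroid morphometry and equi-volumetric shell analysis.

The spheroid mask is a morphological closure of the nuclei foreground
(n dilations then n erosions with the connectivity-1 structuring element),
hole-filled, keeping the largest connected component. Iterated
connectivity-1 dilation/erosion is computed exactly via taxicab (L1)
distance transforms: dilate^k(M) == {d_L1(., M) <= k} and
erode^k(M) == {d_L1(., ~M) > k}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .features import NucleusRecord, STRUCT_6CONN
from .volumes import LabelVolume, VoxelSpacing

__all__ = [
    "SpheroidMetrics",
    "ShellPartition",
    "build_spheroid_mask",
    "void_fraction",
    "nuclei_density",
    "largest_equivalent_xy_diameter",
    "SpheroidGeometry",
    "nucleus_distances",
    "partition_shells",
    "shell_statistics",
    "compute_spheroid_metrics",
]


@dataclass
class SpheroidMetrics:
    volume_um3: float
    void_fraction: float
    density_per_um3: float
    largest_xy_diameter_um: float
    center_um: tuple[float, float, float]
    n_nuclei: int


def _l1_dilate(mask: np.ndarray, n: int) -> np.ndarray:
    dist = ndimage.distance_transform_cdt(~mask, metric="taxicab")
    return dist <= n


def _l1_erode(mask: np.ndarray, n: int) -> np.ndarray:
    dist = ndimage.distance_transform_cdt(mask, metric="taxicab")
    return dist > n


def build_spheroid_mask(labels, n_iter: int = 40) -> np.ndarray:
    """Closure of the nuclei foreground into one solid spheroid mask.

    n_iter dilations followed by n_iter erosions (connectivity 1), holes
    filled, largest connected component kept. The working array is padded by
    n_iter + 1 voxels so dilation never touches the boundary.
    """
    lab = labels.labels if isinstance(labels, LabelVolume) else labels
    fg = lab > 0
    if not fg.any():
        raise ValueError("cannot build a spheroid mask from an empty label volume")
    pad = n_iter + 1
    padded = np.pad(fg, pad)
    closed = _l1_erode(_l1_dilate(padded, n_iter), n_iter)
    filled = ndimage.binary_fill_holes(closed)
    comp, n_comp = ndimage.label(filled, structure=STRUCT_6CONN)
    if n_comp > 1:
        sizes = ndimage.sum_labels(filled, comp, index=np.arange(1, n_comp + 1))
        filled = comp == (int(np.argmax(sizes)) + 1)
    core = tuple(slice(pad, -pad) for _ in range(3))
    return filled[core]


def void_fraction(mask: np.ndarray, labels) -> float:
    """Fraction of the spheroid mask not occupied by segmented nuclei."""
    lab = labels.labels if isinstance(labels, LabelVolume) else labels
    total = int(mask.sum())
    if total == 0:
        raise ValueError("spheroid mask is empty")
    inside = int(((lab > 0) & mask).sum())
    return (total - inside) / total


def nuclei_density(n_nuclei: int, spheroid_volume_um3: float) -> float:
    """Nuclei per µm³ of spheroid volume (an index of cellular compactness)."""
    if spheroid_volume_um3 <= 0:
        raise ValueError(f"spheroid volume must be > 0; got {spheroid_volume_um3}")
    if n_nuclei < 0:
        raise ValueError("nucleus count must be >= 0")
    return n_nuclei / spheroid_volume_um3


def largest_equivalent_xy_diameter(mask: np.ndarray, spacing: VoxelSpacing) -> float:
    """Max over z-planes of the diameter of a circle with the plane's area."""
    if not mask.any():
        raise ValueError("spheroid mask is empty")
    areas = mask.sum(axis=(1, 2)) * spacing.dy * spacing.dx
    return float(2.0 * np.sqrt(areas.max() / np.pi))


class SpheroidGeometry:
    """Precomputed geometry of one spheroid mask for per-nucleus distances.

    Hull distance is the Euclidean distance from a nucleus centroid to the
    nearest voxel of the mask surface (mask voxels adjacent to background),
    read off a distance transform at the centroid's voxel.
    """

    def __init__(self, mask: np.ndarray, spacing: VoxelSpacing):
        if not mask.any():
            raise ValueError("spheroid mask is empty")
        self.mask = mask
        self.spacing = spacing
        samp = spacing.as_tuple()
        self.center_um = tuple(
            float(c) * s for c, s in zip(ndimage.center_of_mass(mask), samp)
        )
        surface = mask & ~ndimage.binary_erosion(mask, structure=STRUCT_6CONN)
        self._dist_to_surface = ndimage.distance_transform_edt(~surface, sampling=samp)

    def distances(self, centroid_um) -> tuple[float, float, bool]:
        """(distance to spheroid center µm, distance to hull µm, inside-mask flag).

        A centroid falling outside the mask reports hull distance 0 and is
        flagged (inside == False).
        """
        centroid_um = np.asarray(centroid_um, dtype=np.float64)
        d_center = float(np.linalg.norm(centroid_um - np.asarray(self.center_um)))
        vox = np.round(centroid_um / np.asarray(self.spacing.as_tuple())).astype(int)
        vox = np.clip(vox, 0, np.asarray(self.mask.shape) - 1)
        inside = bool(self.mask[tuple(vox)])
        d_hull = float(self._dist_to_surface[tuple(vox)]) if inside else 0.0
        return d_center, d_hull, inside


def nucleus_distances(mask: np.ndarray, centroid_um, spacing: VoxelSpacing):
    """Convenience wrapper around :class:`SpheroidGeometry` for one centroid."""
    return SpheroidGeometry(mask, spacing).distances(centroid_um)


@dataclass
class ShellPartition:
    """Concentric equi-volumetric shells of a spheroid mask.

    ``shell_map`` labels voxels 1 = outer, ..., n_shells = inner, 0 = outside.
    ``erosion_depth`` is the taxicab distance to background (the number of
    connectivity-1 erosions a voxel survives).
    """

    masks: list[np.ndarray]  # outer first, inner last
    achieved_fractions: list[float]
    erosion_depths: list[int]  # depth threshold entering each inner boundary
    shell_map: np.ndarray
    erosion_depth: np.ndarray
    spacing: VoxelSpacing

    @property
    def n_shells(self) -> int:
        return len(self.masks)

    def shell_volumes_um3(self) -> list[float]:
        v = self.spacing.voxel_volume_um3
        return [float(m.sum()) * v for m in self.masks]


def partition_shells(mask: np.ndarray, spacing: VoxelSpacing, n_shells: int = 3) -> ShellPartition:
    """Partition a spheroid mask into concentric shells of equal volume.

    Erodes iteratively (connectivity-1) and records the first eroded state
    whose volume is at or below each target fraction (k-1)/k, ..., 1/k of the
    total; set differences of consecutive states are the shells, ordered
    outer -> inner. The stop rule may overshoot by one erosion ring, so the
    achieved fractions are reported.
    """
    if n_shells < 1:
        raise ValueError("n_shells must be >= 1")
    total = int(mask.sum())
    if total == 0:
        raise ValueError("spheroid mask is empty")
    depth = ndimage.distance_transform_cdt(mask, metric="taxicab")
    # volume remaining after k erosions, for every k
    max_depth = int(depth.max())
    counts = np.bincount(depth[mask].ravel(), minlength=max_depth + 1)
    remaining = total - np.cumsum(counts)  # remaining[k] = |depth > k|

    thresholds = []
    for j in range(n_shells - 1, 0, -1):
        target = total * j / n_shells
        ks = np.flatnonzero(remaining <= target)
        thresholds.append(int(ks[0]) if ks.size else max_depth + 1)

    states = [mask] + [depth > k for k in thresholds]
    masks = [states[i] & ~states[i + 1] for i in range(n_shells - 1)] + [states[-1]]
    fractions = [float(m.sum()) / total for m in masks]
    if any(f == 0.0 for f in fractions):
        raise ValueError(
            f"mask too small to partition into {n_shells} non-empty shells; "
            f"achieved fractions {fractions}"
        )
    shell_map = np.zeros(mask.shape, dtype=np.int8)
    for i, m in enumerate(masks):
        shell_map[m] = i + 1
    return ShellPartition(
        masks=masks,
        achieved_fractions=fractions,
        erosion_depths=thresholds,
        shell_map=shell_map,
        erosion_depth=depth,
        spacing=spacing,
    )


def _centroid_voxel(centroid_um, spacing: VoxelSpacing, shape) -> tuple[int, ...]:
    vox = np.round(np.asarray(centroid_um) / np.asarray(spacing.as_tuple())).astype(int)
    return tuple(np.clip(vox, 0, np.asarray(shape) - 1))


def assign_shells(partition: ShellPartition, records: list[NucleusRecord]) -> None:
    """Set shell_index (1 = outer .. n = inner) and erosion depth on each record.

    Membership is by centroid voxel; a centroid falling outside every shell
    is assigned to the outer shell (index 1).
    """
    for r in records:
        vox = _centroid_voxel(r.centroid_um, partition.spacing, partition.shell_map.shape)
        idx = int(partition.shell_map[vox])
        r.shell_index = idx if idx > 0 else 1
        r.erosion_depth = int(partition.erosion_depth[vox])


def shell_statistics(
    partition: ShellPartition,
    records: list[NucleusRecord],
    marker_flags: dict[str, list[bool]] | None = None,
) -> pd.DataFrame:
    """Per-shell nucleus count, density, mean nuclear volume, and marker shares.

    Marker distributions are percentages of the marker-positive cells per
    shell; over all shells they sum to 100 whenever at least one positive
    cell exists.
    """
    assign_shells(partition, records)
    names = {1: "outer", 2: "middle", 3: "inner"}
    volumes = partition.shell_volumes_um3()
    rows = []
    for i in range(1, partition.n_shells + 1):
        members = [r for r in records if r.shell_index == i]
        n = len(members)
        rows.append(
            {
                "shell": names.get(i, f"shell_{i}"),
                "volume_um3": volumes[i - 1],
                "n_nuclei": n,
                "density_per_um3": n / volumes[i - 1],
                "mean_nucleus_volume_um3": (
                    float(np.mean([r.volume_um3 for r in members])) if n else np.nan
                ),
            }
        )
    frame = pd.DataFrame(rows)
    if marker_flags:
        for marker, flags in marker_flags.items():
            if len(flags) != len(records):
                raise ValueError(f"marker {marker!r}: {len(flags)} flags for {len(records)} records")
            per_shell = np.zeros(partition.n_shells)
            for r, f in zip(records, flags):
                if f:
                    per_shell[r.shell_index - 1] += 1
            tot = per_shell.sum()
            frame[f"pct_{marker}"] = 100.0 * per_shell / tot if tot > 0 else 0.0
    return frame


def compute_spheroid_metrics(
    mask: np.ndarray, labels, records: list[NucleusRecord], spacing: VoxelSpacing
) -> SpheroidMetrics:
    geom = SpheroidGeometry(mask, spacing)
    volume = float(mask.sum()) * spacing.voxel_volume_um3
    return SpheroidMetrics(
        volume_um3=volume,
        void_fraction=void_fraction(mask, labels),
        density_per_um3=nuclei_density(len(records), volume),
        largest_xy_diameter_um=largest_equivalent_xy_diameter(mask, spacing),
        center_um=geom.center_um,
        n_nuclei=len(records),
    )
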