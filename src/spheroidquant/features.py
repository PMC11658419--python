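"""Per-nucleus morphology and intensity features.

Implements the volume filter (debris / segmentation-error rejection),
masked Gaussian smoothing by normalized convolution, perinuclear outer
regions via connectivity-1 binary dilation, and moment-based ellipsoid
morphology, and assembles the per-nucleus cell table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from .config import AnalysisConfig
from .volumes import LabelVolume, MultiChannelVolume

__all__ = [
    "IntensityStats",
    "NucleusRecord",
    "VolumeExclusion",
    "filter_nuclei_by_volume",
    "masked_gaussian_smooth",
    "nucleus_intensity_stats",
    "outer_region_mask",
    "nucleus_morphology",
    "build_cell_table",
    "records_to_frame",
]

STRUCT_6CONN = ndimage.generate_binary_structure(3, 1)

_STAT_NAMES = ("mean", "median", "max", "p95", "sd")


@dataclass(frozen=True)
class IntensityStats:
    """Summary statistics of channel intensity over a voxel set.

    ``p95`` uses the linear-interpolated percentile; ``sd`` is the
    population standard deviation (the voxel set is the whole region,
    not a sample from it).
    """

    mean: float
    median: float
    max: float
    p95: float
    sd: float

    @classmethod
    def from_values(cls, values: np.ndarray) -> "IntensityStats":
        values = np.asarray(values, dtype=np.float64)
        if values.size == 0:
            raise ValueError("cannot compute intensity statistics of an empty voxel set")
        return cls(
            mean=float(values.mean()),
            median=float(np.median(values)),
            max=float(values.max()),
            p95=float(np.percentile(values, 95)),
            sd=float(values.std(ddof=0)),
        )

    @classmethod
    def zeros(cls) -> "IntensityStats":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass
class NucleusRecord:
    """One segmented nucleus: morphology, intensity stats, spatial context.

    ``stats[channel][variant][region]`` holds an :class:`IntensityStats`,
    with variant in {"raw", "smooth"} and region in {"nucleus", "outer"}.
    Optional fields stay None until the corresponding analysis stage ran.
    """

    id: int
    volume_um3: float
    centroid_um: tuple[float, float, float]
    axis_lengths_um: tuple[float, float, float]
    elongation: float
    stats: dict[str, dict[str, dict[str, IntensityStats]]] = field(default_factory=dict)
    outer_empty: bool = False
    dist_center_um: float | None = None
    dist_hull_um: float | None = None
    shell_index: int | None = None
    erosion_depth: int | None = None
    ki67_pos: bool | None = None
    lod_pos: bool | None = None
    cell_type: str | None = None

    def stat(self, channel: str, variant: str, region: str) -> IntensityStats:
        try:
            return self.stats[channel][variant][region]
        except KeyError:
            raise KeyError(
                f"nucleus {self.id}: no {variant}/{region} statistics for channel "
                f"{channel!r}; available channels: {sorted(self.stats)}"
            ) from None


@dataclass(frozen=True)
class VolumeExclusion:
    id: int
    volume_um3: float
    reason: str  # "small" or "large"


def filter_nuclei_by_volume(
    labels: LabelVolume, vmin: float = 300.0, vmax: float = 3000.0
) -> tuple[LabelVolume, list[VolumeExclusion]]:
    """Remove nuclei with volume strictly below ``vmin`` or above ``vmax`` µm³.

    Boundary values are retained (exclusion is strict). Volumes are voxel
    count x voxel volume, so the mask should already be isotropic.
    """
    ids, counts = np.unique(labels.labels, return_counts=True)
    fg = ids > 0
    ids, counts = ids[fg], counts[fg]
    if ids.size == 0:
        raise ValueError("label volume contains no nuclei")
    volumes = counts * labels.spacing.voxel_volume_um3
    excluded = []
    drop = []
    for i, v in zip(ids, volumes):
        if v < vmin:
            excluded.append(VolumeExclusion(int(i), float(v), "small"))
            drop.append(i)
        elif v > vmax:
            excluded.append(VolumeExclusion(int(i), float(v), "large"))
            drop.append(i)
    if len(drop) == ids.size:
        raise ValueError(
            f"volume filter [{vmin}, {vmax}] µm³ removed all {ids.size} nuclei"
        )
    if drop:
        out = labels.labels.copy()
        out[np.isin(out, drop)] = 0
        filtered = LabelVolume(labels=out, spacing=labels.spacing)
    else:
        filtered = labels
    return filtered, excluded


def masked_gaussian_smooth(channel: np.ndarray, threshold: float, sigma: float) -> np.ndarray:
    """Gaussian smoothing restricted to foreground by normalized convolution.

    Only voxels above ``threshold`` contribute:
    smooth(I * F) / smooth(F) with F = [I > threshold]. Voxels with no
    foreground support in their neighbourhood map to 0, so a constant
    foreground image is a fixed point and an all-background image maps
    to zero.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0; got {sigma}")
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0; got {threshold}")
    channel = np.asarray(channel, dtype=np.float64)
    fg = channel > threshold
    num = ndimage.gaussian_filter(np.where(fg, channel, 0.0), sigma)
    den = ndimage.gaussian_filter(fg.astype(np.float64), sigma)
    out = np.zeros_like(channel)
    support = den > 0
    out[support] = num[support] / den[support]
    return out


def nucleus_intensity_stats(channel: np.ndarray, labels, nucleus_id: int) -> IntensityStats:
    """Intensity statistics over exactly the voxels of one nucleus."""
    lab = labels.labels if isinstance(labels, LabelVolume) else labels
    mask = lab == nucleus_id
    if not mask.any():
        raise ValueError(f"nucleus id {nucleus_id} not present in label volume")
    return IntensityStats.from_values(np.asarray(channel)[mask])


def outer_region_mask(labels, nucleus_id: int, n_dilations: int = 4) -> np.ndarray:
    """Perinuclear region: n connectivity-1 dilations of the nucleus mask,
    minus the nucleus itself and every voxel of any other nucleus.

    May be empty in extreme crowding.
    """
    lab = labels.labels if isinstance(labels, LabelVolume) else labels
    nucleus = lab == nucleus_id
    if not nucleus.any():
        raise ValueError(f"nucleus id {nucleus_id} not present in label volume")
    dilated = ndimage.binary_dilation(nucleus, structure=STRUCT_6CONN, iterations=n_dilations)
    return dilated & (lab == 0)


def _moment_axes(coords: np.ndarray, spacing_um: float) -> tuple[np.ndarray, float]:
    """Ellipsoid-equivalent full axis lengths (µm) from voxel-coordinate
    covariance eigenvalues (a solid ellipsoid with semi-axis a has variance
    a²/5 along that axis), plus major/minor elongation."""
    center = coords.mean(axis=0)
    d = coords - center
    cov = d.T @ d / coords.shape[0]
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
    eig = np.clip(eig, 0.0, None)
    semi = np.sqrt(5.0 * eig) * spacing_um
    lengths = 2.0 * semi
    if lengths[2] > 0:
        elong = float(lengths[0] / lengths[2])
    else:
        elong = 1.0 if lengths[0] == 0 else float("inf")
    return lengths, elong


def nucleus_morphology(labels, nucleus_id: int) -> tuple[float, tuple, tuple, float]:
    """Volume (µm³), centroid (z,y,x µm), full axis lengths (µm), elongation."""
    if not isinstance(labels, LabelVolume):
        raise TypeError("nucleus_morphology requires a LabelVolume (needs spacing)")
    if not labels.spacing.is_isotropic:
        raise ValueError("nucleus_morphology requires isotropic spacing; rescale first")
    coords = np.argwhere(labels.labels == nucleus_id)
    if coords.size == 0:
        raise ValueError(f"nucleus id {nucleus_id} not present in label volume")
    s = labels.spacing.dx
    volume = coords.shape[0] * labels.spacing.voxel_volume_um3
    centroid = tuple(float(c) * s for c in coords.mean(axis=0))
    lengths, elong = _moment_axes(coords.astype(np.float64), s)
    return float(volume), centroid, tuple(float(v) for v in lengths), elong


def _resolve_thresholds(volume: MultiChannelVolume, config: AnalysisConfig) -> dict[str, float]:
    thr = {}
    for name, arr in volume.channels.items():
        if name in config.fg_threshold:
            thr[name] = float(config.fg_threshold[name])
        else:
            lo, hi = float(arr.min()), float(arr.max())
            thr[name] = lo if hi <= lo else float(threshold_otsu(arr))
    return thr


def build_cell_table(
    volume: MultiChannelVolume, labels: LabelVolume, config: AnalysisConfig
) -> tuple[list[NucleusRecord], list[VolumeExclusion]]:
    """Extract one :class:`NucleusRecord` per surviving nucleus.

    Applies the volume filter, smooths every channel with masked Gaussian
    smoothing (per-channel foreground threshold: config override or Otsu),
    and computes raw + smoothed intensity statistics over each nucleus and
    its outer region. Records are ordered by id.
    """
    if volume.shape != labels.shape:
        raise ValueError(f"image shape {volume.shape} != label shape {labels.shape}")
    if not labels.spacing.is_isotropic:
        raise ValueError("inputs must be isotropic; run rescale_to_isotropic first")

    filtered, excluded = filter_nuclei_by_volume(
        labels, config.volume_min_um3, config.volume_max_um3
    )
    lab = filtered.labels
    thresholds = _resolve_thresholds(volume, config)
    smoothed = {
        name: masked_gaussian_smooth(arr, thresholds[name], config.smooth_sigma)
        for name, arr in volume.channels.items()
    }

    pad = config.outer_dilations
    objects = ndimage.find_objects(lab)
    records: list[NucleusRecord] = []
    for idx, sl in enumerate(objects):
        if sl is None:
            continue
        nid = idx + 1
        grown = tuple(
            slice(max(s.start - pad, 0), min(s.stop + pad, dim))
            for s, dim in zip(sl, lab.shape)
        )
        crop = lab[grown]
        nucleus = crop == nid
        if not nucleus.any():
            continue
        dilated = ndimage.binary_dilation(nucleus, structure=STRUCT_6CONN, iterations=pad)
        outer = dilated & (crop == 0)

        coords = np.argwhere(nucleus).astype(np.float64)
        s = labels.spacing.dx
        vol_um3 = coords.shape[0] * labels.spacing.voxel_volume_um3
        offset = np.array([g.start for g in grown], dtype=np.float64)
        centroid = tuple(float(v) * s for v in coords.mean(axis=0) + offset)
        lengths, elong = _moment_axes(coords, s)

        outer_empty = not outer.any()
        stats: dict[str, dict[str, dict[str, IntensityStats]]] = {}
        for name in volume.channels:
            stats[name] = {}
            for variant, img in (("raw", volume.channels[name]), ("smooth", smoothed[name])):
                sub = img[grown]
                nuc_stats = IntensityStats.from_values(sub[nucleus])
                out_stats = IntensityStats.zeros() if outer_empty else IntensityStats.from_values(sub[outer])
                stats[name][variant] = {"nucleus": nuc_stats, "outer": out_stats}

        records.append(
            NucleusRecord(
                id=nid,
                volume_um3=float(vol_um3),
                centroid_um=centroid,
                axis_lengths_um=tuple(float(v) for v in lengths),
                elongation=elong,
                stats=stats,
                outer_empty=outer_empty,
            )
        )
    records.sort(key=lambda r: r.id)
    return records, excluded


_CORE_COLUMNS = [
    "id",
    "volume_um3",
    "centroid_z_um",
    "centroid_y_um",
    "centroid_x_um",
    "axis_major_um",
    "axis_mid_um",
    "axis_minor_um",
    "elongation",
    "dist_center_um",
    "dist_hull_um",
    "shell_index",
    "erosion_depth",
    "ki67_pos",
    "lod_pos",
    "cell_type",
    "outer_empty",
]


def records_to_frame(records: list[NucleusRecord]) -> pd.DataFrame:
    """Flatten records into a table with a frozen, documented column order:
    the core columns, then ``{channel}_{raw|smooth}_{nucleus|outer}_{stat}``
    sorted by channel name. Unset optional fields become missing values."""
    rows = []
    for r in records:
        row = {
            "id": r.id,
            "volume_um3": r.volume_um3,
            "centroid_z_um": r.centroid_um[0],
            "centroid_y_um": r.centroid_um[1],
            "centroid_x_um": r.centroid_um[2],
            "axis_major_um": r.axis_lengths_um[0],
            "axis_mid_um": r.axis_lengths_um[1],
            "axis_minor_um": r.axis_lengths_um[2],
            "elongation": r.elongation,
            "dist_center_um": r.dist_center_um,
            "dist_hull_um": r.dist_hull_um,
            "shell_index": r.shell_index,
            "erosion_depth": r.erosion_depth,
            "ki67_pos": r.ki67_pos,
            "lod_pos": r.lod_pos,
            "cell_type": r.cell_type,
            "outer_empty": r.outer_empty,
        }
        for ch in sorted(r.stats):
            for variant in ("raw", "smooth"):
                for region in ("nucleus", "outer"):
                    st = r.stats[ch][variant][region]
                    for stat in _STAT_NAMES:
                        row[f"{ch}_{variant}_{region}_{stat}"] = getattr(st, stat)
        rows.append(row)
    frame = pd.DataFrame(rows)
    stat_cols = [c for c in frame.columns if c not in _CORE_COLUMNS]
    return frame[_CORE_COLUMNS + stat_cols]
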