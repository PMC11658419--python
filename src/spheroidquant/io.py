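"""TIFF and table I/O.

TIFF conventions: single-channel stacks are 3D (z, y, x); multi-channel
stacks are 4D with the channel axis first, (c, z, y, x). Files written by
:func:`save_volume` carry ImageJ-style spacing metadata (z spacing + lateral
resolution); on reading, an explicit spacing override always wins over file
metadata because microscope TIFF metadata is frequently unreliable.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .volumes import LabelVolume, MultiChannelVolume, VoxelSpacing

__all__ = [
    "load_volume",
    "load_label_volume",
    "save_volume",
    "save_label_volume",
    "write_cell_table",
    "read_cell_table",
]


def _spacing_from_tiff(tif: tifffile.TiffFile) -> VoxelSpacing | None:
    try:
        ij = tif.imagej_metadata or {}
        dz = float(ij["spacing"])
        page = tif.pages[0]
        xres = page.tags["XResolution"].value
        yres = page.tags["YResolution"].value
        dx = xres[1] / xres[0]
        dy = yres[1] / yres[0]
        return VoxelSpacing(dz=dz, dy=float(dy), dx=float(dx))
    except (KeyError, TypeError, ZeroDivisionError):
        return None


def _resolve_spacing(path: Path, tif: tifffile.TiffFile, spacing) -> VoxelSpacing:
    if spacing is not None:
        if isinstance(spacing, VoxelSpacing):
            return spacing
        return VoxelSpacing(*[float(v) for v in spacing])
    meta = _spacing_from_tiff(tif)
    if meta is None:
        raise ValueError(
            f"{path}: no usable spacing metadata in TIFF and no override given; "
            "pass spacing=(dz, dy, dx) in µm"
        )
    return meta


def load_volume(path, channel_map: dict[str, int], spacing=None) -> MultiChannelVolume:
    """Read a multi-channel TIFF stack into named channels.

    ``channel_map`` maps channel name -> index along the channel axis.
    ``spacing`` (dz, dy, dx in µm, or a VoxelSpacing) overrides file metadata.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        arr = series.asarray()
        axes = series.axes
        sp = _resolve_spacing(path, tif, spacing)
    if arr.ndim == 3:
        arr = arr[np.newaxis]
    elif arr.ndim == 4:
        # honour the declared channel axis if the file names one
        if "C" in axes:
            arr = np.moveaxis(arr, axes.index("C"), 0)
    else:
        raise ValueError(f"{path}: expected a 3D or 4D multi-channel stack, got shape {arr.shape}")
    n_channels = arr.shape[0]
    channels = {}
    for name, idx in channel_map.items():
        if not 0 <= idx < n_channels:
            raise ValueError(
                f"{path}: channel {name!r} requests index {idx} but the file has "
                f"{n_channels} channel(s)"
            )
        channels[name] = np.asarray(arr[idx], dtype=np.float64)
    return MultiChannelVolume(channels=channels, spacing=sp, metadata={"source": str(path)})


def load_label_volume(path, spacing=None) -> LabelVolume:
    """Read a 3D instance label mask (integer TIFF, 0 = background)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"label file not found: {path}")
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        sp = _resolve_spacing(path, tif, spacing)
    if arr.ndim != 3:
        raise ValueError(f"{path}: label mask must be 3D (z,y,x), got shape {arr.shape}")
    if np.issubdtype(arr.dtype, np.floating):
        raise ValueError(f"{path}: label mask has floating-point dtype {arr.dtype}; ids must be integers")
    if arr.min() < 0:
        raise ValueError(f"{path}: label mask contains negative values")
    return LabelVolume(labels=arr.astype(np.int32, copy=False), spacing=sp)


def _imagej_kwargs(spacing: VoxelSpacing) -> dict:
    return dict(
        imagej=True,
        resolution=(1.0 / spacing.dx, 1.0 / spacing.dy),
        metadata={"spacing": spacing.dz, "unit": "um", "axes": None},
    )


def save_volume(vol: MultiChannelVolume, path, channel_order: list[str] | None = None) -> list[str]:
    """Write channels as an ImageJ hyperstack (z, c, y, x) float32 TIFF;
    returns the channel order used."""
    order = channel_order or sorted(vol.channels)
    stack = np.stack([vol.channels[name] for name in order], axis=1).astype(np.float32)
    kw = _imagej_kwargs(vol.spacing)
    kw["metadata"]["axes"] = "ZCYX"
    tifffile.imwrite(path, stack, **kw)
    return order


def save_label_volume(labels: LabelVolume, path) -> None:
    """Write an instance mask as an ImageJ TIFF (uint16 when the ids fit,
    which ImageJ requires; plain uint32 TIFF otherwise)."""
    max_id = int(labels.labels.max()) if labels.labels.size else 0
    if max_id <= np.iinfo(np.uint16).max:
        kw = _imagej_kwargs(labels.spacing)
        kw["metadata"]["axes"] = "ZYX"
        tifffile.imwrite(path, labels.labels.astype(np.uint16), **kw)
    else:
        tifffile.imwrite(
            path, labels.labels.astype(np.uint32),
            resolution=(1.0 / labels.spacing.dx, 1.0 / labels.spacing.dy),
        )


def write_cell_table(records, path) -> None:
    """Write one CSV row per nucleus (RFC 4180, UTF-8, '.' decimal).

    Column order is frozen by :func:`spheroidquant.features.records_to_frame`.
    Unset optional fields (e.g. shell index before shell analysis) are written
    as empty cells, never as 0.
    """
    from .features import records_to_frame

    if not records:
        raise ValueError("cannot write an empty cell table")
    frame = records_to_frame(records)
    frame.to_csv(path, index=False)


def read_cell_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
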