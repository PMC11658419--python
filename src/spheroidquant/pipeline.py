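"""End-to-end orchestration: image + instance mask -> cell table, spheroid
morphometry, shell table.

Stages: isotropic rescaling, nuclear volume filtering, per-nucleus feature
extraction, spheroid mask closure and morphometry, per-nucleus distances,
equi-volumetric shell partitioning and statistics, optional marker gating
with pre-trained models, and the aggregate Cleaved Caspase-3 index. All
randomness is controlled by the config seed; outputs contain no timestamps,
so identical inputs + config reproduce identical bytes.
"""

from __future__ import annotations

import json
import logging
from contextlib import contextmanager
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd

from .config import AnalysisConfig
from .features import build_cell_table, filter_nuclei_by_volume, _resolve_thresholds
from .io import load_label_volume, load_volume, write_cell_table
from .markers import MarkerModel, cas3_index, predict_marker
from .morphometry import (
    ShellPartition,
    SpheroidGeometry,
    SpheroidMetrics,
    build_spheroid_mask,
    compute_spheroid_metrics,
    partition_shells,
    shell_statistics,
)
from .volumes import LabelVolume, MultiChannelVolume, rescale_to_isotropic

logger = logging.getLogger("spheroidquant")

__all__ = ["PipelineError", "PipelineResult", "run_pipeline"]


class PipelineError(RuntimeError):
    pass


@contextmanager
def _stage(name: str):
    logger.info("stage %s: start", name)
    try:
        yield
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc
    logger.info("stage %s: done", name)


@dataclass
class PipelineResult:
    records: list
    excluded: list
    spheroid: SpheroidMetrics
    shells: ShellPartition
    shell_table: pd.DataFrame
    cas3_index_au_per_cell: float | None
    gate_fractions: dict[str, float]
    out_dir: Path | None = None


def run_pipeline(
    config: AnalysisConfig,
    image_path=None,
    labels_path=None,
    out_dir=None,
    volume: MultiChannelVolume | None = None,
    labels: LabelVolume | None = None,
    marker_models: dict[str, MarkerModel] | None = None,
) -> PipelineResult:
    """Run the full quantification on one spheroid.

    Inputs are either file paths (multi-channel TIFF + integer label TIFF)
    or in-memory objects. ``marker_models`` optionally maps "ki67"/"lod" to
    trained gates; without them the marker flags stay unset. When ``out_dir``
    is given, cells.csv, shells.csv, exclusions.csv and spheroid.json are
    written there.
    """
    config.validate()
    marker_models = marker_models or {}

    with _stage("load"):
        if volume is None:
            if image_path is None:
                raise ValueError("either image_path or volume is required")
            volume = load_volume(image_path, config.channel_map, spacing=config.spacing_um)
        if labels is None:
            if labels_path is None:
                raise ValueError("either labels_path or labels is required")
            labels = load_label_volume(labels_path, spacing=config.spacing_um)
        if volume.shape != labels.shape:
            raise ValueError(f"image shape {volume.shape} != labels shape {labels.shape}")

    with _stage("rescale_isotropic"):
        volume = rescale_to_isotropic(volume)
        labels = rescale_to_isotropic(labels)

    with _stage("volume_filter"):
        filtered, excluded = filter_nuclei_by_volume(
            labels, config.volume_min_um3, config.volume_max_um3
        )
        logger.info(
            "volume filter: kept %d nuclei, excluded %d", filtered.n_instances, len(excluded)
        )

    with _stage("cell_table"):
        records, _ = build_cell_table(volume, filtered, config)

    with _stage("spheroid_mask"):
        mask = build_spheroid_mask(filtered, n_iter=config.closing_iterations)
        spheroid = compute_spheroid_metrics(mask, filtered, records, labels.spacing)

    with _stage("distances"):
        geom = SpheroidGeometry(mask, labels.spacing)
        for r in records:
            d_center, d_hull, inside = geom.distances(r.centroid_um)
            r.dist_center_um = d_center
            r.dist_hull_um = d_hull
            if not inside:
                logger.warning("nucleus %d centroid outside spheroid mask", r.id)

    gate_fractions: dict[str, float] = {}
    with _stage("marker_gates"):
        for marker, model in marker_models.items():
            result = predict_marker(model, records)
            gate_fractions[marker] = result.fraction
            attr = f"{marker}_pos"
            for r, flag in zip(records, result.flags):
                if hasattr(r, attr):
                    setattr(r, attr, flag)
            logger.info("gate %s: %d/%d positive", marker, result.positive_count, result.total)

    with _stage("shells"):
        shells = partition_shells(mask, labels.spacing, n_shells=config.n_shells)
        marker_flags = {}
        if all(r.ki67_pos is not None for r in records):
            marker_flags["ki67"] = [bool(r.ki67_pos) for r in records]
        if all(r.lod_pos is not None for r in records):
            marker_flags["lod"] = [bool(r.lod_pos) for r in records]
        shell_table = shell_statistics(shells, records, marker_flags or None)

    cas3 = None
    with _stage("cas3_index"):
        if config.cas3_channel in volume.channels:
            thr = _resolve_thresholds(volume, config)[config.cas3_channel]
            cas3 = cas3_index(volume.channel(config.cas3_channel), thr, len(records))

    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        with _stage("write_outputs"):
            out.mkdir(parents=True, exist_ok=True)
            write_cell_table(records, out / "cells.csv")
            shell_table.to_csv(out / "shells.csv", index=False)
            pd.DataFrame([asdict(e) for e in excluded]).to_csv(
                out / "exclusions.csv", index=False
            )
            summary = {
                "n_nuclei": spheroid.n_nuclei,
                "n_excluded": len(excluded),
                "spheroid_volume_um3": spheroid.volume_um3,
                "void_fraction": spheroid.void_fraction,
                "density_per_um3": spheroid.density_per_um3,
                "largest_xy_diameter_um": spheroid.largest_xy_diameter_um,
                "center_um": list(spheroid.center_um),
                "shell_fractions": shells.achieved_fractions,
                "cas3_index_au_per_cell": cas3,
                "gate_fractions": gate_fractions,
            }
            (out / "spheroid.json").write_text(json.dumps(summary, indent=2, sort_keys=True))

    return PipelineResult(
        records=records,
        excluded=excluded,
        spheroid=spheroid,
        shells=shells,
        shell_table=shell_table,
        cas3_index_au_per_cell=cas3,
        gate_fractions=gate_fractions,
        out_dir=out,
    )
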