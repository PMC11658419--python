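"""Analysis configuration: channel mapping, thresholds, morphology iteration counts."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    """Settings for the quantification pipeline.

    Volume bounds are in µm³ (defaults: nuclei below 300 or above 3000 µm³
    are treated as debris / segmentation errors). ``outer_dilations`` is the
    number of connectivity-1 binary dilations defining the perinuclear outer
    region; ``closing_iterations`` the dilation/erosion count for the
    whole-spheroid mask. ``smooth_sigma`` (voxels) drives the masked Gaussian
    smoothing of every intensity channel.
    """

    # channel-name -> index map used when loading multi-channel TIFFs
    channel_map: dict[str, int] = field(
        default_factory=lambda: {"nuclei": 0, "ki67": 1, "cas3": 2, "lod": 3, "collagen1": 4}
    )
    # canonical channel roles (names into channel_map / MultiChannelVolume)
    nuclei_channel: str = "nuclei"
    ki67_channel: str = "ki67"
    cas3_channel: str = "cas3"
    lod_channel: str = "lod"
    collagen_channel: str = "collagen1"
    celltracker_channel: str = "celltracker"

    volume_min_um3: float = 300.0
    volume_max_um3: float = 3000.0
    # per-channel foreground thresholds; channels absent here fall back to Otsu
    fg_threshold: dict[str, float] = field(default_factory=dict)
    smooth_sigma: float = 1.0
    outer_dilations: int = 4
    closing_iterations: int = 40
    n_shells: int = 3
    # marker gates use raw nuclear means by default: masked smoothing
    # extrapolates a bright neighbour's signal into adjacent nuclei in
    # crowded spheroids, which contaminates smoothed gate features
    use_smoothed_features: bool = False
    # spacing override (dz, dy, dx) µm; None -> take from TIFF metadata
    spacing_um: tuple[float, float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.volume_min_um3 < self.volume_max_um3:
            raise ValueError(
                f"volume filter bounds must satisfy min < max; got "
                f"({self.volume_min_um3}, {self.volume_max_um3})"
            )
        if self.n_shells < 1:
            raise ValueError(f"shell count must be >= 1; got {self.n_shells}")
        if self.smooth_sigma <= 0:
            raise ValueError(f"smooth_sigma must be > 0; got {self.smooth_sigma}")
        if self.outer_dilations < 1 or self.closing_iterations < 1:
            raise ValueError("morphology iteration counts must be >= 1")
        if int(self.seed) != self.seed:
            raise ValueError("seed must be an integer")
        if self.spacing_um is not None:
            self.spacing_um = tuple(float(v) for v in self.spacing_um)
            if len(self.spacing_um) != 3 or any(v <= 0 for v in self.spacing_um):
                raise ValueError(f"spacing_um must be 3 positive values; got {self.spacing_um}")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        if d["spacing_um"] is not None:
            d["spacing_um"] = list(d["spacing_um"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if d.get("spacing_um") is not None:
            d["spacing_um"] = tuple(d["spacing_um"])
        return cls(**d)
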