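"""Run configuration with the pipeline's documented defaults.

Defaults follow the published acquisition settings where one exists:
top-hat radii of 10 µm (green) and 100 µm (red), a colour threshold of
0.7 on normalized top-hat output, a local-density radius of five times
the mean nearest-neighbour distance, and a local-density threshold of 40.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class SegmentationParams:
    """Per-channel morphological top-hat segmentation parameters."""

    green_tophat_radius_um: float = 10.0
    red_tophat_radius_um: float = 100.0
    colour_threshold: float = 0.7
    min_area_px: int = 4

    def __post_init__(self) -> None:
        if self.green_tophat_radius_um <= 0 or self.red_tophat_radius_um <= 0:
            raise ValueError("top-hat radii must be strictly positive")
        if not 0 < self.colour_threshold < 1:
            raise ValueError("colour_threshold must lie in (0, 1)")
        if self.min_area_px < 1:
            raise ValueError("min_area_px must be >= 1")

    def radius_um(self, channel: str) -> float:
        if channel == "green":
            return self.green_tophat_radius_um
        if channel == "red":
            return self.red_tophat_radius_um
        raise ValueError(f"unknown channel {channel!r}; expected green/red")


@dataclass
class KineticsParams:
    """Log-linear decay fit settings.

    ``log_floor_frac`` is the fraction of the series maximum below which
    values are excluded from the log fit; ``fit_window`` optionally pins
    the (start, stop) indices (inclusive) instead of the automatic window.
    """

    log_floor_frac: float = 1e-3
    fit_window: tuple[int, int] | None = None


@dataclass
class SmlmParams:
    """Localization-clustering parameters.

    ``density_radius_multiplier`` scales the per-aggregate mean
    nearest-neighbour distance into the local-density radius;
    ``density_threshold`` is the local-density count above which a
    molecule belongs to a receptor cluster.  ``min_localizations`` /
    ``max_localizations`` filter aggregates by localization count.
    """

    density_radius_multiplier: float = 5.0
    density_threshold: float = 40.0
    min_members: int = 3
    min_localizations: int = 100
    max_localizations: int | None = None
    render_pixel_nm: float = 20.0


@dataclass
class RunConfig:
    """Full pipeline configuration; round-trips losslessly through YAML."""

    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    kinetics: KineticsParams = field(default_factory=KineticsParams)
    smlm: SmlmParams = field(default_factory=SmlmParams)
    seed: int = 0

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        text = Path(source).read_text() if Path(str(source)).exists() \
            else str(source)
        raw = yaml.safe_load(text) or {}
        kin = raw.get("kinetics", {})
        if kin.get("fit_window") is not None:
            kin["fit_window"] = tuple(kin["fit_window"])
        return cls(
            segmentation=SegmentationParams(**raw.get("segmentation", {})),
            kinetics=KineticsParams(**kin),
            smlm=SmlmParams(**raw.get("smlm", {})),
            seed=int(raw.get("seed", 0)),
        )
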