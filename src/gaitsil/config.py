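"""Pipeline configuration.

All tunables of the silhouette pipeline live here so that a single object can
be passed through the feature-extraction chain, serialized to/from YAML for
the CLI, and overridden in experiments.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Knobs of the silhouette feature-extraction pipeline.

    Parameters
    ----------
    height:
        Target silhouette height after normalization, in pixels. 200 keeps the
        bottom-10% feet band 20 rows tall, enough for stable Otsu thresholding
        of the average feet image.
    smoothing_window:
        Centered moving-average window (frames) applied to the feet-distance
        signal. ``None`` means ``round(fps / 6)`` (5 frames at 30 fps), which
        suppresses single-frame segmentation noise without merging step peaks.
    peak_prominence:
        Minimum prominence (px) for a width-signal maximum to count as an
        initial contact.
    min_peak_separation_s:
        Minimum spacing between initial contacts, in seconds. A human half
        cycle is at least 0.25 s even in fast gait.
    feet_band_fraction:
        Fraction of the normalized height treated as the feet region (bottom
        rows), following the standard human-anatomy ratio.
    coverage_full, coverage_partial:
        Footprint-coverage levels that define "foot completely on the ground"
        (flat-foot frames) and the stance-phase end proxy (toe-off), for the
        foot-flat ratio.
    torso_top_fraction, torso_bottom_fraction:
        Torso band limits as fractions of the silhouette height measured from
        the top (head about the top 13%, hip near 47%).
    quantization_levels:
        Gray levels used when quantizing a gait energy image before the
        adjacent-pixel-difference entropy.
    direction_eps:
        Minimum |centroid drift| in px/frame below which walking-direction
        estimation reports "no net translation".
    """

    height: int = 200
    smoothing_window: int | None = None
    peak_prominence: float = 5.0
    min_peak_separation_s: float = 0.25
    feet_band_fraction: float = 0.10
    coverage_full: float = 0.95
    coverage_partial: float = 0.50
    torso_top_fraction: float = 0.13
    torso_bottom_fraction: float = 0.47
    quantization_levels: int = 256
    direction_eps: float = 0.05

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
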