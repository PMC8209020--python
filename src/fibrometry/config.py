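"""Pipeline configuration: one serializable record of every free parameter.

Every run embeds the hash of its effective configuration in its outputs, so
two result tables are comparable iff their hashes match.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ValidationError

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable parameters of the image-analysis chain.

    Attributes
    ----------
    um_per_px
        Pixel calibration in micrometres per pixel.
    background_scale_px
        Disk radius of the illumination-flattening opening; should exceed
        five fiber widths.
    tophat_radius_px
        Disk radius of the white top-hat; about twice the expected fiber
        width preserves fibers while suppressing wider structures.
    threshold_window_px
        Side of the local-mean window of the adaptive threshold (odd; 15 by
        default).
    threshold_offset
        Offset constant added to the local mean, on the [0, 1] intensity
        scale.  The single biggest free parameter of the segmentation; the
        default 0.05 was calibrated once on the synthetic presets.
    min_object_px
        Minimum 8-connected component area kept after thresholding.
    circularity_cutoff
        Components with isoperimetric circularity above this are removed as
        blob artifacts; ``None`` disables the filter.
    fill_holes_px
        Enclosed background holes smaller than this (noise pinholes that
        would survive as spurious skeleton loops) are filled; 0 disables.
    skeleton_prune_px
        Terminal skeleton branches up to this many pixels that end in a
        junction are pruned as boundary-roughness spurs; 0 disables.
    bp_merge_radius_px
        Branching points closer than this are fused into one; about one
        fiber width undoes the splitting of single bifurcations into
        multiple pixel-level junctions.  0 disables.
    length_estimator
        ``"adjacency"`` (orthogonal/diagonal-weighted) or ``"pixel-count"``.
    ttest_variant
        ``"student"`` or ``"welch"``.
    seed
        Seed for any randomized step (none in the analysis chain itself;
        recorded for provenance of simulated inputs).
    """

    um_per_px: float = 1.0
    background_scale_px: int = 50
    tophat_radius_px: int = 12
    threshold_window_px: int = 15
    threshold_offset: float = 0.05
    min_object_px: int = 50
    circularity_cutoff: float | None = 0.6
    fill_holes_px: int = 40
    skeleton_prune_px: int = 5
    bp_merge_radius_px: float = 5.0
    length_estimator: str = "adjacency"
    ttest_variant: str = "student"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.um_per_px > 0:
            raise ValidationError(f"um_per_px: must be > 0, got {self.um_per_px}")
        if self.background_scale_px <= 0:
            raise ValidationError(
                f"background_scale_px: must be > 0, got {self.background_scale_px}"
            )
        if self.tophat_radius_px < 1:
            raise ValidationError(
                f"tophat_radius_px: must be >= 1, got {self.tophat_radius_px}"
            )
        if self.threshold_window_px < 3 or self.threshold_window_px % 2 == 0:
            raise ValidationError(
                "threshold_window_px: must be an odd integer >= 3, got "
                f"{self.threshold_window_px}"
            )
        if self.threshold_offset < 0:
            raise ValidationError(
                f"threshold_offset: must be >= 0, got {self.threshold_offset}"
            )
        if self.min_object_px < 0:
            raise ValidationError(
                f"min_object_px: must be >= 0, got {self.min_object_px}"
            )
        if self.fill_holes_px < 0:
            raise ValidationError(
                f"fill_holes_px: must be >= 0, got {self.fill_holes_px}"
            )
        if self.skeleton_prune_px < 0:
            raise ValidationError(
                f"skeleton_prune_px: must be >= 0, got {self.skeleton_prune_px}"
            )
        if self.bp_merge_radius_px < 0:
            raise ValidationError(
                f"bp_merge_radius_px: must be >= 0, got {self.bp_merge_radius_px}"
            )
        if self.length_estimator not in ("adjacency", "pixel-count"):
            raise ValidationError(
                "length_estimator: expected 'adjacency' or 'pixel-count', got "
                f"{self.length_estimator!r}"
            )
        if self.ttest_variant not in ("student", "welch"):
            raise ValidationError(
                "ttest_variant: expected 'student' or 'welch', got "
                f"{self.ttest_variant!r}"
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Short stable hash of the effective configuration."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def replace(self, **changes) -> "PipelineConfig":
        return dataclasses.replace(self, **changes)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load from a JSON or YAML file (a ``segmentation:`` style flat map)."""
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValidationError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        p = Path(path)
        if p.suffix in (".yaml", ".yml"):
            p.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        else:
            p.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))
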