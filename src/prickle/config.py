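"""Pipeline configuration: one YAML file drives every stage.

The file has four sections -- ``partition`` (band fractions and
orientation), ``detector`` (one parameter block per tongue area; ``tip``
and ``margin`` may share values with the tight ``root_center`` block kept
separate), ``reference_colors`` (exemplar prickle RGB triples per area) and
``pipeline`` (box padding, evaluation IoU threshold).  The packaged default
ships the partitioned detector parameter set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .blobs import BlobParams
from .color import ReferenceColorSet
from .partition import PartitionFractions

__all__ = ["PipelineConfig", "load_config", "default_config", "save_config"]


@dataclass
class PipelineConfig:
    fractions: PartitionFractions = field(default_factory=PartitionFractions)
    root_at_top: bool = True
    detector: dict[str, BlobParams] = field(default_factory=dict)
    reference_colors: ReferenceColorSet = field(default_factory=ReferenceColorSet)
    box_pad: int = 1
    iou_threshold: float = 0.5

    def to_dict(self) -> dict:
        return {
            "partition": {
                "f_root": self.fractions.f_root,
                "f_tip": self.fractions.f_tip,
                "f_margin": self.fractions.f_margin,
                "root_at_top": self.root_at_top,
            },
            "detector": {
                name: {k: getattr(p, k) for k in BlobParams.__dataclass_fields__}
                for name, p in self.detector.items()
            },
            "reference_colors": {
                name: [list(map(int, c)) for c in colors]
                for name, colors in self.reference_colors.colors_by_region.items()
            },
            "pipeline": {"box_pad": self.box_pad, "iou_threshold": self.iou_threshold},
        }


def _config_from_dict(raw: dict) -> PipelineConfig:
    part = dict(raw.get("partition", {}))
    root_at_top = bool(part.pop("root_at_top", True))
    fractions = PartitionFractions(**part) if part else PartitionFractions()
    detector = {name: BlobParams(**block) for name, block in raw.get("detector", {}).items()}
    refs = ReferenceColorSet(
        {
            name: [tuple(int(v) for v in c) for c in colors]
            for name, colors in (raw.get("reference_colors") or {}).items()
        }
    )
    pipe = raw.get("pipeline", {})
    return PipelineConfig(
        fractions=fractions,
        root_at_top=root_at_top,
        detector=detector,
        reference_colors=refs,
        box_pad=int(pipe.get("box_pad", 1)),
        iou_threshold=float(pipe.get("iou_threshold", 0.5)),
    )


def default_config() -> PipelineConfig:
    """The packaged default configuration (partitioned detector parameters)."""
    text = resources.files("prickle.data").joinpath("default_config.yaml").read_text()
    return _config_from_dict(yaml.safe_load(text))


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a YAML configuration, or the packaged default when path is None."""
    if path is None:
        return default_config()
    with open(path) as fh:
        return _config_from_dict(yaml.safe_load(fh))


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
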