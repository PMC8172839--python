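"""Validated pipeline configuration.

One nested parameter tree covers every stage with the pipeline's standard
defaults (training patches 256 px, inference patches 1024 px with stride
512, perturbation radius 128 px, hybrid-loss weights 0.5/0.25/0.25,
staging thresholds 0.5/0.9).  The tree round-trips losslessly through
JSON; unknown keys are rejected at load time.
"""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SynthConfig(_Strict):
    width0: int = 2048
    height0: int = 2048
    n_tissue_blobs: int = 2
    n_tumor_regions: int = 1
    tumor_size_min: float = 150.0
    tumor_size_max: float = 400.0
    mpp0: float = 4.0
    n_levels: int = 3
    add_black_border: bool = False
    stain_jitter: float = 0.5


class MaskConfig(_Strict):
    level: int | None = None  # None -> level whose long side is nearest 2000 px
    closing_radius: int = 2
    opening_radius: int = 2
    fill_holes_area: int = 0
    black_border_preprocess: bool = False
    black_threshold: int = 10
    median_kernel: int = 7


class PatchConfig(_Strict):
    training_patch_size: int = 256
    inference_patch_size: int = 1024
    stride: int = 512
    perturb_radius: int = 128
    n_per_class: int = 100


class LossConfig(_Strict):
    alpha: float = 0.5
    beta: float = 0.25
    gamma: float = 0.25


class TrainConfig(_Strict):
    n_members: int = 3
    channels: int = 8
    max_epochs: int = 12
    learning_rate: float = 1e-3
    decay_every: int = 4
    decay_factor: float = 0.5
    freeze_encoder_epochs: int = 2
    patience: int = 2
    val_fraction: float = 0.2


class StagingConfig(_Strict):
    low_threshold: float = 0.5
    high_threshold: float = 0.9
    n_members: int = 4
    n_estimators: int = 200


class BurdenConfig(_Strict):
    threshold: float = 0.5
    min_object_px: int | None = None  # None -> 0.05% of tissue area
    max_hole_px: int | None = None  # None -> 0.01% of tissue area


class UncertaintyConfig(_Strict):
    kind: str = "epistemic"
    tta: list[str] = Field(
        default_factory=lambda: ["identity", "rot90", "rot180", "rot270", "vflip", "hflip"]
    )


class PipelineConfig(_Strict):
    """Root configuration for every pipeline stage."""

    seed: int = 0
    synth: SynthConfig = Field(default_factory=SynthConfig)
    mask: MaskConfig = Field(default_factory=MaskConfig)
    patches: PatchConfig = Field(default_factory=PatchConfig)
    loss: LossConfig = Field(default_factory=LossConfig)
    train: TrainConfig = Field(default_factory=TrainConfig)
    staging: StagingConfig = Field(default_factory=StagingConfig)
    burden: BurdenConfig = Field(default_factory=BurdenConfig)
    uncertainty: UncertaintyConfig = Field(default_factory=UncertaintyConfig)

    def to_json(self) -> str:
        return json.dumps(self.model_dump(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls.model_validate(json.loads(text))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_json(Path(path).read_text())
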