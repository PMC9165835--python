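"""Pipeline configuration: defaults, YAML loading, strict validation."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    """Every tunable knob of the pose pipeline, with library defaults.

    Unknown keys are rejected on load so typos cannot silently fall back
    to defaults.
    """

    # heatmap / PAF encoding
    sigma: float = 2.0  # Gaussian spread of keypoint heatmaps, px
    limb_width: float = 4.0  # half-width of the PAF limb band, px
    # decoding / grouping
    peak_threshold: float = 0.1
    score_threshold: float = 0.05  # minimum PAF line-integral for a limb match
    min_parts: int = 4  # minimum keypoints to keep an assembled instance
    n_samples: int = 10  # quadrature points of the PAF line integral
    # detection geometry
    nms_iou: float = 0.5
    decode_mode: str = "literal"  # or "canonical"
    detection_mode: str = "literal"  # TP/FP/FN rule; or "coco"
    # evaluation
    oks_k: float = 0.1  # per-part OKS normalization constant
    oks_threshold: float = 0.5
    # classifier
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1.0e-3
    normalize_features: bool = True
    n_per_pose: int = 600  # synthetic training set size per class
    jitter_sd: float = 2.0  # keypoint labeling noise of the generator, px
    # global
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.limb_width <= 0:
            raise ValueError("limb_width must be positive")
        if not 0 < self.peak_threshold < 1:
            raise ValueError("peak_threshold must lie in (0, 1)")
        if not 0 < self.nms_iou < 1:
            raise ValueError("nms_iou must lie in (0, 1)")
        if self.min_parts < 1 or self.min_parts > 16:
            raise ValueError("min_parts must lie in 1..16")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.decode_mode not in ("literal", "canonical"):
            raise ValueError(f"unknown decode_mode {self.decode_mode!r}")
        if self.detection_mode not in ("literal", "coco"):
            raise ValueError(f"unknown detection_mode {self.detection_mode!r}")
        if self.oks_k <= 0:
            raise ValueError("oks_k must be positive")
        if self.epochs < 1 or self.batch_size < 2:
            raise ValueError("epochs must be >= 1 and batch_size >= 2")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(
                f"unknown config keys: {sorted(unknown)}; valid keys: {sorted(known)}"
            )
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> PipelineConfig:
    """Load a YAML config file, rejecting unknown keys."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return PipelineConfig.from_dict(data)
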