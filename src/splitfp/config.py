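"""Project configuration: one YAML file with per-module sections.

Precedence is CLI flag > config file > dataclass default.  Unknown keys are
rejected with the offending key named, and every section is validated by
its dataclass on construction, so a malformed config fails before any I/O
or simulation happens.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .simulate.flow import TransfectionSimConfig
from .simulate.imaging import ImagingSimConfig

__all__ = [
    "FlowPipelineParams",
    "ImagePipelineParams",
    "SampleSpec",
    "ProjectConfig",
    "load_config",
    "save_config",
]

SAMPLE_ROLES = ("split", "full_length_control", "untransfected")


@dataclass(frozen=True)
class FlowPipelineParams:
    retain_fraction: float = 0.5
    singlet_band: tuple[float, float] = (0.8, 1.3)
    threshold_quantile: float = 0.999
    min_events: int = 100
    robust: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.retain_fraction <= 1.0:
            raise ValueError(
                f"retain_fraction must lie in (0, 1], got {self.retain_fraction!r}"
            )
        if not 0.0 < self.threshold_quantile < 1.0:
            raise ValueError(
                f"threshold_quantile must lie in (0, 1), got {self.threshold_quantile!r}"
            )
        lo, hi = self.singlet_band
        if not lo < hi:
            raise ValueError(f"singlet_band must be a non-empty interval, got {self.singlet_band!r}")
        if self.min_events < 2:
            raise ValueError("min_events must be >= 2")


@dataclass(frozen=True)
class ImagePipelineParams:
    ball_radius_px: int = 20
    bandpass_small_px: float = 3.0
    bandpass_large_px: float = 40.0
    size_range_um2: tuple[float, float] = (80.0, 2000.0)
    circularity_range: tuple[float, float] = (0.1, 1.0)
    pixel_size_um: float = 0.65
    histogram_bins: int = 50

    def __post_init__(self) -> None:
        if self.ball_radius_px < 1:
            raise ValueError("ball_radius_px must be >= 1")
        if not self.bandpass_small_px < self.bandpass_large_px:
            raise ValueError("bandpass_small_px must be < bandpass_large_px")
        if not self.size_range_um2[0] < self.size_range_um2[1]:
            raise ValueError(f"size_range_um2 must be ordered, got {self.size_range_um2!r}")
        if not 0.0 <= self.circularity_range[0] < self.circularity_range[1] <= 1.0:
            raise ValueError(
                f"circularity_range must be ordered within [0, 1], got {self.circularity_range!r}"
            )
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")


@dataclass(frozen=True)
class SampleSpec:
    name: str
    path: str
    role: str

    def __post_init__(self) -> None:
        if self.role not in SAMPLE_ROLES:
            raise ValueError(f"role must be one of {SAMPLE_ROLES}, got {self.role!r}")


@dataclass(frozen=True)
class ProjectConfig:
    seed: int = 0
    output_dir: str = "results"
    log_level: str = "INFO"
    flow_sim: TransfectionSimConfig = field(
        default_factory=lambda: TransfectionSimConfig(n_events=20000)
    )
    imaging_sim: ImagingSimConfig = field(default_factory=ImagingSimConfig)
    imaging_conditions: dict[str, float] = field(
        default_factory=lambda: {"1x": 1.0, "5x": 2.3}
    )
    flow_pipeline: FlowPipelineParams = field(default_factory=FlowPipelineParams)
    image_pipeline: ImagePipelineParams = field(default_factory=ImagePipelineParams)
    samples: tuple[SampleSpec, ...] = ()

    def validate_manifest(self, require_controls: bool = True) -> None:
        """Check the sample manifest before any pipeline run."""
        if require_controls:
            for role in ("untransfected", "full_length_control"):
                n = sum(1 for s in self.samples if s.role == role)
                if n != 1:
                    raise ValueError(
                        f"manifest must name exactly one {role!r} sample, found {n}"
                    )

    def sample_by_role(self, role: str) -> SampleSpec:
        matches = [s for s in self.samples if s.role == role]
        if len(matches) != 1:
            raise ValueError(f"expected exactly one sample with role {role!r}")
        return matches[0]


def _build(cls, data: dict, context: str):
    if not isinstance(data, dict):
        raise ValueError(f"{context}: expected a mapping, got {type(data).__name__}")
    names = {f.name for f in fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"{context}: unknown keys {sorted(unknown)}")
    converted = {}
    for f in fields(cls):
        if f.name not in data:
            continue
        value = data[f.name]
        if isinstance(value, list):
            value = tuple(value)
        converted[f.name] = value
    return cls(**converted)


def load_config(path: str | Path) -> ProjectConfig:
    """Load and fully validate a project config; defaults fill missing keys."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    top = {f.name for f in fields(ProjectConfig)}
    unknown = set(raw) - top
    if unknown:
        raise ValueError(f"{path}: unknown top-level keys {sorted(unknown)}")

    kwargs: dict = {}
    for key in ("seed", "output_dir", "log_level"):
        if key in raw:
            kwargs[key] = raw[key]
    if "flow_sim" in raw:
        kwargs["flow_sim"] = _build(TransfectionSimConfig, raw["flow_sim"], "flow_sim")
    if "imaging_sim" in raw:
        kwargs["imaging_sim"] = _build(ImagingSimConfig, raw["imaging_sim"], "imaging_sim")
    if "imaging_conditions" in raw:
        cond = raw["imaging_conditions"]
        if not isinstance(cond, dict) or not all(
            isinstance(v, (int, float)) and v > 0 for v in cond.values()
        ):
            raise ValueError("imaging_conditions: must map names to positive folds")
        kwargs["imaging_conditions"] = {k: float(v) for k, v in cond.items()}
    if "flow_pipeline" in raw:
        kwargs["flow_pipeline"] = _build(FlowPipelineParams, raw["flow_pipeline"], "flow_pipeline")
    if "image_pipeline" in raw:
        kwargs["image_pipeline"] = _build(
            ImagePipelineParams, raw["image_pipeline"], "image_pipeline"
        )
    if "samples" in raw:
        entries = raw["samples"]
        if not isinstance(entries, list):
            raise ValueError("samples: expected a list of {name, path, role} mappings")
        kwargs["samples"] = tuple(
            _build(SampleSpec, entry, f"samples[{i}]") for i, entry in enumerate(entries)
        )
    return ProjectConfig(**kwargs)


def save_config(config: ProjectConfig, path: str | Path) -> None:
    """Write a normalized config file equivalent to ``config``."""
    data = asdict(config)
    data["samples"] = [asdict(s) for s in config.samples]

    def _clean(obj):
        if isinstance(obj, tuple):
            return [_clean(v) for v in obj]
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        return obj

    Path(path).write_text(yaml.safe_dump(_clean(data), sort_keys=False))
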