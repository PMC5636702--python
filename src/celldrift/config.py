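"""Run configuration: one nested, strictly-validated key-value structure.

A YAML file (or plain dict) holds one section per pipeline stage plus
run-level keys.  Unknown keys are rejected outright so silent typos
cannot change an analysis.  The canonical serialized form is hashed and
the hash is stamped into every output file the run writes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .segmentation import SegmentationParams
from .synthetic import RenderParams, WalkerParams
from .tracking import TrackingParams


@dataclass(frozen=True)
class MsmConfig:
    n_cols: int = 56
    n_rows: int = 20
    length_scale: float | None = None
    mode: str = "soft"
    window_start: int | None = None
    window_end: int | None = None

    def validate(self) -> None:
        if self.mode not in ("soft", "hard"):
            raise ValueError("msm.mode must be 'soft' or 'hard'")
        if (self.window_start is None) != (self.window_end is None):
            raise ValueError("window_start and window_end must be set together")

    @property
    def window(self) -> tuple[int, int] | None:
        if self.window_start is None:
            return None
        return (self.window_start, self.window_end)


@dataclass(frozen=True)
class MetricsConfig:
    gradient_axis: tuple[float, float] = (0.0, 1.0)
    min_points: int = 2

    def validate(self) -> None:
        if self.min_points < 2:
            raise ValueError("metrics.min_points must be >= 2")


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "celldrift_out"
    simulate: bool = True
    input_stack: str | None = None
    walker: WalkerParams = field(default_factory=WalkerParams)
    render: RenderParams = field(default_factory=RenderParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    tracking: TrackingParams = field(default_factory=TrackingParams)
    msm: MsmConfig = field(default_factory=MsmConfig)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)

    def validate(self) -> None:
        if not self.simulate and self.input_stack is None:
            raise ValueError("either simulate: true or input_stack must be given")
        self.walker.validate()
        self.render.validate()
        self.segmentation.validate()
        self.tracking.validate()
        self.msm.validate()
        self.metrics.validate()

    def to_dict(self) -> dict:
        out = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            out[f.name] = dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v
        return out

    @property
    def config_hash(self) -> str:
        """Hash of the scientific parameters (paths excluded)."""
        d = {k: v for k, v in self.to_dict().items() if k not in ("outdir", "input_stack")}
        canon = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


_SECTIONS = {
    "walker": WalkerParams,
    "render": RenderParams,
    "segmentation": SegmentationParams,
    "tracking": TrackingParams,
    "msm": MsmConfig,
    "metrics": MetricsConfig,
}
_RUN_KEYS = {"seed", "outdir", "simulate", "input_stack"}


def _build_section(cls, data: dict, section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown keys in section '{section}': {sorted(unknown)}")
    kwargs = dict(data)
    for f in dataclasses.fields(cls):
        if f.name in kwargs and isinstance(kwargs[f.name], list):
            kwargs[f.name] = tuple(kwargs[f.name])
    return cls(**kwargs)


def config_from_dict(data: dict) -> RunConfig:
    data = dict(data or {})
    unknown = set(data) - _RUN_KEYS - set(_SECTIONS)
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    kwargs = {k: data[k] for k in _RUN_KEYS if k in data}
    for name, cls in _SECTIONS.items():
        if name in data:
            kwargs[name] = _build_section(cls, data[name] or {}, name)
    cfg = RunConfig(**kwargs)
    cfg.validate()
    return cfg


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data)


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
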