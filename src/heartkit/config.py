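"""Run configuration: one JSON document driving every pipeline stage.

The document nests one section per stage; unknown keys are rejected with a
JSON-path location and omitted keys fall back to the package defaults (which
include the training defaults lr=0.0001, momentum=0, batch_size=5,
epochs=100, folds=3).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Any

from .classify import TrainConfig
from .denoise import FilterSpec
from .errors import ConfigError
from .features import MFCCConfig
from .segmentation import WaveletConfig
from .synth import SynthConfig


@dataclass
class SegmentationConfig:
    frame_len: int = 40  # envelope frame, samples at the working rate
    hop: int = 20
    min_period: float = 0.4  # s (150 bpm)
    max_period: float = 1.6  # s (37 bpm)


@dataclass
class SelectionConfig:
    enabled: bool = True
    per_class: bool = True  # pool segments per class across the corpus
    tol: float = 1e-6
    max_iter: int = 200


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str | None = None
    target_rate: int = 2000
    render_images: bool = False
    filter: FilterSpec = field(default_factory=FilterSpec)
    wavelet: WaveletConfig = field(default_factory=WaveletConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    mfcc: MFCCConfig = field(default_factory=MFCCConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    synth: SynthConfig = field(default_factory=SynthConfig)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, indent=1)


_SCALARS = (int, float, str, bool, type(None))


def _coerce(value: Any, target, path: str):
    """Coerce a JSON value onto a dataclass field, strictly enough to catch typos."""
    if dataclasses.is_dataclass(target):
        raise ConfigError("expected an object", path)
    if isinstance(value, bool):
        if target is bool:
            return value
        raise ConfigError(f"expected {getattr(target, '__name__', target)}, got bool", path)
    if target is float and isinstance(value, int):
        return float(value)
    if target is int and isinstance(value, float) and value.is_integer():
        return int(value)
    if target is tuple and isinstance(value, list):
        return tuple(value)
    if isinstance(target, type) and isinstance(value, target):
        return value
    if value is None:
        return None
    raise ConfigError(
        f"expected {getattr(target, '__name__', target)}, got {type(value).__name__}", path
    )


def _fill_dataclass(cls, doc: dict, path: str):
    if not isinstance(doc, dict):
        raise ConfigError("expected an object", path)
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in doc.items():
        if key not in fields:
            raise ConfigError(f"unknown key {key!r}", f"{path}.{key}")
        f = fields[key]
        sub_path = f"{path}.{key}"
        default = _field_default(f)
        if dataclasses.is_dataclass(default):
            kwargs[key] = _fill_dataclass(type(default), value, sub_path)
        elif isinstance(default, tuple):
            kwargs[key] = _coerce(value, tuple, sub_path)
        elif default is None:
            if not isinstance(value, _SCALARS):
                raise ConfigError("expected a scalar", sub_path)
            kwargs[key] = value
        else:
            kwargs[key] = _coerce(value, type(default), sub_path)
    return cls(**kwargs)


def _field_default(f: dataclasses.Field):
    if f.default is not dataclasses.MISSING:
        return f.default
    if f.default_factory is not dataclasses.MISSING:  # type: ignore[misc]
        return f.default_factory()  # type: ignore[misc]
    return None


def validate_config(document: dict | str) -> RunConfig:
    """Parse and validate a run-config document, filling defaults.

    Violations raise :class:`ConfigError` carrying a JSON-path location.
    """
    if isinstance(document, str):
        try:
            document = json.loads(document)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"invalid JSON: {exc}") from exc
    cfg = _fill_dataclass(RunConfig, document, "$")
    # cross-field sanity that dataclass construction cannot express
    if cfg.train.folds < 2:
        raise ConfigError("folds must be >= 2", "$.train.folds")
    if cfg.train.epochs < 1:
        raise ConfigError("epochs must be >= 1", "$.train.epochs")
    if cfg.target_rate <= 0:
        raise ConfigError("target_rate must be positive", "$.target_rate")
    if cfg.segmentation.min_period >= cfg.segmentation.max_period:
        raise ConfigError("min_period must be < max_period", "$.segmentation.min_period")
    if cfg.mfcc.window_len > cfg.mfcc.n_fft:
        raise ConfigError("window_len must be <= n_fft", "$.mfcc.window_len")
    return cfg
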