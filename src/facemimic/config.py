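"""Run configuration: defaults, validation and YAML round-trip.

Every numeric default matches the reference analysis where one exists:
response windows 0-1 s / 2.5-3 s, quality thresholds 0.6 / 0.75 / 0.75,
cross-correlation max lag 45, 10,000 bootstrap resamples, standardized
residual threshold 3. Unknown keys are rejected rather than ignored so typos
cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .contrasts import ExclusionRule
from .design import GroundTruthParams, SessionDesign
from .latency import QualityThresholds
from .preprocess import PreprocParams
from .responses import ResponseWindows


class ConfigError(ValueError):
    """Raised for unknown keys or invariant violations, naming the keys."""


@dataclass(frozen=True)
class XcorrConfig:
    max_lag: int = 45
    peak_search: str = "nonnegative"
    method: str = "pearson_per_lag"

    def __post_init__(self) -> None:
        if self.max_lag < 1:
            raise ConfigError("xcorr.max_lag must be >= 1")


@dataclass(frozen=True)
class RmcorrConfig:
    n_boot: int = 10000

    def __post_init__(self) -> None:
        if self.n_boot < 0:
            raise ConfigError("rmcorr.n_boot must be >= 0")


@dataclass
class RunConfig:
    """Aggregated configuration for a pipeline run."""

    design: SessionDesign = field(default_factory=SessionDesign)
    ground_truth: GroundTruthParams = field(default_factory=GroundTruthParams)
    preprocess: PreprocParams = field(default_factory=PreprocParams)
    windows: ResponseWindows = field(default_factory=ResponseWindows)
    quality: QualityThresholds = field(default_factory=QualityThresholds)
    exclusion: ExclusionRule = field(default_factory=ExclusionRule)
    xcorr: XcorrConfig = field(default_factory=XcorrConfig)
    rmcorr: RmcorrConfig = field(default_factory=RmcorrConfig)
    software_tag: str = "generic"
    exclude_live_mishaps: bool = False
    seed: int = 0
    outdir: str = "facemimic_out"

    def to_dict(self) -> dict:
        out = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if dataclasses.is_dataclass(v):
                out[f.name] = {
                    sf.name: _plain(getattr(v, sf.name)) for sf in dataclasses.fields(v)
                }
            else:
                out[f.name] = _plain(v)
        return out

    @classmethod
    def from_dict(cls, raw: dict | None) -> "RunConfig":
        raw = dict(raw or {})
        kwargs = {}
        sections = {f.name: f for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - set(sections))
        if unknown:
            raise ConfigError(f"unknown config keys: {', '.join(unknown)}")
        for name, f in sections.items():
            if name not in raw:
                continue
            v = raw[name]
            factory = _SECTION_TYPES.get(name)
            if factory is not None:
                if not isinstance(v, dict):
                    raise ConfigError(f"section {name!r} must be a mapping")
                allowed = {sf.name for sf in dataclasses.fields(factory)}
                bad = sorted(set(v) - allowed)
                if bad:
                    raise ConfigError(
                        f"unknown keys in section {name!r}: {', '.join(bad)}"
                    )
                v = {k: _tuplify(factory, k, val) for k, val in v.items()}
                try:
                    kwargs[name] = factory(**v)
                except (ValueError, TypeError) as exc:
                    raise ConfigError(f"invalid values in section {name!r}: {exc}") from exc
            else:
                kwargs[name] = v
        return cls(**kwargs)

    def validate(self) -> None:
        self.ground_truth.validate_against(self.design)
        if self.software_tag not in ("generic", "facereader_like", "pyfeat_like", "openface_like"):
            raise ConfigError(f"unknown software_tag {self.software_tag!r}")


_SECTION_TYPES = {
    "design": SessionDesign,
    "ground_truth": GroundTruthParams,
    "preprocess": PreprocParams,
    "windows": ResponseWindows,
    "quality": QualityThresholds,
    "exclusion": ExclusionRule,
    "xcorr": XcorrConfig,
    "rmcorr": RmcorrConfig,
}

_TUPLE_FIELDS = {
    ("preprocess", "baseline_window_s"),
    ("windows", "neutral_s"),
    ("windows", "maximal_s"),
}


def _plain(v):
    if isinstance(v, tuple):
        return list(v)
    return v


def _tuplify(factory, key, val):
    for section, name in _TUPLE_FIELDS:
        if _SECTION_TYPES[section] is factory and name == key and isinstance(val, list):
            return tuple(val)
    return val


def load_config(path) -> RunConfig:
    """Load and validate a YAML config; an empty file yields full defaults."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping")
    try:
        cfg = RunConfig.from_dict(raw)
    except (ValueError, TypeError) as exc:
        raise ConfigError(str(exc)) from exc
    cfg.validate()
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
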