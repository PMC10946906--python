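"""Run configuration: one YAML file drives the whole pipeline.

Sections mirror the stages (``generator``, ``signature``, ``screen``,
``trend``) plus a top-level ``seed`` and ``log_level``.  Unknown keys are
rejected so typos fail loudly; missing sections fall back to the documented
defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import yaml

from .synthetic_data import GeneratorConfig

__all__ = ["RunConfig", "SignatureConfig", "ScreenConfig", "TrendConfig"]


@dataclass(frozen=True)
class SignatureConfig:
    alpha: float = 0.01      # DE-filter p-value threshold (strict)
    cap: int = 7             # signature size cap (fewer than 8 genes)
    tolerance: float = 0.0   # allowed LOOCV drop during divergence reduction


@dataclass(frozen=True)
class ScreenConfig:
    k_sd: float = 2.0        # control-QC standard-deviation multiplier


@dataclass(frozen=True)
class TrendConfig:
    b: int = 100             # permutations per gene
    alpha: float = 0.05      # BH-adjusted significance threshold


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    log_level: str = "INFO"
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    signature: SignatureConfig = field(default_factory=SignatureConfig)
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    trend: TrendConfig = field(default_factory=TrendConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(doc, dict):
            raise ValueError(f"{path}: top level must be a mapping")
        return cls.from_dict(doc, source=str(path))

    @classmethod
    def from_dict(cls, doc: dict, source: str = "config") -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"{source}: unknown key(s) {sorted(unknown)}")
        sections = {
            "generator": GeneratorConfig,
            "signature": SignatureConfig,
            "screen": ScreenConfig,
            "trend": TrendConfig,
        }
        kwargs = {}
        for key, value in doc.items():
            if key in sections:
                kwargs[key] = _build_section(sections[key], value,
                                             f"{source}:{key}")
            else:
                kwargs[key] = value
        cfg = cls(**kwargs)
        # a single top-level seed drives every stage
        if "seed" in doc and "seed" not in (doc.get("generator") or {}):
            cfg = replace(cfg, generator=cfg.generator.with_seed(cfg.seed))
        return cfg

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(self, seed=seed,
                       generator=self.generator.with_seed(seed))


def _build_section(section_cls, value, source: str):
    value = value or {}
    if not isinstance(value, dict):
        raise ValueError(f"{source}: must be a mapping")
    known = {f.name for f in fields(section_cls)}
    unknown = set(value) - known
    if unknown:
        raise ValueError(f"{source}: unknown key(s) {sorted(unknown)}")
    coerced = {k: _coerce(v) for k, v in value.items()}
    return section_cls(**coerced)


def _coerce(v):
    # YAML lists become the tuples the frozen configs expect
    if isinstance(v, list):
        return tuple(_coerce(x) for x in v)
    return v
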