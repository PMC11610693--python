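"""Run configuration: one YAML file drives the whole pipeline.

Every tunable of the generators, rate curve, covariate construction, model
fits, blocked split and hindcast lives in a single nested config with
documented defaults; ``seed`` is the one top-level source of randomness,
from which each stage deterministically derives its own seed.  Unknown keys
are rejected by name so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .germination import RateCurveParams
from .sdm import GamConfig
from .synth import MicroclimateConfig, SiteGenConfig, SynthTruth


def _build(cls, mapping: dict, context: str):
    """Instantiate a (frozen) dataclass from a mapping, rejecting unknown keys."""
    mapping = dict(mapping or {})
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(mapping) - names)
    if unknown:
        raise ValueError(f"unknown config keys in {context}: {unknown}")
    tuple_fields = {
        f.name
        for f in dataclasses.fields(cls)
        if f.default is not dataclasses.MISSING and isinstance(f.default, tuple)
    }
    for name in tuple_fields & set(mapping):
        mapping[name] = tuple(mapping[name])
    return cls(**mapping)


@dataclass(frozen=True)
class SplitConfig:
    test_fraction: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("split.test_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class HindcastConfig:
    window: tuple[int, int] | None = None  # None: use the reference period
    threshold: float = 0.5
    strata: str = "tercile"  # "tercile" | "tercile_aspect"

    def __post_init__(self) -> None:
        if self.window is not None and self.window[0] > self.window[1]:
            raise ValueError("hindcast.window start must be <= end")
        if self.strata not in ("tercile", "tercile_aspect"):
            raise ValueError(f"unknown hindcast.strata: {self.strata!r}")


@dataclass(frozen=True)
class RunConfig:
    """Effective configuration of a full pipeline run."""

    seed: int = 0
    output_dir: str = "seedbed_run"
    n_sites: int = 200
    n_watersheds: int = 20
    reference_period: tuple[int, int] = (1990, 2019)
    observation_years: tuple[int, int] = (2002, 2016)
    n_observations: int = 2000
    sites_csv: str | None = None
    microclimate_csv: str | None = None
    observations_csv: str | None = None
    write_microclimate: bool = False
    sites: SiteGenConfig = field(default_factory=SiteGenConfig)
    microclimate: MicroclimateConfig = field(default_factory=MicroclimateConfig)
    rate_curve: RateCurveParams = field(default_factory=RateCurveParams)
    truth: SynthTruth = field(default_factory=SynthTruth)
    gam: GamConfig = field(default_factory=GamConfig)
    split: SplitConfig = field(default_factory=SplitConfig)
    hindcast: HindcastConfig = field(default_factory=HindcastConfig)

    def __post_init__(self) -> None:
        ref0, ref1 = self.reference_period
        obs0, obs1 = self.observation_years
        if ref0 > ref1 or obs0 > obs1:
            raise ValueError("year ranges must be increasing")
        if obs0 < ref0 or obs1 > ref1:
            raise ValueError("observation_years must lie within reference_period")
        if self.hindcast.window is not None:
            hc0, hc1 = self.hindcast.window
            if hc0 < ref0 or hc1 > ref1:
                raise ValueError("hindcast.window must lie within reference_period")
        if self.n_observations <= 0:
            raise ValueError("n_observations must be positive")

    @property
    def hindcast_window(self) -> tuple[int, int]:
        return self.hindcast.window or self.reference_period


_SECTION_BUILDERS = {
    "sites": SiteGenConfig,
    "microclimate": MicroclimateConfig,
    "rate_curve": RateCurveParams,
    "truth": SynthTruth,
    "gam": GamConfig,
    "split": SplitConfig,
    "hindcast": HindcastConfig,
}


def config_from_mapping(mapping: dict | None) -> RunConfig:
    mapping = dict(mapping or {})
    sections = {}
    for name, cls in _SECTION_BUILDERS.items():
        if name in mapping:
            sections[name] = _build(cls, mapping.pop(name), name)
    top = _build_top(mapping)
    return dataclasses.replace(top, **sections)


def _build_top(mapping: dict) -> RunConfig:
    names = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(mapping) - names)
    if unknown:
        raise ValueError(f"unknown top-level config keys: {unknown}")
    for key in ("reference_period", "observation_years"):
        if key in mapping:
            mapping[key] = tuple(int(v) for v in mapping[key])
    return RunConfig(**mapping)


def validate_config(path) -> RunConfig:
    """Load and validate a YAML config file; an empty file means all defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a YAML mapping")
    return config_from_mapping(raw)


def effective_config_dict(config: RunConfig) -> dict:
    """The fully-resolved configuration as a plain mapping (for logging)."""

    def convert(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: convert(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, tuple):
            return list(obj)
        return obj

    return convert(config)
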