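"""YAML configuration: schema, defaults and strict validation.

The on-disk format is YAML, ``schema_version: 1``.  Every default is
materialized at load time so no implicit value exists at run time; unknown
keys are hard errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import yaml

from .binding import EngagementBand, KD_WORKING_MAX, KD_WORKING_MIN
from .agents import (
    DEFAULT_BCR_PER_CELL,
    DEFAULT_DELTA_B1,
    DEFAULT_EDIT_ATTEMPTS,
    DEFAULT_P_B1_DIVIDE,
    DEFAULT_POPULATION_CAP,
    DEFAULT_SWITCH_GAIN,
    SHMParams,
)
from .gc import (
    DEFAULT_CYCLES_PER_DOSE,
    DEFAULT_DOSE_CONC,
    DEFAULT_N_DOSES,
    GCParams,
    GCRunConfig,
)
from .niches import BLOOD_VOLUME_L

SCHEMA_VERSION = 1

__all__ = ["SimConfig", "ConfigError", "load_config", "default_config"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


@dataclass(frozen=True)
class NicheConfig:
    volume: float
    n_species: int = 8
    conc_low: float = 1e-12
    conc_high: float = 1e-3
    display_efficiency: float = 1.0


@dataclass(frozen=True)
class CellConfig:
    bcr_per_cell: float = DEFAULT_BCR_PER_CELL
    edit_attempts: int = DEFAULT_EDIT_ATTEMPTS
    population_cap: int = DEFAULT_POPULATION_CAP
    delta_b1: float = DEFAULT_DELTA_B1
    switch_gain: float = DEFAULT_SWITCH_GAIN
    p_b1_divide: float = DEFAULT_P_B1_DIVIDE


@dataclass(frozen=True)
class GermlineConfig:
    kd_low: float = 1e-10
    kd_high: float = 1e-6


@dataclass(frozen=True)
class GCConfig:
    volume: float = 1e-9
    dose_conc: float = DEFAULT_DOSE_CONC
    n_cycles: int = DEFAULT_CYCLES_PER_DOSE
    n_doses: int = DEFAULT_N_DOSES
    n_founders: int = 20
    alpha: float = 4.0
    div_cap: int = 6
    f_present: float = 0.5
    pool_decay: float = 0.10
    residual_frac: float = 0.01
    stochastic_capture: bool = False

    def run_config(self, band: EngagementBand, shm: SHMParams,
                   germline: GermlineConfig) -> GCRunConfig:
        return GCRunConfig(
            volume=self.volume,
            n_founders=self.n_founders,
            germline_low=germline.kd_low,
            germline_high=germline.kd_high,
            band=band,
            params=GCParams(
                alpha=self.alpha,
                div_cap=self.div_cap,
                f_present=self.f_present,
                pool_decay=self.pool_decay,
                residual_frac=self.residual_frac,
                stochastic_capture=self.stochastic_capture,
            ),
            shm=shm,
        )

    def schedule(self) -> list[tuple[float, int]]:
        return [(self.dose_conc, self.n_cycles)] * self.n_doses


@dataclass(frozen=True)
class FounderConfig:
    n_clones: int = 20
    stage: str = "SMALL_PRE_BII"


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_steps: int = 100
    second_signal: bool = False
    band: EngagementBand = field(default_factory=EngagementBand)
    shm: SHMParams = field(default_factory=SHMParams)
    germline: GermlineConfig = field(default_factory=GermlineConfig)
    cells: CellConfig = field(default_factory=CellConfig)
    blood: NicheConfig = field(default_factory=lambda: NicheConfig(volume=BLOOD_VOLUME_L))
    bone_marrow: NicheConfig = field(
        default_factory=lambda: NicheConfig(volume=1e-6, display_efficiency=0.1)
    )
    follicle: NicheConfig = field(
        default_factory=lambda: NicheConfig(volume=1e-6, display_efficiency=0.1)
    )
    memory_niche: NicheConfig = field(
        default_factory=lambda: NicheConfig(volume=1e-6, display_efficiency=0.1)
    )
    gc: GCConfig = field(default_factory=GCConfig)
    founders: FounderConfig = field(default_factory=FounderConfig)
    kd_working_min: float = KD_WORKING_MIN
    kd_working_max: float = KD_WORKING_MAX
    panel_file: str | None = None
    output_dir: str = "out"

    def __post_init__(self) -> None:
        if self.n_steps < 0:
            raise ConfigError("n_steps must be >= 0")
        if not (0 < self.kd_working_min < self.kd_working_max):
            raise ConfigError("working range bounds out of order")
        if not (0 < self.germline.kd_low < self.germline.kd_high):
            raise ConfigError("germline bounds out of order")


_SECTION_TYPES: dict[str, type] = {
    "band": EngagementBand,
    "shm": SHMParams,
    "germline": GermlineConfig,
    "cells": CellConfig,
    "blood": NicheConfig,
    "bone_marrow": NicheConfig,
    "follicle": NicheConfig,
    "memory_niche": NicheConfig,
    "gc": GCConfig,
    "founders": FounderConfig,
}

_SCALAR_KEYS = {
    "seed",
    "n_steps",
    "second_signal",
    "kd_working_min",
    "kd_working_max",
    "panel_file",
    "output_dir",
}


def _build_section(name: str, cls: type, data: Mapping[str, Any]) -> Any:
    allowed = set(cls.__dataclass_fields__)  # type: ignore[attr-defined]
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in section {name!r}: {sorted(unknown)}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid section {name!r}: {exc}") from exc


def config_from_dict(data: Mapping[str, Any]) -> SimConfig:
    data = dict(data)
    version = data.pop("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ConfigError(f"unsupported schema_version {version!r}")
    unknown = set(data) - _SCALAR_KEYS - set(_SECTION_TYPES)
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    for key, value in data.items():
        if key in _SECTION_TYPES:
            if not isinstance(value, Mapping):
                raise ConfigError(f"section {key!r} must be a mapping")
            kwargs[key] = _build_section(key, _SECTION_TYPES[key], value)
        else:
            kwargs[key] = value
    try:
        return SimConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path: str | Path) -> SimConfig:
    """Load and validate a YAML config file."""
    try:
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse YAML in {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, Mapping):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    return config_from_dict(raw)


def default_config(**overrides: Any) -> SimConfig:
    """A fully materialized default configuration."""
    return config_from_dict(overrides)


def dump_config(config: SimConfig) -> str:
    """Serialize a config (with every default made explicit) back to YAML."""
    data = {"schema_version": SCHEMA_VERSION, **asdict(config)}
    return yaml.safe_dump(data, sort_keys=True)
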