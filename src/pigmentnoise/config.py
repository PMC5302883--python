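"""Hierarchical analysis configuration with strict validation.

A configuration document groups every tunable default of the analysis
modules.  Unknown keys are rejected so typos fail loudly.  Configurations
load from TOML and round-trip losslessly through ``to_dict``/``from_dict``
(and hence JSON).
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from .errors import DataError


@dataclass
class ThermalConfig:
    lambda_max: float = 481.0        # nm
    temperature: float = 310.5       # K
    modes: int = 45
    pocket: str = "closed"
    A: float = 0.0                   # s^-1; 0 -> derive from pocket
    constants: str = "precise"       # or 'printed'


@dataclass
class EventConfig:
    amplitude_fraction: float = 0.30
    ti_low: float = 0.5
    ti_high: float = 2.0
    counting_filter_hz: float = 3.0
    epoch_length: float = 100.0      # s
    n_pigments: float = 6.5e7


@dataclass
class PsdConfig:
    segment_s: float = 8.192
    overlap: float = 0.5
    quiet_s: float = 60.0
    band_low: float = 0.1            # Hz
    band_high: float = 5.0           # Hz


@dataclass
class MspConfig:
    unmix_low: float = 510.0         # nm
    unmix_high: float = 750.0        # nm
    baseline_low: float = 650.0      # nm
    baseline_high: float = 700.0     # nm
    template_degree: int = 10


@dataclass
class SimulateConfig:
    duration: float = 600.0          # s
    sampling_rate: float = 1000.0    # Hz
    event_rate: float = 0.005        # s^-1
    noise_sd: float = 1.0            # pA
    acquisition_filter_hz: float = 20.0


@dataclass
class AnalysisConfig:
    """Top-level configuration; sections mirror the analysis modules."""

    seed: int = 0
    thermal: ThermalConfig = field(default_factory=ThermalConfig)
    events: EventConfig = field(default_factory=EventConfig)
    psd: PsdConfig = field(default_factory=PsdConfig)
    msp: MspConfig = field(default_factory=MspConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "AnalysisConfig":
        return _build(cls, data, path="config")


def _build(dc_type: type, data: dict[str, Any], path: str):
    if not isinstance(data, dict):
        raise DataError(f"{path}: expected a table/mapping")
    fields = {f.name: f for f in dataclasses.fields(dc_type)}
    unknown = set(data) - set(fields)
    if unknown:
        raise DataError(f"{path}: unknown keys {sorted(unknown)}; allowed: {sorted(fields)}")
    kwargs = {}
    for name, value in data.items():
        if dataclasses.is_dataclass(_SECTION_TYPES.get(name, None)):
            kwargs[name] = _build(_SECTION_TYPES[name], value, f"{path}.{name}")
        else:
            kwargs[name] = value
    try:
        return dc_type(**kwargs)
    except TypeError as exc:
        raise DataError(f"{path}: {exc}") from exc


_SECTION_TYPES = {
    "thermal": ThermalConfig,
    "events": EventConfig,
    "psd": PsdConfig,
    "msp": MspConfig,
    "simulate": SimulateConfig,
}


def load_config(path: str | Path) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a TOML file."""
    path = Path(path)
    try:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    except (OSError, tomllib.TOMLDecodeError) as exc:
        raise DataError(f"{path}: cannot load config: {exc}") from exc
    return AnalysisConfig.from_dict(data)
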