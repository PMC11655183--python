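"""Pipeline configuration: documented defaults, YAML loading, strict keys."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

from .chamber import ChamberParams
from .constants import DEFAULT_GWP_CH4
from .pairing import PairingThresholds

__all__ = ["PipelineConfig", "load_config", "config_to_dict"]


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of the synthetic end-to-end pipeline.

    Every field has a documented default; unknown keys in a config file are
    rejected.  Seeds fully determine the run.
    """

    seed: int = 1
    sites: tuple[str, ...] = ("open", "tree")  # subset of {open, tree}
    hydro_year_start: str = "2020-11-01"  # start of the balance year (365 days)
    n_campaigns: int = 14  # chamber campaigns spread over the year
    closures_per_plot: int = 4  # closures per plot, type and campaign
    analyzer_sd_ppm: float = 0.0  # white analyzer noise on traces
    ec_noise_sd: float = 0.0  # Gaussian noise on half-hourly EC fluxes
    gap_fraction: float = 0.1  # fraction of EC records turned into gaps
    ec_nee_sd_annual: float = 5.0  # assumed SD of the annual EC NEE sum
    gwp_ch4: float = DEFAULT_GWP_CH4  # 100-year CH4 global warming potential
    interp: str = "linear"  # campaign parameter interpolation: linear|constant
    chamber: ChamberParams = field(default_factory=ChamberParams)
    thresholds: PairingThresholds = field(default_factory=PairingThresholds)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sites", tuple(self.sites))
        unknown = set(self.sites) - {"open", "tree"}
        if unknown:
            raise ValueError(f"unknown sites {sorted(unknown)}")
        if self.interp not in ("linear", "constant"):
            raise ValueError(f"unknown interp mode {self.interp!r}")


def _from_mapping(cls, data: dict[str, Any], path: str):
    if not isinstance(data, dict):
        raise ValueError(f"expected a mapping at {path}")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config keys at {path}: {sorted(unknown)}")
    return cls(**data)


def load_config(path) -> PipelineConfig:
    """Load a YAML config file, rejecting unknown keys at any level."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    nested = {"chamber": ChamberParams, "thresholds": PairingThresholds}
    top = {k: v for k, v in data.items() if k not in nested}
    cfg = _from_mapping(PipelineConfig, top, "<root>")
    overrides = {
        key: _from_mapping(cls, data[key] or {}, key)
        for key, cls in nested.items()
        if key in data
    }
    if overrides:
        cfg = dataclasses.replace(cfg, **overrides)
    return cfg


def config_to_dict(cfg: PipelineConfig) -> dict:
    """Config as a plain nested dict (for logging and round-tripping)."""
    d = dataclasses.asdict(cfg)
    d["sites"] = list(d["sites"])
    return d
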