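"""Pipeline configuration: defaults, validation, YAML round-trip.

All defaults mirror the deployed instrument and analysis conventions:
sampling at 30,517 Hz, insect band 10-900 Hz, accepted durations
10 ms - 1 s, 0.5 degC temperature bins starting at 10 degC, reference
temperature 20 degC, and cluster counts searched over 1-10.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

from .sigproc import InstrumentConfig
from .synth import CampaignSpec, ClusterSpec, DEFAULT_FIVE_CLUSTERS

__all__ = ["ClusteringConfig", "ThermalConfig", "PipelineConfig"]


@dataclass(frozen=True)
class ClusteringConfig:
    k_max: int = 10
    restarts: int = 10
    tol: float = 1e-4

    def __post_init__(self) -> None:
        if self.k_max < 1:
            raise ValueError("k_max must be at least 1")
        if self.restarts < 1:
            raise ValueError("restarts must be at least 1")


@dataclass(frozen=True)
class ThermalConfig:
    bin_width: float = 0.5
    t_min: float = 10.0
    t_max: float | None = None
    t_ref: float = 20.0
    min_bin_count: int = 20

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.t_max is not None and self.t_min >= self.t_max:
            raise ValueError("t_min must be below t_max")
        if self.min_bin_count < 1:
            raise ValueError("min_bin_count must be at least 1")


@dataclass(frozen=True)
class PipelineConfig:
    instrument: InstrumentConfig = field(default_factory=InstrumentConfig)
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)
    thermal: ThermalConfig = field(default_factory=ThermalConfig)
    simulation: CampaignSpec | None = field(default_factory=CampaignSpec)
    events_path: str | None = None  # measured event table; overrides simulation

    def __post_init__(self) -> None:
        if self.simulation is None and self.events_path is None:
            raise ValueError("need either a simulation spec or an events table")
        if self.simulation is not None:
            lo, hi = self.simulation.temp_range
            if self.thermal.t_min >= hi:
                raise ValueError(
                    "thermal.t_min is at or above the simulated temperature range"
                )

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("instrument", "clustering", "thermal"):
            d[key] = dataclasses.asdict(getattr(self, key))
        if self.simulation is not None:
            sim = dataclasses.asdict(self.simulation)
            sim["clusters"] = [dataclasses.asdict(c) for c in self.simulation.clusters]
            d["simulation"] = sim
        return _plain(d)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PipelineConfig":
        kwargs: dict[str, Any] = {}
        if "instrument" in d:
            inst = dict(d["instrument"])
            if "band" in inst:
                inst["band"] = tuple(inst["band"])
            kwargs["instrument"] = InstrumentConfig(**inst)
        if "clustering" in d:
            kwargs["clustering"] = ClusteringConfig(**d["clustering"])
        if "thermal" in d:
            kwargs["thermal"] = ThermalConfig(**d["thermal"])
        if "simulation" in d:
            sim = d["simulation"]
            if sim is None:
                kwargs["simulation"] = None
            else:
                sim = dict(sim)
                if "clusters" in sim:
                    sim["clusters"] = tuple(
                        ClusterSpec(**c) for c in sim["clusters"]
                    )
                if "temp_range" in sim:
                    sim["temp_range"] = tuple(sim["temp_range"])
                kwargs["simulation"] = CampaignSpec(**sim)
        if "events_path" in d:
            kwargs["events_path"] = d["events_path"]
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _plain(obj):
    """Recursively convert tuples to lists so YAML stays plain."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj
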