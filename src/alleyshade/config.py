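"""Run configuration: a single human-editable YAML file describing one run.

Every model default (growth rates, allometry coefficients, seasonal
opacities, 20-minute interval, radiation parameters) is explicit in the
generated template so a run is self-documenting, and a config round-trips
losslessly through its file form.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import date
from pathlib import Path

import yaml

from .radiation import RadiationParams
from .solar import Site
from .trees import TreeGrowthPattern

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    """Invalid run configuration; the message names the offending field."""


@dataclass
class ScenarioLayout:
    orientation_deg: float = 0.0
    row_spacing: float = 32.0
    tree_spacing: float = 12.0
    row_width: float = 1.0
    buffer: float = 20.0


@dataclass
class Schedule:
    start: date = date(2021, 1, 1)
    years: int = 1
    interval_minutes: int = 20


@dataclass
class RunConfig:
    site: Site = field(default_factory=lambda: Site(52.9, 12.8, 1.0))
    schedule: Schedule = field(default_factory=Schedule)
    dem_path: str = "dem.asc"
    field_path: str = "field.geojson"
    layout: ScenarioLayout = field(default_factory=ScenarioLayout)
    pattern: TreeGrowthPattern = field(default_factory=TreeGrowthPattern)
    radiation: RadiationParams = field(default_factory=RadiationParams)
    planting_date: date = date(2021, 1, 1)
    output_dir: str = "out"

    # -- validation ---------------------------------------------------------
    def validate(self, base_dir: str | Path | None = None, check_files: bool = True) -> None:
        lay = self.layout
        for name in ("row_spacing", "tree_spacing", "row_width"):
            if getattr(lay, name) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(lay, name)}")
        if lay.buffer < 0:
            raise ConfigError(f"buffer must be non-negative, got {lay.buffer}")
        if self.schedule.years < 1:
            raise ConfigError(f"schedule.years must be >= 1, got {self.schedule.years}")
        if self.schedule.interval_minutes < 1:
            raise ConfigError(f"interval_minutes must be >= 1, got {self.schedule.interval_minutes}")
        if check_files:
            base = Path(base_dir) if base_dir else Path(".")
            for name in ("dem_path", "field_path"):
                p = Path(getattr(self, name))
                if not p.is_absolute():
                    p = base / p
                if not p.exists():
                    raise ConfigError(f"{name} does not exist: {p}")

    def resolve(self, name: str, base_dir: str | Path | None = None) -> Path:
        p = Path(getattr(self, name))
        if not p.is_absolute() and base_dir:
            p = Path(base_dir) / p
        return p

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["schedule"]["start"] = self.schedule.start.isoformat()
        d["planting_date"] = self.planting_date.isoformat()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        try:
            site = Site(**d.pop("site"))
            sched = dict(d.pop("schedule"))
            sched["start"] = date.fromisoformat(sched["start"])
            schedule = Schedule(**sched)
            layout = ScenarioLayout(**d.pop("layout"))
            pattern = TreeGrowthPattern(**d.pop("pattern"))
            radiation = RadiationParams(**d.pop("radiation"))
            planting = date.fromisoformat(d.pop("planting_date"))
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"malformed config: {exc}") from exc
        return cls(
            site=site,
            schedule=schedule,
            layout=layout,
            pattern=pattern,
            radiation=radiation,
            planting_date=planting,
            **d,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        """Stable hash of the config content, embedded in every output."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
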