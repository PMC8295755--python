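"""Run configuration: a flat, human-editable YAML document.

Defaults encode the analysis conventions of the pipeline: SPI scales
{1, 3, 6, 12, 24, 48}, severity thresholds (-1, -1.5, -2), a 9-year
resistance window with 2 post-drought recovery years, and the curated
drought years 1993/2000/2003.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "results"

    # input paths; empty strings mean "use the simulator"
    ring_csv: str = ""
    station_csv: str = ""

    # sites: site_id -> (latitude, longitude); simulated when ring_csv is empty
    sites: dict = field(default_factory=lambda: {"SIM1": [48.40, 16.10], "SIM2": [48.60, 16.40]})

    # SPI / drought identification
    spi_scales: list = field(default_factory=lambda: [1, 3, 6, 12, 24, 48])
    spi_calibration: list | None = None          # [first_year, last_year] or None = full series
    severity_thresholds: list = field(default_factory=lambda: [-1.0, -1.5, -2.0])
    detect_threshold: float = -1.5
    detect_scales: list = field(default_factory=lambda: [1, 3])
    detect_month_window: list = field(default_factory=lambda: [4, 9])
    curated_events: bool = True                  # curated list overrides detection
    event_years: list = field(default_factory=lambda: [1993, 2000, 2003])
    event_years_by_site: dict = field(default_factory=dict)

    # response windows
    window: int = 9
    post_window: int = 2
    include_event_in_window: bool = True

    # statistics
    transform: bool = True
    ist_definition: str = "deviation"
    significance_level: float = 0.05

    # simulator scale (used when ring_csv is empty)
    sim_provenances: int = 11
    sim_trees: int = 16
    sim_years: list = field(default_factory=lambda: [1971, 2010])

    def __post_init__(self) -> None:
        th = self.severity_thresholds
        if any(b >= a for a, b in zip(th, th[1:])):
            raise ValueError("severity thresholds must be strictly decreasing")
        if self.window % 2 == 0 or self.window < 3:
            raise ValueError("window must be an odd integer >= 3")
        if not self.event_years and not self.event_years_by_site:
            raise ValueError("no drought event years configured")

    def events_for(self, site_id: str) -> list[int]:
        return list(self.event_years_by_site.get(site_id, self.event_years))

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_yaml(fh.read())

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]
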