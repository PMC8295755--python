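"""Synthetic provenance-trial data with known genetic structure.

The generator emulates the study design the pipeline targets: a common
garden of 9-16 provenances with ~16 trees each, ~40 years of annual ring
widths with an age trend, a handful of drought years that depress growth,
and monthly gamma-distributed precipitation with embedded dry spells at the
nearby stations.

The genetic signal lives on the log scale.  For tree i of provenance p at
drought event e the log response is

    y_ipe = mu + P_p + A_i + eps_ie,
    P ~ N(0, provenance_effect_sd^2),  A ~ N(0, tree_sensitivity_sd^2),
    eps ~ N(0, residual_sd^2),

so the generative model is conjugate to the log-scale random-intercept
analysis downstream and the implied true repeatability is

    r_true = tree_sensitivity_sd^2 / (tree_sensitivity_sd^2 + residual_sd^2).

Ring widths multiply an age trend, a tree-level growth factor, lognormal
year-to-year noise, and per-event reduction multipliers
exp(-(m + E_e + P_p + A_i + eps_ie)); all noise is lognormal so widths stay
positive.  Every draw is reproducible from the configured seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .climate import StationSeries
from .response import RESPONSE_COLUMNS, ResponseTable
from .ringio import CoreSeries, TreeCollection, average_cores

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_precip",
    "simulate_response_table",
    "simulate_cores",
    "simulate_ring_widths",
]

# monthly precipitation normals (mm), a dry continental lowland regime of
# roughly 540 mm/year with a summer maximum
DEFAULT_MONTHLY_MEAN_MM = (26.0, 25.0, 35.0, 40.0, 55.0, 70.0, 72.0, 62.0, 45.0, 35.0, 40.0, 35.0)


@dataclass(frozen=True)
class DroughtSpell:
    """Months [start_month, end_month] of ``year`` scaled by ``factor`` (< 1)."""

    year: int
    start_month: int = 4
    end_month: int = 9
    factor: float = 0.3


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic trial.

    Defaults mirror the target trial scale: 11 provenances x 16 trees
    observed over 1971-2010 with drought events in 1993, 2000 and 2003, a
    mean event multiplier of exp(-0.5) ~ 0.61 on ring width, and log-scale
    effect SDs giving a true repeatability near 0.26.
    """

    seed: int = 0
    site_id: str = "SIM"
    latitude: float = 48.4
    longitude: float = 16.1
    n_provenances: int = 11
    trees_per_provenance: int = 16
    years: tuple[int, int] = (1971, 2010)
    # age trend
    age_trend: str = "negative_exponential"   # or "constant"
    trend_scale_mm: float = 2.5
    trend_decay_per_year: float = 0.04
    trend_asymptote_mm: float = 1.0
    # genetic / noise structure (log scale)
    provenance_effect_sd: float = 0.10
    tree_sensitivity_sd: float = 0.15
    tree_growth_sd: float = 0.15
    residual_sd: float = 0.25
    year_noise_sd: float = 0.15
    core_noise_sd: float = 0.03
    cores_per_tree: int = 2
    # drought events
    event_years: tuple[int, ...] = (1993, 2000, 2003)
    event_log_reduction_mean: float = 0.5
    event_effect_sd: float = 0.15
    # direct response simulation (log-scale trait means); optional fixed
    # per-event offsets add a drought main effect to the direct draws
    mu_log_res: float = math.log(0.7)
    mu_log_rec: float = math.log(1.3)
    event_log_offsets: tuple[float, ...] | None = None
    # precipitation
    n_stations: int = 4
    monthly_mean_mm: tuple[float, ...] = DEFAULT_MONTHLY_MEAN_MM
    precip_gamma_shape: float = 1.6
    drought_spells: tuple[DroughtSpell, ...] = (
        DroughtSpell(1992), DroughtSpell(1993), DroughtSpell(2000), DroughtSpell(2003),
    )

    def __post_init__(self) -> None:
        for name in ("provenance_effect_sd", "tree_sensitivity_sd", "tree_growth_sd",
                     "residual_sd", "year_noise_sd", "core_noise_sd", "event_effect_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        y0, y1 = self.years
        bad = [e for e in self.event_years if not (y0 <= e <= y1)]
        if bad:
            raise ValueError(f"event years outside simulated span: {bad}")
        if self.precip_gamma_shape <= 0 or any(m <= 0 for m in self.monthly_mean_mm):
            raise ValueError("invalid precipitation gamma parameters")
        if self.event_log_offsets is not None and len(self.event_log_offsets) != len(self.event_years):
            raise ValueError("event_log_offsets must match event_years in length")

    @property
    def r_true(self) -> float:
        a = self.tree_sensitivity_sd**2
        w = self.residual_sd**2
        return a / (a + w) if a + w > 0 else 0.0

    def rng(self, stream: int) -> np.random.Generator:
        """Independent, reproducible stream derived from the seed."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


@dataclass
class SimulationTruth:
    """The latent draws behind a simulated dataset."""

    r_true: float
    provenance_effects: dict[str, float]
    tree_sensitivities: dict[str, float]
    event_effects: dict[int, float]
    event_multipliers: dict[str, dict[int, float]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["event_effects"] = {str(k): v for k, v in payload["event_effects"].items()}
        payload["event_multipliers"] = {
            t: {str(e): m for e, m in d.items()} for t, d in payload["event_multipliers"].items()
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def _labels(config: SimulationConfig) -> list[tuple[str, str]]:
    out = []
    for p in range(config.n_provenances):
        pid = f"P{p + 1:02d}"
        for t in range(config.trees_per_provenance):
            out.append((pid, f"{pid}_T{t + 1:02d}"))
    return out


def simulate_precip(config: SimulationConfig) -> list[StationSeries]:
    """Monthly station precipitation with embedded dry spells."""
    rng = config.rng(101)
    y0, y1 = config.years
    grid = pd.period_range(f"{y0}-01", f"{y1}-12", freq="M")
    shape = config.precip_gamma_shape
    means = np.array([config.monthly_mean_mm[m - 1] for m in grid.month])
    spells = {(s.year, m): s.factor
              for s in config.drought_spells for m in range(s.start_month, s.end_month + 1)}
    stations = []
    for i in range(config.n_stations):
        lat = config.latitude + float(rng.uniform(-0.25, 0.25))
        lon = config.longitude + float(rng.uniform(-0.35, 0.35))
        vals = rng.gamma(shape, means / shape)
        factors = np.array([spells.get((y, m), 1.0) for y, m in zip(grid.year, grid.month)])
        series = pd.Series(vals * factors, index=grid)
        stations.append(StationSeries(f"ST{i + 1}", lat, lon, series))
    return stations


def _draw_effects(config: SimulationConfig, rng: np.random.Generator):
    labels = _labels(config)
    prov_ids = sorted({p for p, _ in labels})
    P = {p: float(rng.normal(0.0, config.provenance_effect_sd)) for p in prov_ids}
    A = {t: float(rng.normal(0.0, config.tree_sensitivity_sd)) for _, t in labels}
    E = {e: float(rng.normal(0.0, config.event_effect_sd)) for e in config.event_years}
    return labels, P, A, E


def simulate_response_table(config: SimulationConfig) -> tuple[ResponseTable, SimulationTruth]:
    """Draw per-(tree, event) responses directly from the generative model.

    Resistance and recovery get independent provenance/tree/residual draws
    around their configured log-scale means, with the SDs shared, so both
    traits carry the same true repeatability.
    """
    if len(config.event_years) < 2:
        raise ValueError("need at least 2 events for repeatability testing")
    rng = config.rng(202)
    labels, P, A, E = _draw_effects(config, rng)
    # independent effect draws for the second trait
    P2 = {p: float(rng.normal(0.0, config.provenance_effect_sd)) for p in P}
    A2 = {t: float(rng.normal(0.0, config.tree_sensitivity_sd)) for _, t in labels}
    offsets = dict(zip(config.event_years, config.event_log_offsets or ()))
    rows = []
    for pid, tid in labels:
        for ev in config.event_years:
            off = offsets.get(ev, 0.0)
            res = math.exp(config.mu_log_res + off + P[pid] + A[tid]
                           + rng.normal(0.0, config.residual_sd))
            rec = math.exp(config.mu_log_rec + off + P2[pid] + A2[tid]
                           + rng.normal(0.0, config.residual_sd))
            rows.append((config.site_id, pid, tid, int(ev),
                         math.nan, math.nan, math.nan, res, rec, ()))
    df = pd.DataFrame(rows, columns=RESPONSE_COLUMNS)
    table = ResponseTable(df, sorted(config.event_years))
    truth = SimulationTruth(config.r_true, P, A, E)
    return table, truth


def simulate_cores(config: SimulationConfig) -> tuple[list[CoreSeries], SimulationTruth]:
    """Two-core ring-width series per tree under the generative growth model.

    Event-related draws come from a stream separate from the growth/noise
    draws, so two configs differing only in ``event_years`` share identical
    baseline widths — the no-event run is an exact counterfactual.
    """
    rng = config.rng(303)        # genetic structure: P, A
    rng_event = config.rng(304)  # event effects and event residuals
    rng_noise = config.rng(305)  # growth level, year noise, core noise
    labels, P, A, _ = _draw_effects(config, rng)
    E = {e: float(rng_event.normal(0.0, config.event_effect_sd)) for e in config.event_years}
    y0, y1 = config.years
    years = np.arange(y0, y1 + 1)
    t_rel = years - y0
    if config.age_trend == "negative_exponential":
        trend = (config.trend_scale_mm * np.exp(-config.trend_decay_per_year * t_rel)
                 + config.trend_asymptote_mm)
    elif config.age_trend == "constant":
        trend = np.full_like(t_rel, config.trend_scale_mm, dtype=float)
    else:
        raise ValueError(f"unknown age trend {config.age_trend!r}")
    cores: list[CoreSeries] = []
    multipliers: dict[str, dict[int, float]] = {}
    for pid, tid in labels:
        g = rng_noise.normal(0.0, config.tree_growth_sd)
        noise = rng_noise.normal(0.0, config.year_noise_sd, size=len(years))
        mult = np.ones(len(years))
        multipliers[tid] = {}
        for ev in config.event_years:
            eps = rng_event.normal(0.0, config.residual_sd)
            m = math.exp(-(config.event_log_reduction_mean + E[ev] + P[pid] + A[tid] + eps))
            mult[ev - y0] = m
            multipliers[tid][int(ev)] = m
        widths = trend * math.exp(g) * np.exp(noise) * mult
        for c in range(config.cores_per_tree):
            cnoise = rng_noise.normal(0.0, config.core_noise_sd, size=len(years))
            cores.append(CoreSeries(f"{tid}{chr(ord('a') + c)}", tid, pid, config.site_id,
                                    int(y0), widths * np.exp(cnoise)))
    truth = SimulationTruth(config.r_true, P, A, E, multipliers)
    return cores, truth


def simulate_ring_widths(config: SimulationConfig) -> tuple[TreeCollection, SimulationTruth]:
    """Simulated cores averaged per tree, as the readers would deliver them."""
    cores, truth = simulate_cores(config)
    by_tree: dict[str, list[CoreSeries]] = {}
    for c in cores:
        by_tree.setdefault(c.tree_id, []).append(c)
    series = [average_cores(cs) for cs in by_tree.values()]
    return TreeCollection.from_series(series, site_id=config.site_id), truth
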