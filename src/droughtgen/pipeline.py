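"""Pipeline stages: orchestration of the analysis modules over a RunConfig.

Each stage reads the artifacts of its predecessors from the output
directory and writes tidy CSVs.  Reruns with an identical configuration and
inputs are byte-identical; logging goes to the logging subsystem (stderr by
default), never into the artifacts.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import climate, quantgen, response, ringio, simulate, stability
from .config import RunConfig

log = logging.getLogger(__name__)

__all__ = ["run_stage", "run_all", "STAGES"]


def _outdir(cfg: RunConfig) -> Path:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _sim_config(cfg: RunConfig, site_id: str, idx: int) -> simulate.SimulationConfig:
    lat, lon = cfg.sites[site_id]
    return simulate.SimulationConfig(
        seed=int((cfg.seed + 7919 * (idx + 1)) % 2**31),
        site_id=site_id, latitude=float(lat), longitude=float(lon),
        n_provenances=cfg.sim_provenances, trees_per_provenance=cfg.sim_trees,
        years=tuple(cfg.sim_years), event_years=tuple(cfg.events_for(site_id)),
    )


def run_simulate(cfg: RunConfig) -> None:
    out = _outdir(cfg)
    all_cores = []
    for i, site_id in enumerate(sorted(cfg.sites)):
        sc = _sim_config(cfg, site_id, i)
        cores, truth = simulate.simulate_cores(sc)
        all_cores.extend(cores)
        stations = simulate.simulate_precip(sc)
        climate.write_station_csv(stations, out / f"stations_{site_id}.csv")
        truth.to_json(out / f"truth_{site_id}.json")
    ringio.write_long_csv(all_cores, out / "ring_widths.csv")
    log.info("simulated %d cores for %d sites", len(all_cores), len(cfg.sites))


def _ring_csv(cfg: RunConfig) -> Path:
    return Path(cfg.ring_csv) if cfg.ring_csv else _outdir(cfg) / "ring_widths.csv"


def _stations_for(cfg: RunConfig, site_id: str) -> list[climate.StationSeries]:
    if cfg.station_csv:
        return climate.read_station_csv(cfg.station_csv)
    return climate.read_station_csv(_outdir(cfg) / f"stations_{site_id}.csv")


def run_spi(cfg: RunConfig) -> None:
    out = _outdir(cfg)
    calibration = tuple(cfg.spi_calibration) if cfg.spi_calibration else None
    for site_id in sorted(cfg.sites):
        lat, lon = cfg.sites[site_id]
        site = climate.idw_interpolate(_stations_for(cfg, site_id), site_id, float(lat), float(lon))
        sp = site.precip
        pd.DataFrame({"year": sp.index.year, "month": sp.index.month, "precip_mm": sp.to_numpy()}
                     ).to_csv(out / f"site_precip_{site_id}.csv", index=False)
        for k in cfg.spi_scales:
            s = climate.spi(site, int(k), calibration=calibration)
            v = s.values
            pd.DataFrame({"year": v.index.year, "month": v.index.month, "spi": v.to_numpy()}
                         ).to_csv(out / f"spi_{site_id}_k{k}.csv", index=False)
            sidecar = {"site_id": site_id, "scale_k": int(k),
                       "calibration": list(calibration) if calibration else None,
                       "fit_params": {str(m): p for m, p in s.fit_params.items()}}
            (out / f"spi_{site_id}_k{k}.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def _load_spi(cfg: RunConfig, site_id: str) -> dict[int, climate.SPISeries]:
    out = _outdir(cfg)
    series = {}
    for k in cfg.spi_scales:
        df = pd.read_csv(out / f"spi_{site_id}_k{k}.csv")
        vals = climate.monthly_series(df["year"], df["month"], df["spi"])
        series[int(k)] = climate.SPISeries(site_id, int(k), vals)
    return series


def run_events(cfg: RunConfig) -> None:
    out = _outdir(cfg)
    rows = []
    for site_id in sorted(cfg.sites):
        spi_set = _load_spi(cfg, site_id)
        override = cfg.events_for(site_id) if cfg.curated_events else None
        events = climate.detect_drought_years(
            spi_set, threshold=cfg.detect_threshold, scales=cfg.detect_scales,
            month_window=tuple(cfg.detect_month_window), override=override)
        for ev in events:
            rows.append((site_id, ev.event_year, ev.severity or "", ev.min_spi, ev.curated))
    pd.DataFrame(rows, columns=["site_id", "event_year", "severity", "min_spi", "curated"]
                 ).to_csv(out / "events.csv", index=False)


def _load_collections(cfg: RunConfig) -> dict[str, ringio.TreeCollection]:
    cores = ringio.read_long_csv(_ring_csv(cfg))
    by_site: dict[str, list] = {}
    for c in cores:
        by_site.setdefault(c.site_id, []).append(c)
    return {sid: ringio.collection_from_cores(cs, site_id=sid) for sid, cs in by_site.items()}


def run_response(cfg: RunConfig) -> None:
    out = _outdir(cfg)
    tables = []
    for site_id, coll in sorted(_load_collections(cfg).items()):
        tab = response.compute_response_table(
            coll, cfg.events_for(site_id), window=cfg.window, post_window=cfg.post_window,
            include_event=cfg.include_event_in_window)
        log.info("site %s response completeness: %s", site_id, tab.completeness)
        tables.append(tab.df)
    df = pd.concat(tables, ignore_index=True)
    df = df.assign(flags=df["flags"].map(lambda f: ";".join(f) if f else ""))
    df.to_csv(out / "response.csv", index=False)


def _load_response(cfg: RunConfig, site_id: str) -> response.ResponseTable:
    df = pd.read_csv(_outdir(cfg) / "response.csv")
    df = df[df["site_id"] == site_id].reset_index(drop=True)
    df["flags"] = df["flags"].fillna("").map(lambda s: tuple(str(s).split(";")) if s else ())
    return response.ResponseTable(df, sorted(df["event_year"].unique().tolist()))


def run_stability(cfg: RunConfig) -> None:
    out = _outdir(cfg)
    slope_rows, summary_rows, rank_rows = [], [], []
    for site_id in sorted(cfg.sites):
        tab = _load_response(cfg, site_id)
        for trait in ("Res", "Rec"):
            result = stability.finlay_wilkinson(tab, trait, ist_definition=cfg.ist_definition)
            s = result.slopes.assign(site_id=site_id, trait=trait)
            slope_rows.append(s)
            summary_rows.append((site_id, trait, result.b_dev, result.b_ist, cfg.ist_definition))
            rank_rows.append(stability.rank_stability(tab, trait).assign(site_id=site_id, trait=trait))
    pd.concat(slope_rows, ignore_index=True).to_csv(out / "stability_slopes.csv", index=False)
    pd.DataFrame(summary_rows, columns=["site_id", "trait", "b_dev", "b_ist", "ist_definition"]
                 ).to_csv(out / "stability_summary.csv", index=False)
    pd.concat(rank_rows, ignore_index=True).to_csv(out / "rank_stability.csv", index=False)


def run_repeatability(cfg: RunConfig) -> None:
    out = _outdir(cfg)
    prov_rows, sp_rows = [], []
    for site_id in sorted(cfg.sites):
        tab = _load_response(cfg, site_id)
        for trait in ("Res", "Rec"):
            prov_rows.append(quantgen.repeatability_table(tab, trait).assign(site_id=site_id, trait=trait))
            sp_rows.append({"site_id": site_id, **quantgen.repeatability_summary(tab, trait)})
    pd.concat(prov_rows, ignore_index=True).to_csv(out / "repeatability.csv", index=False)
    pd.DataFrame(sp_rows).to_csv(out / "repeatability_species.csv", index=False)


def run_evolvability(cfg: RunConfig) -> None:
    out = _outdir(cfg)
    rows = []
    for site_id in sorted(cfg.sites):
        tab = _load_response(cfg, site_id)
        for trait in ("Res", "Rec"):
            rows.append(quantgen.evolvability_table(tab, trait).assign(site_id=site_id, trait=trait))
    pd.concat(rows, ignore_index=True).to_csv(out / "evolvability.csv", index=False)


def run_report(cfg: RunConfig) -> None:
    out = _outdir(cfg)
    resp = pd.read_csv(out / "response.csv")
    anova_rows, letters_rows, sel_rows = [], [], []
    for trait in ("Res", "Rec"):
        if resp["site_id"].nunique() >= 2:
            an = quantgen.two_way_anova(resp, trait, species_col="site_id")
            anova_rows.append(an.assign(trait=trait, term=an.index))
            letters = quantgen.posthoc_pairwise(resp.dropna(subset=[trait]), trait, "site_id",
                                                alpha=cfg.significance_level)
            letters_rows.append(letters.assign(trait=trait))
        for site_id in sorted(cfg.sites):
            tab = _load_response(cfg, site_id)
            sel = quantgen.repeated_measures_selection(tab, trait, transform=cfg.transform)
            sel_rows.append(sel.table.assign(site_id=site_id, trait=trait))
    if anova_rows:
        pd.concat(anova_rows, ignore_index=True).to_csv(out / "anova_species.csv", index=False)
        pd.concat(letters_rows, ignore_index=True).to_csv(out / "posthoc_letters.csv", index=False)
    pd.concat(sel_rows, ignore_index=True).to_csv(out / "model_selection.csv", index=False)


STAGES = {
    "simulate": run_simulate,
    "spi": run_spi,
    "events": run_events,
    "response": run_response,
    "stability": run_stability,
    "repeatability": run_repeatability,
    "evolvability": run_evolvability,
    "report": run_report,
}


def run_stage(name: str, cfg: RunConfig) -> None:
    if name == "all":
        run_all(cfg)
        return
    if name not in STAGES:
        raise ValueError(f"unknown stage {name!r}; choose from {sorted(STAGES)} or 'all'")
    log.info("stage %s (config %s, seed %d)", name, cfg.config_hash(), cfg.seed)
    STAGES[name](cfg)


def run_all(cfg: RunConfig) -> None:
    names = list(STAGES)
    if cfg.ring_csv:
        names.remove("simulate")
    for name in names:
        log.info("stage %s (config %s, seed %d)", name, cfg.config_hash(), cfg.seed)
        STAGES[name](cfg)
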