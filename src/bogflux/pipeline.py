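"""End-to-end orchestration of the synthetic analysis pipeline.

One run covers, per site: driver and campaign synthesis, chamber flux
processing, campaign model fitting, daily reconstruction, EC daily
aggregation, source partitioning, chamber-EC comparison and the annual
carbon / GHG balances.  All intermediate tables are written as CSV; the
summary is deterministic for a fixed config and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .balances import SiteBalance, ValueSD, site_balance, site_summary
from .chamber import process_campaign
from .config import PipelineConfig, config_to_dict
from .models import daily_reconstruct, fit_campaigns, models_to_frame
from .pairing import build_groups, compare, match_ec
from .partition import annual_sums, ec_daily, partition_year
from .synthetic import (
    SiteScenario,
    generate_campaign,
    generate_drivers,
    generate_ec,
    open_site_scenario,
    tree_site_scenario,
)
from .tables import validate_tables

__all__ = ["run_pipeline", "run_site", "scenario_for"]

log = logging.getLogger(__name__)


def scenario_for(site: str, config: PipelineConfig) -> SiteScenario:
    if site == "open":
        return open_site_scenario(seed=config.seed)
    if site == "tree":
        return tree_site_scenario(seed=config.seed + 100)
    raise ValueError(f"unknown site {site!r}")


def campaign_schedule(drivers: pd.DataFrame, n_campaigns: int) -> pd.DatetimeIndex:
    """Campaign days spread evenly over the driver span (margins excluded)."""
    start = drivers.index[0] + pd.Timedelta(days=14)
    end = drivers.index[-1] - pd.Timedelta(days=14)
    return pd.date_range(start, end, periods=n_campaigns).normalize()


def site_ch4(scenario: SiteScenario) -> ValueSD:
    """Areal upscaling of per-microform annual CH4-C balances."""
    value = sum(m.areal_share * m.ch4_annual for m in scenario.ground_microforms)
    sd = math.sqrt(sum((m.areal_share * m.ch4_sd) ** 2 for m in scenario.ground_microforms))
    return ValueSD(value, sd)


def run_site(site: str, config: PipelineConfig, outdir: Path) -> dict:
    """Run all stages for one site; returns the JSON-serialisable summary."""
    outdir.mkdir(parents=True, exist_ok=True)
    scenario = scenario_for(site, config)
    start = pd.Timestamp(config.hydro_year_start)
    end = start + pd.Timedelta(days=365)

    log.info("[%s] generating drivers and observations", site)
    drivers = generate_drivers(scenario, start, end)
    campaigns = campaign_schedule(drivers, config.n_campaigns)
    traces = generate_campaign(
        scenario,
        drivers,
        campaigns,
        closures_per_plot=config.closures_per_plot,
        analyzer_sd_ppm=config.analyzer_sd_ppm,
        par_attenuation=config.chamber.par_attenuation,
        mean_leaf_area=config.chamber.mean_leaf_area,
    )
    ec, ec_filled = generate_ec(
        scenario, drivers, noise_sd=config.ec_noise_sd, gap_fraction=config.gap_fraction
    )

    log.info("[%s] processing %d chamber traces", site, len(traces))
    obs = process_campaign(traces, config.chamber)
    from .chamber import observations_to_frame

    obs_df = observations_to_frame(obs)

    log.info("[%s] fitting campaign models", site)
    models = fit_campaigns(obs_df)
    daily = daily_reconstruct(
        models, drivers, (start, end - pd.Timedelta(days=1)), interp=config.interp
    )

    ecd = ec_daily(ec_filled)
    partitioned, flags = partition_year(daily, scenario.shares, scenario.lai_at, ecd)
    annual = annual_sums(partitioned, start.date())

    groups = build_groups(
        obs_df, site, scenario.shares, config.thresholds, lai_at=scenario.lai_at
    )
    pairs = match_ec(groups, ec, config.thresholds)
    comparison: dict = {}
    for flux_type, g in pairs.groupby("flux_type") if len(pairs) else []:
        if len(g) >= 3:
            comparison.update(compare(g))

    nee_annual = float(ecd["NEE"].sum())
    balance = site_balance(
        site,
        gpp=float(ecd["GPP"].sum()),
        reco=float(ecd["Reco"].sum()),
        nee=ValueSD(nee_annual, config.ec_nee_sd_annual),
        ch4=site_ch4(scenario),
        gwp=config.gwp_ch4,
    )

    io.write_drivers(drivers, outdir / "drivers.csv")
    io.write_ec(ec_filled, outdir / "ec_gapfilled.csv")
    io.write_ec(ec, outdir / "ec.csv")
    io.write_traces(traces, outdir / "trace_samples.csv", outdir / "trace_meta.csv")
    io.write_observations(obs_df, outdir / "observations.csv")
    models_to_frame(models).to_csv(outdir / "models.csv", index=False)
    daily.to_csv(outdir / "daily_sources.csv", index=False)
    partitioned.to_csv(outdir / "partitioned.csv", index=False)
    annual.to_csv(outdir / "annual_contributions.csv", index=False)
    if len(pairs):
        pairs.to_csv(outdir / "pairs.csv", index=False)
    with open(outdir / "comparison.json", "w") as fh:
        json.dump(comparison, fh, indent=2, sort_keys=True)

    return {
        "site": site,
        "n_traces": len(traces),
        "n_observations": int(len(obs_df)),
        "n_groups": len(groups),
        "n_pairs": int(len(pairs)),
        "annual": {
            row["microform"]: {
                "Reco": round(row["Reco"], 6),
                "GPP": round(row["GPP"], 6),
                "NEE": round(row["NEE"], 6),
                "share_Reco": round(row["share_Reco"], 3),
                "share_GPP": round(row["share_GPP"], 3),
            }
            for _, row in annual.iterrows()
        },
        "balance": {
            "GPP": round(balance.gpp, 6),
            "Reco": round(balance.reco, 6),
            "NEE": [round(balance.nee.value, 6), round(balance.nee.sd, 6)],
            "CH4": [round(balance.ch4.value, 6), round(balance.ch4.sd, 6)],
            "carbon": [round(balance.carbon.value, 6), round(balance.carbon.sd, 6)],
            "GHG": [round(balance.ghg.value, 6), round(balance.ghg.sd, 6)],
            "gwp_ch4": balance.gwp_ch4,
        },
    }


def _balance_from_summary(s: dict) -> SiteBalance:
    b = s["balance"]
    return site_balance(
        s["site"], b["GPP"], b["Reco"], tuple(b["NEE"]), tuple(b["CH4"]), b["gwp_ch4"]
    )


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Run every configured site plus the cross-site summary and table checks."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("bogflux")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        log.info("bogflux %s starting run with seed %d", __version__, config.seed)
        summaries = {}
        for site in config.sites:
            try:
                summaries[site] = run_site(site, config, outdir / site)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage failed for site {site!r}: {exc}") from exc
        summary: dict = {
            "version": __version__,
            "config": config_to_dict(config),
            "sites": summaries,
        }
        if {"open", "tree"} <= set(summaries):
            summary["cross_site"] = site_summary(
                _balance_from_summary(summaries["open"]), _balance_from_summary(summaries["tree"])
            )
        table_report = validate_tables(gwp=config.gwp_ch4)
        table_report.to_csv(outdir / "table_checks.csv", index=False)
        summary["table_checks_passed"] = int(table_report["passed"].sum())
        summary["table_checks_total"] = int(len(table_report))
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        log.info("run complete: %s", outdir / "summary.json")
    finally:
        root.removeHandler(handler)
        handler.close()
    return outdir
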