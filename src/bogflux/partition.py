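"""Daily attribution of EC-derived GPP and Reco to microforms and trees.

For every day, each source's modelled flux density is weighted by its areal
share (ground microforms) or the current tree LAI (branch source); the
relative weights distribute the EC daily GPP and Reco across the sources,
so the per-source contributions sum to the EC totals by construction.
Per-source NEE is the sum of the signed GPP and Reco contributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date, timedelta
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PartitionedDay",
    "partition_day",
    "partition_year",
    "ec_daily",
    "annual_sums",
    "contribution_shares",
]

log = logging.getLogger(__name__)

BRANCH = "branch"


@dataclass
class PartitionedDay:
    """Per-source daily fluxes (g CO2-C m-2 ground d-1) and relative weights."""

    date: pd.Timestamp
    gpp: dict[str, float]
    reco: dict[str, float]
    nee: dict[str, float]
    rel_gpp: dict[str, float]
    rel_reco: dict[str, float]
    ec_gpp: float
    ec_reco: float
    ec_nee: float
    fallback_gpp: bool = False
    fallback_reco: bool = False


def _relative_weights(
    weights: Mapping[str, float], shares: Mapping[str, float], ec_value: float
) -> tuple[dict[str, float], bool]:
    total = sum(weights.values())
    if total > 0:
        return {k: w / total for k, w in weights.items()}, False
    if ec_value == 0:
        return {k: 0.0 for k in weights}, False
    # chamber models predict no flux but EC observed one: fall back to areal shares
    rel = {k: shares.get(k, 0.0) for k in weights}
    return rel, True


def partition_day(
    source_daily: Mapping[str, tuple[float, float]],
    shares: Mapping[str, float],
    lai: float,
    ec_day: tuple[float, float],
    *,
    day=None,
) -> PartitionedDay:
    """Partition one day's EC GPP and Reco across sources.

    ``source_daily`` maps source name to its modelled (GPP, Reco) density
    per m2 of source; ``shares`` holds ground areal shares (summing to 1)
    and ``lai`` the tree LAI weighting the branch source; ``ec_day`` is the
    EC-derived (GPP, Reco) of that day in g CO2-C m-2 d-1.
    """
    total_share = sum(shares.values())
    if abs(total_share - 1.0) > 1e-6:
        raise ValueError(f"areal shares sum to {total_share}, expected 1")
    ec_gpp, ec_reco = float(ec_day[0]), float(ec_day[1])
    w_gpp: dict[str, float] = {}
    w_reco: dict[str, float] = {}
    for name, (gpp_i, reco_i) in source_daily.items():
        if reco_i < 0:
            raise ValueError(f"negative Reco weight for source {name!r}")
        w = lai if name == BRANCH else shares[name]
        w_gpp[name] = w * abs(gpp_i)
        w_reco[name] = w * reco_i
    rel_gpp, fb_gpp = _relative_weights(w_gpp, shares, ec_gpp)
    rel_reco, fb_reco = _relative_weights(w_reco, shares, ec_reco)
    gpp = {k: rel_gpp[k] * ec_gpp for k in source_daily}
    reco = {k: rel_reco[k] * ec_reco for k in source_daily}
    nee = {k: gpp[k] + reco[k] for k in source_daily}
    return PartitionedDay(
        date=pd.Timestamp(day) if day is not None else pd.NaT,
        gpp=gpp,
        reco=reco,
        nee=nee,
        rel_gpp=rel_gpp,
        rel_reco=rel_reco,
        ec_gpp=ec_gpp,
        ec_reco=ec_reco,
        ec_nee=ec_gpp + ec_reco,
        fallback_gpp=fb_gpp,
        fallback_reco=fb_reco,
    )


def ec_daily(ec_filled: pd.DataFrame) -> pd.DataFrame:
    """Daily sums of half-hourly EC GPP/Reco/NEE (g CO2-C m-2 d-1).

    Requires 48 records per day; the NEE = GPP + Reco identity is asserted.
    """
    days = ec_filled.index.normalize()
    counts = ec_filled.groupby(days).size()
    bad = counts[counts != 48]
    if len(bad):
        raise ValueError(f"incomplete days in EC series: {list(bad.index.date)[:5]} ...")
    daily = ec_filled.groupby(days)[["GPP", "Reco", "NEE"]].sum()
    daily.index.name = "date"
    resid = (daily["NEE"] - daily["GPP"] - daily["Reco"]).abs().max()
    if resid > 1e-6:
        raise ValueError(f"EC daily NEE != GPP + Reco (max residual {resid:.2e})")
    return daily


def partition_year(
    daily_sources: pd.DataFrame,
    shares: Mapping[str, float],
    lai_at,
    ec_day_df: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition every day of an EC daily table.

    ``daily_sources`` is the long table from
    :func:`bogflux.models.daily_reconstruct`; ``lai_at`` maps timestamps to
    tree LAI (use ``lambda ts: 0.0`` for an open site).  Returns a long
    result table (date, source, flux kind columns) and a per-day flag table.
    """
    piv_g = daily_sources.pivot(index="date", columns="microform", values="GPP")
    piv_r = daily_sources.pivot(index="date", columns="microform", values="Reco")
    rows = []
    flags = []
    for day in ec_day_df.index:
        if day not in piv_g.index:
            raise ValueError(f"no modelled source fluxes for {day.date()}")
        source_daily = {
            mf: (float(piv_g.loc[day, mf]), float(piv_r.loc[day, mf])) for mf in piv_g.columns
        }
        lai = float(np.atleast_1d(lai_at(day))[0])
        pday = partition_day(
            source_daily,
            shares,
            lai,
            (float(ec_day_df.loc[day, "GPP"]), float(ec_day_df.loc[day, "Reco"])),
            day=day,
        )
        for mf in source_daily:
            rows.append(
                {
                    "date": day,
                    "microform": mf,
                    "GPP": pday.gpp[mf],
                    "Reco": pday.reco[mf],
                    "NEE": pday.nee[mf],
                    "rel_GPP": pday.rel_gpp[mf],
                    "rel_Reco": pday.rel_reco[mf],
                }
            )
        flags.append(
            {"date": day, "fallback_gpp": pday.fallback_gpp, "fallback_reco": pday.fallback_reco}
        )
    return pd.DataFrame(rows), pd.DataFrame(flags)


def contribution_shares(values: Sequence[float]) -> np.ndarray:
    """Percentage shares 100*|v_i| / sum_j |v_j| of annual flux sums."""
    v = np.abs(np.asarray(values, dtype=float))
    total = v.sum()
    if total == 0:
        raise ValueError("all contributions are zero")
    return 100.0 * v / total


def annual_sums(
    partitioned: pd.DataFrame, hydro_year_start: date = date(2020, 11, 1)
) -> pd.DataFrame:
    """Annual per-source sums and percentage shares over the hydrological year.

    Requires a complete year (365/366 daily records per source starting at
    ``hydro_year_start``); missing days raise an error listing the gaps.
    """
    start = pd.Timestamp(hydro_year_start)
    end = start + pd.DateOffset(years=1) - pd.Timedelta(days=1)
    expected = pd.date_range(start, end, freq="D")
    present = pd.DatetimeIndex(partitioned["date"].unique()).sort_values()
    missing = expected.difference(present)
    if len(missing):
        raise ValueError(
            f"{len(missing)} missing days in partitioned series, e.g. {list(missing.date)[:5]}"
        )
    in_year = partitioned[partitioned["date"].isin(expected)]
    annual = in_year.groupby("microform")[["Reco", "GPP", "NEE"]].sum()
    annual["share_Reco"] = contribution_shares(annual["Reco"].to_numpy())
    annual["share_GPP"] = contribution_shares(annual["GPP"].to_numpy())
    return annual.reset_index()
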