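"""Assembly of chamber observations into ecosystem-scale composite fluxes
and their regression against matched eddy-covariance half-hours.

A composite flux combines one hummock and one hollow observation (two such
pairs at the tree site, plus a leaf-area-weighted branch flux during the
vegetation period), each weighted by its areal share.  Composites are then
matched to EC half-hours under PAR and time criteria and compared by OLS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.diagnostic import linear_rainbow

from .chamber import FluxObservation
from .constants import PAR_UMOL_PER_W

__all__ = [
    "PairingThresholds",
    "CompositeFlux",
    "build_groups",
    "match_ec",
    "compare",
]

log = logging.getLogger(__name__)

LIGHT_TYPES = ("NEE", "GPP")
VEGETATION_MONTHS = (5, 6, 7, 8, 9, 10)


@dataclass(frozen=True)
class PairingThresholds:
    """Pairing thresholds and tolerances for chamber and EC fluxes."""

    par_threshold_wm2: float = 150.0  # minimum PAR for light fluxes, W m-2
    d_par_rel: float = 0.20  # maximum relative PAR difference
    d_t_air: float = 2.0  # degC, light fluxes
    d_t_soil: float = 2.0  # degC, respiration
    chamber_tolerance_min: float = 90.0  # minutes between paired chamber fluxes
    ec_tolerance_days: float = 4.0  # days between composite and EC half-hour
    ec_daytime_tolerance_h: float = 2.0  # clock-time-of-day difference, hours

    def __post_init__(self) -> None:
        for name, value in vars(self).items():
            if value <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def par_threshold_umol(self) -> float:
        return self.par_threshold_wm2 * PAR_UMOL_PER_W


@dataclass
class CompositeFlux:
    """Share/LAI-weighted ecosystem-scale flux assembled from chamber members."""

    site_id: str
    flux_type: str
    timestamp: pd.Timestamp
    value: float  # g CO2-C m-2 30 min-1
    par: float  # umol m-2 s-1 (NaN for Reco)
    t_air: float
    t_soil: float
    members: list[tuple[str, int, float]]  # (microform, observation index, weight)


def _rel_dpar(p1: float, p2: float) -> float:
    return abs(p1 - p2) / max(p1, p2)


class _Rec:
    """Internal running aggregate of a (partial) composite."""

    __slots__ = ("time", "par", "t_air", "t_soil", "value", "members", "n")

    def __init__(self, time, par, t_air, t_soil, value, members, n=1):
        self.time, self.par, self.t_air, self.t_soil = time, par, t_air, t_soil
        self.value, self.members, self.n = value, members, n


def _obs_rec(df: pd.DataFrame, idx, weight: float) -> _Rec:
    row = df.loc[idx]
    return _Rec(
        time=row["timestamp"],
        par=row["PAR"],
        t_air=row["T_air"],
        t_soil=row["T_soil"],
        value=weight * row["flux"],
        members=[(row["microform"], idx, weight)],
    )


def _merge(a: _Rec, b: _Rec) -> _Rec:
    n = a.n + b.n
    mean_t = a.time + (b.time - a.time) * (b.n / n)
    return _Rec(
        time=mean_t,
        par=(a.par * a.n + b.par * b.n) / n,
        t_air=(a.t_air * a.n + b.t_air * b.n) / n,
        t_soil=(a.t_soil * a.n + b.t_soil * b.n) / n,
        value=a.value + b.value,
        members=a.members + b.members,
        n=n,
    )


def _admissible(a: _Rec, b: _Rec, flux_type: str, thr: PairingThresholds) -> float | None:
    """Match quality of two records, or None if any threshold is violated."""
    dt = abs(a.time - b.time)
    if dt > pd.Timedelta(minutes=thr.chamber_tolerance_min):
        return None
    if flux_type in LIGHT_TYPES:
        if np.isnan(a.par) or np.isnan(b.par):
            return None
        if a.par < thr.par_threshold_umol or b.par < thr.par_threshold_umol:
            return None
        dpar = _rel_dpar(a.par, b.par)
        if dpar > thr.d_par_rel:
            return None
        if abs(a.t_air - b.t_air) > thr.d_t_air:
            return None
        return dpar
    if abs(a.t_soil - b.t_soil) > thr.d_t_soil:
        return None
    return dt / pd.Timedelta(minutes=1)


def _greedy_merge(
    recs_a: list[_Rec], recs_b: list[_Rec], flux_type: str, thr: PairingThresholds
) -> list[_Rec]:
    """One-to-one greedy matching ordered by match quality."""
    candidates = []
    for i, a in enumerate(recs_a):
        for j, b in enumerate(recs_b):
            q = _admissible(a, b, flux_type, thr)
            if q is not None:
                candidates.append((q, i, j))
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    merged = []
    for q, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        merged.append(_merge(recs_a[i], recs_b[j]))
    return merged


def _pairing_plan(shares: Mapping[str, float]) -> list[tuple[str, str]]:
    """Hummock/hollow partner names grouped by prefix (e.g. nT_, T_)."""
    plan = []
    for name in sorted(shares):
        if name.endswith("hummock"):
            partner = name[: -len("hummock")] + "hollow"
            if partner not in shares:
                raise ValueError(f"no hollow partner for {name!r}")
            plan.append((name, partner))
    if not plan:
        raise ValueError("no hummock/hollow pairs derivable from areal shares")
    return plan


def build_groups(
    obs: Sequence[FluxObservation] | pd.DataFrame,
    site_id: str,
    shares: Mapping[str, float],
    thresholds: PairingThresholds = PairingThresholds(),
    *,
    lai_at=None,
    veg_months: Sequence[int] = VEGETATION_MONTHS,
    strict_branch: bool = False,
) -> list[CompositeFlux]:
    """Assemble quality-controlled observations into composite fluxes.

    Hummock-hollow pairs are formed within the chamber time tolerance under
    the PAR/temperature thresholds, selected by smallest PAR difference
    (NEE, GPP) or smallest time difference (Reco); at a multi-prefix site
    the per-prefix pairs are combined by the same criteria.  Branch fluxes
    are added, weighted by the current LAI (``lai_at`` maps timestamps to
    LAI), for composites in ``veg_months``; with ``strict_branch`` a
    composite lacking a branch member in those months is dropped.  Each
    observation contributes to at most one group per flux type.
    """
    from .chamber import observations_to_frame

    df = obs if isinstance(obs, pd.DataFrame) else observations_to_frame(obs)
    df = df[df["qc_pass"]]  # original index labels are kept for member references
    plan = _pairing_plan(shares)

    groups: list[CompositeFlux] = []
    for flux_type in ("NEE", "Reco", "GPP"):
        sub = df[df["flux_type"] == flux_type]
        if sub.empty:
            continue
        level: list[_Rec] | None = None
        for hum, hol in plan:
            recs_h = [_obs_rec(sub, i, shares[hum]) for i in sub.index[sub["microform"] == hum]]
            recs_l = [_obs_rec(sub, i, shares[hol]) for i in sub.index[sub["microform"] == hol]]
            pairs = _greedy_merge(recs_h, recs_l, flux_type, thresholds)
            level = pairs if level is None else _greedy_merge(level, pairs, flux_type, thresholds)
        if level is None:
            continue

        branch_idx = list(sub.index[sub["microform"] == "branch"])
        used_branch: set = set()
        for rec in sorted(level, key=lambda r: r.time):
            needs_branch = branch_idx and rec.time.month in veg_months and lai_at is not None
            if needs_branch:
                best = None
                for i in branch_idx:
                    if i in used_branch:
                        continue
                    brec = _obs_rec(sub, i, 1.0)
                    q = _admissible(rec, brec, flux_type, thresholds)
                    if q is not None and (best is None or q < best[0]):
                        best = (q, i)
                if best is not None:
                    _, i = best
                    used_branch.add(i)
                    lai = float(np.atleast_1d(lai_at(rec.time))[0])
                    row = sub.loc[i]
                    rec.value += lai * row["flux"]
                    rec.members.append(("branch", i, lai))
                elif strict_branch:
                    continue
            groups.append(
                CompositeFlux(
                    site_id=site_id,
                    flux_type=flux_type,
                    timestamp=rec.time,
                    value=rec.value,
                    par=rec.par if flux_type in LIGHT_TYPES else np.nan,
                    t_air=rec.t_air,
                    t_soil=rec.t_soil,
                    members=rec.members,
                )
            )
    return groups


def match_ec(
    groups: Sequence[CompositeFlux],
    ec: pd.DataFrame,
    thresholds: PairingThresholds = PairingThresholds(),
) -> pd.DataFrame:
    """Match each composite to its best EC half-hour.

    Only original EC records (``qc_flag == 0``, not gapfilled) are
    candidates; a candidate must lie within the day tolerance and the
    clock-time-of-day tolerance, and for light fluxes additionally satisfy
    the PAR threshold and maximum relative PAR difference.  The candidate
    minimising the relative PAR difference (NEE, GPP) or the absolute time
    difference (Reco) wins; unmatched composites are dropped (count logged).

    Returns one row per matched pair with the composite and EC values plus
    the matching context needed for post-hoc threshold checks.
    """
    cand = ec[(ec["qc_flag"] == 0) & (~ec.get("gapfilled", pd.Series(False, index=ec.index)))]
    ts = cand.index
    tod = ts.hour + ts.minute / 60.0
    rows = []
    unmatched = 0
    for g in groups:
        dt_ok = np.abs(ts - g.timestamp) <= pd.Timedelta(days=thresholds.ec_tolerance_days)
        g_tod = g.timestamp.hour + g.timestamp.minute / 60.0
        dtod = np.abs(tod - g_tod)
        dtod = np.minimum(dtod, 24.0 - dtod)
        mask = dt_ok & (dtod <= thresholds.ec_daytime_tolerance_h)
        if g.flux_type in LIGHT_TYPES:
            ec_par = cand["PAR"].to_numpy()
            par_ok = ec_par / PAR_UMOL_PER_W >= thresholds.par_threshold_wm2
            with np.errstate(invalid="ignore", divide="ignore"):
                dpar = np.abs(ec_par - g.par) / np.maximum(ec_par, g.par)
            mask = mask & par_ok & (dpar <= thresholds.d_par_rel)
            quality = dpar
        else:
            quality = np.abs((ts - g.timestamp).total_seconds())
        if not mask.any():
            unmatched += 1
            continue
        pos = np.flatnonzero(mask)
        best = pos[np.argmin(np.asarray(quality)[pos])]
        rows.append(
            {
                "flux_type": g.flux_type,
                "chamber": g.value,
                "ec": float(cand[g.flux_type].iloc[best]),
                "t_chamber": g.timestamp,
                "t_ec": ts[best],
                "par_chamber": g.par,
                "par_ec": float(cand["PAR"].iloc[best]),
            }
        )
    if unmatched:
        log.info("%d of %d composites had no admissible EC half-hour", unmatched, len(groups))
    return pd.DataFrame(rows)


def compare(pairs: pd.DataFrame, *, rainbow_frac: float = 0.5) -> dict[str, dict]:
    """OLS comparison of composite chamber fluxes against matched EC fluxes.

    Per flux type: slope/intercept/r2/n of chamber ~ EC, flux ranges, mean
    offset, and a rainbow linearity test on the data ordered by EC flux
    magnitude.  Requires at least 3 pairs per flux type.
    """
    report: dict[str, dict] = {}
    for flux_type, g in pairs.groupby("flux_type"):
        if len(g) < 3:
            raise ValueError(f"need >= 3 pairs for {flux_type}, got {len(g)}")
        g = g.sort_values("ec", key=lambda s: s.abs()).reset_index(drop=True)
        x = sm.add_constant(g["ec"].to_numpy())
        res = sm.OLS(g["chamber"].to_numpy(), x).fit()
        try:
            rb_stat, rb_p = linear_rainbow(res, frac=rainbow_frac)
        except (ValueError, np.linalg.LinAlgError):
            rb_stat, rb_p = np.nan, np.nan
        report[str(flux_type)] = {
            "slope": float(res.params[1]),
            "intercept": float(res.params[0]),
            "r_squared": float(res.rsquared),
            "n": int(len(g)),
            "rainbow_stat": float(rb_stat),
            "rainbow_p": float(rb_p),
            "chamber_range": [float(g["chamber"].min()), float(g["chamber"].max())],
            "ec_range": [float(g["ec"].min()), float(g["ec"].max())],
            "mean_offset": float((g["chamber"] - g["ec"]).mean()),
        }
    return report
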