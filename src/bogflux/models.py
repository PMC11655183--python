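"""Empirical flux-response models and campaign-wise fitting.

Ecosystem respiration follows an exponential temperature response with a
fixed lower temperature parameter (Lloyd-Taylor form); gross primary
production follows a rectangular-hyperbola light response.  Both are fitted
per microform and measurement campaign and interpolated in time to
reconstruct daily flux densities over a hydrological year.

Units: model parameters are hourly rates (g CO2-C m-2 h-1); reconstructed
daily fluxes are g CO2-C m-2 of source d-1.  The atmospheric sign
convention is used throughout (respiration >= 0, GPP <= 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .constants import KELVIN

__all__ = [
    "T_REF_K",
    "T_ZERO_K",
    "DegenerateFitError",
    "SourceModel",
    "lloyd_taylor",
    "light_response",
    "fit_reco",
    "fit_gpp",
    "fit_campaigns",
    "daily_reconstruct",
]

log = logging.getLogger(__name__)

#: Reference temperature (10 degC) of the basal respiration rate, K.
T_REF_K = 283.15

#: Fixed lower temperature parameter of the respiration response, K.
T_ZERO_K = 227.13

_E0_START = 308.56


class DegenerateFitError(ValueError):
    """Raised when observations cannot support a model fit."""


def lloyd_taylor(t_c, r_ref, e0):
    """Respiration rate at temperature ``t_c`` (degC).

    Parameters
    ----------
    t_c : array_like
        Temperature in degC.
    r_ref : float
        Basal respiration at 10 degC, g CO2-C m-2 h-1.
    e0 : float
        Temperature-sensitivity parameter, K.
    """
    t_k = np.asarray(t_c, dtype=float) + KELVIN
    return r_ref * np.exp(e0 * (1.0 / (T_REF_K - T_ZERO_K) - 1.0 / (t_k - T_ZERO_K)))


def light_response(par, alpha, gp_max):
    """GPP (<= 0) at photon flux density ``par`` (umol m-2 s-1).

    Rectangular hyperbola with initial slope ``alpha`` (g CO2-C m-2 h-1 per
    umol m-2 s-1) saturating at ``-gp_max`` (g CO2-C m-2 h-1).
    """
    par = np.asarray(par, dtype=float)
    denom = alpha * par + gp_max
    safe = np.where(denom > 0, denom, 1.0)
    return np.where(denom > 0, -(alpha * par * gp_max) / safe, 0.0)


def _hyperbola_mag(par, alpha, gp_max):
    denom = np.maximum(alpha * par + gp_max, 1e-300)
    return (alpha * par * gp_max) / denom


def fit_reco(t_c, flux, *, min_n: int = 3, min_spread: float = 2.0) -> tuple[float, float]:
    """Fit (r_ref, e0) to respiration observations.

    ``flux`` in g CO2-C m-2 h-1, ``t_c`` in degC.  Raises
    :class:`DegenerateFitError` for fewer than ``min_n`` observations or a
    temperature spread below ``min_spread`` degC.
    """
    t = np.asarray(t_c, dtype=float)
    y = np.asarray(flux, dtype=float)
    if t.size != y.size:
        raise ValueError("temperature and flux arrays differ in length")
    if t.size < min_n:
        raise DegenerateFitError(f"need >= {min_n} observations, got {t.size}")
    if np.ptp(t) < min_spread:
        raise DegenerateFitError(
            f"temperature spread {np.ptp(t):.2f} degC below {min_spread} degC"
        )
    scale = lloyd_taylor(t, 1.0, _E0_START)
    r0 = float(np.median(y / scale))
    p0 = (max(r0, 1e-6), _E0_START)
    popt, _ = curve_fit(
        lloyd_taylor, t, y, p0=p0, bounds=([0.0, 0.0], [np.inf, 2000.0]), maxfev=20000
    )
    return float(popt[0]), float(popt[1])


def fit_gpp(par, gpp, *, min_n: int = 3) -> tuple[float, float]:
    """Fit (alpha, gp_max) to GPP observations (``gpp`` <= 0 expected).

    The fit is performed on flux magnitudes; the sign is reapplied by
    :func:`light_response`.  All-dark campaigns (no positive PAR) yield the
    zero model ``(0, 0)``.
    """
    p = np.asarray(par, dtype=float)
    y = -np.asarray(gpp, dtype=float)
    if p.size != y.size:
        raise ValueError("PAR and flux arrays differ in length")
    if p.size < min_n:
        raise DegenerateFitError(f"need >= {min_n} observations, got {p.size}")
    lit = p > 0
    if not lit.any() or np.all(np.abs(y[lit]) < 1e-12):
        return 0.0, 0.0
    gp0 = max(float(np.max(y)) * 1.2, 1e-6)
    alpha0 = max(float(np.median(y[lit] / p[lit])) * 2.0, 1e-8)
    popt, _ = curve_fit(
        _hyperbola_mag,
        p,
        y,
        p0=(alpha0, gp0),
        bounds=([0.0, 0.0], [np.inf, np.inf]),
        maxfev=20000,
    )
    return float(popt[0]), float(popt[1])


@dataclass(frozen=True)
class SourceModel:
    """Fitted per-microform, per-campaign flux model parameters."""

    microform: str
    campaign_date: pd.Timestamp
    r_ref: float
    e0: float
    alpha: float
    gp_max: float
    n_reco: int = 0
    n_gpp: int = 0
    rmse_reco: float = np.nan
    rmse_gpp: float = np.nan
    fallback_reco: bool = False
    fallback_gpp: bool = False

    def __post_init__(self) -> None:
        for name in ("r_ref", "e0", "alpha", "gp_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _rmse(pred: np.ndarray, obs: np.ndarray) -> float:
    if obs.size == 0:
        return np.nan
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def fit_campaigns(
    obs: pd.DataFrame,
    *,
    air_temp_sources: Sequence[str] = ("branch",),
) -> list[SourceModel]:
    """Fit respiration and light-response models per microform and campaign.

    ``obs`` is a flux-observation table (see
    :func:`bogflux.chamber.observations_to_frame`): one row per quality-
    controlled flux with columns ``microform``, ``flux_type`` (Reco/NEE/GPP),
    ``flux_per_s``, ``PAR``, ``T_soil``, ``T_air`` and ``timestamp``.
    Campaigns are the calendar dates of the observations.  Microforms listed
    in ``air_temp_sources`` (branch chambers) use air instead of soil
    temperature as the respiration driver.

    Campaigns whose fit is degenerate or fails to converge reuse the
    parameters of the nearest successful campaign of the same microform and
    are flagged via ``fallback_reco`` / ``fallback_gpp``.
    """
    df = obs[obs["qc_pass"]].copy()
    if df.empty:
        raise ValueError("no quality-controlled observations to fit")
    df["campaign"] = pd.to_datetime(df["timestamp"]).dt.normalize()

    models: list[SourceModel] = []
    for microform, mf_obs in df.groupby("microform", sort=True):
        t_col = "T_air" if microform in air_temp_sources else "T_soil"
        rows = []
        for day, g in mf_obs.groupby("campaign", sort=True):
            reco = g[g["flux_type"] == "Reco"]
            gppo = g[g["flux_type"] == "GPP"]
            entry: dict = {
                "campaign_date": day,
                "n_reco": len(reco),
                "n_gpp": len(gppo),
            }
            try:
                r_ref, e0 = fit_reco(reco[t_col].to_numpy(), reco["flux_per_s"].to_numpy() * 3600.0)
                entry["reco"] = (r_ref, e0)
                entry["rmse_reco"] = _rmse(
                    lloyd_taylor(reco[t_col].to_numpy(), r_ref, e0),
                    reco["flux_per_s"].to_numpy() * 3600.0,
                )
            except (DegenerateFitError, RuntimeError) as exc:
                log.info("Reco fit fallback for %s @ %s: %s", microform, day.date(), exc)
                entry["reco"] = None
            try:
                alpha, gp_max = fit_gpp(gppo["PAR"].to_numpy(), gppo["flux_per_s"].to_numpy() * 3600.0)
                entry["gpp"] = (alpha, gp_max)
                entry["rmse_gpp"] = _rmse(
                    -_hyperbola_mag(gppo["PAR"].to_numpy(), alpha, gp_max),
                    gppo["flux_per_s"].to_numpy() * 3600.0,
                )
            except (DegenerateFitError, RuntimeError) as exc:
                log.info("GPP fit fallback for %s @ %s: %s", microform, day.date(), exc)
                entry["gpp"] = None
            rows.append(entry)

        good_reco = [r for r in rows if r["reco"] is not None]
        good_gpp = [r for r in rows if r["gpp"] is not None]
        if not good_reco:
            raise DegenerateFitError(f"no successful respiration fit for {microform!r}")
        if not good_gpp:
            raise DegenerateFitError(f"no successful GPP fit for {microform!r}")

        def _nearest(pool, day, key):
            best = min(pool, key=lambda r: abs((r["campaign_date"] - day).days))
            return best[key]

        for r in rows:
            fb_reco = r["reco"] is None
            fb_gpp = r["gpp"] is None
            r_ref, e0 = r["reco"] if not fb_reco else _nearest(good_reco, r["campaign_date"], "reco")
            alpha, gp_max = r["gpp"] if not fb_gpp else _nearest(good_gpp, r["campaign_date"], "gpp")
            models.append(
                SourceModel(
                    microform=str(microform),
                    campaign_date=r["campaign_date"],
                    r_ref=r_ref,
                    e0=e0,
                    alpha=alpha,
                    gp_max=gp_max,
                    n_reco=r["n_reco"],
                    n_gpp=r["n_gpp"],
                    rmse_reco=r.get("rmse_reco", np.nan),
                    rmse_gpp=r.get("rmse_gpp", np.nan),
                    fallback_reco=fb_reco,
                    fallback_gpp=fb_gpp,
                )
            )
    return models


def models_to_frame(models: Iterable[SourceModel]) -> pd.DataFrame:
    """Tabulate fitted models (one row per microform and campaign)."""
    return pd.DataFrame(
        [
            {
                "microform": m.microform,
                "campaign_date": m.campaign_date,
                "r_ref": m.r_ref,
                "e0": m.e0,
                "alpha": m.alpha,
                "gp_max": m.gp_max,
                "n_reco": m.n_reco,
                "n_gpp": m.n_gpp,
                "rmse_reco": m.rmse_reco,
                "rmse_gpp": m.rmse_gpp,
                "fallback_reco": m.fallback_reco,
                "fallback_gpp": m.fallback_gpp,
            }
            for m in models
        ]
    )


def _check_halfhourly(index: pd.DatetimeIndex) -> None:
    diffs = np.diff(index.view("int64"))
    if len(diffs) and not np.all(diffs == 1800 * 10**9):
        raise ValueError("driver series has gaps or is not half-hourly")


def daily_reconstruct(
    models: Sequence[SourceModel],
    drivers: pd.DataFrame,
    span: tuple,
    *,
    air_temp_sources: Sequence[str] = ("branch",),
    interp: str = "linear",
) -> pd.DataFrame:
    """Reconstruct daily source fluxes over ``span`` (start, end dates, inclusive).

    Model parameters are interpolated between campaign midpoints (held
    constant beyond the first/last campaign); with ``interp='constant'``
    each campaign's parameters apply as blocks up to the midpoint between
    campaigns.  Half-hourly fluxes are evaluated from the drivers and
    integrated to daily sums.

    Returns a long table with columns ``date``, ``microform``, ``GPP``,
    ``Reco`` and ``NEE`` (g CO2-C m-2 of source d-1; branch per m2 leaf).
    """
    if interp not in ("linear", "constant"):
        raise ValueError(f"unknown interpolation mode {interp!r}")
    start = pd.Timestamp(span[0])
    end = pd.Timestamp(span[1])
    window = drivers.loc[start : end + pd.Timedelta(days=1) - pd.Timedelta(minutes=30)]
    if window.empty:
        raise ValueError("drivers do not cover the requested span")
    _check_halfhourly(window.index)
    expected = pd.date_range(start, end + pd.Timedelta(hours=23, minutes=30), freq="30min")
    if len(window) != len(expected):
        raise ValueError("drivers do not fully cover the requested span")

    x = window.index.view("int64").astype(float)
    frames = []
    by_mf: dict[str, list[SourceModel]] = {}
    for m in models:
        by_mf.setdefault(m.microform, []).append(m)
    for microform in sorted(by_mf):
        group = sorted(by_mf[microform], key=lambda m: m.campaign_date)
        # campaign midpoint = campaign day at 12:00
        xp = np.array(
            [(m.campaign_date + pd.Timedelta(hours=12)).value for m in group], dtype=float
        )
        params = np.array([[m.r_ref, m.e0, m.alpha, m.gp_max] for m in group], dtype=float)
        if interp == "linear" or len(group) == 1:
            cols = [np.interp(x, xp, params[:, k]) for k in range(4)]
        else:
            edges = (xp[:-1] + xp[1:]) / 2.0
            idx = np.searchsorted(edges, x, side="right")
            cols = [params[idx, k] for k in range(4)]
        r_ref_t, e0_t, alpha_t, gp_max_t = cols
        t_col = "T_air" if microform in air_temp_sources else "T_soil"
        reco = lloyd_taylor(window[t_col].to_numpy(), r_ref_t, e0_t) / 2.0
        gpp = light_response(window["PAR"].to_numpy(), alpha_t, gp_max_t) / 2.0
        daily = (
            pd.DataFrame({"GPP": gpp, "Reco": reco}, index=window.index)
            .groupby(window.index.normalize())
            .sum()
        )
        daily.index.name = "date"
        daily = daily.reset_index()
        daily["microform"] = microform
        frames.append(daily)
    out = pd.concat(frames, ignore_index=True)
    out["NEE"] = out["GPP"] + out["Reco"]
    return out[["date", "microform", "GPP", "Reco", "NEE"]]
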