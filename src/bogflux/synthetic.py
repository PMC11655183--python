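"""Synthetic drivers, eddy-covariance series and chamber campaigns.

Generates half-hourly meteorological drivers, per-microform "true" flux
densities, an ecosystem-scale eddy-covariance (EC) series that is their
areal/LAI-weighted sum, and 1 Hz chamber concentration traces whose slope
encodes the true flux through the ideal-gas relation.  Every stage of the
processing pipeline can therefore be validated against known truth without
any field data.

All randomness is driven by explicit seeds; identical seeds give
bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chamber import ChamberTrace
from .constants import DEFAULT_MEAN_LEAF_AREA, KELVIN, M_C, R_GAS
from .models import light_response, lloyd_taylor

__all__ = [
    "MicroformSpec",
    "SiteScenario",
    "open_site_scenario",
    "tree_site_scenario",
    "generate_drivers",
    "true_flux",
    "generate_ec",
    "generate_campaign",
]

BRANCH = "branch"


@dataclass(frozen=True)
class MicroformSpec:
    """One flux source: a ground microform or the birch-branch canopy.

    Flux parameters are per m2 of source (per m2 leaf for the branch
    source); ``areal_share`` is the fraction of ground area (0 for the
    branch source, which is weighted by leaf area index instead).
    """

    name: str
    areal_share: float
    r_ref: float  # g CO2-C m-2 h-1 at 10 degC
    e0: float  # K
    alpha: float  # g CO2-C m-2 h-1 per umol m-2 s-1
    gp_max: float  # g CO2-C m-2 h-1
    ch4_annual: float = 0.0  # g CH4-C m-2 yr-1
    ch4_sd: float = 0.0
    wl_offset: float = 0.0  # m relative to site mean water level

    def __post_init__(self) -> None:
        if self.r_ref <= 0:
            raise ValueError("r_ref must be > 0")
        if self.e0 < 0 or self.alpha < 0 or self.gp_max < 0:
            raise ValueError("e0, alpha and gp_max must be >= 0")
        if not 0.0 <= self.areal_share <= 1.0:
            raise ValueError("areal_share must be within [0, 1]")
        if self.ch4_sd < 0:
            raise ValueError("ch4_sd must be >= 0")

    @property
    def is_branch(self) -> bool:
        return self.name == BRANCH


@dataclass(frozen=True)
class SiteScenario:
    """Complete description of one synthetic site."""

    site_id: str
    microforms: tuple[MicroformSpec, ...]
    tree_lai_series: tuple[tuple[pd.Timestamp, float], ...] = ()
    hydro_year_start: date = date(2020, 11, 1)
    mean_t_air: float = 9.9
    seed: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "microforms", tuple(self.microforms))
        lai = tuple((pd.Timestamp(d), float(v)) for d, v in self.tree_lai_series)
        object.__setattr__(self, "tree_lai_series", lai)
        total = sum(m.areal_share for m in self.ground_microforms)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"ground areal shares sum to {total}, expected 1")
        if any(v < 0 for _, v in lai):
            raise ValueError("LAI must be >= 0")
        dates = [d for d, _ in lai]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError("LAI dates must be strictly increasing")

    @property
    def ground_microforms(self) -> tuple[MicroformSpec, ...]:
        return tuple(m for m in self.microforms if not m.is_branch)

    @property
    def branch(self) -> MicroformSpec | None:
        for m in self.microforms:
            if m.is_branch:
                return m
        return None

    @property
    def shares(self) -> dict[str, float]:
        return {m.name: m.areal_share for m in self.ground_microforms}

    def lai_at(self, timestamps) -> np.ndarray:
        """Tree LAI linearly interpolated between observations, 0 outside."""
        ts = pd.DatetimeIndex(np.atleast_1d(np.asarray(timestamps, dtype="datetime64[ns]")))
        if not self.tree_lai_series:
            return np.zeros(len(ts))
        xp = np.array([d.value for d, _ in self.tree_lai_series], dtype=float)
        fp = np.array([v for _, v in self.tree_lai_series], dtype=float)
        x = ts.view("int64").astype(float)
        out = np.interp(x, xp, fp)
        out[(x < xp[0]) | (x > xp[-1])] = 0.0
        return out


def _biweekly_lai(start: str, end: str, peak: float) -> tuple[tuple[pd.Timestamp, float], ...]:
    dates = pd.date_range(start, end, freq="14D")
    frac = (dates - dates[0]) / (dates[-1] - dates[0])
    lai = peak * np.sin(np.pi * np.asarray(frac, dtype=float))
    return tuple((d, max(float(v), 0.0)) for d, v in zip(dates, lai))


def open_site_scenario(seed: int = 1) -> SiteScenario:
    """Open bog: two ground microforms, no trees (hollow 56.5%, hummock 43.5%)."""
    microforms = (
        MicroformSpec("hollow", 0.565, 0.030, 250.0, 0.0009, 0.30, ch4_annual=50.0, ch4_sd=5.0, wl_offset=0.10),
        MicroformSpec("hummock", 0.435, 0.060, 300.0, 0.0011, 0.45, ch4_annual=25.0, ch4_sd=4.0, wl_offset=0.0),
    )
    return SiteScenario("open", microforms, seed=seed)


def tree_site_scenario(seed: int = 2) -> SiteScenario:
    """Birch-encroached bog: four ground microforms plus a branch source."""
    microforms = (
        MicroformSpec("nT_hollow", 0.190, 0.045, 280.0, 0.0006, 0.18, ch4_annual=12.0, ch4_sd=2.0, wl_offset=0.08),
        MicroformSpec("T_hollow", 0.191, 0.050, 290.0, 0.0005, 0.16, ch4_annual=12.0, ch4_sd=2.0, wl_offset=0.10),
        MicroformSpec("nT_hummock", 0.310, 0.095, 320.0, 0.0007, 0.22, ch4_annual=4.0, ch4_sd=1.0, wl_offset=-0.04),
        MicroformSpec("T_hummock", 0.309, 0.105, 330.0, 0.00065, 0.21, ch4_annual=4.0, ch4_sd=1.0, wl_offset=-0.08),
        MicroformSpec(BRANCH, 0.0, 0.020, 250.0, 0.0015, 0.50),
    )
    lai = _biweekly_lai("2021-05-01", "2021-10-31", peak=1.0)
    return SiteScenario("tree", microforms, tree_lai_series=lai, mean_t_air=9.9, seed=seed)


def _ar1(rng: np.random.Generator, n: int, sd: float, phi: float) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation ``sd``."""
    if sd == 0:
        return np.zeros(n)
    innov = rng.normal(0.0, sd * math.sqrt(1.0 - phi**2), n)
    out = np.empty(n)
    out[0] = rng.normal(0.0, sd)
    for i in range(1, n):
        out[i] = phi * out[i - 1] + innov[i]
    return out


def generate_drivers(
    scenario: SiteScenario,
    start=None,
    end=None,
    *,
    mean_t_air: float | None = None,
) -> pd.DataFrame:
    """Half-hourly PAR, air/soil temperature and water level series.

    Sinusoidal annual and diurnal cycles with autocorrelated noise; PAR is
    zero outside the day-length window (no light at night).  Defaults to the
    hydrological year starting at ``scenario.hydro_year_start``.
    """
    if start is None:
        start = scenario.hydro_year_start
    if end is None:
        end = pd.Timestamp(start) + pd.Timedelta(days=365)
    start, end = pd.Timestamp(start), pd.Timestamp(end)
    if end <= start:
        raise ValueError("empty driver span")
    ts = pd.date_range(start, end, freq="30min", inclusive="left")

    rng = np.random.default_rng(scenario.seed)
    n = len(ts)
    t_mean = scenario.mean_t_air if mean_t_air is None else mean_t_air
    doy = ts.dayofyear.to_numpy().astype(float)
    hod = ts.hour.to_numpy() + ts.minute.to_numpy() / 60.0

    annual = np.sin(2 * np.pi * (doy - 110.0) / 365.25)
    season = np.sin(2 * np.pi * (doy - 80.0) / 365.25)
    diurnal = np.sin(2 * np.pi * (hod - 9.0) / 24.0)  # peaks at 15:00

    t_air = t_mean + 9.0 * annual + 4.0 * diurnal + _ar1(rng, n, 1.5, 0.95)
    t_soil = (
        t_mean
        + 5.5 * np.sin(2 * np.pi * (doy - 125.0) / 365.25)
        + 1.5 * diurnal
        + _ar1(rng, n, 0.5, 0.98)
    )

    daylength = 12.0 + 4.5 * season
    sunrise = 12.0 - daylength / 2.0
    phase = (hod - sunrise) / daylength
    solar = np.where((phase > 0) & (phase < 1), np.sin(np.pi * phase), 0.0)
    cloud = np.clip(0.7 + 0.3 * _ar1(rng, n, 1.0, 0.97), 0.15, 1.0)
    par = 1800.0 * (0.7 + 0.3 * season) * solar * cloud
    par = np.clip(par, 0.0, None)

    wl = -0.14 + 0.06 * np.sin(2 * np.pi * (doy - 30.0) / 365.25) + _ar1(rng, n, 0.02, 0.995)

    drivers = pd.DataFrame(
        {"PAR": par, "T_air": t_air, "T_soil": t_soil, "WL": wl}, index=ts
    )
    drivers.index.name = "timestamp"
    return drivers


def true_flux(mf: MicroformSpec, drivers: pd.DataFrame) -> pd.DataFrame:
    """Per-step GPP and Reco densities, g CO2-C m-2 of source per 30 min.

    Ground microforms respond to soil temperature, the branch source to air
    temperature; both use the ambient PAR of the drivers.
    """
    if (drivers["PAR"].to_numpy() < 0).any():
        raise ValueError("negative PAR in drivers")
    t = drivers["T_air"] if mf.is_branch else drivers["T_soil"]
    reco = lloyd_taylor(t.to_numpy(), mf.r_ref, mf.e0) / 2.0
    gpp = light_response(drivers["PAR"].to_numpy(), mf.alpha, mf.gp_max) / 2.0
    return pd.DataFrame({"GPP": gpp, "Reco": reco}, index=drivers.index)


def generate_ec(
    scenario: SiteScenario,
    drivers: pd.DataFrame,
    *,
    noise_sd: float = 0.0,
    gap_fraction: float = 0.0,
    seed: int | None = None,
    qc_probs: Sequence[float] = (0.7, 0.2, 0.1),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic EC record series plus its gap-free "gapfilled" twin.

    EC NEE is the areal-share-weighted sum of ground-microform fluxes plus
    the LAI-weighted branch flux, with optional Gaussian noise (added to the
    respiration component so that ``NEE = GPP + Reco`` holds exactly and
    Reco stays >= 0).  Returns ``(ec, ec_filled)`` where ``ec`` has the gap
    rows removed and ``ec_filled`` is complete with ``gapfilled`` flags
    (standing in for an external gap-filling step).
    """
    if not 0.0 <= gap_fraction < 1.0:
        raise ValueError("gap_fraction must be in [0, 1)")
    total = sum(m.areal_share for m in scenario.ground_microforms)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"ground areal shares sum to {total}, expected 1")

    rng = np.random.default_rng(scenario.seed + 1 if seed is None else seed)
    n = len(drivers)
    gpp_w = np.zeros(n)
    reco_w = np.zeros(n)
    for mf in scenario.ground_microforms:
        f = true_flux(mf, drivers)
        gpp_w += mf.areal_share * f["GPP"].to_numpy()
        reco_w += mf.areal_share * f["Reco"].to_numpy()
    if scenario.branch is not None:
        lai = scenario.lai_at(drivers.index)
        f = true_flux(scenario.branch, drivers)
        gpp_w += lai * f["GPP"].to_numpy()
        reco_w += lai * f["Reco"].to_numpy()

    if noise_sd > 0:
        reco_obs = np.clip(reco_w + rng.normal(0.0, noise_sd, n), 0.0, None)
    else:
        reco_obs = reco_w
    nee = gpp_w + reco_obs
    qc = rng.choice(np.array([0, 1, 2]), size=n, p=np.asarray(qc_probs, dtype=float))
    gaps = rng.random(n) < gap_fraction

    ec = pd.DataFrame(
        {
            "NEE": nee,
            "GPP": gpp_w,
            "Reco": reco_obs,
            "PAR": drivers["PAR"].to_numpy(),
            "qc_flag": qc,
            "gapfilled": False,
        },
        index=drivers.index,
    )
    ec.index.name = "timestamp"
    ec_filled = ec.copy()
    ec_filled["gapfilled"] = gaps
    return ec[~gaps], ec_filled


def _slope_from_flux(
    flux_per_s: float, t_air_c: float, pressure: float, volume: float, source_area: float
) -> float:
    """Invert the ideal-gas flux relation: g CO2-C m-2 s-1 -> ppm s-1."""
    return flux_per_s * (R_GAS * (t_air_c + KELVIN) * source_area) / (
        1e-6 * pressure * volume * M_C
    )


def generate_campaign(
    scenario: SiteScenario,
    drivers: pd.DataFrame,
    campaign_dates: Iterable,
    *,
    closures_per_plot: int = 4,
    analyzer_sd_ppm: float = 0.0,
    seed: int | None = None,
    volume: float = 0.3,
    area: float = 0.75,
    branch_radius: float = 0.095,
    branch_height: float = 0.40,
    leaf_count: int = 30,
    mean_leaf_area: float = DEFAULT_MEAN_LEAF_AREA,
    pressure: float = 101325.0,
    co2_ambient: float = 420.0,
    par_attenuation: float = 0.05,
) -> list[ChamberTrace]:
    """Chamber concentration traces for a set of campaign days.

    For every microform, closure slot and chamber type (transparent then
    opaque 5 min later) a 120-180 s trace at 1 Hz is produced whose linear
    slope encodes the true flux at that half-hour.  Transparent chambers see
    PAR attenuated by ``par_attenuation`` (recorded PAR is the outside
    value); branch traces carry a leaf count and are generated per leaf
    area.  Closures are spread from pre-dawn to afternoon.
    """
    if closures_per_plot < 1:
        raise ValueError("closures_per_plot must be >= 1")
    rng = np.random.default_rng(scenario.seed + 2 if seed is None else seed)
    slots = np.round(np.linspace(4.5, 15.0, closures_per_plot) * 2.0) / 2.0
    branch_volume = math.pi * branch_radius**2 * branch_height
    branch_area = math.pi * branch_radius**2

    traces: list[ChamberTrace] = []
    for day in campaign_dates:
        day = pd.Timestamp(day).normalize()
        for mf in scenario.microforms:
            plot_id = f"{scenario.site_id}_{mf.name}"
            for slot in slots:
                ts0 = day + pd.Timedelta(hours=float(slot))
                if ts0 not in drivers.index:
                    raise ValueError(f"campaign time {ts0} outside driver span")
                env = drivers.loc[ts0]
                t_air = float(env["T_air"])
                t_soil = float(env["T_soil"])
                par_out = float(env["PAR"])
                t_resp = t_air if mf.is_branch else t_soil
                reco_h = float(lloyd_taylor(t_resp, mf.r_ref, mf.e0))
                par_in = (1.0 - par_attenuation) * par_out
                gpp_h = float(light_response(par_in, mf.alpha, mf.gp_max))

                if mf.is_branch:
                    vol, geom_area = branch_volume, branch_area
                    source_area = leaf_count * mean_leaf_area
                    lc: int | None = leaf_count
                else:
                    vol, geom_area = volume, area
                    source_area = area
                    lc = None

                for chamber_type, flux_h, offset in (
                    (BRANCH if mf.is_branch else "transparent", gpp_h + reco_h, 0),
                    ("opaque", reco_h, 5),
                ):
                    duration = int(rng.integers(120, 181))
                    slope = _slope_from_flux(flux_h / 3600.0, t_air, pressure, vol, source_area)
                    t = np.arange(duration, dtype=float)
                    co2 = co2_ambient + slope * t
                    if analyzer_sd_ppm > 0:
                        co2 = co2 + rng.normal(0.0, analyzer_sd_ppm, duration)
                    traces.append(
                        ChamberTrace(
                            plot_id=plot_id,
                            site_id=scenario.site_id,
                            microform=mf.name,
                            chamber_type=chamber_type,
                            start_time=ts0 + pd.Timedelta(minutes=offset),
                            t=t,
                            co2=co2,
                            volume=vol,
                            area=geom_area,
                            t_air_inside=t_air,
                            pressure=pressure,
                            par_outside=None if chamber_type == "opaque" else par_out,
                            t_soil=t_soil,
                            leaf_count=lc,
                        )
                    )
    return traces
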