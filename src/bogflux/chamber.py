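"""Closed-chamber CO2 flux computation with quality control.

A chamber closure yields a 1 Hz CO2 concentration trace.  The flux is the
ordinary-least-squares slope of the best (maximum r2) moving window after a
deadband, converted to a mass flux through the ideal-gas law.  Fluxes whose
magnitude falls below the minimal detectable flux for the analyzer noise
level are set to zero.  Transparent chambers yield NEE, opaque chambers
Reco; branch chambers are normalised to the enclosed leaf area.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .constants import DEFAULT_MEAN_LEAF_AREA, KELVIN, M_C, R_GAS, SECONDS_PER_HALFHOUR

__all__ = [
    "ChamberTrace",
    "FluxObservation",
    "ChamberParams",
    "WindowFit",
    "select_window",
    "compute_flux",
    "minimal_detectable_flux",
    "process_trace",
    "qc_filter",
    "derive_gpp",
    "process_campaign",
    "observations_to_frame",
]

log = logging.getLogger(__name__)

CHAMBER_TYPES = ("opaque", "transparent", "branch")


@dataclass
class ChamberTrace:
    """One chamber closure: concentration vs time plus geometry and environment.

    ``t`` holds seconds since closure, ``co2`` the dry mole fraction in ppm.
    For branch traces ``area`` is the geometric chamber footprint; the flux
    source area is the enclosed leaf area (``leaf_count`` x mean leaf area).
    """

    plot_id: str
    site_id: str
    microform: str
    chamber_type: str
    start_time: pd.Timestamp
    t: np.ndarray
    co2: np.ndarray
    volume: float  # m3
    area: float  # m2 ground / footprint
    t_air_inside: float  # degC
    pressure: float = 101325.0  # Pa
    par_outside: float | None = None  # umol m-2 s-1; None for opaque
    t_soil: float | None = None  # degC, plot-level
    leaf_count: int | None = None  # branch traces only

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.co2 = np.asarray(self.co2, dtype=float)
        if self.chamber_type not in CHAMBER_TYPES:
            raise ValueError(f"unknown chamber_type {self.chamber_type!r}")
        if self.t.size != self.co2.size:
            raise ValueError("t and co2 differ in length")
        if self.t.size and not np.all(np.diff(self.t) > 0):
            raise ValueError("t must be strictly increasing")
        if self.volume <= 0 or self.area <= 0:
            raise ValueError("volume and area must be > 0")
        if (self.co2 <= 0).any():
            raise ValueError("co2 must be > 0")
        self.start_time = pd.Timestamp(self.start_time)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def is_branch(self) -> bool:
        return self.chamber_type == "branch" or self.microform == "branch"


@dataclass
class FluxObservation:
    """One computed CO2 flux (atmospheric sign convention: positive = emission)."""

    plot_id: str
    site_id: str
    microform: str
    flux_type: str  # NEE | Reco | GPP (GPP only via derive_gpp)
    flux: float  # g CO2-C m-2 30 min-1
    flux_per_s: float  # g CO2-C m-2 s-1
    par: float | None  # umol m-2 s-1, attenuation-corrected (NEE/GPP only)
    t_soil: float | None
    t_air: float
    timestamp: pd.Timestamp
    window: tuple[float, float]
    r_squared: float
    below_mdf: bool = False
    qc_pass: bool = True
    chamber_type: str = "opaque"


@dataclass(frozen=True)
class ChamberParams:
    """Processing parameters for chamber traces (all defaults documented)."""

    window_len: float = 60.0  # s
    step: float = 5.0  # s
    deadband: float = 10.0  # s discarded after closure
    analyzer_sd_ppm: float = 0.0  # 1 Hz analyzer noise level
    mdf_z: float = 1.96  # detection z-level for the minimal detectable flux
    morning_cutoff_hour: int = 10  # local hour below which the morning rule applies
    morning_factor: float = 3.0  # multiple of the campaign median that flags a flux
    mean_leaf_area: float = DEFAULT_MEAN_LEAF_AREA  # m2 per leaf
    par_attenuation: float = 0.05  # in-chamber PAR reduction of transparent chambers


@dataclass(frozen=True)
class WindowFit:
    start: float
    end: float
    slope: float  # ppm s-1
    r_squared: float


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Slope and r2 of an OLS line fit.

    A window with zero concentration variance is a perfect horizontal line:
    slope 0, r2 defined as 1.
    """
    xm = x - x.mean()
    ym = y - y.mean()
    sxx = float(xm @ xm)
    if sxx == 0.0:
        raise ValueError("constant time vector in window")
    syy = float(ym @ ym)
    sxy = float(xm @ ym)
    slope = sxy / sxx
    if syy == 0.0:
        return 0.0, 1.0
    return slope, sxy * sxy / (sxx * syy)


def select_window(
    trace: ChamberTrace,
    window_len: float = 60.0,
    step: float = 5.0,
    deadband: float = 10.0,
) -> WindowFit:
    """Best OLS window of the trace (maximum r2, ties broken by earliest start).

    Candidate windows of length ``window_len`` start every ``step`` seconds
    after the ``deadband``; samples are taken from the half-open interval
    ``[start, start + window_len)``.
    """
    t = trace.t - trace.t[0]
    if trace.duration < deadband + window_len:
        raise ValueError(
            f"trace of {trace.duration:.0f} s too short for deadband {deadband} s "
            f"+ window {window_len} s"
        )
    best: WindowFit | None = None
    start = deadband
    while start + window_len <= trace.duration + 1e-9:
        mask = (t >= start - 1e-9) & (t < start + window_len - 1e-9)
        if mask.sum() >= 3:
            slope, r2 = _ols(t[mask], trace.co2[mask])
            if best is None or r2 > best.r_squared + 1e-12:
                best = WindowFit(start, start + window_len, slope, r2)
        start += step
    if best is None:
        raise ValueError("no candidate window with >= 3 samples")
    return best


def _source_area(trace: ChamberTrace, mean_leaf_area: float) -> float:
    if trace.is_branch:
        if trace.leaf_count is None:
            raise ValueError("branch trace without leaf_count")
        return trace.leaf_count * mean_leaf_area
    return trace.area


def compute_flux(
    trace: ChamberTrace,
    slope: float,
    *,
    mean_leaf_area: float = DEFAULT_MEAN_LEAF_AREA,
) -> float:
    """Convert a concentration slope (ppm s-1) to g CO2-C m-2 s-1.

    flux = slope * 1e-6 * p V / (R T A) * M_C with the source area A being
    the ground area, or the enclosed leaf area for branch traces.  The sign
    of the slope is kept (positive = emission).
    """
    t_k = trace.t_air_inside + KELVIN
    if t_k <= 0:
        raise ValueError("non-physical chamber temperature")
    area = _source_area(trace, mean_leaf_area)
    return slope * 1e-6 * (trace.pressure * trace.volume) / (R_GAS * t_k * area) * M_C


def minimal_detectable_flux(
    trace: ChamberTrace,
    analyzer_sd_ppm: float,
    window_len: float = 60.0,
    *,
    z: float = 1.96,
    mean_leaf_area: float = DEFAULT_MEAN_LEAF_AREA,
) -> float:
    """Smallest flux distinguishable from zero at the analyzer noise level.

    The detection limit of the OLS slope over ``n`` evenly spaced samples in
    a window of length L is z * sd * sqrt(12 / (n * L^2 (n+1)/(n-1))); it is
    converted to a flux with the trace's geometry.
    """
    if analyzer_sd_ppm < 0:
        raise ValueError("analyzer_sd_ppm must be >= 0")
    dt = float(np.median(np.diff(trace.t)))
    n = int(round(window_len / dt))
    if n < 3:
        raise ValueError("fewer than 3 samples in the MDF window")
    slope_min = z * analyzer_sd_ppm * np.sqrt(
        12.0 / (n * (window_len**2 * (n + 1) / (n - 1)))
    )
    return abs(compute_flux(trace, slope_min, mean_leaf_area=mean_leaf_area))


def process_trace(trace: ChamberTrace, params: ChamberParams = ChamberParams()) -> FluxObservation:
    """Full single-trace processing: window selection, flux, MDF screening."""
    fit = select_window(trace, params.window_len, params.step, params.deadband)
    flux_per_s = compute_flux(trace, fit.slope, mean_leaf_area=params.mean_leaf_area)
    below = False
    if params.analyzer_sd_ppm > 0:
        mdf = minimal_detectable_flux(
            trace,
            params.analyzer_sd_ppm,
            params.window_len,
            z=params.mdf_z,
            mean_leaf_area=params.mean_leaf_area,
        )
        if abs(flux_per_s) < mdf:
            flux_per_s = 0.0
            below = True
    flux_type = "Reco" if trace.chamber_type == "opaque" else "NEE"
    par = None
    if trace.par_outside is not None and flux_type == "NEE":
        par = (1.0 - params.par_attenuation) * trace.par_outside
    return FluxObservation(
        plot_id=trace.plot_id,
        site_id=trace.site_id,
        microform=trace.microform,
        flux_type=flux_type,
        flux=flux_per_s * SECONDS_PER_HALFHOUR,
        flux_per_s=flux_per_s,
        par=par,
        t_soil=trace.t_soil,
        t_air=trace.t_air_inside,
        timestamp=trace.start_time,
        window=(fit.start, fit.end),
        r_squared=fit.r_squared,
        below_mdf=below,
        qc_pass=True,
        chamber_type=trace.chamber_type,
    )


def qc_filter(
    obs: Sequence[FluxObservation],
    *,
    cutoff_hour: int = 10,
    factor: float = 3.0,
) -> list[FluxObservation]:
    """Flag implausibly high morning fluxes of transparent chambers.

    An NEE observation before ``cutoff_hour`` whose |flux| exceeds
    ``factor`` times the campaign (same plot, same day) median |flux| is
    marked ``qc_pass = False``; all other observations are returned
    unchanged.  Removal counts are logged.
    """
    out = list(obs)
    medians: dict[tuple, float] = {}
    for o in out:
        if o.flux_type != "NEE":
            continue
        key = (o.plot_id, o.timestamp.normalize())
        medians.setdefault(key, np.nan)
    for key in medians:
        vals = [
            abs(o.flux)
            for o in out
            if o.flux_type == "NEE" and (o.plot_id, o.timestamp.normalize()) == key
        ]
        medians[key] = float(np.median(vals))
    removed = 0
    for i, o in enumerate(out):
        if o.flux_type != "NEE" or o.timestamp.hour >= cutoff_hour:
            continue
        med = medians[(o.plot_id, o.timestamp.normalize())]
        if abs(o.flux) > factor * med:
            out[i] = replace(o, qc_pass=False)
            removed += 1
    if removed:
        log.info("morning-flux rule removed %d of %d observations", removed, len(out))
    return out


def derive_gpp(
    obs_nee: FluxObservation,
    obs_reco_pool: Iterable[FluxObservation],
    *,
    max_gap: pd.Timedelta = pd.Timedelta(hours=2),
) -> FluxObservation | None:
    """GPP = NEE - nearest same-plot Reco within ``max_gap``; None if no candidate."""
    if obs_nee.flux_type != "NEE":
        raise ValueError("derive_gpp expects an NEE observation")
    candidates = [
        o
        for o in obs_reco_pool
        if o.flux_type == "Reco"
        and o.plot_id == obs_nee.plot_id
        and o.qc_pass
        and abs(o.timestamp - obs_nee.timestamp) <= max_gap
    ]
    if not candidates:
        return None
    nearest = min(candidates, key=lambda o: abs(o.timestamp - obs_nee.timestamp))
    return replace(
        obs_nee,
        flux_type="GPP",
        flux=obs_nee.flux - nearest.flux,
        flux_per_s=obs_nee.flux_per_s - nearest.flux_per_s,
        below_mdf=False,
    )


def process_campaign(
    traces: Sequence[ChamberTrace], params: ChamberParams = ChamberParams()
) -> list[FluxObservation]:
    """Process traces to observations, apply the morning rule, derive GPP."""
    obs = [process_trace(tr, params) for tr in traces]
    obs = qc_filter(obs, cutoff_hour=params.morning_cutoff_hour, factor=params.morning_factor)
    gpp = [
        g
        for o in obs
        if o.flux_type == "NEE" and o.qc_pass
        if (g := derive_gpp(o, obs)) is not None
    ]
    return obs + gpp


def observations_to_frame(obs: Iterable[FluxObservation]) -> pd.DataFrame:
    """Flux observations as a flat table (PAR is NaN where not recorded)."""
    rows = [
        {
            "plot_id": o.plot_id,
            "site_id": o.site_id,
            "microform": o.microform,
            "flux_type": o.flux_type,
            "flux": o.flux,
            "flux_per_s": o.flux_per_s,
            "PAR": np.nan if o.par is None else o.par,
            "T_soil": np.nan if o.t_soil is None else o.t_soil,
            "T_air": o.t_air,
            "timestamp": o.timestamp,
            "window_start": o.window[0],
            "window_end": o.window[1],
            "r_squared": o.r_squared,
            "below_mdf": o.below_mdf,
            "qc_pass": o.qc_pass,
            "chamber_type": o.chamber_type,
        }
        for o in obs
    ]
    return pd.DataFrame(rows)
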