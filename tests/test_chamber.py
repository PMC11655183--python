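"""Chamber flux computation: window selection, ideal-gas conversion, MDF, QC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from bogflux.chamber import (
    ChamberParams,
    ChamberTrace,
    FluxObservation,
    compute_flux,
    derive_gpp,
    minimal_detectable_flux,
    process_trace,
    qc_filter,
    select_window,
)

T0 = pd.Timestamp("2021-06-15 10:00")


def make_trace(co2, t=None, duration=180, **kw):
    t = np.arange(duration, dtype=float) if t is None else np.asarray(t, dtype=float)
    co2 = np.asarray(co2, dtype=float)
    defaults = dict(
        plot_id="p1",
        site_id="open",
        microform="hummock",
        chamber_type="opaque",
        start_time=T0,
        t=t,
        co2=co2,
        volume=0.3,
        area=0.75,
        t_air_inside=20.0,
        t_soil=12.0,
    )
    defaults.update(kw)
    return ChamberTrace(**defaults)


def oracle_best_window(trace, window_len=60.0, step=5.0, deadband=10.0):
    """Independent exhaustive enumeration using scipy.stats.linregress."""
    t = trace.t - trace.t[0]
    best = None
    start = deadband
    while start + window_len <= trace.duration + 1e-9:
        mask = (t >= start - 1e-9) & (t < start + window_len - 1e-9)
        if mask.sum() >= 3:
            res = stats.linregress(t[mask], trace.co2[mask])
            r2 = res.rvalue**2
            if best is None or r2 > best[1] + 1e-12:
                best = (start, r2, res.slope)
        start += step
    return best


class TestSelectWindow:
    def test_linear_trace_earliest_window(self):
        tr = make_trace(420.0 + 0.05 * np.arange(180.0))
        fit = select_window(tr)
        assert fit.start == 10.0  # deadband; earliest of the tied windows
        assert fit.slope == pytest.approx(0.05, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_exact_slope_recovery(self):
        tr = make_trace(400.0 + 0.05 * np.arange(150.0), duration=150)
        assert select_window(tr).slope == pytest.approx(0.05, rel=1e-12)

    def test_piecewise_matches_bruteforce(self):
        t = np.arange(180.0)
        co2 = np.where(t < 60, 420 + 0.10 * t, 420 + 0.10 * 60 + 0.02 * (t - 60))
        rng = np.random.default_rng(0)
        co2 = co2 + rng.normal(0, 0.05, t.size)
        tr = make_trace(co2)
        fit = select_window(tr, window_len=60, step=5, deadband=10)
        start, r2, slope = oracle_best_window(tr, 60, 5, 10)
        assert fit.start == start
        assert fit.slope == pytest.approx(slope, rel=1e-9)
        assert fit.r_squared == pytest.approx(r2, rel=1e-9)

    def test_too_short_trace(self):
        tr = make_trace(420 + 0.05 * np.arange(50.0), duration=50)
        with pytest.raises(ValueError, match="too short"):
            select_window(tr)

    def test_constant_time_vector_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            make_trace([420.0, 421.0, 422.0], t=[0.0, 0.0, 0.0])

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_oracle_equivalence_random_traces(self, seed):
        rng = np.random.default_rng(seed)
        slope = rng.uniform(-0.5, 0.5)
        curve = rng.uniform(-0.002, 0.002)
        t = np.arange(int(rng.integers(120, 181)), dtype=float)
        co2 = 420 + slope * t + curve * t**2 + rng.normal(0, 0.3, t.size)
        co2 = np.clip(co2, 1.0, None)
        tr = make_trace(co2, t=t)
        fit = select_window(tr)
        start, r2, oslope = oracle_best_window(tr)
        assert fit.start == start
        assert fit.slope == pytest.approx(oslope, rel=1e-9, abs=1e-12)


class TestComputeFlux:
    def test_hand_evaluated_ideal_gas(self):
        # 0.1e-6 * (101325*0.3) / (8.314*293.15*0.75) * 12.011, frozen by hand
        tr = make_trace(420 + 0.1 * np.arange(180.0), t_air_inside=20.0)
        assert compute_flux(tr, 0.1) == pytest.approx(1.99737e-5, rel=1e-4)
        assert compute_flux(tr, 0.1) == pytest.approx(2.0e-5, rel=0.01)

    def test_zero_slope_zero_flux(self):
        tr = make_trace(np.full(180, 420.0))
        assert compute_flux(tr, 0.0) == 0.0

    def test_doubling_area_halves_flux(self):
        tr1 = make_trace(420 + 0.1 * np.arange(180.0), area=0.75)
        tr2 = make_trace(420 + 0.1 * np.arange(180.0), area=1.5)
        assert compute_flux(tr1, 0.1) == pytest.approx(2 * compute_flux(tr2, 0.1), rel=1e-12)

    def test_sign_kept(self):
        tr = make_trace(np.full(180, 420.0))
        assert compute_flux(tr, -0.1) < 0

    def test_branch_needs_leaf_count(self):
        tr = make_trace(
            420 + 0.1 * np.arange(180.0), chamber_type="branch", microform="branch",
            par_outside=800.0,
        )
        with pytest.raises(ValueError, match="leaf_count"):
            compute_flux(tr, 0.1)

    def test_branch_uses_leaf_area(self):
        tr = make_trace(
            420 + 0.1 * np.arange(180.0), chamber_type="branch", microform="branch",
            par_outside=800.0, leaf_count=10,
        )
        ground = make_trace(420 + 0.1 * np.arange(180.0))
        leaf_area = 10 * 0.0012
        assert compute_flux(tr, 0.1, mean_leaf_area=0.0012) == pytest.approx(
            compute_flux(ground, 0.1) * 0.75 / leaf_area, rel=1e-12
        )


class TestMDF:
    def test_zero_noise_zero_mdf(self):
        tr = make_trace(420 + 0.1 * np.arange(180.0))
        assert minimal_detectable_flux(tr, 0.0) == 0.0

    def test_decreases_with_window_length(self):
        tr = make_trace(420 + 0.1 * np.arange(180.0))
        assert minimal_detectable_flux(tr, 1.0, 120.0) < minimal_detectable_flux(tr, 1.0, 60.0)

    @settings(max_examples=25, deadline=None)
    @given(st.floats(0.0, 5.0), st.floats(0.0, 5.0))
    def test_monotone_in_noise(self, sd1, sd2):
        tr = make_trace(420 + 0.1 * np.arange(180.0))
        lo, hi = sorted([sd1, sd2])
        assert minimal_detectable_flux(tr, lo) <= minimal_detectable_flux(tr, hi)

    def test_too_few_samples(self):
        tr = make_trace([400.0, 401.0, 402.0, 403.0], t=[0.0, 60.0, 120.0, 180.0])
        with pytest.raises(ValueError, match="3 samples"):
            minimal_detectable_flux(tr, 1.0, 60.0)

    def test_strong_flux_not_flagged(self):
        tr = make_trace(420 + 0.5 * np.arange(180.0))
        params = ChamberParams(analyzer_sd_ppm=0.3)
        mdf = minimal_detectable_flux(tr, 0.3)
        obs = process_trace(tr, params)
        assert abs(obs.flux_per_s) > 10 * mdf
        assert not obs.below_mdf

    def test_below_mdf_zeroed(self):
        tr = make_trace(420 + 1e-6 * np.arange(180.0))
        obs = process_trace(tr, ChamberParams(analyzer_sd_ppm=5.0))
        assert obs.below_mdf
        assert obs.flux == 0.0


def make_obs(flux, hour, plot="p1", flux_type="NEE", day="2021-06-15"):
    ts = pd.Timestamp(f"{day} {hour:02d}:00")
    return FluxObservation(
        plot_id=plot,
        site_id="open",
        microform="hummock",
        flux_type=flux_type,
        flux=flux,
        flux_per_s=flux / 1800.0,
        par=900.0 if flux_type in ("NEE", "GPP") else None,
        t_soil=12.0,
        t_air=18.0,
        timestamp=ts,
        window=(10.0, 70.0),
        r_squared=0.99,
        chamber_type="opaque" if flux_type == "Reco" else "transparent",
    )


class TestQCFilter:
    def test_empty(self):
        assert qc_filter([]) == []

    def test_all_equal_none_removed(self):
        obs = [make_obs(-0.1, h) for h in (6, 7, 8, 11, 14)]
        out = qc_filter(obs, factor=1.5)
        assert all(o.qc_pass for o in out)

    def test_single_morning_outlier_removed(self):
        obs = [make_obs(-0.1, h) for h in (11, 12, 13, 14)] + [make_obs(-0.5, 8)]
        out = qc_filter(obs, cutoff_hour=10, factor=3.0)
        flagged = [o for o in out if not o.qc_pass]
        assert len(flagged) == 1
        assert flagged[0].timestamp.hour == 8

    def test_afternoon_outlier_kept(self):
        obs = [make_obs(-0.1, h) for h in (6, 7, 8)] + [make_obs(-0.5, 14)]
        out = qc_filter(obs, cutoff_hour=10, factor=3.0)
        assert all(o.qc_pass for o in out)

    def test_reco_untouched(self):
        obs = [make_obs(5.0, 8, flux_type="Reco"), make_obs(0.1, 8, flux_type="Reco")]
        assert all(o.qc_pass for o in qc_filter(obs))


class TestDeriveGPP:
    def test_subtraction(self):
        nee = make_obs(-0.10, 10)
        reco = make_obs(0.06, 10, flux_type="Reco")
        gpp = derive_gpp(nee, [reco])
        assert gpp.flux == pytest.approx(-0.16)
        assert gpp.flux_type == "GPP"

    def test_none_when_no_reco_within_2h(self):
        nee = make_obs(-0.10, 10)
        reco = make_obs(0.06, 13, flux_type="Reco")
        assert derive_gpp(nee, [reco]) is None

    def test_nearest_candidate_selected(self):
        nee = make_obs(-0.10, 10)
        near = make_obs(0.06, 10)
        near = make_obs(0.06, 10, flux_type="Reco")
        near.timestamp = nee.timestamp + pd.Timedelta(minutes=30)
        far = make_obs(0.20, 10, flux_type="Reco")
        far.timestamp = nee.timestamp + pd.Timedelta(minutes=90)
        gpp = derive_gpp(nee, [far, near])
        assert gpp.flux == pytest.approx(-0.16)

    def test_other_plot_ignored(self):
        nee = make_obs(-0.10, 10)
        reco = make_obs(0.06, 10, plot="other", flux_type="Reco")
        assert derive_gpp(nee, [reco]) is None


class TestSignConvention:
    def test_opaque_traces_positive_fluxes(self, open_scenario, open_drivers, campaign_dates):
        from bogflux.synthetic import generate_campaign

        traces = generate_campaign(open_scenario, open_drivers, campaign_dates[:3])
        for tr in traces:
            if tr.chamber_type == "opaque":
                obs = process_trace(tr)
                assert obs.flux >= 0

    def test_par_attenuation_correction(self, open_scenario, open_drivers, campaign_dates):
        from bogflux.synthetic import generate_campaign

        traces = generate_campaign(open_scenario, open_drivers, campaign_dates[:1])
        tr = next(t for t in traces if t.chamber_type == "transparent")
        obs = process_trace(tr, ChamberParams(par_attenuation=0.05))
        assert obs.par == pytest.approx(0.95 * tr.par_outside)
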