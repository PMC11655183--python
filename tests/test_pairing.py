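"""Composite flux assembly, EC matching and the method-comparison regression."""

import numpy as np
import pandas as pd
import pytest

from bogflux.chamber import FluxObservation
from bogflux.constants import PAR_UMOL_PER_W
from bogflux.pairing import (
    CompositeFlux,
    PairingThresholds,
    build_groups,
    compare,
    match_ec,
)

SHARES = {"hummock": 0.435, "hollow": 0.565}
PAR_OK = 200.0 * PAR_UMOL_PER_W  # comfortably above the 150 W m-2 threshold


def obs(microform, flux, ts, par=PAR_OK, t_air=15.0, t_soil=10.0, flux_type="NEE"):
    return FluxObservation(
        plot_id=f"open_{microform}",
        site_id="open",
        microform=microform,
        flux_type=flux_type,
        flux=flux,
        flux_per_s=flux / 1800.0,
        par=par if flux_type in ("NEE", "GPP") else None,
        t_soil=t_soil,
        t_air=t_air,
        timestamp=pd.Timestamp(ts),
        window=(10.0, 70.0),
        r_squared=0.99,
        chamber_type="opaque" if flux_type == "Reco" else "transparent",
    )


class TestThresholds:
    def test_defaults_positive(self):
        thr = PairingThresholds()
        assert thr.par_threshold_umol == pytest.approx(150 * 4.57)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            PairingThresholds(d_par_rel=0.0)


class TestBuildGroups:
    def test_simple_pair(self):
        o = [
            obs("hummock", -0.10, "2021-06-15 10:00", par=PAR_OK),
            obs("hollow", -0.06, "2021-06-15 10:30", par=PAR_OK * 0.9, t_air=15.5),
        ]
        groups = build_groups(o, "open", SHARES)
        assert len(groups) == 1
        g = groups[0]
        assert g.flux_type == "NEE"
        assert g.value == pytest.approx(0.435 * -0.10 + 0.565 * -0.06)

    def test_par_difference_blocks_pair(self):
        o = [
            obs("hummock", -0.10, "2021-06-15 10:00", par=PAR_OK),
            obs("hollow", -0.06, "2021-06-15 10:30", par=PAR_OK * 0.74),
        ]
        assert build_groups(o, "open", SHARES) == []

    def test_time_tolerance_blocks_pair(self):
        o = [
            obs("hummock", -0.10, "2021-06-15 10:00"),
            obs("hollow", -0.06, "2021-06-15 12:00"),
        ]
        assert build_groups(o, "open", SHARES) == []

    def test_smallest_dpar_candidate_wins(self):
        hum = obs("hummock", -0.10, "2021-06-15 10:00", par=1000.0)
        hollows = [
            obs("hollow", -0.01, "2021-06-15 10:10", par=1000.0 * 0.85),
            obs("hollow", -0.02, "2021-06-15 10:20", par=1000.0 * 0.95),
            obs("hollow", -0.03, "2021-06-15 10:30", par=1000.0 * 0.92),
        ]
        groups = build_groups([hum] + hollows, "open", SHARES)
        assert len(groups) == 1
        # the 5% candidate (-0.02) is chosen by smallest PAR difference
        assert groups[0].value == pytest.approx(0.435 * -0.10 + 0.565 * -0.02)

    def test_reco_pairs_by_time(self):
        hum = obs("hummock", 0.10, "2021-06-15 10:00", flux_type="Reco")
        r1 = obs("hollow", 0.05, "2021-06-15 11:00", flux_type="Reco")
        r2 = obs("hollow", 0.06, "2021-06-15 10:10", flux_type="Reco")
        groups = build_groups([hum, r1, r2], "open", SHARES)
        assert groups[0].value == pytest.approx(0.435 * 0.10 + 0.565 * 0.06)

    def test_reco_t_soil_threshold(self):
        hum = obs("hummock", 0.10, "2021-06-15 10:00", flux_type="Reco", t_soil=10.0)
        hol = obs("hollow", 0.05, "2021-06-15 10:10", flux_type="Reco", t_soil=13.0)
        assert build_groups([hum, hol], "open", SHARES) == []

    def test_no_reuse_within_flux_type(self):
        o = [
            obs("hummock", -0.10, "2021-06-15 10:00"),
            obs("hollow", -0.06, "2021-06-15 10:10"),
            obs("hollow", -0.07, "2021-06-15 10:20"),
        ]
        groups = build_groups(o, "open", SHARES)
        assert len(groups) == 1  # only one hummock available

    def test_composite_is_weighted_member_sum(self, tree_run, tree_scenario):
        groups = build_groups(
            tree_run["obs_df"],
            "tree",
            tree_scenario.shares,
            lai_at=tree_scenario.lai_at,
        )
        assert groups
        df = tree_run["obs_df"]
        for g in groups:
            total = sum(w * df.loc[i, "flux"] for _, i, w in g.members)
            assert g.value == pytest.approx(total, rel=1e-12)

    def test_observation_used_once_per_flux_type(self, tree_run, tree_scenario):
        groups = build_groups(
            tree_run["obs_df"], "tree", tree_scenario.shares, lai_at=tree_scenario.lai_at
        )
        for flux_type in ("NEE", "Reco", "GPP"):
            seen = [
                i for g in groups if g.flux_type == flux_type for _, i, _ in g.members
            ]
            assert len(seen) == len(set(seen))

    def test_branch_included_in_vegetation_period(self, tree_run, tree_scenario):
        groups = build_groups(
            tree_run["obs_df"], "tree", tree_scenario.shares, lai_at=tree_scenario.lai_at
        )
        summer = [g for g in groups if g.timestamp.month in (6, 7, 8)]
        assert any(
            any(m[0] == "branch" for m in g.members) for g in summer
        )
        winter = [g for g in groups if g.timestamp.month in (12, 1, 2)]
        assert all(all(m[0] != "branch" for m in g.members) for g in winter)


def comp(value, ts, flux_type="NEE", par=1000.0):
    return CompositeFlux(
        site_id="open",
        flux_type=flux_type,
        timestamp=pd.Timestamp(ts),
        value=value,
        par=par if flux_type in ("NEE", "GPP") else np.nan,
        t_air=15.0,
        t_soil=10.0,
        members=[],
    )


def ec_frame(timestamps, nee, par):
    idx = pd.DatetimeIndex(timestamps)
    return pd.DataFrame(
        {
            "NEE": nee,
            "GPP": np.asarray(nee) - 0.01,
            "Reco": 0.01,
            "PAR": par,
            "qc_flag": 0,
            "gapfilled": False,
        },
        index=idx,
    )


class TestMatchEC:
    def test_exact_match(self):
        ec = ec_frame(["2021-06-15 10:00"], [-0.1], [1000.0])
        pairs = match_ec([comp(-0.1, "2021-06-15 10:00")], ec)
        assert len(pairs) == 1
        assert pairs["ec"].iloc[0] == pytest.approx(-0.1)

    def test_outside_day_tolerance_unmatched(self):
        ec = ec_frame(["2021-06-20 10:00"], [-0.1], [1000.0])
        assert len(match_ec([comp(-0.1, "2021-06-15 10:00")], ec)) == 0

    def test_daytime_tolerance(self):
        ec = ec_frame(["2021-06-16 15:00"], [-0.1], [1000.0])
        assert len(match_ec([comp(-0.1, "2021-06-15 10:00")], ec)) == 0

    def test_minimises_dpar_over_candidates(self):
        ec = ec_frame(
            ["2021-06-12 10:00", "2021-06-14 10:00"], [-0.2, -0.3], [1030.0, 1010.0]
        )
        pairs = match_ec([comp(-0.1, "2021-06-15 10:00", par=1000.0)], ec)
        assert pairs["ec"].iloc[0] == pytest.approx(-0.3)  # 1% dPAR beats 3%

    def test_qc_nonzero_excluded(self):
        ec = ec_frame(["2021-06-15 10:00"], [-0.1], [1000.0])
        ec["qc_flag"] = 1
        assert len(match_ec([comp(-0.1, "2021-06-15 10:00")], ec)) == 0

    def test_low_par_ec_excluded_for_light(self):
        low = 100.0 * PAR_UMOL_PER_W
        ec = ec_frame(["2021-06-15 10:00"], [-0.1], [low])
        assert len(match_ec([comp(-0.1, "2021-06-15 10:00", par=low)], ec)) == 0

    def test_reco_matches_by_time(self):
        ec = ec_frame(["2021-06-15 09:00", "2021-06-15 10:00"], [0.2, 0.3], [0.0, 0.0])
        ec["Reco"] = [0.2, 0.3]
        pairs = match_ec([comp(0.25, "2021-06-15 09:50", flux_type="Reco")], ec)
        assert pairs["ec"].iloc[0] == pytest.approx(0.3)


class TestCompare:
    def test_identity(self):
        x = np.linspace(-0.3, 0.3, 20)
        pairs = pd.DataFrame({"flux_type": "NEE", "chamber": x, "ec": x})
        rep = compare(pairs)["NEE"]
        assert rep["slope"] == pytest.approx(1.0)
        assert rep["intercept"] == pytest.approx(0.0, abs=1e-12)
        assert rep["r_squared"] == pytest.approx(1.0)

    def test_constant_offset(self):
        x = np.linspace(-0.3, 0.3, 20)
        pairs = pd.DataFrame({"flux_type": "NEE", "chamber": x + 0.05, "ec": x})
        rep = compare(pairs)["NEE"]
        assert rep["slope"] == pytest.approx(1.0)
        assert rep["intercept"] == pytest.approx(0.05)
        assert rep["mean_offset"] == pytest.approx(0.05)

    def test_known_correlation_r_squared(self):
        # simulation oracle: y = 0.8 x + sqrt(1-0.64) e gives population r2 0.64
        rng = np.random.default_rng(7)
        x = rng.standard_normal(200)
        y = 0.8 * x + np.sqrt(1 - 0.64) * rng.standard_normal(200)
        pairs = pd.DataFrame({"flux_type": "NEE", "chamber": y, "ec": x})
        rep = compare(pairs)["NEE"]
        assert 0.54 < rep["r_squared"] < 0.74  # Monte-Carlo CI around 0.64

    def test_too_few_pairs(self):
        pairs = pd.DataFrame({"flux_type": "NEE", "chamber": [0.1, 0.2], "ec": [0.1, 0.2]})
        with pytest.raises(ValueError, match=">= 3"):
            compare(pairs)

    def test_rainbow_reported(self, tree_run, tree_scenario):
        groups = build_groups(
            tree_run["obs_df"], "tree", tree_scenario.shares, lai_at=tree_scenario.lai_at
        )
        pairs = match_ec(groups, tree_run["ec"])
        rep = compare(pairs)
        for stats in rep.values():
            assert "rainbow_p" in stats and stats["n"] >= 3
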