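"""Shared fixtures: synthetic scenarios, drivers and processed artifacts.

Everything is generated programmatically at test time; expensive artifacts
are session-scoped so the suite stays fast.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from bogflux.chamber import ChamberParams, observations_to_frame, process_campaign
from bogflux.models import daily_reconstruct, fit_campaigns
from bogflux.partition import ec_daily, partition_year
from bogflux.synthetic import (
    generate_campaign,
    generate_drivers,
    generate_ec,
    open_site_scenario,
    tree_site_scenario,
)

HYDRO_START = pd.Timestamp("2020-11-01")
HYDRO_END = pd.Timestamp("2021-10-31")


@pytest.fixture(scope="session")
def open_scenario():
    return open_site_scenario(seed=11)


@pytest.fixture(scope="session")
def tree_scenario():
    return tree_site_scenario(seed=12)


@pytest.fixture(scope="session")
def open_drivers(open_scenario):
    return generate_drivers(open_scenario)


@pytest.fixture(scope="session")
def tree_drivers(tree_scenario):
    return generate_drivers(tree_scenario)


@pytest.fixture(scope="session")
def campaign_dates():
    return pd.date_range("2020-11-20", "2021-10-15", periods=14).normalize()


@pytest.fixture(scope="session")
def tree_run(tree_scenario, tree_drivers, campaign_dates):
    """Noiseless end-to-end artifacts for the default tree-site scenario."""
    scenario, drivers = tree_scenario, tree_drivers
    traces = generate_campaign(scenario, drivers, campaign_dates)
    obs = process_campaign(traces, ChamberParams())
    obs_df = observations_to_frame(obs)
    models = fit_campaigns(obs_df)
    daily = daily_reconstruct(models, drivers, (HYDRO_START, HYDRO_END))
    ec, ec_filled = generate_ec(scenario, drivers, gap_fraction=0.1)
    ecd = ec_daily(ec_filled)
    partitioned, flags = partition_year(daily, scenario.shares, scenario.lai_at, ecd)
    return {
        "scenario": scenario,
        "drivers": drivers,
        "traces": traces,
        "obs": obs,
        "obs_df": obs_df,
        "models": models,
        "daily": daily,
        "ec": ec,
        "ec_filled": ec_filled,
        "ec_daily": ecd,
        "partitioned": partitioned,
        "flags": flags,
    }
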