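"""Plain-CSV readers and writers for all pipeline tables.

All tabular I/O uses CSV with documented headers and ISO-8601 timestamps;
fluxes follow the atmospheric sign convention (negative = ecosystem
uptake).  Chamber traces are stored as a per-sample table plus a closure
metadata table keyed by ``trace_id``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chamber import ChamberTrace, FluxObservation, observations_to_frame

__all__ = [
    "write_drivers",
    "read_drivers",
    "write_ec",
    "read_ec",
    "traces_to_frames",
    "frames_to_traces",
    "write_traces",
    "read_traces",
    "write_observations",
    "read_observations",
]


def write_drivers(drivers: pd.DataFrame, path) -> None:
    drivers.to_csv(path, index_label="timestamp")


def read_drivers(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["timestamp"], index_col="timestamp")
    return df


def write_ec(ec: pd.DataFrame, path) -> None:
    ec.to_csv(path, index_label="timestamp")


def read_ec(path) -> pd.DataFrame:
    return pd.read_csv(path, parse_dates=["timestamp"], index_col="timestamp")


def traces_to_frames(traces: Sequence[ChamberTrace]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split traces into a samples table (trace_id, t, co2) and a metadata table."""
    samples = []
    meta = []
    for i, tr in enumerate(traces):
        samples.append(pd.DataFrame({"trace_id": i, "t": tr.t, "co2": tr.co2}))
        meta.append(
            {
                "trace_id": i,
                "plot_id": tr.plot_id,
                "site_id": tr.site_id,
                "microform": tr.microform,
                "chamber_type": tr.chamber_type,
                "start_time": tr.start_time,
                "volume": tr.volume,
                "area": tr.area,
                "T_air_inside": tr.t_air_inside,
                "pressure": tr.pressure,
                "PAR_outside": np.nan if tr.par_outside is None else tr.par_outside,
                "T_soil": np.nan if tr.t_soil is None else tr.t_soil,
                "leaf_count": np.nan if tr.leaf_count is None else tr.leaf_count,
            }
        )
    return pd.concat(samples, ignore_index=True), pd.DataFrame(meta)


def frames_to_traces(samples: pd.DataFrame, meta: pd.DataFrame) -> list[ChamberTrace]:
    traces = []
    grouped = samples.groupby("trace_id")
    for _, row in meta.iterrows():
        g = grouped.get_group(row["trace_id"]).sort_values("t")
        traces.append(
            ChamberTrace(
                plot_id=row["plot_id"],
                site_id=row["site_id"],
                microform=row["microform"],
                chamber_type=row["chamber_type"],
                start_time=pd.Timestamp(row["start_time"]),
                t=g["t"].to_numpy(),
                co2=g["co2"].to_numpy(),
                volume=float(row["volume"]),
                area=float(row["area"]),
                t_air_inside=float(row["T_air_inside"]),
                pressure=float(row["pressure"]),
                par_outside=None if pd.isna(row["PAR_outside"]) else float(row["PAR_outside"]),
                t_soil=None if pd.isna(row["T_soil"]) else float(row["T_soil"]),
                leaf_count=None if pd.isna(row["leaf_count"]) else int(row["leaf_count"]),
            )
        )
    return traces


def write_traces(traces: Sequence[ChamberTrace], samples_path, meta_path) -> None:
    samples, meta = traces_to_frames(traces)
    samples.to_csv(samples_path, index=False)
    meta.to_csv(meta_path, index=False)


def read_traces(samples_path, meta_path) -> list[ChamberTrace]:
    samples = pd.read_csv(samples_path)
    meta = pd.read_csv(meta_path, parse_dates=["start_time"])
    return frames_to_traces(samples, meta)


def write_observations(obs: Iterable[FluxObservation] | pd.DataFrame, path) -> None:
    df = obs if isinstance(obs, pd.DataFrame) else observations_to_frame(obs)
    df.to_csv(path, index=False)


def read_observations(path) -> pd.DataFrame:
    return pd.read_csv(path, parse_dates=["timestamp"])
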