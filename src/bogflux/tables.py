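"""Published annual-balance tables as packaged fixtures, and their validation.

The per-microform annual sums (table2), the site balances (table3) and the
reported cross-site ratios ship with the package as plain CSV.  Every cell
that is derivable from other printed cells (shares, NEE sums, carbon and
GHG balances, ratios) can be recomputed and compared at printed precision.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from . import balances
from .partition import contribution_shares

__all__ = [
    "load_table2",
    "load_table3",
    "load_reported_ratios",
    "validate_tables",
]


def _read_fixture(name: str, as_str: bool = False) -> pd.DataFrame:
    text = resources.files("bogflux.data").joinpath(name).read_text()
    return pd.read_csv(io.StringIO(text), dtype=str if as_str else None)


def load_table2(as_str: bool = False) -> pd.DataFrame:
    """Per-microform annual Reco/GPP/NEE sums and percentage shares."""
    return _read_fixture("table2.csv", as_str)


def load_table3(as_str: bool = False) -> pd.DataFrame:
    """Annual site balances (GPP, Reco, NEE, CH4, carbon, GHG with SDs)."""
    return _read_fixture("table3.csv", as_str)


def load_reported_ratios(as_str: bool = False) -> pd.DataFrame:
    """Reported cross-site percentage ratios."""
    return _read_fixture("reported_ratios.csv", as_str)


def _decimals(printed: str) -> int:
    printed = printed.strip()
    return len(printed.split(".", 1)[1]) if "." in printed else 0


def _tol(printed: str) -> float:
    # 1.5 units of the last printed digit: covers rounding of the printed
    # inputs plus the table-internal rounding inconsistencies of the source.
    return 1.5 * 10.0 ** (-_decimals(printed))


@dataclass(frozen=True)
class Check:
    name: str
    expected: float
    computed: float
    tol: float

    @property
    def passed(self) -> bool:
        return abs(self.computed - self.expected) <= self.tol


def validate_tables(
    table2: pd.DataFrame | None = None,
    table3: pd.DataFrame | None = None,
    ratios: pd.DataFrame | None = None,
    *,
    gwp: float = balances.DEFAULT_GWP_CH4,
) -> pd.DataFrame:
    """Recompute every derivable table cell and compare at printed precision.

    Fixture frames may be passed explicitly (values as strings or floats);
    by default the packaged fixtures are used.  Passing an empty frame
    skips that table's checks; an entirely empty input yields an empty
    report.  Returns a table with columns name/expected/computed/tol/passed.
    """
    t2 = load_table2(as_str=True) if table2 is None else table2.astype(str)
    t3 = load_table3(as_str=True) if table3 is None else table3.astype(str)
    rr = load_reported_ratios(as_str=True) if ratios is None else ratios.astype(str)
    checks: list[Check] = []

    def add(name: str, printed: str, computed: float) -> None:
        checks.append(Check(name, float(printed), float(computed), _tol(printed)))

    if len(t2):
        for site, g in t2.groupby("site", sort=False):
            reco = g["reco"].astype(float).to_numpy()
            gpp = g["gpp"].astype(float).to_numpy()
            nee = g["nee"].astype(float).to_numpy()
            share_r = contribution_shares(reco)
            share_g = contribution_shares(gpp)
            for i, (_, row) in enumerate(g.iterrows()):
                mf = row["microform"]
                add(f"table2/{site}/{mf}/share_reco", row["share_reco"], share_r[i])
                add(f"table2/{site}/{mf}/share_gpp", row["share_gpp"], share_g[i])
                add(
                    f"table2/{site}/{mf}/nee",
                    row["nee"],
                    float(row["gpp"]) + float(row["reco"]),
                )
            if len(t3):
                t3_site = t3[t3["site"] == site]
                if len(t3_site):
                    add(f"table2/{site}/nee_sum", t3_site["nee"].iloc[0], nee.sum())

    if len(t3):
        for _, row in t3.iterrows():
            site = row["site"]
            nee = balances.ValueSD(float(row["nee"]), float(row["nee_sd"]))
            ch4 = balances.ValueSD(float(row["ch4"]), float(row["ch4_sd"]))
            carbon = balances.c_balance(nee, ch4)
            ghg = balances.ghg_balance(nee, ch4, gwp)
            add(f"table3/{site}/carbon", row["carbon"], carbon.value)
            add(f"table3/{site}/carbon_sd", row["carbon_sd"], carbon.sd)
            add(f"table3/{site}/ghg", row["ghg"], ghg.value)
            add(f"table3/{site}/ghg_sd", row["ghg_sd"], ghg.sd)

    if len(rr) and len(t3) >= 2:
        sites = list(t3["site"])
        bal = {
            row["site"]: balances.site_balance(
                row["site"],
                float(row["gpp"]),
                float(row["reco"]),
                (float(row["nee"]), float(row["nee_sd"])),
                (float(row["ch4"]), float(row["ch4_sd"])),
                gwp,
            )
            for _, row in t3.iterrows()
        }
        summary = balances.site_summary(bal[sites[0]], bal[sites[1]])
        reported = dict(zip(rr["name"], rr["value"]))
        if "reco_ratio_pct" in reported:
            add("ratios/reco_ratio_pct", reported["reco_ratio_pct"], summary["reco_ratio_pct"])
        if "gpp_ratio_pct" in reported:
            add("ratios/gpp_ratio_pct", reported["gpp_ratio_pct"], summary["gpp_ratio_pct"])
        for site in sites:
            key = f"ch4_equiv_share_{site}_pct"
            if key in reported:
                add(
                    f"ratios/{key}",
                    reported[key],
                    summary["ch4_equiv_share_pct"][site],
                )

    return pd.DataFrame(
        [
            {
                "check": c.name,
                "expected": c.expected,
                "computed": c.computed,
                "tol": c.tol,
                "passed": c.passed,
            }
            for c in checks
        ]
    )
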