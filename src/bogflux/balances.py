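"""Annual site-level carbon and greenhouse-gas balances.

The carbon balance sums the CO2-C and CH4-C exchange; the GHG balance
expresses both in CO2 equivalents (CH4 weighted by its 100-year global
warming potential) in t CO2-eq ha-1 yr-1.  Standard deviations propagate
in quadrature.  N2O is taken as zero (unfertilised, fully vegetated bog).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

from .constants import (
    CH4_PER_C,
    CO2_PER_C,
    DEFAULT_GWP_CH4,
    G_PER_M2_TO_T_PER_HA,
)

__all__ = [
    "ValueSD",
    "SiteBalance",
    "c_balance",
    "ghg_balance",
    "ch4_equiv_share",
    "site_balance",
    "site_summary",
]


class ValueSD(NamedTuple):
    """A quantity with a standard deviation."""

    value: float
    sd: float = 0.0


def _as_vsd(x) -> ValueSD:
    if isinstance(x, ValueSD):
        return x
    if isinstance(x, (tuple, list)):
        return ValueSD(float(x[0]), float(x[1]))
    return ValueSD(float(x), 0.0)


def c_balance(nee_c, ch4_c) -> ValueSD:
    """Annual carbon balance NEE-C + CH4-C, g C m-2 yr-1, SD in quadrature."""
    nee, ch4 = _as_vsd(nee_c), _as_vsd(ch4_c)
    return ValueSD(nee.value + ch4.value, math.hypot(nee.sd, ch4.sd))


def ghg_balance(
    nee_c,
    ch4_c,
    gwp: float = DEFAULT_GWP_CH4,
    *,
    co2_per_c: float = CO2_PER_C,
    ch4_per_c: float = CH4_PER_C,
) -> ValueSD:
    """Annual GHG balance in t CO2-eq ha-1 yr-1.

    value = (NEE-C * 44/12 + CH4-C * 16/12 * gwp) * 0.01; the SD propagates
    the NEE and CH4 uncertainties in quadrature.  Integer molar-mass ratios
    are the defaults (they reproduce published balance tables); exact atomic
    masses can be passed instead.
    """
    if gwp <= 0:
        raise ValueError("gwp must be > 0")
    nee, ch4 = _as_vsd(nee_c), _as_vsd(ch4_c)
    value = (nee.value * co2_per_c + ch4.value * ch4_per_c * gwp) * G_PER_M2_TO_T_PER_HA
    sd = G_PER_M2_TO_T_PER_HA * math.hypot(nee.sd * co2_per_c, ch4.sd * ch4_per_c * gwp)
    return ValueSD(value, sd)


def ch4_equiv_share(
    nee_c: float,
    ch4_c: float,
    gwp: float = DEFAULT_GWP_CH4,
    *,
    co2_per_c: float = CO2_PER_C,
    ch4_per_c: float = CH4_PER_C,
) -> float:
    """Percentage of total CO2 equivalents attributable to CH4."""
    ch4_eq = abs(ch4_c * ch4_per_c * gwp)
    co2_eq = abs(nee_c * co2_per_c)
    if ch4_eq + co2_eq == 0:
        raise ValueError("both NEE and CH4 are zero")
    return 100.0 * ch4_eq / (ch4_eq + co2_eq)


@dataclass(frozen=True)
class SiteBalance:
    """Annual site balance: CO2 components, CH4, carbon and GHG totals."""

    site_id: str
    gpp: float  # g CO2-C m-2 yr-1
    reco: float
    nee: ValueSD
    ch4: ValueSD  # g CH4-C m-2 yr-1
    carbon: ValueSD  # g C m-2 yr-1
    ghg: ValueSD  # t CO2-eq ha-1 yr-1
    gwp_ch4: float = DEFAULT_GWP_CH4

    def __post_init__(self) -> None:
        for v in (self.nee, self.ch4, self.carbon, self.ghg):
            if v.sd < 0:
                raise ValueError("standard deviations must be >= 0")


def site_balance(site_id, gpp, reco, nee, ch4, gwp: float = DEFAULT_GWP_CH4) -> SiteBalance:
    """Assemble a :class:`SiteBalance` from annual sums and CH4 inputs."""
    nee, ch4 = _as_vsd(nee), _as_vsd(ch4)
    return SiteBalance(
        site_id=site_id,
        gpp=float(gpp),
        reco=float(reco),
        nee=nee,
        ch4=ch4,
        carbon=c_balance(nee, ch4),
        ghg=ghg_balance(nee, ch4, gwp),
        gwp_ch4=gwp,
    )


def site_summary(a: SiteBalance, b: SiteBalance) -> dict:
    """Cross-site ratio report for two site balances.

    Reports b's respiration as a percentage of a's, a's GPP magnitude as a
    percentage of b's, the NEE difference, and per-site CH4 equivalent
    shares, all rounded to integer percentages where printed that way.
    """
    if a.reco == 0 or b.gpp == 0:
        raise ZeroDivisionError("cannot form ratios with zero denominators")
    return {
        "sites": [a.site_id, b.site_id],
        "reco_ratio_pct": round(100.0 * b.reco / a.reco),
        "gpp_ratio_pct": round(100.0 * abs(a.gpp) / abs(b.gpp)),
        "nee_difference": abs(a.nee.value - b.nee.value),
        "ch4_equiv_share_pct": {
            a.site_id: round(ch4_equiv_share(a.nee.value, a.ch4.value, a.gwp_ch4)),
            b.site_id: round(ch4_equiv_share(b.nee.value, b.ch4.value, b.gwp_ch4)),
        },
    }
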