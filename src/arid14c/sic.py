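"""Carbonate (SIC) contribution to incubation-respired CO₂.

Rewetting carbonate-bearing soils can release CO₂ from carbonate
dissolution as well as from SOC decomposition, biasing the apparent
radiocarbon age of respiration. This module partitions respired CO₂ into
SOC- and SIC-derived fractions with a δ¹³C two-endmember mass balance,
adjusts the respired Δ¹⁴C for the carbonate contribution, and applies the
site screening rules:

* SIC content below a floor (default 0.1 mass-%) — assume all respired CO₂
  is SOC-derived (f_SIC = 0).
* f_SIC above an exclusion threshold (default 15%) — exclude the site from
  respiration analyses (the Δ¹⁴C adjustment would be too uncertain).
* Region on a configured exclusion list — dataset-specific judgement calls
  (e.g. dropping the remainder of a region whose gradient coverage collapsed
  after f_SIC exclusions).
* Otherwise the site is included and downstream analysis uses the original,
  unadjusted respired Δ¹⁴C (minor SIC effects are tolerated rather than
  corrected).

The carbonate endmember is the δ¹³C of CO₂ in isotopic *equilibrium* with
calcite, i.e. the measured δ¹³C_SIC minus the calcite–CO₂ fractionation of
9.6‰ at 20 °C (the incubation temperature).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

__all__ = [
    "SICPartition",
    "SIC_STATUSES",
    "sic_equilibrium_d13c",
    "f_sic_from_d13c",
    "adjust_delta14c_for_sic",
    "screen_site",
    "partition_site",
    "SIC_DEFAULTS",
]

#: Calcite–CO₂ equilibrium fractionation at 20 °C (‰).
CALCITE_CO2_OFFSET = 9.6

SIC_STATUSES = (
    "assumed_zero_sic",
    "included_original",
    "excluded_high_fsic",
    "excluded_region",
)

SIC_DEFAULTS = {
    "calcite_co2_offset": CALCITE_CO2_OFFSET,
    "sic_content_floor": 0.1,       # mass-% C
    "f_sic_exclusion": 0.15,
    "d13c_separation_floor": 2.0,   # ‰
    "delta14c_sic_endmember": -1000.0,  # parent-material carbonate, ¹⁴C-dead
    "excluded_regions": (),
}


class FSicEstimate(NamedTuple):
    value: float
    clamped: bool


@dataclass
class SICPartition:
    """Result of the δ¹³C partition and screening for one site."""

    d13c_sic_eq: float | None
    f_sic: float
    f_soc: float
    delta14c_co2_soc: float | None
    status: str
    reason: str = ""
    clamped: bool = False

    def __post_init__(self) -> None:
        if self.status not in SIC_STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if abs((self.f_sic + self.f_soc) - 1.0) > 1e-12:
            raise ValueError("f_sic + f_soc must equal 1")


def sic_equilibrium_d13c(d13c_sic: float,
                         offset: float = CALCITE_CO2_OFFSET) -> float:
    """δ¹³C of CO₂ in equilibrium with calcite: δ¹³C_SIC − offset (‰)."""
    import math
    if not math.isfinite(d13c_sic):
        raise ValueError("d13c_sic must be finite")
    return d13c_sic - offset


def f_sic_from_d13c(d13c_co2: float, d13c_sic_eq: float, d13c_soc: float,
                    separation_floor: float = 2.0) -> FSicEstimate:
    """Fraction of respired CO₂ attributable to carbonate, from δ¹³C.

    f_SIC = (δ¹³C_CO₂ − δ¹³C_SOC) / (δ¹³C_SIC_eq − δ¹³C_SOC). Values outside
    [0, 1] (measurement noise) are clamped to the boundary and flagged.
    Raises when the endmembers are closer than ``separation_floor`` ‰: the
    partition is then unidentifiable.
    """
    sep = d13c_sic_eq - d13c_soc
    if abs(sep) < separation_floor:
        raise ValueError(
            f"unidentifiable partition: endmember separation {sep:.2f}‰ "
            f"below floor {separation_floor:g}‰"
        )
    f = (d13c_co2 - d13c_soc) / sep
    if f < 0.0:
        return FSicEstimate(0.0, True)
    if f > 1.0:
        return FSicEstimate(1.0, True)
    return FSicEstimate(f, False)


def adjust_delta14c_for_sic(delta14c_co2: float, f_sic: float,
                            delta14c_co2_sic: float) -> float:
    """Δ¹⁴C of SOC-derived CO₂ after removing the carbonate contribution.

    Inverts the Δ¹⁴C mixing:
    Δ¹⁴C-CO₂,SOC = (Δ¹⁴C-CO₂ − f_SIC·Δ¹⁴C-CO₂,SIC) / (1 − f_SIC).
    """
    if not 0.0 <= f_sic < 1.0:
        if f_sic == 1.0:
            raise ValueError("f_sic = 1: no SOC-derived CO₂")
        raise ValueError("f_sic must lie in [0, 1)")
    return (delta14c_co2 - f_sic * delta14c_co2_sic) / (1.0 - f_sic)


def screen_site(sic_content: float, f_sic: float | None, region: str | None,
                config: dict | None = None) -> str:
    """Apply the inclusion/exclusion rules; returns one of SIC_STATUSES.

    ``sic_content`` is mass-% C. Rule order: content floor, then the f_SIC
    exclusion, then the regional exclusion list.
    """
    cfg = dict(SIC_DEFAULTS)
    if config:
        cfg.update(config)
    if sic_content < 0:
        raise ValueError("sic_content must be non-negative")
    if sic_content < cfg["sic_content_floor"]:
        return "assumed_zero_sic"
    if f_sic is not None and f_sic > cfg["f_sic_exclusion"]:
        return "excluded_high_fsic"
    if region is not None and region in tuple(cfg["excluded_regions"]):
        return "excluded_region"
    return "included_original"


def partition_site(d13c_co2: float | None, d13c_soc: float | None,
                   d13c_sic: float | None, sic_content: float,
                   delta14c_co2: float | None, region: str | None = None,
                   delta14c_sic: float | None = None,
                   config: dict | None = None) -> SICPartition:
    """Full per-site partition: equilibrium endmember, f_SIC, screening,
    and the Δ¹⁴C adjustment (reported for audit even though included sites
    keep their original respired Δ¹⁴C downstream).

    ``delta14c_sic`` overrides the configured carbonate Δ¹⁴C endmember when
    the site's own carbonate was measured.
    """
    cfg = dict(SIC_DEFAULTS)
    if config:
        cfg.update(config)

    if sic_content < cfg["sic_content_floor"]:
        return SICPartition(
            d13c_sic_eq=None, f_sic=0.0, f_soc=1.0,
            delta14c_co2_soc=delta14c_co2,
            status="assumed_zero_sic",
            reason=f"SIC content {sic_content:g}% below "
                   f"{cfg['sic_content_floor']:g}% floor",
        )

    if d13c_sic is None or d13c_co2 is None or d13c_soc is None:
        raise ValueError(
            "sites above the SIC content floor need δ¹³C of CO₂, SOC and SIC"
        )
    eq = sic_equilibrium_d13c(d13c_sic, cfg["calcite_co2_offset"])
    f_sic, clamped = f_sic_from_d13c(
        d13c_co2, eq, d13c_soc, cfg["d13c_separation_floor"]
    )
    status = screen_site(sic_content, f_sic, region, cfg)

    endmember = (delta14c_sic if delta14c_sic is not None
                 else cfg["delta14c_sic_endmember"])
    adjusted = None
    if delta14c_co2 is not None and f_sic < 1.0:
        adjusted = adjust_delta14c_for_sic(delta14c_co2, f_sic, endmember)

    reasons = {
        "included_original": f"f_SIC = {f_sic:.3f} ≤ "
                             f"{cfg['f_sic_exclusion']:g}; original respired "
                             "Δ¹⁴C used",
        "excluded_high_fsic": f"f_SIC = {f_sic:.3f} > "
                              f"{cfg['f_sic_exclusion']:g}",
        "excluded_region": f"region {region!r} on exclusion list",
    }
    return SICPartition(
        d13c_sic_eq=eq, f_sic=f_sic, f_soc=1.0 - f_sic,
        delta14c_co2_soc=adjusted, status=status,
        reason=reasons[status], clamped=clamped,
    )
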