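"""Radiocarbon unit conversions and stable-isotope bookkeeping.

Conventions
-----------
Δ¹⁴C_sample (‰) is the per-mil deviation of a sample's ¹⁴C/¹²C ratio from
the absolute (decay-corrected) 1950 standard:

    Δ¹⁴C_sample = (F¹⁴C · exp(λ_C (1950 − t)) − 1) · 1000

with F¹⁴C the fraction modern and λ_C = 1/8267 yr⁻¹ the radiocarbon decay
constant. To compare sites sampled in different years, values are then
background-corrected by the atmosphere of the sampling year:

    Δ¹⁴C = Δ¹⁴C_sample − Δ¹⁴C_atmosphere(t).

δ¹³C values are ‰ vs VPDB. The carbonate (SIC) δ¹³C signature is not
measured directly but obtained from a mass balance between total C and
organic C:  δ¹³C_TC·w_TC = δ¹³C_SOC·w_SOC + δ¹³C_SIC·w_SIC.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .atmos import AtmosphericCurve

__all__ = [
    "LAMBDA_14C",
    "RadiocarbonSample",
    "CarbonPools13C",
    "IncubationSetup",
    "f14c_to_delta14c",
    "delta14c_to_f14c",
    "background_correct",
    "delta13c_sic",
    "respiration_rate",
]

#: Radiocarbon decay constant, 1/8267 yr⁻¹ (mean life 8267 y).
LAMBDA_14C = 1.0 / 8267.0

#: Ideal gas constant in incubation-friendly units (L atm mol⁻¹ K⁻¹).
R_GAS = 0.082057

#: Molar mass of CO₂ (g mol⁻¹).
M_CO2 = 44.01


def f14c_to_delta14c(f14c, t):
    """Convert fraction modern to Δ¹⁴C_sample (‰) for sampling year ``t``.

    Accepts fractional years (sampling dates are continuous). Vectorized
    over both arguments.
    """
    f = np.asarray(f14c, dtype=float)
    if np.any(f <= 0) or not np.all(np.isfinite(f)):
        raise ValueError("fraction modern must be finite and > 0")
    out = (f * np.exp(LAMBDA_14C * (1950.0 - np.asarray(t, float))) - 1.0) * 1000.0
    return float(out) if out.ndim == 0 else out


def delta14c_to_f14c(delta14c, t):
    """Inverse of :func:`f14c_to_delta14c`."""
    d = np.asarray(delta14c, dtype=float)
    if np.any(d < -1000.0):
        raise ValueError("Δ¹⁴C cannot be below −1000‰")
    out = (d / 1000.0 + 1.0) * np.exp(-LAMBDA_14C * (1950.0 - np.asarray(t, float)))
    return float(out) if out.ndim == 0 else out


def background_correct(delta14c_sample, curve: AtmosphericCurve, t):
    """Δ¹⁴C = Δ¹⁴C_sample − Δ¹⁴C_atmosphere(t).

    Removes the sampling-year atmospheric background so that sites sampled
    in different years are comparable. ``t`` must lie within the curve
    domain.
    """
    out = np.asarray(delta14c_sample, dtype=float) - curve.at(t)
    return float(out) if out.ndim == 0 else out


@dataclass
class RadiocarbonSample:
    """One radiocarbon measurement carried through the correction chain."""

    f14c: float
    sampling_year: float
    delta14c_sample: float | None = None
    delta14c_corrected: float | None = None

    def __post_init__(self) -> None:
        if self.f14c <= 0:
            raise ValueError("fraction modern must be > 0")
        if self.delta14c_sample is None:
            self.delta14c_sample = f14c_to_delta14c(self.f14c, self.sampling_year)

    def correct(self, curve: AtmosphericCurve) -> float:
        self.delta14c_corrected = background_correct(
            self.delta14c_sample, curve, self.sampling_year
        )
        return self.delta14c_corrected


@dataclass
class CarbonPools13C:
    """δ¹³C and C contents of total, organic, and inorganic soil carbon.

    Because TC and SIC are measured by different methods (dry combustion vs
    450 °C ignition), exact closure w_TC = w_SOC + w_SIC is not guaranteed;
    the mass balance is checked with a warning above ``tol_warn`` relative
    misclosure and a hard error above ``tol_error``.
    """

    d13c_tc: float
    d13c_soc: float
    w_tc: float
    w_soc: float
    w_sic: float
    tol_warn: float = 0.10
    tol_error: float = 0.25

    def __post_init__(self) -> None:
        if min(self.w_tc, self.w_soc, self.w_sic) < 0:
            raise ValueError("carbon contents must be non-negative")

    def misclosure(self) -> float:
        if self.w_tc == 0:
            return 0.0
        return abs(self.w_tc - (self.w_soc + self.w_sic)) / self.w_tc


def delta13c_sic(pools: CarbonPools13C) -> float:
    """δ¹³C of soil inorganic carbon from the TC/SOC mass balance (‰).

    Raises if ``w_sic`` is zero (no carbonate: the SIC signature is
    undefined) or the mass balance misclosure exceeds the hard tolerance.
    """
    if pools.w_sic == 0:
        raise ValueError("w_sic = 0: no carbonate, SIC δ¹³C undefined")
    mis = pools.misclosure()
    if mis > pools.tol_error:
        raise ValueError(
            f"carbon mass balance misclosure {mis:.0%} exceeds "
            f"{pools.tol_error:.0%}: w_tc={pools.w_tc} vs "
            f"w_soc+w_sic={pools.w_soc + pools.w_sic}"
        )
    if mis > pools.tol_warn:
        warnings.warn(
            f"carbon mass balance misclosure {mis:.0%} above "
            f"{pools.tol_warn:.0%}", stacklevel=2
        )
    return (pools.d13c_tc * pools.w_tc - pools.d13c_soc * pools.w_soc) / pools.w_sic


@dataclass(frozen=True)
class IncubationSetup:
    """Static-incubation geometry for the headspace CO₂ flux calculation."""

    co2_slope: float            # ppm day⁻¹
    headspace_pressure: float = 1.0    # atm
    headspace_volume: float = 0.54     # L (570 mL flask − 30 g soil)
    temperature: float = 293.15        # K (20 °C incubation)
    soil_mass: float = 30.0            # g dry soil

    def __post_init__(self) -> None:
        for name in ("headspace_pressure", "headspace_volume",
                     "temperature", "soil_mass"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.co2_slope < 0:
            raise ValueError("co2_slope must be non-negative")


def respiration_rate(setup: IncubationSetup) -> float:
    """Soil respiration rate (µg CO₂ g soil⁻¹ day⁻¹) via the ideal gas law.

    rate = dC/dt · P·V·M_CO2 / (R·T·m_soil), with dC/dt in ppm day⁻¹.
    The 10⁻⁶ (ppm → mole fraction) and 10⁶ (g → µg) factors cancel.
    """
    return (
        setup.co2_slope
        * setup.headspace_pressure
        * setup.headspace_volume
        * M_CO2
        / (R_GAS * setup.temperature * setup.soil_mass)
    )
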