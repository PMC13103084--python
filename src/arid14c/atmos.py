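"""Atmospheric Δ¹⁴C forcing.

All compartment models in this package are driven by a time series of
atmospheric Δ¹⁴C (‰). Users can supply a published record as a two-column
CSV (``load_curve``) or use the packaged parametric bomb curve
(``synthetic_bomb_curve``), which captures the essential shape of the
post-1950 atmospheric record: a flat pre-bomb baseline, a steep rise during
the era of atmospheric weapons testing, a peak in the early 1960s, and a
quasi-exponential relaxation back toward the pre-bomb level as bomb ¹⁴C was
taken up by the oceans and biosphere (and diluted by fossil-fuel CO₂).

The same curve supplies the "young" endmember for the Δ¹⁴C mixing models and
the background term of the sample correction (Δ¹⁴C = Δ¹⁴C_sample −
Δ¹⁴C_atmosphere in the sampling year).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AtmosphericCurve",
    "BombCurveParams",
    "synthetic_bomb_curve",
    "load_curve",
    "atm_delta14c",
]


@dataclass(frozen=True)
class BombCurveParams:
    """Parameters of the packaged parametric bomb curve.

    Attributes
    ----------
    baseline
        Pre-bomb atmospheric Δ¹⁴C (‰). Default 0‰; the small pre-1950
        Suess-effect depression is ignored.
    rise_start
        Calendar year at which Δ¹⁴C starts rising above the baseline.
    peak_year
        Year of the bomb peak.
    peak_amp
        Height of the peak above the baseline (‰).
    decay_efold
        e-folding time of the post-peak relaxation (years).
    end_level
        Δ¹⁴C (‰) the curve passes through at ``end_year``. Together with
        ``decay_efold`` this pins the post-peak asymptote, so the tail can
        dip slightly below the asymptote implied by a pure decay to
        ``baseline`` — mirroring the real record, which crosses 0‰ around
        2020 due to fossil-fuel dilution.
    end_year
        Reference year at which the curve equals ``end_level``.
    """

    baseline: float = 0.0
    rise_start: float = 1955.0
    peak_year: float = 1964.0
    peak_amp: float = 700.0
    decay_efold: float = 16.0
    end_level: float = 0.0
    end_year: float = 2020.0

    def __post_init__(self) -> None:
        vals = [self.baseline, self.rise_start, self.peak_year,
                self.peak_amp, self.decay_efold, self.end_level, self.end_year]
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("bomb-curve parameters must be finite")
        if not self.rise_start < self.peak_year:
            raise ValueError("rise_start must precede peak_year")
        if self.decay_efold <= 0:
            raise ValueError("decay_efold must be positive")
        if not self.peak_amp > self.end_level:
            raise ValueError("peak_amp must exceed end_level")
        if not self.end_year > self.peak_year:
            raise ValueError("end_year must follow peak_year")

    @property
    def peak_value(self) -> float:
        return self.baseline + self.peak_amp

    @property
    def decay_asymptote(self) -> float:
        """Asymptote of the post-peak exponential.

        Solved so that the tail passes through ``end_level`` at ``end_year``:
        A + (peak − A)·exp(−(end_year − peak_year)/τ) = end_level.
        """
        q = math.exp(-(self.end_year - self.peak_year) / self.decay_efold)
        return (self.end_level - self.peak_value * q) / (1.0 - q)


@dataclass
class AtmosphericCurve:
    """Annual atmospheric Δ¹⁴C series with linear interpolation.

    ``years`` must be strictly increasing. Evaluation between grid points is
    linear; evaluation before the first grid year returns the first value
    (constant pre-industrial extrapolation); evaluation past the last grid
    year is an error — extend the curve instead of extrapolating forward.
    """

    years: np.ndarray
    delta14c: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=float)
        self.delta14c = np.asarray(self.delta14c, dtype=float)
        if self.years.ndim != 1 or self.years.shape != self.delta14c.shape:
            raise ValueError("years and delta14c must be 1-D and equal length")
        if self.years.size < 2:
            raise ValueError("curve needs at least two nodes")
        if not np.all(np.isfinite(self.years)) or not np.all(np.isfinite(self.delta14c)):
            raise ValueError("curve nodes must be finite")
        if not np.all(np.diff(self.years) > 0):
            raise ValueError("years must be strictly increasing")

    @property
    def last_year(self) -> float:
        return float(self.years[-1])

    def at(self, t):
        """Δ¹⁴C (‰) at year(s) ``t`` (possibly fractional)."""
        arr = np.asarray(t, dtype=float)
        if np.any(arr > self.years[-1] + 1e-9):
            raise ValueError(
                f"year {np.max(arr):g} beyond curve end {self.years[-1]:g}; "
                "regenerate or load a longer curve"
            )
        out = np.interp(arr, self.years, self.delta14c)
        return float(out) if np.isscalar(t) or arr.ndim == 0 else out


def synthetic_bomb_curve(params: BombCurveParams | None = None,
                         last_year: float = 2020.0) -> AtmosphericCurve:
    """Build the packaged parametric bomb curve on an annual grid from 1900.

    Piecewise form: ``baseline`` before ``rise_start``; linear rise to the
    peak; exponential relaxation after the peak with e-folding time
    ``decay_efold`` toward an asymptote pinned so the curve passes through
    ``end_level`` at ``end_year``.
    """
    if params is None:
        params = BombCurveParams()
    if last_year < params.peak_year:
        raise ValueError("last_year must not precede peak_year")
    years = np.arange(1900.0, math.floor(last_year) + 1.0)
    vals = _bomb_values(params, years)
    return AtmosphericCurve(years, vals, label="synthetic bomb curve")


def _bomb_values(p: BombCurveParams, years: np.ndarray) -> np.ndarray:
    years = np.asarray(years, dtype=float)
    vals = np.full_like(years, p.baseline)
    rising = (years >= p.rise_start) & (years <= p.peak_year)
    vals[rising] = p.baseline + p.peak_amp * (
        (years[rising] - p.rise_start) / (p.peak_year - p.rise_start)
    )
    after = years > p.peak_year
    a = p.decay_asymptote
    vals[after] = a + (p.peak_value - a) * np.exp(
        -(years[after] - p.peak_year) / p.decay_efold
    )
    return vals


def load_curve(path) -> AtmosphericCurve:
    """Load an atmospheric Δ¹⁴C record from a CSV of (year, Δ¹⁴C ‰).

    Expects a header ``year,delta14c_permil`` (any two-column numeric table
    with those semantics is accepted). Rows are sorted by year; duplicate
    years are an error.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("curve file needs two columns: year, delta14c_permil")
    cols = list(df.columns[:2])
    sub = df[cols].apply(pd.to_numeric, errors="coerce")
    if sub.isna().any().any():
        bad = sub[sub.isna().any(axis=1)].index.tolist()
        raise ValueError(f"non-numeric curve rows at index {bad}")
    sub = sub.sort_values(cols[0])
    years = sub[cols[0]].to_numpy(float)
    if np.any(np.diff(years) == 0):
        raise ValueError("duplicate years in curve file")
    return AtmosphericCurve(years, sub[cols[1]].to_numpy(float),
                            label=str(path))


def atm_delta14c(curve: AtmosphericCurve, t) -> float:
    """Atmospheric Δ¹⁴C (‰) in year ``t`` — alias for ``curve.at(t)``."""
    return curve.at(t)
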