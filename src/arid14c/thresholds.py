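"""Breakpoint (threshold) detection by continuous broken-line regression.

Fits y = β₀ + β₁·x + β₂·(x − ψ)₊ by profiling the breakpoint ψ over a grid
of candidate values (midpoints between sorted unique x, excluding an edge
margin) and solving ordinary least squares at each candidate. The ψ
minimizing the residual sum of squares is returned with Gaussian-likelihood
AICs for the broken-line and the simple linear model
(AIC = n·ln(RSS/n) + 2p), and a nonparametric bootstrap interval for ψ.

The broken line shares an intercept across segments (continuity at ψ), so
β₂ is the slope *change*; the right-hand slope is β₁ + β₂. A positive
delta_aic (piecewise minus linear) means no threshold is supported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BreakpointFit", "fit_breakpoint", "compare_aic",
           "THRESHOLD_DEFAULTS"]

THRESHOLD_DEFAULTS = {
    "edge_margin": 0.05,
    "min_per_side": 5,
    "n_boot": 499,
    "ci_level": 0.95,
}


@dataclass(frozen=True)
class BreakpointFit:
    psi: float
    intercept: float
    slope_left: float
    slope_right: float
    r2: float
    aic_piecewise: float
    aic_linear: float
    delta_aic: float
    psi_ci: tuple | None
    rss: float
    n: int


def _candidates(x: np.ndarray, edge_margin: float,
                min_per_side: int) -> np.ndarray:
    xs = np.unique(x)
    lo = x.min() + edge_margin * np.ptp(x)
    hi = x.max() - edge_margin * np.ptp(x)
    mids = 0.5 * (xs[:-1] + xs[1:])
    mids = mids[(mids >= lo) & (mids <= hi)]
    keep = [(np.sum(x < m) >= min_per_side) and (np.sum(x > m) >= min_per_side)
            for m in mids]
    return mids[np.asarray(keep, bool)] if len(mids) else mids


def _profile_rss(x: np.ndarray, y: np.ndarray, psis: np.ndarray):
    """OLS of the broken-line model at every candidate ψ.

    Batched 3×3 normal equations (the design is tiny and well scaled);
    returns (coefs (m,3), rss (m,)).
    """
    u = np.clip(x[None, :] - psis[:, None], 0.0, None)   # (m, n)
    n = x.size
    ones = np.ones(n)
    sx, sxx = x.sum(), (x * x).sum()
    su = u.sum(axis=1)
    sxu = u @ x
    suu = (u * u).sum(axis=1)
    sy, sxy = y.sum(), x @ y
    suy = u @ y

    m = psis.size
    g = np.empty((m, 3, 3))
    g[:, 0, 0] = n
    g[:, 0, 1] = g[:, 1, 0] = sx
    g[:, 0, 2] = g[:, 2, 0] = su
    g[:, 1, 1] = sxx
    g[:, 1, 2] = g[:, 2, 1] = sxu
    g[:, 2, 2] = suu
    b = np.stack([np.full(m, sy), np.full(m, sxy), suy], axis=1)
    try:
        coefs = np.linalg.solve(g, b[..., None])[..., 0]
    except np.linalg.LinAlgError:
        coefs = np.stack([np.linalg.lstsq(
            np.column_stack([ones, x, u[i]]), y, rcond=None)[0]
            for i in range(m)])
    yhat = coefs[:, [0]] + coefs[:, [1]] * x[None, :] + coefs[:, [2]] * u
    rss = ((y[None, :] - yhat) ** 2).sum(axis=1)
    return coefs, rss


def _best_psi(x, y, psis):
    coefs, rss = _profile_rss(x, y, psis)
    i = int(np.argmin(rss))
    return psis[i], coefs[i], float(rss[i])


def fit_breakpoint(x, y, edge_margin: float = 0.05, min_per_side: int = 5,
                   n_boot: int = 499, ci_level: float = 0.95,
                   seed: int = 0) -> BreakpointFit:
    """Fit the broken-line model and compare it to a simple linear model.

    Parameters
    ----------
    x, y
        Predictor and response arrays (n ≥ 10; x must vary).
    edge_margin
        Fraction of the x-range excluded from each end of the candidate
        grid (avoids degenerate one-sided segments).
    min_per_side
        Minimum observations required on each side of a candidate ψ.
    n_boot
        Bootstrap resamples for the ψ confidence interval; 0 disables the
        interval (``psi_ci = None``).
    seed
        Seed for the bootstrap resampler (results are reproducible).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    if x.size < 10:
        raise ValueError("need at least 10 observations")
    if np.ptp(x) == 0:
        raise ValueError("x is constant")

    psis = _candidates(x, edge_margin, min_per_side)
    if psis.size == 0:
        raise ValueError(
            f"no candidate breakpoint has ≥ {min_per_side} points per side"
        )
    psi, coefs, rss_pw = _best_psi(x, y, psis)

    # simple linear reference model
    design = np.column_stack([np.ones_like(x), x])
    beta_lin, *_ = np.linalg.lstsq(design, y, rcond=None)
    rss_lin = float(((y - design @ beta_lin) ** 2).sum())

    n = x.size
    aic_pw = n * np.log(rss_pw / n) + 2 * 4     # β₀, β₁, β₂, ψ
    aic_lin = n * np.log(rss_lin / n) + 2 * 2
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss_pw / tss if tss > 0 else 0.0

    ci = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boot = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, n, n)
            xb, yb = x[idx], y[idx]
            ok = np.array([(np.sum(xb < m) >= min_per_side)
                           and (np.sum(xb > m) >= min_per_side)
                           for m in psis])
            if not ok.any() or np.ptp(xb) == 0:
                boot[b] = psi
                continue
            boot[b] = _best_psi(xb, yb, psis[ok])[0]
        alpha = (1.0 - ci_level) / 2.0
        ci = (float(np.quantile(boot, alpha)),
              float(np.quantile(boot, 1.0 - alpha)))

    return BreakpointFit(
        psi=float(psi),
        intercept=float(coefs[0]),
        slope_left=float(coefs[1]),
        slope_right=float(coefs[1] + coefs[2]),
        r2=float(np.clip(r2, 0.0, 1.0)),
        aic_piecewise=float(aic_pw),
        aic_linear=float(aic_lin),
        delta_aic=float(aic_pw - aic_lin),
        psi_ci=ci,
        rss=rss_pw,
        n=n,
    )


def compare_aic(fit: BreakpointFit) -> str:
    """"piecewise" iff the broken-line AIC is strictly lower; ties go to
    the simpler linear model."""
    return "piecewise" if fit.delta_aic < 0 else "linear"
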