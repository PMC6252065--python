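"""Lagged cross-correlation between predator and prey diel profiles.

The 24 hourly detection counts of the predator (x) are correlated with
those of the prey (y) at every integer lag h from -12 to +11 hours, with
circular (wrap-around) shifting so that all 24 bin pairs contribute at
every lag and the degrees of freedom stay at n - 2 = 22.  A positive lag
correlates x at hour a+h with y at hour a.

Significance of a per-lag correlation r uses the t transform

    t = r * sqrt((n - 2) / (1 - r^2))

against the one-tailed Student-t critical value at p = 0.05 with 22
degrees of freedom (1.72), applied to |t| so that strong correlations of
either sign are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CcfResult",
    "circular_ccf",
    "t_statistic",
    "critical_t",
    "summarise_ccf",
    "LAGS",
]

#: Reported lags, in hours.
LAGS = np.arange(-12, 12)


@dataclass
class CcfResult:
    """Cross-correlation summary for one predator-prey pair and season."""

    pair: tuple[str, str]
    season: str
    lags: np.ndarray
    r: np.ndarray
    t: np.ndarray
    n: int
    t_crit: float
    significant_ranges: list[tuple[int, int]]
    peak_lag: int | None
    peak_r: float | None

    @property
    def df(self) -> int:
        return self.n - 2


def circular_ccf(profile_x: np.ndarray, profile_y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-lag Pearson correlation of two 24-bin profiles with wrap-around.

    Returns ``(lags, r)`` with lags -12..+11.  r at lag h is the Pearson
    correlation of x shifted forward by h hours against y, over all 24
    hourly bins.  Constant profiles have undefined correlation and raise.
    """
    x = np.asarray(profile_x, dtype=float)
    y = np.asarray(profile_y, dtype=float)
    if x.shape != (24,) or y.shape != (24,):
        raise ValueError("profiles must have 24 hourly bins")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant profile: correlation undefined")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    r = np.empty(len(LAGS))
    for i, h in enumerate(LAGS):
        # element a of roll(x, -h) is x[(a + h) mod 24]
        r[i] = (np.roll(xc, -h) * yc).sum() / denom
    return LAGS.copy(), r


def t_statistic(r: float | np.ndarray, n: int) -> float | np.ndarray:
    """t transform of a correlation coefficient: t = r sqrt((n-2)/(1-r^2)).

    Correlations of magnitude 1 map to signed infinity.
    """
    if n <= 2:
        raise ValueError("need n > 2 for the t transform")
    r_arr = np.asarray(r, dtype=float)
    if np.any(np.abs(r_arr) > 1):
        raise ValueError("|r| cannot exceed 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(
            np.abs(r_arr) == 1.0,
            np.sign(r_arr) * np.inf,
            r_arr * np.sqrt((n - 2) / (1.0 - r_arr**2)),
        )
    return float(t) if np.isscalar(r) else t


def critical_t(p: float = 0.05, df: int = 22, tails: int = 1) -> float:
    """Student-t critical value: upper quantile at p (one- or two-tailed)."""
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    if df < 1:
        raise ValueError("df must be >= 1")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    return float(stats.t.ppf(1.0 - p / tails, df))


def _significant_runs(lags: np.ndarray, sig: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of consecutive significant lags, as (from, to) pairs."""
    runs: list[tuple[int, int]] = []
    start: int | None = None
    for lag, s in zip(lags, sig):
        if s and start is None:
            start = int(lag)
        elif not s and start is not None:
            runs.append((start, int(lag) - 1))
            start = None
    if start is not None:
        runs.append((start, int(lags[-1])))
    return runs


def summarise_ccf(
    lags: np.ndarray,
    r: np.ndarray,
    n: int = 24,
    t_crit: float | None = None,
    pair: tuple[str, str] = ("x", "y"),
    season: str = "annual",
) -> CcfResult:
    """Turn per-lag correlations into ranges of significance and a peak lag.

    A lag is significant when |t| exceeds ``t_crit`` (default: the
    one-tailed 5% Student-t value for n-2 df).  The peak lag is the
    significant lag with the largest |r|; ties break to the smallest
    |lag| and then to the negative lag.  With no significant lag the
    ranges are empty and the peak is None.
    """
    if t_crit is None:
        t_crit = critical_t(0.05, n - 2, tails=1)
    lags = np.asarray(lags)
    r = np.asarray(r, dtype=float)
    t = np.asarray(t_statistic(r, n))
    sig = np.abs(t) > t_crit
    ranges = _significant_runs(lags, sig)
    peak_lag: int | None = None
    peak_r: float | None = None
    if sig.any():
        cand = sorted(
            zip(lags[sig], r[sig]),
            key=lambda lr: (-abs(lr[1]), abs(lr[0]), lr[0]),
        )
        peak_lag, peak_r = int(cand[0][0]), float(cand[0][1])
    return CcfResult(
        pair=pair,
        season=season,
        lags=lags,
        r=r,
        t=t,
        n=n,
        t_crit=t_crit,
        significant_ranges=ranges,
        peak_lag=peak_lag,
        peak_r=peak_r,
    )
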