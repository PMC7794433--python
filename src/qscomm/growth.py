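"""Growth modelling and fitness comparisons.

Population growth in batch culture is described by the logistic model

    N(t) = Nmax / (1 + ((Nmax - N0)/N0) * exp(-r t))

with N the optical density (OD650, arbitrary units), N0 the inoculum
density, Nmax the carrying capacity and r the intrinsic specific growth
rate (h^-1).  The specific growth rate at time t is mu(t) = r (1 - N/Nmax).

Fitness comparisons between signal-producing and non-producing strains use
(i) the slope of log2(OD) versus time over a trusted OD window — doublings
per hour, i.e. the natural-log growth rate divided by ln 2 — compared by a
two-sample t-test on slopes, and (ii) serial-transfer competition assays
summarised as the per-transfer slope of log2(CFU ratio), a selection
coefficient proxy.  Oxygen drawdown tracking growth is quantified by the
Pearson correlation between OD and dissolved-O2 series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lmfit import Model
from scipy import stats

from .errors import DomainError, FitError, InsufficientDataError

__all__ = [
    "LogisticParams",
    "SlopeEstimate",
    "CompetitionResult",
    "fit_logistic",
    "exponential_slope",
    "compare_slopes",
    "competition_ratio",
    "correlate_od_do",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class LogisticParams:
    """Logistic growth parameters (OD650 a.u., rates in h^-1)."""

    n0: float
    nmax: float
    r: float
    n0_se: float = 0.0
    nmax_se: float = 0.0
    r_se: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.n0 < self.nmax):
            raise DomainError(f"require 0 < n0 < nmax, got n0={self.n0}, nmax={self.nmax}")
        if self.r <= 0.0:
            raise DomainError(f"growth rate r must be positive, got {self.r}")

    def density(self, t):
        """N(t) on a scalar or array time grid (hours)."""
        t = np.asarray(t, dtype=float)
        return self.nmax / (1.0 + ((self.nmax - self.n0) / self.n0) * np.exp(-self.r * t))

    def mu(self, t):
        """Specific growth rate mu(t) = r (1 - N(t)/Nmax), h^-1."""
        return self.r * (1.0 - self.density(t) / self.nmax)

    def mu_log2(self, t):
        """Specific growth rate expressed in doublings per hour."""
        return self.mu(t) / LN2


def _logistic(t, n0, nmax, r):
    return nmax / (1.0 + ((nmax - n0) / n0) * np.exp(-r * t))


def fit_logistic(curve: pd.DataFrame) -> LogisticParams:
    """Fit the logistic model to a growth curve.

    Parameters
    ----------
    curve : DataFrame with columns ``time_h`` and ``od650``.

    Returns
    -------
    LogisticParams with standard errors from the least-squares covariance.
    """
    t = np.asarray(curve["time_h"], dtype=float)
    od = np.asarray(curve["od650"], dtype=float)
    if len(t) < 5:
        raise InsufficientDataError("logistic fit needs at least 5 points")
    model = Model(_logistic)
    params = model.make_params(n0=max(od.min(), 1e-6), nmax=od.max(), r=0.5)
    params["n0"].set(min=1e-9)
    params["nmax"].set(min=1e-9)
    params["r"].set(min=1e-9)
    result = model.fit(od, params, t=t)
    if not result.success:
        raise FitError(f"logistic fit did not converge: {result.message}")
    p = result.params
    return LogisticParams(
        n0=p["n0"].value,
        nmax=p["nmax"].value,
        r=p["r"].value,
        n0_se=p["n0"].stderr or 0.0,
        nmax_se=p["nmax"].stderr or 0.0,
        r_se=p["r"].stderr or 0.0,
    )


@dataclass(frozen=True)
class SlopeEstimate:
    """Exponential-phase growth rate as slope of log2(OD) vs time."""

    slope: float  # doublings per hour
    se: float
    n_points: int
    intercept: float

    @property
    def rate_ln(self) -> float:
        """The natural-log specific growth rate mu = slope * ln 2."""
        return self.slope * LN2


def exponential_slope(
    curve: pd.DataFrame, od_window: tuple[float, float] = (0.1, 0.7)
) -> SlopeEstimate:
    """Slope of log2(OD650) versus time restricted to a trusted OD window.

    The default window (0.1, 0.7) a.u. keeps the points where OD is a
    reliable proxy for cell density.  The result is invariant under
    rescaling the OD series (only the intercept shifts).
    """
    t = np.asarray(curve["time_h"], dtype=float)
    od = np.asarray(curve["od650"], dtype=float)
    lo, hi = od_window
    mask = (od > lo) & (od < hi)
    if mask.sum() < 3:
        raise InsufficientDataError(
            f"need >= 3 points with OD in ({lo}, {hi}), got {int(mask.sum())}"
        )
    res = stats.linregress(t[mask], np.log2(od[mask]))
    return SlopeEstimate(
        slope=res.slope, se=res.stderr, n_points=int(mask.sum()), intercept=res.intercept
    )


def compare_slopes(a: SlopeEstimate, b: SlopeEstimate) -> tuple[float, float]:
    """Two-sided t-test for equality of two regression slopes.

    Returns ``(t_statistic, p_value)`` using the standard slope-comparison
    statistic t = (s1 - s2)/sqrt(se1^2 + se2^2) with n1 + n2 - 4 degrees of
    freedom.
    """
    se = math.hypot(a.se, b.se)
    if se == 0.0:
        raise DomainError("both slopes have zero standard error; test undefined")
    tstat = (a.slope - b.slope) / se
    df = a.n_points + b.n_points - 4
    p = 2.0 * stats.t.sf(abs(tstat), df)
    return tstat, p


@dataclass(frozen=True)
class CompetitionResult:
    """Serial-transfer competition summary.

    ``log2_ratio`` holds log2(CFU_a / CFU_b) per transfer (NaN where a
    count was zero and the ratio is undefined).  ``selection_coefficient``
    is the slope of log2-ratio versus transfer index: 0 for neutral
    coexistence, positive when strain a gains per transfer.
    """

    log2_ratio: pd.Series
    selection_coefficient: float
    se: float
    ci95: tuple[float, float]
    p_value: float
    undefined_transfers: tuple[int, ...]


def competition_ratio(series: pd.DataFrame) -> CompetitionResult:
    """Per-transfer log ratio and selection-coefficient estimate.

    Parameters
    ----------
    series : DataFrame with columns ``transfer``, ``cfu_a``, ``cfu_b``.
    """
    transfer = np.asarray(series["transfer"], dtype=float)
    a = np.asarray(series["cfu_a"], dtype=float)
    b = np.asarray(series["cfu_b"], dtype=float)
    if len(transfer) < 2:
        raise InsufficientDataError("competition series needs at least 2 transfers")
    if a[0] <= 0 or b[0] <= 0:
        raise DomainError("both strains must have positive counts at transfer 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where((a > 0) & (b > 0), np.log2(np.where(b > 0, a, 1) / np.where(b > 0, b, 1)), np.nan)
    undefined = tuple(int(tr) for tr, v in zip(transfer, ratio) if not np.isfinite(v))
    ok = np.isfinite(ratio)
    if ok.sum() < 2:
        raise InsufficientDataError("fewer than 2 transfers with defined ratio")
    res = stats.linregress(transfer[ok], ratio[ok])
    df = int(ok.sum()) - 2
    if df > 0 and res.stderr > 0:
        tcrit = stats.t.ppf(0.975, df)
        ci = (res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr)
        p = res.pvalue
    else:
        # two points or a perfect line: slope exact, no dispersion estimate
        ci = (res.slope, res.slope)
        p = float("nan") if res.slope != 0 else 1.0
    return CompetitionResult(
        log2_ratio=pd.Series(ratio, index=pd.Index(transfer.astype(int), name="transfer")),
        selection_coefficient=res.slope,
        se=res.stderr,
        ci95=ci,
        p_value=p,
        undefined_transfers=undefined,
    )


def correlate_od_do(curve: pd.DataFrame) -> tuple[float, float]:
    """Pearson correlation between OD650 and dissolved O2 (% saturation).

    Returns ``(r, p_value)``.  A culture drawing down oxygen as it grows
    shows a strong negative correlation.
    """
    if "do_percent" not in curve.columns:
        raise DomainError("growth curve has no dissolved-O2 series (column 'do_percent')")
    od = np.asarray(curve["od650"], dtype=float)
    do = np.asarray(curve["do_percent"], dtype=float)
    if len(od) < 3 or len(od) != len(do):
        raise InsufficientDataError("need paired OD and O2 series of equal length >= 3")
    r, p = stats.pearsonr(od, do)
    return float(r), float(p)
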