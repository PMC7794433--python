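"""Signal-molecule production: the encoder of the quorum-sensing channel.

The concentration of the secreted signal peptide tracks cell density
through an allometric (power) law

    SM(N) = a * N**b        [SM in nM, N = OD650 in a.u.]

An exponent b > 1 makes the encoder ultra-sensitive: the signal rises
faster than linearly with density, so the per-cell signal share itself
grows with the population.  The same law follows mechanistically if each
cell produces signal at a rate proportional to the product of its specific
growth rate and the population density: with dN/dt = mu N,

    dSM/dt = c * mu(t) * N(t)^2   =>   SM(t) = (c/2) (N(t)^2 - N0^2),

i.e. a power law with exponent 2 once N >> N0 — growth-rate-coupled
production is an alternative route to encoder ultra-sensitivity that does
not require a signal-dependent positive feedback loop.

``fit_allometric`` estimates (a, b) from SM-versus-OD data by
Levenberg-Marquardt least squares, optionally weighted by the reported
standard errors, using only rows at or above the assay's detection limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lmfit import Model
from scipy.integrate import solve_ivp

from .errors import DomainError, FitError, InsufficientDataError
from .growth import LogisticParams

__all__ = [
    "AllometricParams",
    "OD_TO_CELLS_PER_ML",
    "sm_concentration",
    "fit_allometric",
    "integrate_rate_law",
    "rate_law_closed_form",
]

#: Optional OD-to-density conversion (cells per mL at OD650 = 1 a.u.).
#: Provided as a constant for reporting; never applied implicitly.
OD_TO_CELLS_PER_ML = 4.0e8


@dataclass(frozen=True)
class AllometricParams:
    """Encoder-law coefficients: SM = a * N**b.

    a is the signal concentration at unit density (nM per (a.u.)^b) and b
    the dimensionless density exponent; *_se are standard errors.
    """

    a: float
    b: float
    a_se: float = 0.0
    b_se: float = 0.0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise DomainError(f"allometric parameters must be positive, got a={self.a}, b={self.b}")
        if self.a_se < 0 or self.b_se < 0:
            raise DomainError("standard errors must be non-negative")


def sm_concentration(density, params: AllometricParams):
    """Signal concentration (nM) at the given density (OD650 a.u.).

    Strictly increasing in density for b > 0; accepts scalars or arrays.
    """
    density = np.asarray(density, dtype=float)
    if np.any(density < 0):
        raise DomainError("density must be non-negative")
    out = params.a * np.power(density, params.b)
    return out if out.ndim else float(out)


def _power_law(od, a, b):
    return a * np.power(od, b)


def fit_allometric(
    data: pd.DataFrame,
    weighted: bool | None = None,
    log_space: bool = False,
) -> AllometricParams:
    """Fit SM = a * N**b to an SM-versus-density table.

    Parameters
    ----------
    data : DataFrame with columns ``od650`` and ``sm_nM``; optional
        ``sm_se_nM`` (replicate standard errors) and ``below_lod``
        (rows flagged below the detection limit are excluded from the fit,
        never dropped from the table).
    weighted : use 1/se^2 weights.  Default: weighted iff ``sm_se_nM`` is
        present with all-positive entries.
    log_space : fit ln(SM) = ln(a) + b ln(N) by ordinary least squares
        instead of the direct (default) linear-space fit.
    """
    usable = data
    if "below_lod" in data.columns:
        usable = data.loc[~data["below_lod"].astype(bool)]
    od = np.asarray(usable["od650"], dtype=float)
    sm = np.asarray(usable["sm_nM"], dtype=float)
    if len(od) < 4:
        raise InsufficientDataError(
            f"allometric fit needs >= 4 rows above the detection limit, got {len(od)}"
        )
    if np.any(od <= 0):
        raise DomainError("density must be positive for fitting")

    se = None
    if "sm_se_nM" in usable.columns:
        se_arr = np.asarray(usable["sm_se_nM"], dtype=float)
        if np.all(se_arr > 0):
            se = se_arr
    if weighted is None:
        weighted = se is not None
    if weighted and se is None:
        raise DomainError("weighted fit requested but no positive sm_se_nM column")

    if log_space:
        if np.any(sm <= 0):
            raise DomainError("log-space fit requires positive SM values")
        coef, cov = np.polyfit(np.log(od), np.log(sm), 1, cov=True)
        b, ln_a = coef
        a = float(np.exp(ln_a))
        b_se = float(np.sqrt(cov[0, 0]))
        a_se = float(a * np.sqrt(cov[1, 1]))
        return AllometricParams(a=a, b=float(b), a_se=a_se, b_se=b_se)

    model = Model(_power_law)
    params = model.make_params(a=max(sm[np.argmax(od)], 1e-6), b=2.0)
    params["a"].set(min=1e-12)
    params["b"].set(min=1e-12)
    result = model.fit(sm, params, od=od, weights=None if not weighted else 1.0 / se)
    if not result.success:
        raise FitError(f"allometric fit did not converge: {result.message}")
    p = result.params
    return AllometricParams(
        a=p["a"].value, b=p["b"].value, a_se=p["a"].stderr or 0.0, b_se=p["b"].stderr or 0.0
    )


def rate_law_closed_form(c: float, growth: LogisticParams, t_grid) -> np.ndarray:
    """Closed-form SM(t) = (c/2) (N(t)^2 - N0^2) of the growth-coupled rate law."""
    n = growth.density(np.asarray(t_grid, dtype=float))
    return 0.5 * c * (n**2 - growth.n0**2)


def integrate_rate_law(c: float, growth: LogisticParams, t_grid) -> pd.DataFrame:
    """Integrate the growth-coupled production rate dSM/dt = c mu(t) N(t)^2.

    Starts from SM(0) = 0 and integrates with adaptive Runge-Kutta
    (rtol 1e-8); the result agrees with the closed form
    (c/2)(N(t)^2 - N0^2) to integration tolerance.  Returns an
    SM time-series table (time_h, od650, sm_nM, sm_se_nM, below_lod).
    """
    if c <= 0:
        raise DomainError(f"rate constant c must be positive, got {c}")
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2 or np.any(np.diff(t_grid) <= 0):
        raise DomainError("t_grid must be strictly increasing with >= 2 points")
    if t_grid[0] < 0:
        raise DomainError("t_grid must start at or after t = 0 (SM(0) = 0)")

    def rhs(t, y):
        return [c * growth.mu(t) * growth.density(t) ** 2]

    sol = solve_ivp(
        rhs, (0.0, float(t_grid[-1])), [0.0], t_eval=t_grid, rtol=1e-8, atol=1e-12, method="RK45"
    )
    if not sol.success:
        raise FitError(f"rate-law integration failed: {sol.message}")
    return pd.DataFrame(
        {
            "time_h": t_grid,
            "od650": growth.density(t_grid),
            "sm_nM": sol.y[0],
            "sm_se_nM": 0.0,
            "below_lod": False,
        }
    )
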