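"""Growth-coupled dynamics of the per-cell response.

During batch growth the per-cell reporter signal (Miller units per OD
unit) is the sum of two terms:

    RM(t)/N(t) = RM0/N(t) + RM1(t)/N(t)

RM0 is the reporter stock accumulated in the overnight pre-culture; with
no new synthesis it is only diluted by division, halving per population
doubling.  RM1 accumulates after inoculation at the per-cell rate

    d(RM1)/dt = k * Whats(SM(t)) * mu(t) * N(t)

where Whats = W/Wmax is the normalized decoder response evaluated at the
encoder-law signal concentration SM(t) = a N(t)^b, mu(t) the specific
growth rate, and k the response-magnitude constant: the per-cell response
produced at full decoder output (Whats = 1) and unit specific growth rate
(1 h^-1).  The signal is assumed stable (no degradation).  The composition
produces the characteristic dilution-then-upturn trajectory: an early
minimum while the overnight stock dilutes, then a rise once the signal
crosses the decoder's sensitive range, after which the per-cell response
grows approximately linearly with density.

Because dN = mu N dt, RM1(t) = k * Int_{N0}^{N(t)} Whats(a nu^b) d nu — a
quadrature over density used internally for fast fitting; the public
simulator integrates the ODE with adaptive Runge-Kutta (rtol 1e-8).

``fit_dynamics`` estimates (k, RM0) from an observed trajectory with the
encoder, decoder and growth parameters held fixed at their independently
fitted values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lmfit import Parameters, minimize as lm_minimize
from scipy.integrate import solve_ivp

from .decoder import HillParams, hill_response
from .encoder import AllometricParams, sm_concentration
from .errors import DomainError, FitError, InsufficientDataError
from .growth import LogisticParams

__all__ = ["DynamicsParams", "simulate_response", "fit_dynamics"]


@dataclass(frozen=True)
class DynamicsParams:
    """Response-dynamics constants.

    k : Miller units; per-cell response magnitude at full decoder output
        and specific growth rate 1 h^-1.
    rm0 : Miller units * a.u.; overnight-accumulated reporter stock.
    """

    k: float
    rm0: float
    k_se: float = 0.0
    rm0_se: float = 0.0
    r_squared: float | None = None

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise DomainError(f"k must be positive, got {self.k}")
        if self.rm0 < 0:
            raise DomainError(f"rm0 must be non-negative, got {self.rm0}")


def _what(density, enc: AllometricParams, dec: HillParams):
    """Normalized decoder output Whats(N) = W(a N^b)/Wmax in [0, 1)."""
    return hill_response(sm_concentration(density, enc), dec) / dec.wmax


def _rm1_per_k(growth: LogisticParams, enc: AllometricParams, dec: HillParams, t_grid):
    """RM1(t)/k on the grid, by adaptive RK integration of the production ODE."""

    def rhs(t, y):
        n = growth.density(t)
        return [_what(n, enc, dec) * growth.mu(t) * n]

    sol = solve_ivp(
        rhs, (0.0, float(t_grid[-1])), [0.0], t_eval=t_grid, rtol=1e-8, atol=1e-12, method="RK45"
    )
    if not sol.success:
        raise FitError(f"response-dynamics integration failed: {sol.message}")
    return sol.y[0]


def simulate_response(
    growth: LogisticParams,
    enc: AllometricParams,
    dec: HillParams,
    dyn: DynamicsParams,
    t_grid,
) -> pd.DataFrame:
    """Simulate the per-cell response trajectory on ``t_grid`` (hours).

    Returns a ResponseTrajectory table (time_h, od650, response_per_cell,
    se) with se = 0; the response is in Miller units per OD a.u.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2 or np.any(np.diff(t_grid) <= 0) or t_grid[0] < 0:
        raise DomainError("t_grid must be strictly increasing, starting at t >= 0")
    n = growth.density(t_grid)
    rm1 = dyn.k * _rm1_per_k(growth, enc, dec, t_grid)
    return pd.DataFrame(
        {
            "time_h": t_grid,
            "od650": n,
            "response_per_cell": (dyn.rm0 + rm1) / n,
            "se": 0.0,
        }
    )


def fit_dynamics(
    traj: pd.DataFrame,
    growth: LogisticParams,
    enc: AllometricParams,
    dec: HillParams,
) -> DynamicsParams:
    """Fit (k, rm0) to an observed per-cell response trajectory.

    All other parameters are fixed at their independently fitted values,
    so the model is linear in (k, rm0); RM1/k is integrated once on the
    observation grid and the two constants estimated by least squares
    (standard errors from the covariance, plus the fit's R^2).
    """
    t = np.asarray(traj["time_h"], dtype=float)
    y = np.asarray(traj["response_per_cell"], dtype=float)
    if len(t) < 3:
        raise InsufficientDataError("dynamics fit needs >= 3 trajectory points")
    if np.any(np.diff(t) <= 0) or t[0] < 0:
        raise DomainError("trajectory times must be strictly increasing, starting at t >= 0")
    n = growth.density(t)
    rm1_per_k = _rm1_per_k(growth, enc, dec, t)

    def residual(pars):
        model = (pars["rm0"].value + pars["k"].value * rm1_per_k) / n
        return model - y

    pars = Parameters()
    pars.add("k", value=max(y[-1] * n[-1] / max(rm1_per_k[-1], 1e-12), 1.0), min=1e-9)
    pars.add("rm0", value=max(y[0] * n[0], 1e-6), min=0.0)
    out = lm_minimize(residual, pars, method="leastsq")
    if not out.success:
        raise FitError(f"dynamics fit did not converge: {out.message}")
    resid = residual(out.params)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return DynamicsParams(
        k=out.params["k"].value,
        rm0=out.params["rm0"].value,
        k_se=out.params["k"].stderr or 0.0,
        rm0_se=out.params["rm0"].stderr or 0.0,
        r_squared=r2,
    )
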