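"""Cooperative response to the signal: the decoder of the channel.

The target-gene response to the signal molecule is sigmoidal and modelled
by the Hill equation

    W(SM) = Wmax * SM^n / (Km^n + SM^n)

with Km the half-maximal signal concentration (nM) and n the Hill
coefficient.  n > 1 means positive cooperativity — an ultra-sensitive
decoder, steeper than the hyperbolic Michaelis-Menten response.

Besides fitting, this module implements the lower-limit-of-response (LLR)
rule: the smallest tabulated signal concentration whose blank-subtracted
mean response has a lower confidence bound above zero, scanning in the
direction of increasing concentration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lmfit import Model
from scipy import stats

from .errors import DomainError, FitError, InsufficientDataError

__all__ = [
    "HillParams",
    "hill_response",
    "inverse_hill",
    "fit_hill",
    "determine_llr",
]


@dataclass(frozen=True)
class HillParams:
    """Hill-law parameters: W(SM) = wmax SM^n / (km^n + SM^n)."""

    wmax: float
    km: float
    n: float
    wmax_se: float = 0.0
    km_se: float = 0.0
    n_se: float = 0.0
    redchi: float | None = None  # reduced chi-square of the fit, if fitted

    def __post_init__(self) -> None:
        if self.wmax <= 0 or self.km <= 0 or self.n <= 0:
            raise DomainError(
                f"Hill parameters must be positive, got wmax={self.wmax}, km={self.km}, n={self.n}"
            )


def hill_response(sm, params: HillParams):
    """Response at signal concentration ``sm`` (nM); W(km) = wmax/2 exactly."""
    sm = np.asarray(sm, dtype=float)
    if np.any(sm < 0):
        raise DomainError("signal concentration must be non-negative")
    # (sm/km)^n form avoids overflow for large km^n
    x = np.power(sm / params.km, params.n)
    out = params.wmax * x / (1.0 + x)
    return out if out.ndim else float(out)


def inverse_hill(response, params: HillParams):
    """Signal concentration producing the given response; inverse of hill_response.

    Defined for responses in [0, wmax); returns 0 at response 0.
    """
    response = np.asarray(response, dtype=float)
    if np.any(response < 0) or np.any(response >= params.wmax):
        raise DomainError("response must lie in [0, wmax)")
    f = response / params.wmax
    out = params.km * np.power(f / (1.0 - f), 1.0 / params.n)
    return out if out.ndim else float(out)


def _hill(sm, wmax, km, n):
    x = np.power(np.maximum(sm, 0.0) / km, n)
    return wmax * x / (1.0 + x)


def fit_hill(
    data: pd.DataFrame | Sequence[pd.DataFrame],
    fix_n: float | None = None,
) -> HillParams:
    """Fit the Hill law to a dose-response table.

    Parameters
    ----------
    data : long-format DataFrame with columns ``sm_nM`` and ``response``
        (one row per replicate), or a sequence of such tables to be fitted
        concatenated (a single parameter set across replicate datasets).
    fix_n : optionally freeze the Hill coefficient (shared-shape fits).

    Returns
    -------
    HillParams with standard errors and the reduced chi-square.  A warning
    is issued when the fitted Km falls outside the sampled concentration
    range (extrapolated sensitivity).
    """
    if not isinstance(data, pd.DataFrame):
        data = pd.concat(list(data), ignore_index=True)
    sm = np.asarray(data["sm_nM"], dtype=float)
    y = np.asarray(data["response"], dtype=float)
    if len(np.unique(sm)) < 5:
        raise InsufficientDataError("Hill fit needs >= 5 distinct concentrations")

    pos = sm > 0
    guess_km = float(np.median(sm[pos])) if pos.any() else 1.0
    model = Model(_hill)
    params = model.make_params(wmax=float(np.max(y)), km=guess_km, n=2.0)
    params["wmax"].set(min=1e-12)
    params["km"].set(min=1e-12)
    if fix_n is not None:
        params["n"].set(value=fix_n, vary=False)
    else:
        params["n"].set(min=1e-12)
    result = model.fit(y, params, sm=sm)
    if not result.success:
        raise FitError(f"Hill fit did not converge: {result.message}")
    p = result.params
    km = p["km"].value
    if pos.any() and not (np.min(sm[pos]) <= km <= np.max(sm)):
        warnings.warn(
            f"fitted Km = {km:.3g} nM lies outside the sampled range "
            f"[{np.min(sm[pos]):.3g}, {np.max(sm):.3g}] nM; fit quality suspect",
            stacklevel=2,
        )
    return HillParams(
        wmax=p["wmax"].value,
        km=km,
        n=p["n"].value,
        wmax_se=p["wmax"].stderr or 0.0,
        km_se=p["km"].stderr or 0.0,
        n_se=p["n"].stderr or 0.0,
        redchi=result.redchi,
    )


def determine_llr(data: pd.DataFrame, confidence: float = 0.95) -> float | None:
    """Lower limit of response: first concentration with a significant response.

    Responses are blank-subtracted (blank = mean response of the sm = 0
    rows).  Scanning in the direction of increasing concentration, the LLR
    is the smallest concentration whose per-concentration t-based lower
    confidence bound (two-sided interval at ``confidence``) exceeds zero.
    Returns None when no concentration qualifies.
    """
    if not 0 < confidence < 1:
        raise DomainError("confidence must be a fraction in (0, 1)")
    grouped = data.groupby("sm_nM")["response"]
    counts = grouped.count()
    if (counts < 2).any():
        raise DomainError("LLR needs >= 2 replicates at every concentration")
    blank = float(grouped.mean().get(0.0, 0.0))
    for conc in sorted(c for c in counts.index if c > 0):
        vals = np.asarray(grouped.get_group(conc), dtype=float) - blank
        m = vals.mean()
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        if se == 0.0:
            lower = m
        else:
            lower = m - stats.t.ppf(0.5 + confidence / 2.0, len(vals) - 1) * se
        if lower > 0.0:
            return float(conc)
    return None
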