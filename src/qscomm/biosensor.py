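"""Absolute signal quantification from paired biosensor curves.

The biosensor reports an unknown signal concentration by comparing two
dose-response curves measured side by side under identical conditions:

* a calibration curve — reporter output versus *known* signal
  concentration (purified signal spiked into signal-free spent medium);
* a sample curve — reporter output versus *dilution fraction* of the
  unknown spent medium (diluted in the same signal-free medium, so only
  the signal concentration varies along the series).

Both are sigmoidal and fitted by the Hill law.  Because the sample series
is the calibration series re-parameterized by an unknown concentration
scale, the undiluted sample concentration follows from the horizontal
offset of the matched sigmoids:

    C_sample = Km_cal / Km_sample         [Km_sample in dilution units]

restricted to the linear part of the sigmoid (responses between 20% and
80% of the calibration maximum) to avoid saturation and the resulting
underestimation.  A point-wise alternative inverts the calibration curve
at each usable sample dilution.

The limit of detection (LOD) is the concentration whose predicted
response equals the blank mean plus three blank standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decoder import HillParams, fit_hill, inverse_hill
from .errors import DomainError, InsufficientDataError, QuantificationError

__all__ = ["QuantResult", "quantify_sample", "lod", "LINEAR_REGION"]

#: Response interval (as fractions of fitted wmax) treated as the
#: "linear part" of the sigmoid.
LINEAR_REGION = (0.20, 0.80)


@dataclass(frozen=True)
class QuantResult:
    """Absolute quantification outcome.

    concentration/se are nM of the undiluted sample; lod is the assay's
    limit of detection (nM) when blanks were supplied, else None.
    """

    concentration: float
    se: float
    lod: float | None
    saturation: bool
    below_lod: bool
    cal_params: HillParams
    sample_params: HillParams

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise DomainError("concentration must be non-negative")


def _linear_overlap(cal: HillParams, responses: np.ndarray) -> np.ndarray:
    lo, hi = LINEAR_REGION
    return (responses >= lo * cal.wmax) & (responses <= hi * cal.wmax)


def quantify_sample(
    cal: pd.DataFrame,
    sample: pd.DataFrame,
    blanks=None,
    tie_n: bool = True,
    method: str = "km_offset",
) -> QuantResult:
    """Quantify the undiluted sample concentration (nM) from paired curves.

    Parameters
    ----------
    cal : long-format table with columns ``sm_nM`` and ``response``
        (known-concentration calibration series, blank-subtracted).
    sample : long-format table with columns ``dilution`` (fraction of the
        undiluted sample, in (0, 1]) and ``response``.
    blanks : optional replicate blank responses; when given, the LOD is
        computed and the estimate flagged if it falls below it.
    tie_n : share the Hill coefficient between the two fits (both curves
        measure the same biosensor); untied when False.
    method : "km_offset" (default; ratio of half-maximal positions) or
        "linear_interp" (median of point-wise inversions of the
        calibration curve over the linear region).
    """
    dil = np.asarray(sample["dilution"], dtype=float)
    if np.any(dil <= 0) or np.any(dil > 1):
        raise DomainError("dilutions must lie in (0, 1]")
    cal_params = fit_hill(cal)

    sample_means = sample.groupby("dilution")["response"].mean()
    in_linear = _linear_overlap(cal_params, sample_means.to_numpy())
    saturation = bool(np.any(sample_means.to_numpy() > LINEAR_REGION[1] * cal_params.wmax))
    if not np.any(in_linear):
        if saturation:
            raise QuantificationError(
                "all sample responses are saturated; quantification would underestimate"
            )
        raise QuantificationError(
            "sample responses do not overlap the linear part of the calibration curve"
        )

    sample_fit = sample.rename(columns={"dilution": "sm_nM"})
    sample_params = fit_hill(sample_fit, fix_n=cal_params.n if tie_n else None)

    if method == "km_offset":
        conc = cal_params.km / sample_params.km
        rel = np.hypot(
            cal_params.km_se / cal_params.km,
            (sample_params.km_se / sample_params.km) if sample_params.km_se else 0.0,
        )
        se = conc * rel
    elif method == "linear_interp":
        usable = sample_means[in_linear]
        ests = np.array(
            [inverse_hill(resp, cal_params) / d for d, resp in usable.items()]
        )
        conc = float(np.median(ests))
        se = float(np.std(ests, ddof=1) / np.sqrt(len(ests))) if len(ests) > 1 else 0.0
    else:
        raise DomainError(f"unknown method {method!r}")

    lod_value = None
    below = False
    if blanks is not None:
        lod_value = lod(cal_params, blanks)
        below = conc < lod_value
    return QuantResult(
        concentration=float(conc),
        se=float(se),
        lod=lod_value,
        saturation=saturation,
        below_lod=below,
        cal_params=cal_params,
        sample_params=sample_params,
    )


def lod(cal: HillParams, blanks) -> float:
    """Limit of detection: concentration at blank mean + 3 blank SDs.

    The calibration curve is blank-subtracted, so the net threshold is
    3 * SD(blanks); with zero blank scatter the LOD degenerates to the
    blank level itself (0 nM net).  Strictly increasing in the blank SD.
    """
    blanks = np.asarray(blanks, dtype=float)
    if len(blanks) < 3:
        raise InsufficientDataError("LOD needs >= 3 blank replicates")
    threshold = 3.0 * blanks.std(ddof=1)
    if threshold >= cal.wmax:
        raise QuantificationError(
            f"blank + 3 SD threshold ({threshold:.3g}) exceeds the calibration "
            f"maximum ({cal.wmax:.3g}); assay cannot resolve the LOD"
        )
    return float(inverse_hill(threshold, cal))
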