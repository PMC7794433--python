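"""Single-cell heterogeneity statistics for dual-reporter populations.

Per-cell fluorescence of a promoter reporter is lognormally distributed,
but a measured tagged-cell intensity is the sum of the marker signal and
cellular autofluorescence, which cannot simply be subtracted.  Treating
the two contributions as independent, the tagged-cell distribution is the
convolution of the (empirical) autofluorescence distribution with the
unknown lognormal marker distribution; ``deconvolve_marker`` recovers the
marker parameters by chi-square fitting of that convolution to the
tagged-cell histogram.

Rare hyperproducing cells (roughly ten-fold brighter than the population
median) are flagged by an iterative Grubbs outlier test on
log-intensities.  Channel co-localization — do strong signal producers
also respond strongly? — is assessed by comparing the observed Pearson
correlation of paired (YFP, CFP) intensities against a simulated null in
which independently drawn marker intensities are added onto real
autofluorescence-only control cells.  Microplate replicate QC uses the
modified Z-score (median/MAD based) to exclude gross outliers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import DomainError, InsufficientDataError

__all__ = [
    "LognormalParams",
    "HyperproducerReport",
    "ColocalizationResult",
    "deconvolve_marker",
    "detect_hyperproducers",
    "colocalization",
    "modified_z_filter",
    "normalize_to_standard",
]


@dataclass(frozen=True)
class LognormalParams:
    """Lognormal marker-intensity distribution: log X ~ Normal(mu_log, sigma_log)."""

    mu_log: float
    sigma_log: float
    redchi: float | None = None  # reduced chi-square of the convolution fit

    def __post_init__(self) -> None:
        if self.sigma_log <= 0:
            raise DomainError(f"sigma_log must be positive, got {self.sigma_log}")


def _shared_bins(tagged: np.ndarray, control: np.ndarray) -> np.ndarray:
    """Freedman-Diaconis bins on the pooled data, shared by both samples."""
    pooled = np.concatenate([tagged, control])
    iqr = np.subtract(*np.percentile(pooled, [75, 25]))
    width = 2.0 * iqr / len(pooled) ** (1.0 / 3.0)
    lo = 0.0
    hi = float(tagged.max()) * 1.05 + 1e-12
    if width <= 0:
        n_bins = 60
    else:
        n_bins = max(40, min(400, int(np.ceil(hi / width))))
    return np.linspace(lo, hi, n_bins + 1)


def _control_point_masses(control: np.ndarray, max_atoms: int = 200):
    """Empirical autofluorescence distribution as weighted point masses."""
    values, counts = np.unique(control, return_counts=True)
    if len(values) > max_atoms:
        hist, edges = np.histogram(control, bins=max_atoms)
        centers = 0.5 * (edges[:-1] + edges[1:])
        keep = hist > 0
        values, counts = centers[keep], hist[keep]
    return values, counts / counts.sum()


def _convolved_probs(mu: float, sigma: float, atoms, weights, bin_edges) -> np.ndarray:
    """P(tagged in bin) for tagged = control + LogNormal(mu, sigma).

    Exact mixture over the control point masses: for each atom c, the
    marker must land in (edge - c); probabilities from the lognormal CDF.
    """
    # edges x atoms matrix of shifted CDF evaluations
    shifted = bin_edges[:, None] - atoms[None, :]
    cdf = np.zeros_like(shifted)
    pos = shifted > 0
    cdf[pos] = stats.lognorm.cdf(shifted[pos], s=sigma, scale=np.exp(mu))
    per_atom = np.diff(cdf, axis=0)  # bins x atoms
    return per_atom @ weights


def deconvolve_marker(tagged, control, min_expected: float = 4.0) -> LognormalParams:
    """Recover the lognormal marker distribution from tagged and control cells.

    Fits the tagged-intensity histogram with the convolution of the
    empirical control (autofluorescence) distribution and a candidate
    lognormal, minimizing Pearson chi-square over (mu_log, sigma_log).
    Bins with expected counts below ``min_expected`` are pooled out of the
    statistic.  Requires >= 200 cells in each set.
    """
    tagged = np.asarray(tagged, dtype=float)
    control = np.asarray(control, dtype=float)
    if len(tagged) < 200 or len(control) < 200:
        raise InsufficientDataError("deconvolution needs >= 200 cells in each set")
    if tagged.mean() <= control.mean():
        warnings.warn(
            "tagged intensities are not larger than control on average; "
            "marker signal indistinguishable from autofluorescence",
            stacklevel=2,
        )
    edges = _shared_bins(tagged, control)
    obs, _ = np.histogram(tagged, bins=edges)
    atoms, weights = _control_point_masses(control)
    n = len(tagged)

    # moment-based start: marker moments = tagged moments - control moments
    m = max(tagged.mean() - control.mean(), 1e-6)
    v = max(tagged.var(ddof=1) - control.var(ddof=1), 1e-12)
    sigma0 = np.sqrt(np.log1p(v / m**2))
    mu0 = np.log(m) - 0.5 * sigma0**2

    def chisq(theta):
        mu, log_sigma = theta
        probs = _convolved_probs(mu, np.exp(log_sigma), atoms, weights, edges)
        expected = n * probs
        mask = expected >= min_expected
        if mask.sum() < 4:
            return 1e12
        return float(np.sum((obs[mask] - expected[mask]) ** 2 / expected[mask]))

    res = optimize.minimize(
        chisq, x0=[mu0, np.log(max(sigma0, 1e-3))], method="Nelder-Mead",
        options={"xatol": 1e-5, "fatol": 1e-5, "maxiter": 2000},
    )
    mu, sigma = res.x[0], float(np.exp(res.x[1]))
    probs = _convolved_probs(mu, sigma, atoms, weights, edges)
    expected = n * probs
    mask = expected >= min_expected
    dof = max(int(mask.sum()) - 2, 1)
    redchi = float(np.sum((obs[mask] - expected[mask]) ** 2 / expected[mask]) / dof)
    return LognormalParams(mu_log=float(mu), sigma_log=sigma, redchi=redchi)


@dataclass(frozen=True)
class HyperproducerReport:
    """Outcome of iterative Grubbs screening for hyperproducing cells."""

    outlier_indices: tuple[int, ...]
    fraction_percent: float
    fold_brightness: float | None  # median outlier intensity / population median

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_percent <= 100.0:
            raise DomainError("fraction must be a percentage in [0, 100]")


def _grubbs_critical(n: int, alpha: float) -> float:
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))


def detect_hyperproducers(intensities, alpha: float = 0.05) -> HyperproducerReport:
    """Iterative one-at-a-time Grubbs test on log-intensities.

    The population is lognormal, so the test runs on logs.  At each step
    the most deviant value is tested at level ``alpha`` and removed if
    significant; iteration stops at the first non-significant step.
    Flagged cells brighter than the population median are reported as
    hyperproducers with their median fold-brightness.
    """
    x = np.asarray(intensities, dtype=float)
    if len(x) < 30:
        raise InsufficientDataError("Grubbs screening needs >= 30 cells")
    if np.any(x <= 0):
        raise DomainError("intensities must be positive (log scale)")
    logs = np.log(x)
    active = np.arange(len(x))
    outliers: list[int] = []
    while len(active) > 3:
        vals = logs[active]
        sd = vals.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(vals - vals.mean()) / sd
        imax = int(np.argmax(dev))
        if dev[imax] <= _grubbs_critical(len(active), alpha):
            break
        outliers.append(int(active[imax]))
        active = np.delete(active, imax)
    median_all = float(np.median(x))
    high = [i for i in outliers if x[i] > median_all]
    fold = float(np.median(x[high]) / median_all) if high else None
    return HyperproducerReport(
        outlier_indices=tuple(high),
        fraction_percent=100.0 * len(high) / len(x),
        fold_brightness=fold,
    )


@dataclass(frozen=True)
class ColocalizationResult:
    """Observed vs control vs simulated-null channel correlation."""

    r_observed: float
    r_control: float
    r_null_mean: float
    r_null_sd: float
    p_value: float  # two-sided, observed vs the simulated null
    n_draws: int


def colocalization(
    tagged_pairs,
    control_pairs,
    marker_yfp: LognormalParams,
    marker_cfp: LognormalParams,
    n_draws: int = 1000,
    seed: int = 0,
) -> ColocalizationResult:
    """Channel co-localization against an independence null.

    ``tagged_pairs`` and ``control_pairs`` are (n, 2) arrays of per-cell
    (YFP, CFP) intensities for reporter-tagged and untagged control cells.
    The null is built by adding *independently* drawn lognormal marker
    intensities (per channel) onto the control cells, so it carries the
    autofluorescence correlation but no marker coupling; the two-sided
    p-value locates the observed correlation within that null.
    """
    tagged = np.asarray(tagged_pairs, dtype=float)
    control = np.asarray(control_pairs, dtype=float)
    if tagged.ndim != 2 or tagged.shape[1] != 2 or len(tagged) < 30:
        raise InsufficientDataError("need >= 30 tagged (yfp, cfp) pairs")
    if control.ndim != 2 or control.shape[1] != 2 or len(control) < 30:
        raise InsufficientDataError("need >= 30 control (yfp, cfp) pairs")
    rng = np.random.default_rng(seed)
    r_obs = float(stats.pearsonr(tagged[:, 0], tagged[:, 1])[0])
    r_ctl = float(stats.pearsonr(control[:, 0], control[:, 1])[0])
    nc = len(control)
    null = np.empty(n_draws)
    for i in range(n_draws):
        y = control[:, 0] + rng.lognormal(marker_yfp.mu_log, marker_yfp.sigma_log, nc)
        c = control[:, 1] + rng.lognormal(marker_cfp.mu_log, marker_cfp.sigma_log, nc)
        null[i] = stats.pearsonr(y, c)[0]
    hi = float(np.sum(null >= r_obs))
    lo = float(np.sum(null <= r_obs))
    p = min(1.0, 2.0 * (min(hi, lo) + 1.0) / (n_draws + 1.0))
    return ColocalizationResult(
        r_observed=r_obs,
        r_control=r_ctl,
        r_null_mean=float(null.mean()),
        r_null_sd=float(null.std(ddof=1)),
        p_value=p,
        n_draws=n_draws,
    )


def modified_z_filter(values, threshold: float = 3.5):
    """Median/MAD modified Z-score outlier exclusion for replicate sets.

    Excludes values with |0.6745 (x - median)/MAD| > threshold (the
    standard Iglewicz-Hoaglin cutoff).  With MAD = 0 no exclusion is
    possible; a warning is issued and everything kept.

    Returns ``(kept_values, excluded_indices)``.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 4:
        raise InsufficientDataError("modified Z-score QC needs >= 4 replicates")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        warnings.warn("MAD is zero; modified Z-score undefined, keeping all values", stacklevel=2)
        return x.copy(), np.array([], dtype=int)
    z = 0.6745 * (x - med) / mad
    excluded = np.flatnonzero(np.abs(z) > threshold)
    return np.delete(x, excluded), excluded


def normalize_to_standard(raw, standard_reading: float):
    """Divide raw intensities by a fluorescein-standard reading.

    A per-channel scale factor; scale-free statistics (correlations,
    fractions, fold-changes) are unchanged downstream.
    """
    if standard_reading <= 0:
        raise DomainError(f"standard reading must be positive, got {standard_reading}")
    return np.asarray(raw, dtype=float) / standard_reading
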