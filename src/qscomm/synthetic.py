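"""Seeded generators emulating every dataset the analysis consumes.

Each generator is the statistical inverse of a fitting stage: it draws
noisy observations from the forward model at known ("true") parameters so
that round-trip parameter recovery can be tested without any external
data.  Defaults are the fitted operating point of the studied system —
encoder (a = 9.6 nM a.u.^-b, b = 2.09), decoder (Km = 4 nM, n = 2.3),
dynamics (k = 760 M.U., RM0 = 5.5 M.U. a.u.) — with measurement noise
multiplicative lognormal for concentrations, fluorescence and reporter
responses (strictly positive quantities) and the replicate structure of
the emulated assays (8 technical replicates).  Dose-response replicates
additionally carry a small additive background floor so that
near-blank scatter, and hence the lower-limit-of-response rule, behaves
like the real assay.  All generators are bit-reproducible for a fixed
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .decoder import HillParams, hill_response
from .dynamics import DynamicsParams, simulate_response
from .encoder import AllometricParams, sm_concentration
from .errors import DomainError
from .growth import LogisticParams

__all__ = [
    "NoiseModel",
    "SimConfig",
    "gen_sm_series",
    "gen_dose_response",
    "gen_response_trajectory",
    "gen_cell_population",
]


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative CVs per measurement type, plus the assay background floor."""

    cv_concentration: float = 0.10
    cv_response: float = 0.05
    cv_od: float = 0.03
    response_floor_sd: float = 0.003  # additive, as a fraction of wmax

    def __post_init__(self) -> None:
        if min(self.cv_concentration, self.cv_response, self.cv_od, self.response_floor_sd) < 0:
            raise DomainError("noise parameters must be non-negative")


def _default_growth() -> LogisticParams:
    # fermenter batch culture: 2% inoculum reaching carrying capacity in ~8 h
    return LogisticParams(n0=0.02, nmax=1.0, r=0.7)


def _default_encoder() -> AllometricParams:
    return AllometricParams(a=9.6, b=2.09, a_se=0.6, b_se=0.10)


def _default_decoder() -> HillParams:
    return HillParams(wmax=1.0, km=4.0, n=2.3, km_se=0.5, n_se=0.2)


def _default_dynamics() -> DynamicsParams:
    return DynamicsParams(k=760.0, rm0=5.5)


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic study: true parameters, noise, replicates."""

    seed: int = 0
    growth: LogisticParams = field(default_factory=_default_growth)
    encoder: AllometricParams = field(default_factory=_default_encoder)
    decoder: HillParams = field(default_factory=_default_decoder)
    dynamics: DynamicsParams = field(default_factory=_default_dynamics)
    noise: NoiseModel = field(default_factory=NoiseModel)
    n_technical: int = 8
    detection_limit_nM: float = 0.1

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


def _lognormal_factor(rng, cv, size):
    """Mean-one multiplicative lognormal noise at the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(-0.5 * sigma**2, sigma, size)


def gen_sm_series(cfg: SimConfig, n_points: int = 24, od_span=(0.05, 0.97)) -> pd.DataFrame:
    """Signal-versus-density series as measured in a batch fermenter run.

    The OD grid follows the logistic growth curve between the two density
    fractions of carrying capacity in ``od_span``; at each point the
    signal concentration a N^b is measured with ``n_technical`` lognormal
    replicates summarized to mean +- SE.  Rows whose measured mean falls
    below the detection limit are flagged, not dropped.
    """
    g = cfg.growth
    lo, hi = od_span
    t_lo = np.log((g.nmax - g.n0) / g.n0 * lo * g.nmax / (g.nmax - lo * g.nmax)) / g.r
    t_hi = np.log((g.nmax - g.n0) / g.n0 * hi * g.nmax / (g.nmax - hi * g.nmax)) / g.r
    t = np.linspace(max(t_lo, 0.0), t_hi, n_points)
    od = g.density(t)
    rng = np.random.default_rng(cfg.seed)
    truth = sm_concentration(od, cfg.encoder)
    reps = truth[:, None] * _lognormal_factor(
        rng, cfg.noise.cv_concentration, (n_points, cfg.n_technical)
    )
    mean = reps.mean(axis=1)
    se = reps.std(axis=1, ddof=1) / np.sqrt(cfg.n_technical)
    return pd.DataFrame(
        {
            "time_h": t,
            "od650": od,
            "sm_nM": mean,
            "sm_se_nM": se,
            "below_lod": mean < cfg.detection_limit_nM,
        }
    )


def gen_dose_response(
    cfg: SimConfig,
    stock_nM: float = 200.0,
    dilution_factor: float = 1.5,
    n_dilutions: int = 18,
    include_blank: bool = True,
) -> pd.DataFrame:
    """Dose-response table from a serial dilution of a signal stock.

    Emulates the plate assay: a ``dilution_factor`` series from
    ``stock_nM``, 8 technical replicates per dose, Hill-law mean response
    under multiplicative CV noise plus the additive background floor.
    Long format (sm_nM, replicate_id, response).
    """
    conc = stock_nM / dilution_factor ** np.arange(n_dilutions)
    if include_blank:
        conc = np.append(conc, 0.0)
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for c in conc:
        mean = hill_response(c, cfg.decoder)
        vals = mean * _lognormal_factor(rng, cfg.noise.cv_response, cfg.n_technical)
        vals = vals + rng.normal(
            0.0, cfg.noise.response_floor_sd * cfg.decoder.wmax, cfg.n_technical
        )
        for i, v in enumerate(vals):
            rows.append((c, i, v))
    return pd.DataFrame(rows, columns=["sm_nM", "replicate_id", "response"])


def gen_response_trajectory(cfg: SimConfig, n_points: int = 15, t_max: float = 8.0) -> pd.DataFrame:
    """Noisy per-cell response trajectory over a fermenter time course.

    ``simulate_response`` output on an even grid (default ~15 points over
    8 h) with multiplicative CV noise; the se column is the implied
    technical-replicate standard error.
    """
    t = np.linspace(0.0, t_max, n_points)
    clean = simulate_response(cfg.growth, cfg.encoder, cfg.decoder, cfg.dynamics, t)
    rng = np.random.default_rng(cfg.seed)
    y = clean["response_per_cell"].to_numpy() * _lognormal_factor(
        rng, cfg.noise.cv_response, n_points
    )
    out = clean.copy()
    out["response_per_cell"] = y
    out["se"] = cfg.noise.cv_response * y / np.sqrt(cfg.n_technical)
    return out


def gen_cell_population(
    cfg: SimConfig,
    n_cells: int = 1000,
    n_control: int = 1000,
    hyper_fraction: float = 0.0,
    hyper_fold: float = 10.0,
    channel_correlation: float = 0.0,
    autofluorescence=(4.0, 0.3),
    marker_yfp=(5.0, 0.5),
    marker_cfp=(4.8, 0.5),
    timepoint: str = "t3",
) -> pd.DataFrame:
    """Per-cell two-channel intensity table with controls.

    Tagged-cell intensity per channel = lognormal autofluorescence +
    lognormal marker.  ``channel_correlation`` is the correlation of the
    two channels' log-marker levels via a shared standard-normal factor
    (0 = independent channels); ``hyper_fraction`` (percent of tagged
    cells) have their marker set to ``hyper_fold`` times the median
    marker level in both channels — hyperproducers are a discrete bright
    class, not a scaled tail.  Control cells (tagged = False) carry autofluorescence
    only.  Long format: cell_id, channel, intensity, timepoint, tagged.
    """
    if not 0.0 <= hyper_fraction <= 100.0:
        raise DomainError("hyper_fraction is a percentage in [0, 100]")
    if hyper_fold < 1.0:
        raise DomainError("hyper_fold must be >= 1")
    if not 0.0 <= channel_correlation <= 1.0:
        raise DomainError("channel_correlation must lie in [0, 1]")
    rng = np.random.default_rng(cfg.seed)
    mu_a, sd_a = autofluorescence
    rho = channel_correlation
    shared = rng.standard_normal(n_cells)
    markers = {}
    for channel, (mu_m, sd_m) in (("yfp", marker_yfp), ("cfp", marker_cfp)):
        own = rng.standard_normal(n_cells)
        z = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * own
        markers[channel] = np.exp(mu_m + sd_m * z)
    n_hyper = int(round(n_cells * hyper_fraction / 100.0))
    hyper_ids = rng.choice(n_cells, size=n_hyper, replace=False) if n_hyper else np.array([], int)
    rows = []
    for channel in ("yfp", "cfp"):
        auto = rng.lognormal(mu_a, sd_a, n_cells)
        marker = markers[channel].copy()
        marker[hyper_ids] = hyper_fold * np.median(marker)
        intensity = auto + marker
        for cid in range(n_cells):
            rows.append((cid, channel, intensity[cid], timepoint, True))
        control = rng.lognormal(mu_a, sd_a, n_control)
        for j in range(n_control):
            rows.append((n_cells + j, channel, control[j], timepoint, False))
    return pd.DataFrame(
        rows, columns=["cell_id", "channel", "intensity", "timepoint", "tagged"]
    )
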