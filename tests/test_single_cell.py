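"""Lognormal deconvolution, hyperproducer detection, co-localization, QC."""

import numpy as np
import pytest

import qscomm as q
from qscomm.errors import DomainError, InsufficientDataError


def _paired(pop, tagged):
    sub = pop[pop.tagged == tagged]
    piv = sub.pivot(index="cell_id", columns="channel", values="intensity")
    return piv[["yfp", "cfp"]].to_numpy()


class TestDeconvolution:
    def test_point_mass_control_reduces_to_direct_fit(self):
        """With (near) zero autofluorescence the fit is a plain lognormal fit."""
        rng = np.random.default_rng(0)
        tagged = rng.lognormal(5.0, 0.5, 4000)
        control = np.zeros(1000)
        fit = q.deconvolve_marker(tagged, control)
        assert fit.mu_log == pytest.approx(5.0, abs=0.05)
        assert fit.sigma_log == pytest.approx(0.5, abs=0.05)

    def test_parameter_recovery_under_convolution(self):
        """Marker parameters recovered within 5% despite autofluorescence."""
        mus, sigmas = [], []
        for seed in range(50):
            pop = q.gen_cell_population(q.SimConfig(seed=seed), n_cells=5000, n_control=5000)
            sub = pop[pop.channel == "yfp"]
            fit = q.deconvolve_marker(
                sub.loc[sub.tagged, "intensity"].to_numpy(),
                sub.loc[~sub.tagged, "intensity"].to_numpy(),
            )
            mus.append(fit.mu_log)
            sigmas.append(fit.sigma_log)
        assert abs(np.median(mus) - 5.0) / 5.0 < 0.05
        assert abs(np.median(sigmas) - 0.5) / 0.5 < 0.05

    def test_closure_reduced_chi_square_near_one(self):
        """Re-convolving the fitted marker reproduces the tagged histogram."""
        redchis = []
        for seed in range(10):
            pop = q.gen_cell_population(q.SimConfig(seed=seed), n_cells=5000, n_control=5000)
            sub = pop[pop.channel == "yfp"]
            fit = q.deconvolve_marker(
                sub.loc[sub.tagged, "intensity"].to_numpy(),
                sub.loc[~sub.tagged, "intensity"].to_numpy(),
            )
            redchis.append(fit.redchi)
        assert 0.3 < np.median(redchis) < 2.0

    def test_warns_when_marker_indistinguishable(self):
        rng = np.random.default_rng(1)
        base = rng.lognormal(4.0, 0.3, 2000)
        with pytest.warns(UserWarning, match="indistinguishable"):
            q.deconvolve_marker(base[:1000], base[1000:] * 1.5)

    def test_requires_enough_cells(self):
        with pytest.raises(InsufficientDataError):
            q.deconvolve_marker(np.ones(50), np.ones(300))


class TestHyperproducers:
    def test_null_population_rarely_flagged(self):
        fractions = [
            q.detect_hyperproducers(np.random.default_rng(seed).lognormal(5.0, 0.5, 1000))
            .fraction_percent
            for seed in range(100)
        ]
        # per-iteration false-positive rate <= alpha: almost all runs flag nothing
        assert np.mean(np.asarray(fractions) > 0) <= 0.10
        assert np.median(fractions) == 0.0

    def test_spiked_outliers_detected(self):
        """Cells at 10x the population median are caught in >= 90% of runs."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            base = rng.lognormal(5.0, 0.5, 1000)
            spiked = np.concatenate([base, np.full(5, 10 * np.median(base))])
            report = q.detect_hyperproducers(spiked)
            flagged_spikes = sum(i >= 1000 for i in report.outlier_indices)
            hits += flagged_spikes >= 4
        assert hits >= 90

    def test_fold_brightness_reported(self):
        rng = np.random.default_rng(2)
        base = rng.lognormal(5.0, 0.4, 1000)
        spiked = np.concatenate([base, np.full(8, 10 * np.median(base))])
        report = q.detect_hyperproducers(spiked)
        assert report.fold_brightness == pytest.approx(10.0, rel=0.1)
        assert 0.1 <= report.fraction_percent <= 1.5

    def test_round_trip_with_generator(self):
        pop = q.gen_cell_population(
            q.SimConfig(seed=4), n_cells=1000, hyper_fraction=0.5, hyper_fold=10
        )
        tagged = pop.query("channel == 'yfp' and tagged")["intensity"].to_numpy()
        report = q.detect_hyperproducers(tagged)
        assert report.fraction_percent == pytest.approx(0.5, abs=0.3)

    def test_requires_minimum_cells(self):
        with pytest.raises(InsufficientDataError):
            q.detect_hyperproducers(np.ones(10) * 2.0)


class TestColocalization:
    @pytest.fixture
    def markers(self):
        return q.LognormalParams(5.0, 0.5), q.LognormalParams(4.8, 0.5)

    def test_independent_channels_match_null(self, markers):
        pop = q.gen_cell_population(
            q.SimConfig(seed=5), n_cells=3000, n_control=3000, channel_correlation=0.0
        )
        res = q.colocalization(
            _paired(pop, True), _paired(pop, False), *markers, n_draws=400, seed=1
        )
        assert abs(res.r_observed - res.r_null_mean) < 0.05
        assert res.p_value > 0.05

    def test_shared_factor_detected(self, markers):
        hits = 0
        for seed in range(20):
            pop = q.gen_cell_population(
                q.SimConfig(seed=seed), n_cells=800, n_control=800, channel_correlation=0.5
            )
            res = q.colocalization(
                _paired(pop, True), _paired(pop, False), *markers, n_draws=200, seed=seed
            )
            hits += (res.p_value < 0.05) and (res.r_observed > res.r_null_mean)
        assert hits >= 19

    def test_needs_enough_pairs(self, markers):
        with pytest.raises(InsufficientDataError):
            q.colocalization(np.ones((10, 2)), np.ones((100, 2)), *markers)


class TestMicroplateQC:
    def test_identical_replicates_kept(self):
        kept, excluded = q.modified_z_filter(np.full(8, 7.0) + np.arange(8) * 0.01)
        assert len(excluded) == 0 and len(kept) == 8

    def test_gross_outlier_excluded(self):
        vals = np.array([101.0, 99.0, 100.5, 100.0, 99.5, 100.2, 98.8, 1e6])
        kept, excluded = q.modified_z_filter(vals)
        assert list(excluded) == [7]
        assert 1e6 not in kept

    def test_mad_zero_warns_and_keeps_all(self):
        with pytest.warns(UserWarning, match="MAD"):
            kept, excluded = q.modified_z_filter(np.full(6, 3.0))
        assert len(kept) == 6 and len(excluded) == 0

    def test_false_positive_rate_on_gaussian_replicates(self):
        """Exclusion rate on clean 8-replicate Gaussian sets stays near 2%.

        The MAD-based score is heavy-tailed at n = 8, so the simulated
        per-value false-positive rate sits just above 2%.
        """
        rng = np.random.default_rng(0)
        excluded = 0
        trials = 10_000
        for _ in range(trials):
            _, exc = q.modified_z_filter(rng.normal(100.0, 5.0, 8))
            excluded += len(exc)
        assert excluded / (8 * trials) < 0.025


class TestNormalization:
    def test_identity_and_scaling(self):
        x = np.array([1.0, 2.0, 4.0])
        assert q.normalize_to_standard(x, 1.0) == pytest.approx(x)
        assert q.normalize_to_standard(x, 2.0) == pytest.approx(x / 2)

    def test_rejects_nonpositive_standard(self):
        with pytest.raises(DomainError):
            q.normalize_to_standard([1.0], 0.0)

    def test_correlation_invariant_under_per_channel_scaling(self):
        rng = np.random.default_rng(6)
        y = rng.lognormal(5, 0.5, 500)
        c = y * rng.lognormal(0, 0.2, 500)
        r_raw = np.corrcoef(y, c)[0, 1]
        r_norm = np.corrcoef(
            q.normalize_to_standard(y, 3.7), q.normalize_to_standard(c, 1.9)
        )[0, 1]
        assert r_norm == pytest.approx(r_raw, rel=1e-12)
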