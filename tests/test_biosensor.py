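"""Absolute quantification from paired calibration/sample curves, and the LOD."""

import numpy as np
import pandas as pd
import pytest

import qscomm as q
from qscomm.errors import InsufficientDataError, QuantificationError


def _hill_table(params, xs, colname, rng=None, cv=0.0, floor=0.0, n_rep=1):
    rows = []
    for x in xs:
        mean = q.hill_response(x, params)
        for i in range(n_rep):
            v = mean
            if rng is not None:
                v = mean * rng.lognormal(-0.5 * np.log1p(cv**2), np.sqrt(np.log1p(cv**2)))
                v += rng.normal(0, floor * params.wmax)
            rows.append((x, v))
    return pd.DataFrame(rows, columns=[colname, "response"])


@pytest.fixture
def cal_truth():
    return q.HillParams(wmax=100.0, km=4.0, n=2.3)


@pytest.fixture
def cal_table(cal_truth):
    conc = np.append(200 / 1.5 ** np.arange(16), 0.0)
    return _hill_table(cal_truth, conc, "sm_nM")


def _sample_table(cal_truth, truth_nM, dilutions):
    return pd.DataFrame(
        {
            "dilution": dilutions,
            "response": [q.hill_response(truth_nM * d, cal_truth) for d in dilutions],
        }
    )


def test_km_offset_quantification(cal_truth, cal_table):
    """Sample with half-max at dilution 0.4 on a Km = 4 curve is 10 nM undiluted."""
    dil = 1 / 1.5 ** np.arange(12)
    res = q.quantify_sample(cal_table, _sample_table(cal_truth, 10.0, dil))
    assert res.concentration == pytest.approx(10.0, rel=1e-6)
    assert res.sample_params.km == pytest.approx(0.4, rel=1e-6)


def test_self_quantification_equality_case(cal_truth, cal_table):
    """A sample identical to the calibration (measured in dilution units) returns Km."""
    dil = 1 / 1.5 ** np.arange(12)
    res = q.quantify_sample(cal_table, _sample_table(cal_truth, cal_truth.km, dil))
    assert res.concentration == pytest.approx(cal_truth.km, rel=1e-6)


def test_linear_interp_method_agrees(cal_truth, cal_table):
    dil = 1 / 1.5 ** np.arange(12)
    res = q.quantify_sample(cal_table, _sample_table(cal_truth, 10.0, dil), method="linear_interp")
    assert res.concentration == pytest.approx(10.0, rel=1e-6)


def test_quantification_tracks_dilution_relabeling(cal_truth, cal_table):
    """Relabeling the dilution axis by a common factor (same physical series,
    claimed truth scaled accordingly) scales the estimate by that factor."""
    dil = 1 / 1.5 ** np.arange(10)
    est1 = q.quantify_sample(cal_table, _sample_table(cal_truth, 10.0, dil)).concentration
    # identical responses, dilution labels halved => undiluted truth doubled
    est2 = q.quantify_sample(cal_table, _sample_table(cal_truth, 20.0, dil / 2)).concentration
    assert est2 == pytest.approx(2 * est1, rel=1e-6)
    assert est1 == pytest.approx(10.0, rel=1e-6)


def test_saturated_only_sample_raises(cal_truth, cal_table):
    # every dilution deep into saturation
    sample = _sample_table(cal_truth, 4000.0, 1 / 1.5 ** np.arange(5))
    with pytest.raises(QuantificationError):
        q.quantify_sample(cal_table, sample)


def test_end_to_end_recovery_with_noise(cal_truth):
    """Both curves measured with 10% CV, 8 replicates: median estimate within 15%."""
    truth = 12.0
    estimates = []
    for seed in range(100):
        rng = np.random.default_rng(seed)
        conc = np.append(200 / 1.5 ** np.arange(16), 0.0)
        cal = _hill_table(cal_truth, conc, "sm_nM", rng, cv=0.10, floor=0.003, n_rep=8)
        dil = 1 / 1.5 ** np.arange(12)
        samp = _hill_table(
            q.HillParams(cal_truth.wmax, cal_truth.km / truth, cal_truth.n),
            dil, "dilution", rng, cv=0.10, floor=0.003, n_rep=8,
        )
        estimates.append(q.quantify_sample(cal, samp).concentration)
    assert abs(np.median(estimates) - truth) / truth < 0.15


def test_lod_degenerate_blanks(cal_truth):
    assert q.lod(cal_truth, [10.0, 10.0, 10.0]) == 0.0


def test_lod_three_sigma_value(cal_truth):
    """Blanks 10 +- 2: threshold is 6 net response units above blank."""
    blanks = np.array([10.0, 12.0, 8.0])  # mean 10, sd 2
    expected = q.inverse_hill(6.0, cal_truth)  # = 4 * (0.06/0.94)^(1/2.3)
    assert expected == pytest.approx(1.2092, abs=1e-4)
    assert q.lod(cal_truth, blanks) == pytest.approx(expected, rel=1e-12)


def test_lod_monotone_in_blank_sd(cal_truth):
    lods = [
        q.lod(cal_truth, [10.0, 10.0 + s, 10.0 - s, 10.0, 10.0 + s, 10.0 - s])
        for s in (0.5, 1.0, 2.0, 4.0)
    ]
    assert np.all(np.diff(lods) > 0)


def test_lod_threshold_beyond_calibration_raises(cal_truth):
    with pytest.raises(QuantificationError):
        q.lod(cal_truth, [0.0, 80.0, -80.0])  # sd far above wmax/3


def test_lod_needs_three_blanks(cal_truth):
    with pytest.raises(InsufficientDataError):
        q.lod(cal_truth, [10.0, 11.0])
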