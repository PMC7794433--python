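"""Logistic growth, exponential-slope comparisons, competition, OD-O2 coupling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import qscomm as q
from qscomm.errors import DomainError, InsufficientDataError


def _curve(growth: q.LogisticParams, t):
    return pd.DataFrame({"time_h": t, "od650": growth.density(t)})


def test_fit_logistic_exact_on_noiseless_data(fermenter_growth):
    t = np.linspace(0.0, 10.0, 30)
    fit = q.fit_logistic(_curve(fermenter_growth, t))
    assert fit.n0 == pytest.approx(0.02, rel=1e-6)
    assert fit.nmax == pytest.approx(1.0, rel=1e-6)
    assert fit.r == pytest.approx(0.7, rel=1e-6)


def test_specific_growth_rate_vanishes_at_carrying_capacity(fermenter_growth):
    assert fermenter_growth.mu(200.0) == pytest.approx(0.0, abs=1e-12)
    assert fermenter_growth.mu(0.0) == pytest.approx(0.7 * (1 - 0.02), rel=1e-12)


def test_fit_logistic_recovery_under_noise():
    truth = q.LogisticParams(n0=0.02, nmax=1.0, r=0.35)
    t = np.linspace(0.0, 24.0, 30)
    recovered = []
    for seed in range(100):
        rng = np.random.default_rng(seed)
        od = truth.density(t) * (1 + rng.normal(0, 0.03, len(t)))
        recovered.append(q.fit_logistic(pd.DataFrame({"time_h": t, "od650": od})).r)
    assert np.median(recovered) == pytest.approx(0.35, rel=0.05)


@given(t=st.floats(0.0, 30.0))
def test_logistic_solution_satisfies_its_ode(t):
    g = q.LogisticParams(n0=0.02, nmax=1.0, r=0.7)
    n = g.density(t)
    dt = 1e-4
    deriv = (g.density(t + dt) - g.density(t - dt)) / (2 * dt)
    assert deriv == pytest.approx(g.r * n * (1 - n / g.nmax), rel=1e-5, abs=1e-10)


def test_exponential_slope_exact_on_pure_exponential():
    t = np.linspace(0.0, 8.0, 20)
    od = 0.05 * 2 ** (0.5 * t)
    res = q.exponential_slope(pd.DataFrame({"time_h": t, "od650": od}))
    assert res.slope == pytest.approx(0.5, rel=1e-12)
    assert res.rate_ln == pytest.approx(0.5 * np.log(2), rel=1e-12)


def test_exponential_slope_invariant_to_od_rescaling():
    t = np.linspace(0.0, 8.0, 20)
    rng = np.random.default_rng(0)
    od = 0.05 * 2 ** (0.5 * t) * (1 + rng.normal(0, 0.02, len(t)))
    base = q.exponential_slope(pd.DataFrame({"time_h": t, "od650": od}), od_window=(0.0, 1e9))
    scaled = q.exponential_slope(
        pd.DataFrame({"time_h": t, "od650": 3.0 * od}), od_window=(0.0, 1e9)
    )
    assert scaled.slope == pytest.approx(base.slope, rel=1e-12)


def test_exponential_slope_needs_points_in_window():
    t = np.array([0.0, 1.0, 2.0])
    with pytest.raises(InsufficientDataError):
        q.exponential_slope(pd.DataFrame({"time_h": t, "od650": [0.01, 0.02, 0.03]}))


def test_slope_comparison_null_case():
    t = np.linspace(0.0, 8.0, 20)
    rng = np.random.default_rng(1)
    mk = lambda seed: pd.DataFrame(
        {"time_h": t, "od650": 0.05 * 2 ** (0.5 * t) * (1 + np.random.default_rng(seed).normal(0, 0.02, len(t)))}
    )
    sa = q.exponential_slope(mk(1))
    sb = q.exponential_slope(mk(2))
    t_stat, p = q.compare_slopes(sa, sb)
    assert p > 0.05


def test_competition_constant_ratio_gives_zero_selection():
    series = pd.DataFrame({"transfer": range(7), "cfu_a": [500] * 7, "cfu_b": [500] * 7})
    res = q.competition_ratio(series)
    assert res.selection_coefficient == pytest.approx(0.0, abs=1e-12)
    assert np.allclose(res.log2_ratio, 0.0)


def test_competition_swapping_strains_negates_selection():
    rng = np.random.default_rng(5)
    a = (500 * 1.05 ** np.arange(7) * (1 + rng.normal(0, 0.02, 7))).astype(int)
    b = np.full(7, 500)
    fwd = q.competition_ratio(pd.DataFrame({"transfer": range(7), "cfu_a": a, "cfu_b": b}))
    rev = q.competition_ratio(pd.DataFrame({"transfer": range(7), "cfu_a": b, "cfu_b": a}))
    assert rev.selection_coefficient == pytest.approx(-fwd.selection_coefficient, rel=1e-9)


def test_competition_neutral_drift_ci_covers_zero():
    """Equal fitness with binomial plating noise: the CI contains 0 in >= 90% of runs.

    The co-culture bottleneck is huge, so the composition stays ~1:1 and the
    per-transfer CFU counts are independent binomial samples of it.
    """
    total = 1000
    covered = 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        counts_a = rng.binomial(total, 0.5, 7)
        df = pd.DataFrame(
            {"transfer": range(7), "cfu_a": counts_a, "cfu_b": total - counts_a}
        )
        lo, hi = q.competition_ratio(df).ci95
        covered += lo <= 0.0 <= hi
    assert covered >= 90


def test_competition_detects_five_percent_advantage():
    detected = 0
    for seed in range(50):
        rng = np.random.default_rng(seed)
        a = 500 * 1.05 ** np.arange(7) * (1 + rng.normal(0, 0.01, 7))
        b = np.full(7, 500.0)
        res = q.competition_ratio(pd.DataFrame({"transfer": range(7), "cfu_a": a, "cfu_b": b}))
        detected += res.ci95[0] > 0.0
    assert detected >= 45


def test_competition_flags_zero_count_transfers():
    df = pd.DataFrame({"transfer": [0, 1, 2], "cfu_a": [500, 0, 400], "cfu_b": [500, 600, 500]})
    res = q.competition_ratio(df)
    assert res.undefined_transfers == (1,)
    assert np.isnan(res.log2_ratio.loc[1])


def test_od_do_perfect_anticorrelation():
    od = np.linspace(0.05, 1.0, 20)
    df = pd.DataFrame({"time_h": np.arange(20.0), "od650": od, "do_percent": 100 - 80 * od})
    r, p = q.correlate_od_do(df)
    assert r == pytest.approx(-1.0, abs=1e-12)


def test_od_do_null_when_shuffled():
    rng = np.random.default_rng(3)
    od = np.linspace(0.05, 1.0, 40)
    df = pd.DataFrame(
        {"time_h": np.arange(40.0), "od650": od, "do_percent": rng.permutation(100 - 80 * od)}
    )
    r, p = q.correlate_od_do(df)
    assert abs(r) < 0.4 and p > 0.05


def test_od_do_logistic_drawdown_strongly_negative(fermenter_growth):
    t = np.linspace(0.0, 10.0, 25)
    od = fermenter_growth.density(t)
    rng = np.random.default_rng(7)
    do = 100 * (1 - od / fermenter_growth.nmax) + rng.normal(0, 2.0, len(t))
    df = pd.DataFrame({"time_h": t, "od650": od, "do_percent": do})
    r, _ = q.correlate_od_do(df)
    assert r < -0.95


def test_od_do_requires_o2_series(fermenter_growth):
    t = np.linspace(0.0, 10.0, 25)
    with pytest.raises(DomainError):
        q.correlate_od_do(_curve(fermenter_growth, t))
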