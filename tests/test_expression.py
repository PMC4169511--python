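"""Analytic expression kinetics, onset fitting and distribution summaries."""

import math
from types import SimpleNamespace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lipokinetics as lk

RATES = lk.get_preset("multilipoplex_slow")
TIMES = np.arange(0.0, 30.01, 0.1)


def test_fast_maturation_limit_peak_closed_form():
    """k_M -> inf reduces the cascade to the two-exponential solution."""
    a, c = RATES.d_M, RATES.d_G
    tau_star = math.log(a / c) / (a - c)
    peak = RATES.k_TL * (math.exp(-a * tau_star) - math.exp(-c * tau_star)) / (c - a)
    fast = RATES.replace(k_M=1e7)
    tp, pv = lk.unit_peak(fast)
    assert tp == pytest.approx(tau_star, rel=1e-4)          # ~17.0 h
    assert pv == pytest.approx(peak, rel=1e-4)
    assert 350 * pv == pytest.approx(3.7e5, rel=0.01)


@pytest.mark.parametrize("rates", [
    RATES,
    RATES.replace(d_M=0.056),                 # exact rate coincidence d_M = d_G
    RATES.replace(k_M=0.5),
    lk.get_preset("multilipoplex_fast"),
])
def test_expression_curve_matches_ode(rates):
    from scipy.integrate import solve_ivp

    t0, m0 = 2.0, 500.0
    y = lk.expression_curve(TIMES, t0, m0, rates)

    def rhs(t, s):
        m, g, gs = s
        return [-rates.d_M * m,
                rates.k_TL * m - (rates.k_M + rates.d_G) * g,
                rates.k_M * g - rates.d_G * gs]

    sol = solve_ivp(rhs, (t0, 30.0), [m0, 0, 0], t_eval=TIMES[TIMES >= t0],
                    method="LSODA", rtol=1e-10, atol=1e-10)
    np.testing.assert_allclose(y[TIMES >= t0], sol.y[2], rtol=1e-4, atol=1e-4)


def test_curve_linearity_and_zero():
    assert np.all(lk.expression_curve(TIMES, 3.0, 0.0, RATES) == 0)
    one = lk.expression_curve(TIMES, 3.0, 350.0, RATES)
    two = lk.expression_curve(TIMES, 3.0, 700.0, RATES)
    np.testing.assert_allclose(two, 2 * one, rtol=1e-12)
    with pytest.raises(ValueError):
        lk.expression_curve(TIMES, 3.0, -1.0, RATES)


@pytest.mark.parametrize("t0,m0", [(4.0, 700.0), (0.5, 350.0), (9.0, 1400.0)])
def test_noiseless_recovery(t0, m0):
    """The fit is the exact inverse of the curve on noiseless data."""
    y = lk.expression_curve(TIMES, t0, m0, RATES)
    fit = lk.fit_onset_maxgfp(TIMES, y, RATES, include_maturation=True)
    assert fit.converged
    assert abs(fit.t0 - t0) < 0.01
    _, pv = lk.unit_peak(RATES)
    assert fit.maxGFP == pytest.approx(m0 * pv, rel=1e-3)


def test_flat_trace_flagged_not_silently_zero():
    fit = lk.fit_onset_maxgfp(TIMES, np.zeros_like(TIMES), RATES)
    assert not fit.converged and math.isnan(fit.t0)


def test_two_stage_fit_absorbs_maturation_lag():
    """Default measurement model shifts the onset by ~1/k_M."""
    y = lk.expression_curve(TIMES, 3.0, 350.0, RATES)
    fit = lk.fit_onset_maxgfp(TIMES, y, RATES)  # include_maturation=False
    assert fit.converged
    assert fit.t0 - 3.0 == pytest.approx(1.0 / RATES.k_M, abs=0.05)


def test_noisy_fixture_recovery_median_error():
    table = lk.make_fixtures(100, RATES, seed=2024, noise_sigma=0.05)
    errors = []
    for cid in table.cell_ids:
        t, y = table.trace(cid)
        fit = lk.fit_onset_maxgfp(t, y, RATES, include_maturation=True)
        truth = table.truth.loc[table.truth.cell_id == cid].iloc[0]
        if fit.converged:
            errors.append(abs(fit.t0 - truth.t0))
    assert len(errors) >= 95
    assert np.median(errors) < 0.3


def test_onset_distribution_hand_values():
    assert lk.onset_distribution(np.array([3.0, 3.0, 3.0])) == \
        lk.DistributionSummary("gaussian", 3.0, 0.0, 3)
    d = lk.onset_distribution(np.array([2.0, 4.0]))
    assert d.location == pytest.approx(3.0) and d.width == pytest.approx(math.sqrt(2))
    with pytest.raises(ValueError):
        lk.onset_distribution(np.array([3.0]))


def test_maxgfp_distribution_hand_values():
    d = lk.maxgfp_distribution(np.exp([12.0, 12.0]))
    assert d.location == pytest.approx(math.exp(12)) and d.width == 0.0
    d = lk.maxgfp_distribution(np.exp([11.0, 13.0]))
    assert d.location == pytest.approx(math.exp(12))
    assert d.width == pytest.approx(math.sqrt(2))
    d = lk.maxgfp_distribution(np.array([0.0, -1.0, math.e, math.e]))
    assert d.n == 2 and d.location == pytest.approx(math.e)
    with pytest.raises(ValueError):
        lk.maxgfp_distribution(np.array([0.0, 5.0]))


@given(st.lists(st.floats(0.1, 50.0), min_size=3, max_size=30),
       st.floats(0.5, 20.0))
@settings(max_examples=40, deadline=None)
def test_summaries_permutation_and_scale_invariance(values, scale):
    values = np.array(values)
    rng = np.random.default_rng(0)
    perm = rng.permutation(values)
    a, b = lk.maxgfp_distribution(values), lk.maxgfp_distribution(perm)
    assert a.location == pytest.approx(b.location) and a.width == pytest.approx(b.width)
    scaled = lk.maxgfp_distribution(values * scale)
    assert scaled.location == pytest.approx(a.location * scale, rel=1e-9)
    assert scaled.width == pytest.approx(a.width, abs=1e-9)


def test_transfection_efficiency_poisson_oracle():
    rng = np.random.default_rng(5)
    ens = SimpleNamespace(n_packets=rng.poisson(0.85, size=20000))
    te = lk.transfection_efficiency(ens)
    expected = 1 - math.exp(-0.85)
    se = math.sqrt(expected * (1 - expected) / 20000)
    assert abs(te - expected) < 3 * se
    assert lk.transfection_efficiency(SimpleNamespace(n_packets=np.zeros(10))) == 0.0
    assert lk.transfection_efficiency(SimpleNamespace(n_packets=np.array([]))) == 0.0


def test_fit_based_te_agrees_with_ground_truth():
    rates = RATES
    net = lk.build_network("multilipoplex", rates, lk.make_reference_design(rates))
    ens = lk.simulate_ensemble(net, 300, seed=17)
    fits = [lk.fit_onset_maxgfp(ens.times, ens.gfp[i], rates) for i in range(300)]
    gt = lk.transfection_efficiency(ens)
    fb = lk.transfection_efficiency(ens, method="fit", fits=fits)
    assert fb == pytest.approx(gt, abs=0.02)
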