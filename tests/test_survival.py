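"""Survival-engine tests: Kaplan-Meier, log-rank, Cox PH, risk prediction
and Harrell's C, each checked against an independent route (hand
computation, brute force, or lifelines)."""

import numpy as np
import pandas as pd
import pytest

from sirsurv import (cox_fit, harrell_c, kaplan_meier, logrank_test,
                     predict_event_prob)

# ---------------------------------------------------------------- KM ----


def test_km_hand_product_limit():
    c = kaplan_meier([1, 2, 3], [1, 0, 1])
    assert np.allclose(c.event_times, [1, 3])
    assert c.survival_at(1) == pytest.approx(2 / 3)
    assert c.survival_at(3) == pytest.approx(0.0)


def test_km_hand_product_limit_with_tie():
    c = kaplan_meier([2, 4, 4, 6], [1, 1, 0, 1])
    assert c.survival_at(2) == pytest.approx(3 / 4)
    assert c.survival_at(4) == pytest.approx(1 / 2)
    assert c.survival_at(6) == pytest.approx(0.0)
    assert list(c.at_risk) == [4, 3, 1]


def test_km_all_censored_flat_at_one():
    c = kaplan_meier([1.0, 2.0, 5.0], [0, 0, 0])
    assert c.event_times.size == 0
    assert c.survival_at(10.0) == 1.0
    assert np.isnan(c.median_survival)


def test_km_empty_raises():
    with pytest.raises(ValueError):
        kaplan_meier([], [])


def test_km_uncensored_equals_empirical(rng):
    t = rng.exponential(10, 200)
    c = kaplan_meier(t, np.ones(200))
    emp = np.array([(t > u).mean() for u in c.event_times])
    assert np.allclose(c.survival_prob, emp)


def test_km_matches_lifelines(rng):
    from lifelines import KaplanMeierFitter

    t = np.round(rng.exponential(20, 150)) + 1
    e = (rng.random(150) < 0.6).astype(int)
    ours = kaplan_meier(t, e)
    kmf = KaplanMeierFitter().fit(t, e)
    theirs = kmf.survival_function_at_times(ours.event_times).to_numpy()
    assert np.allclose(ours.survival_prob, theirs)
    med = kmf.median_survival_time_
    assert ours.median_survival == pytest.approx(med) or \
        (np.isnan(ours.median_survival) and np.isinf(med))


def test_km_median_ci_brackets_median(medium_cohort):
    c = kaplan_meier(medium_cohort["os_time"], medium_cohort["os_event"])
    lo, hi = c.median_ci
    assert lo <= c.median_survival <= hi


# ----------------------------------------------------------- log-rank ----


def _logrank_oracle(times, events, groups):
    """Brute-force two-group log-rank: per-event-time hypergeometric terms."""
    times, events, groups = map(np.asarray, (times, events, groups))
    labels = np.unique(groups)
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == labels[0])).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (groups == labels[0])).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e ** 2 / var


def test_logrank_identical_groups_is_null():
    t = [1, 3, 5, 7]
    e = [1, 0, 1, 1]
    res = logrank_test(t + t, e + e, [0] * 4 + [1] * 4)
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)


def test_logrank_matches_hand_oracle():
    t = [2, 3, 5, 6, 8, 11]
    e = [1, 1, 0, 1, 1, 0]
    g = [0, 1, 0, 1, 0, 1]
    res = logrank_test(t, e, g)
    assert res.statistic == pytest.approx(_logrank_oracle(t, e, g))


def test_logrank_label_swap_invariance(rng):
    t = rng.exponential(10, 80)
    e = (rng.random(80) < 0.7).astype(int)
    g = (rng.random(80) < 0.5).astype(int)
    a = logrank_test(t, e, g)
    b = logrank_test(t, e, 1 - g)
    assert a.statistic == pytest.approx(b.statistic)


def test_logrank_three_groups(medium_cohort):
    g = pd.qcut(medium_cohort["nlr"], 3, labels=False)
    res = logrank_test(medium_cohort["os_time"], medium_cohort["os_event"], g)
    assert res.df == 2
    assert 0 <= res.p_value <= 1


def test_logrank_single_group_raises():
    with pytest.raises(ValueError):
        logrank_test([1, 2, 3], [1, 1, 0], [0, 0, 0])


# ---------------------------------------------------------------- Cox ----

_COX8_X = np.array([0.5, -1.2, 0.3, 2.0, -0.7, 1.1, -0.2, 0.9])
_COX8_T = np.array([3.0, 5.0, 7.0, 2.0, 11.0, 4.0, 9.0, 6.0])
_COX8_E = np.array([1, 1, 0, 1, 0, 1, 1, 1])


def _partial_loglik_grid(x, t, e, grid):
    """Exact no-ties partial log-likelihood over a beta grid (oracle)."""
    ll = np.zeros(grid.size)
    for ti in t[e == 1]:
        i = np.flatnonzero(t == ti)[0]
        risk = t >= ti
        ll += x[i] * grid - np.log(
            np.exp(np.outer(x[risk], grid)).sum(axis=0))
    return ll


def test_cox_matches_grid_search_oracle():
    grid = np.arange(-3.0, 3.0, 2e-5)
    oracle = grid[np.argmax(_partial_loglik_grid(_COX8_X, _COX8_T, _COX8_E,
                                                 grid))]
    fit = cox_fit(_COX8_X[:, None], _COX8_T, _COX8_E)
    assert fit.coef[0] == pytest.approx(oracle, abs=1e-4)


def test_cox_scaling_reparameterisation():
    f1 = cox_fit(_COX8_X[:, None], _COX8_T, _COX8_E)
    f2 = cox_fit(2 * _COX8_X[:, None], _COX8_T, _COX8_E)
    assert f2.coef[0] == pytest.approx(f1.coef[0] / 2, rel=1e-8)
    assert f2.loglik_fit == pytest.approx(f1.loglik_fit, abs=1e-10)


def test_cox_score_vanishes_and_loglik_nests(medium_cohort):
    from sirsurv import coxph

    X = np.column_stack([np.log(medium_cohort["nlr"]),
                         medium_cohort["plr"] / 100])
    t = medium_cohort["os_time"].to_numpy()
    e = medium_cohort["os_event"].to_numpy()
    fit = cox_fit(X, t, e)
    prep = coxph.prepare(t, e)
    _, grad, _ = coxph.loglik_grad_hess(prep, X[prep.order], fit.coef)
    assert np.abs(grad).max() < 1e-6
    assert fit.loglik_fit >= fit.loglik_null


def test_cox_matches_lifelines_with_ties(rng):
    from lifelines import CoxPHFitter

    n = 250
    X = rng.normal(size=(n, 3))
    t = np.round(rng.exponential(np.exp(-X @ [0.4, -0.2, 0.1]), n) * 12) + 1
    e = (rng.random(n) < 0.7).astype(float)
    fit = cox_fit(X, t, e)
    df = pd.DataFrame(X, columns=list("abc")).assign(t=t, e=e)
    cph = CoxPHFitter().fit(df, "t", "e")
    assert np.allclose(fit.coef, cph.params_.to_numpy(), atol=1e-6)
    assert np.allclose(fit.se, cph.standard_errors_.to_numpy(), atol=1e-6)
    assert fit.loglik_fit == pytest.approx(cph.log_likelihood_)


def test_cox_flags_perfect_separation():
    x = np.array([0.0, 0, 0, 0, 1, 1, 1, 1])
    t = np.array([1.0, 2, 3, 4, 10, 11, 12, 13])
    e = np.ones(8)
    with pytest.warns(UserWarning, match="monotone"):
        fit = cox_fit(x[:, None], t, e)
    assert not fit.converged


def test_cox_rejects_constant_column():
    with pytest.raises(ValueError, match="constant"):
        cox_fit(np.ones((5, 1)), [1, 2, 3, 4, 5], [1, 1, 1, 0, 1])


def test_cox_no_events_raises():
    with pytest.raises(ValueError):
        cox_fit(np.arange(4.0)[:, None], [1, 2, 3, 4], [0, 0, 0, 0])


# ------------------------------------------------------- predictions ----


def test_predict_zero_before_first_event():
    fit = cox_fit(_COX8_X[:, None], _COX8_T, _COX8_E)
    assert predict_event_prob(fit, [0.0], 0.5) == 0.0


def test_predict_monotone_in_linear_predictor():
    fit = cox_fit(_COX8_X[:, None], _COX8_T, _COX8_E)
    lo = predict_event_prob(fit, [-1.0], 6.0)
    hi = predict_event_prob(fit, [1.0], 6.0)
    assert (hi > lo) == (fit.coef[0] > 0)


def test_predict_beyond_last_event_warns():
    fit = cox_fit(_COX8_X[:, None], _COX8_T, _COX8_E)
    with pytest.warns(UserWarning, match="beyond"):
        p = predict_event_prob(fit, [0.3], 1000.0)
    assert 0 < p <= 1


def test_predicted_risk_averages_to_km(medium_cohort):
    """Mean model-based event probability at a horizon tracks 1 - KM."""
    X = np.column_stack([np.log(medium_cohort["nlr"]),
                         medium_cohort["plr"] / 100])
    t = medium_cohort["os_time"].to_numpy()
    e = medium_cohort["os_event"].to_numpy()
    fit = cox_fit(X, t, e)
    horizon = 36.0
    probs = predict_event_prob(fit, X, horizon)
    km = kaplan_meier(t, e).survival_at(horizon)
    assert abs(probs.mean() - (1 - km)) < 0.02


# ------------------------------------------------------- Harrell's C ----


def _harrell_oracle(risk, t, e):
    num = den = 0.0
    n = len(t)
    for i in range(n):
        for j in range(n):
            if e[i] == 1 and t[i] < t[j]:
                den += 1
                if risk[i] > risk[j]:
                    num += 1
                elif risk[i] == risk[j]:
                    num += 0.5
    return num / den


def test_harrell_perfect_concordance():
    t = np.array([5.0, 3, 8, 1, 6])
    assert harrell_c(-t, t, np.ones(5)) == 1.0


def test_harrell_constant_risk_is_half():
    t = np.array([5.0, 3, 8, 1, 6])
    assert harrell_c(np.zeros(5), t, np.ones(5)) == 0.5


def test_harrell_matches_pairwise_enumeration(rng):
    t = rng.exponential(10, 10)
    e = np.array([1, 0, 1, 1, 0, 1, 1, 0, 1, 1])
    risk = rng.normal(size=10)
    risk[3] = risk[6]  # force a risk tie
    assert harrell_c(risk, t, e) == pytest.approx(_harrell_oracle(risk, t, e))


def test_harrell_no_usable_pairs_raises():
    with pytest.raises(ValueError):
        harrell_c([1.0, 2.0], [3.0, 3.0], [0, 0])
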