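"""Evaluation statistics against exhaustive oracles and survival packages."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from neoresp.metrics import (assign_risk_groups, auc, bootstrap_ci, c_index,
                             hazard_ratio, km_estimate, logrank, net_benefit,
                             permutation_importance, posterior_shift,
                             risk_cutoff, youden_threshold)


# ----------------------------------------------------------------------- AUC


def brute_force_auc(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_auc_examples():
    assert auc([0.9, 0.8, 0.7, 0.1], [1, 0, 1, 0]) == pytest.approx(0.75)
    assert auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
    assert auc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0]) == 0.5


def test_auc_single_class_error():
    with pytest.raises(ValueError):
        auc([0.1, 0.9], [1, 1])


@pytest.mark.parametrize("n,ties", [(50, False), (200, True), (499, True)])
def test_auc_equals_pair_counting(n, ties, rng):
    scores = rng.integers(0, 20, n).astype(float) if ties else rng.normal(size=n)
    labels = rng.integers(0, 2, n)
    labels[:2] = [0, 1]
    assert auc(scores, labels) == pytest.approx(brute_force_auc(scores, labels),
                                                abs=1e-12)


def test_auc_matches_sklearn(rng):
    from sklearn.metrics import roc_auc_score

    scores = rng.normal(size=300)
    labels = rng.integers(0, 2, 300)
    labels[:2] = [0, 1]
    assert auc(scores, labels) == pytest.approx(roc_auc_score(labels, scores))


def test_bootstrap_ci_brackets_point(rng):
    scores = np.concatenate([rng.normal(1, 1, 100), rng.normal(0, 1, 100)])
    labels = np.array([1] * 100 + [0] * 100)
    m = bootstrap_ci(auc, scores, labels, n_bootstrap=200, seed=1)
    assert m.ci_low <= m.estimate <= m.ci_high
    assert m.estimate == pytest.approx(auc(scores, labels))
    # seeded: identical reruns
    m2 = bootstrap_ci(auc, scores, labels, n_bootstrap=200, seed=1)
    assert (m.ci_low, m.ci_high) == (m2.ci_low, m2.ci_high)


# ------------------------------------------------------------------- C-index


def brute_force_cindex(risk, times, events):
    num = den = 0.0
    n = len(risk)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            usable = (events[i] == 1 and times[i] < times[j]) or (
                events[i] == 1 and events[j] == 0 and times[i] == times[j])
            if usable:
                den += 1
                num += 1.0 if risk[i] > risk[j] else (0.5 if risk[i] == risk[j] else 0.0)
    return num / den


def test_cindex_perfect_and_ties():
    times = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
    events = np.ones(5)
    assert c_index(np.arange(5), times, events) == 1.0
    assert c_index(np.zeros(5), times, events) == 0.5


def test_cindex_toy_with_censoring():
    risk = np.array([2.0, 1.0, 3.0, 0.5, 1.5])
    times = np.array([1.0, 3.0, 2.0, 4.0, 2.0])
    events = np.array([1, 0, 1, 1, 0])
    assert c_index(risk, times, events) == pytest.approx(
        brute_force_cindex(risk, times, events))


def test_cindex_matches_brute_force_random(rng):
    n = 200
    risk = rng.integers(0, 10, n).astype(float)
    times = rng.integers(1, 30, n).astype(float)
    events = rng.integers(0, 2, n)
    events[0] = 1
    assert c_index(risk, times, events) == pytest.approx(
        brute_force_cindex(risk, times, events), abs=1e-12)


def test_cindex_matches_lifelines(rng):
    from lifelines.utils import concordance_index

    n = 300
    risk = rng.normal(size=n)
    times = rng.exponential(5, n) + 0.01
    events = rng.integers(0, 2, n)
    events[0] = 1
    # lifelines concordance is for predicted survival time (higher = later)
    assert c_index(risk, times, events) == pytest.approx(
        1.0 - concordance_index(times, risk, events))


def test_cindex_no_comparable_pairs():
    with pytest.raises(ValueError):
        c_index([1.0, 2.0], [1.0, 2.0], [0, 0])


# -------------------------------------------------------------- Kaplan-Meier


def test_km_no_censoring_is_empirical_survival(rng):
    times = rng.exponential(3, 80) + 0.01
    curve = km_estimate(times, np.ones(80))
    for t, s in zip(curve.times, curve.survival):
        assert s == pytest.approx(np.mean(times > t))


def test_km_matches_lifelines(rng):
    from lifelines import KaplanMeierFitter

    times = rng.exponential(3, 120) + 0.01
    events = rng.integers(0, 2, 120)
    events[:2] = 1
    curve = km_estimate(times, events)
    kmf = KaplanMeierFitter().fit(times, events)
    ref = kmf.survival_function_at_times(curve.times).to_numpy()
    np.testing.assert_allclose(curve.survival, ref, atol=1e-10)


def test_km_survival_nonincreasing(rng):
    times = rng.exponential(2, 60) + 0.01
    events = rng.integers(0, 2, 60)
    events[0] = 1
    curve = km_estimate(times, events)
    assert np.all(np.diff(curve.survival) <= 1e-15)
    assert curve.survival[0] <= 1.0


# ------------------------------------------------------------------ log-rank


def test_logrank_identical_groups_null():
    times = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
    events = np.array([1, 1, 0, 1, 1, 0])
    groups = np.array([0, 0, 0, 1, 1, 1])
    chi2, p = logrank(times, events, groups)
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert p >= 0.99


def test_logrank_matches_lifelines(rng):
    from lifelines.statistics import logrank_test

    n = 150
    groups = rng.integers(0, 2, n)
    times = rng.exponential(3 + 2 * groups) + 0.01
    events = rng.integers(0, 2, n)
    events[:4] = 1
    chi2, p = logrank(times, events, groups)
    ref = logrank_test(times[groups == 0], times[groups == 1],
                       events[groups == 0], events[groups == 1])
    assert chi2 == pytest.approx(ref.test_statistic, rel=1e-6)
    assert p == pytest.approx(ref.p_value, rel=1e-6)


def test_logrank_empty_group_error():
    with pytest.raises(ValueError):
        logrank([1.0, 2.0], [1, 1], [0, 0])


# -------------------------------------------------------------- hazard ratio


def test_hazard_ratio_identical_groups_is_one():
    times = np.tile([1.0, 2.0, 3.0, 4.0], 2)
    events = np.tile([1, 1, 0, 1], 2)
    group = np.repeat([0, 1], 4)
    hr = hazard_ratio(group, times, events)
    assert hr["hr"] == pytest.approx(1.0, abs=1e-6)


def test_hazard_ratio_matches_grid_search(rng):
    from neoresp.model import cox_loss

    n = 20
    group = rng.integers(0, 2, n).astype(float)
    times = rng.exponential(2 * np.exp(-0.8 * group)) + 0.01
    events = rng.integers(0, 2, n)
    events[group == 1][:1] = 1
    events[:4] = 1
    hr = hazard_ratio(group, times, events)
    grid = np.linspace(-4, 4, 80001)
    losses = [cox_loss(b * group, times, events) for b in grid]
    beta_grid = grid[int(np.argmin(losses))]
    assert hr["beta"] == pytest.approx(beta_grid, abs=1e-4)


def test_hazard_ratio_matches_lifelines(rng):
    import pandas as pd
    from lifelines import CoxPHFitter

    n = 120
    group = rng.integers(0, 2, n).astype(float)
    times = rng.exponential(3 * np.exp(-0.7 * group)) + 0.01
    events = rng.integers(0, 2, n)
    events[:4] = 1
    hr = hazard_ratio(group, times, events)
    df = pd.DataFrame({"g": group, "T": times, "E": events})
    cph = CoxPHFitter().fit(df, "T", "E")
    assert hr["beta"] == pytest.approx(cph.params_["g"], abs=1e-5)
    assert hr["se"] == pytest.approx(cph.standard_errors_["g"], abs=1e-5)


def test_hazard_ratio_relabel_inverts(rng):
    n = 60
    group = rng.integers(0, 2, n).astype(float)
    times = rng.exponential(2 * np.exp(-group)) + 0.01
    events = np.ones(n, int)
    a = hazard_ratio(group, times, events)["hr"]
    b = hazard_ratio(1 - group, times, events)["hr"]
    assert a == pytest.approx(1.0 / b, rel=1e-6)


def test_hazard_ratio_monotone_flag():
    hr = hazard_ratio([0, 0, 1, 1], [1.0, 2.0, 3.0, 4.0], [1, 1, 0, 0])
    assert hr["monotone"] is True
    assert not np.isfinite(hr["ci_high"]) or hr["ci_high"] == np.inf


# ----------------------------------------------------------------- thresholds


def test_youden_exhaustive_scan_example():
    t = youden_threshold([0.1, 0.2, 0.7, 0.8], [0, 0, 1, 1])
    assert t == pytest.approx(0.7)


def test_youden_degenerate_scores():
    t = youden_threshold([0.5, 0.5, 0.5, 0.5], [0, 1, 0, 1])
    assert t == pytest.approx(0.5)  # J = 0 everywhere; smallest qualifying


def test_youden_monotone_transform_maps_threshold(rng):
    scores = rng.normal(size=60)
    labels = rng.integers(0, 2, 60)
    labels[:2] = [0, 1]
    t1 = youden_threshold(scores, labels)
    t2 = youden_threshold(np.exp(scores), labels)
    assert t2 == pytest.approx(np.exp(t1))


def test_risk_cutoff_quantiles():
    assert risk_cutoff([1.0, 2.0, 3.0, 4.0], 0.25) == pytest.approx(1.75)
    assert risk_cutoff([1.0, 2.0, 3.0, 4.0], 0.0) == 1.0
    assert risk_cutoff([2.0, 2.0, 2.0], 0.25) == 2.0
    # boundary patients are low-risk
    assert assign_risk_groups([2.0, 2.0], 2.0).tolist() == [0, 0]
    assert assign_risk_groups([1.9, 2.1], 2.0).tolist() == [1, 0]


# --------------------------------------------------------------- net benefit


def test_net_benefit_treat_none_zero():
    labels = np.array([1, 0, 1, 0])
    curve = net_benefit(labels, [0.1, 0.25, 0.5], decisions=np.zeros(4))
    np.testing.assert_allclose(curve.model, 0.0)
    np.testing.assert_allclose(curve.treat_none, 0.0)


def test_net_benefit_treat_all_formula(rng):
    labels = rng.integers(0, 2, 200)
    pi = labels.mean()
    grid = np.array([0.1, 0.25, 0.4])
    curve = net_benefit(labels, grid, decisions=np.ones(200), harm_weight=1.0)
    expected = pi - (1 - pi) * grid / (1 - grid)
    np.testing.assert_allclose(curve.model, expected)
    np.testing.assert_allclose(curve.treat_all, expected)


def test_net_benefit_hand_example():
    # n=100, TP=30, FP=10 at p_t=0.25, w=1 -> 0.3 - 0.1/3
    labels = np.array([1] * 40 + [0] * 60)
    decisions = np.array([1] * 30 + [0] * 10 + [1] * 10 + [0] * 50)
    curve = net_benefit(labels, [0.25], decisions=decisions, harm_weight=1.0)
    assert curve.model[0] == pytest.approx(0.3 - 0.1 * (0.25 / 0.75))


def test_net_benefit_threshold_validation():
    with pytest.raises(ValueError):
        net_benefit([1, 0], [0.0, 0.5], decisions=[1, 0])


# ------------------------------------------------------------- explainability


def test_permutation_importance_identity_and_constant(rng):
    X = rng.normal(size=(100, 3))
    X[:, 2] = 1.0  # constant column
    y = (X[:, 0] > 0).astype(int)
    predict = lambda M: M[:, 0]
    imp0, _ = permutation_importance(predict, X, y, auc, column=0, n_perm=5, seed=0)
    imp1, sd1 = permutation_importance(predict, X, y, auc, column=1, n_perm=10, seed=0)
    imp2, _ = permutation_importance(predict, X, y, auc, column=2, n_perm=5, seed=0)
    assert imp0 > 0.3  # the driving variable
    assert abs(imp1) <= max(2 * sd1, 1e-9)  # unused variable
    assert imp2 == 0.0  # constant variable: exactly zero with note


def test_posterior_shift_closed_form():
    mu_tab = np.array([[1.0, -1.0, 0.0]])
    var_tab = np.array([[0.5, 0.5, 0.5]])
    # fusing prior + tab alone: mu_poe = mu_tab * (1/var)/(1+1/var)
    prec = 1.0 + 1.0 / var_tab
    mu_poe = (mu_tab / var_tab) / prec
    var_poe = 1.0 / prec
    shift = posterior_shift(mu_poe, mu_tab, var_poe, var_tab)
    np.testing.assert_allclose(shift["delta_mu"], mu_poe - mu_tab)
    assert np.all(shift["var_ratio"] <= 1.0)
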