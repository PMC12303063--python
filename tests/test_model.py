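"""Core probabilistic operations: PoE fusion, sampling, losses, gradients."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import integrate

from neoresp._autodiff import Tensor
from neoresp.model import (FusedPosterior, ModalityPosterior, ModelConfig,
                           correct_prediction, cox_loss, forward_pass,
                           gaussian_kl, init_response_params, kl_term, pcr_loss,
                           poe_fuse, predict_outcomes, sample_latent, total_loss,
                           SOURCES, KL_SOURCES)

from conftest import finite_diff_grad


# ------------------------------------------------------------------ PoE fusion


def grid_poe(mus, variances, lo=-30, hi=30, n=60001):
    """Independent oracle: normalized product of Gaussian densities (with the
    standard-normal prior) evaluated on a dense grid, one dimension."""
    x = np.linspace(lo, hi, n)
    log_pdf = -0.5 * x**2  # prior N(0,1), unnormalized
    for m, v in zip(mus, variances):
        log_pdf = log_pdf - 0.5 * (x - m) ** 2 / v
    pdf = np.exp(log_pdf - log_pdf.max())
    pdf /= np.trapezoid(pdf, x)
    mean = np.trapezoid(x * pdf, x)
    var = np.trapezoid((x - mean) ** 2 * pdf, x)
    return mean, var


def test_poe_prior_alone():
    fused = poe_fuse([])
    assert fused.mu == pytest.approx(0.0)
    assert fused.var == pytest.approx(1.0)
    assert fused.experts_used == ("prior",)


def test_poe_single_expert_closed_form():
    fused = poe_fuse([(np.array([1.0]), np.array([1.0]))])
    assert fused.mu[0] == pytest.approx(0.5)
    assert fused.var[0] == pytest.approx(0.5)


def test_poe_three_identical_experts():
    experts = [(np.full(3, 2.0), np.full(3, 0.5))] * 3
    fused = poe_fuse(experts)
    np.testing.assert_allclose(fused.var, 1.0 / 7.0)
    np.testing.assert_allclose(fused.mu, 12.0 / 7.0)


def test_poe_matches_grid_product(rng):
    for _ in range(50):
        k = rng.integers(1, 4)
        mus = rng.normal(0, 2, size=k)
        vs = rng.uniform(0.1, 5.0, size=k)
        fused = poe_fuse([(np.array([m]), np.array([v])) for m, v in zip(mus, vs)])
        m_ref, v_ref = grid_poe(mus, vs)
        assert abs(fused.mu[0] - m_ref) < 1e-6
        assert abs(fused.var[0] - v_ref) < 1e-6


def test_poe_rejects_nonpositive_variance():
    with pytest.raises(ValueError):
        poe_fuse([(np.zeros(3), np.array([1.0, -1.0, 1.0]))])
    with pytest.raises(ValueError):
        ModalityPosterior(mu=np.zeros(3), var=np.zeros(3))


@given(st.lists(st.tuples(st.floats(-5, 5), st.floats(0.05, 10)),
                min_size=1, max_size=3))
def test_poe_precision_monotone(experts):
    """Removing any expert never decreases the fused variance."""
    pairs = [(np.array([m]), np.array([v])) for m, v in experts]
    full = poe_fuse(pairs)
    for i in range(len(pairs)):
        reduced = poe_fuse(pairs[:i] + pairs[i + 1:])
        assert np.ravel(reduced.var)[0] >= np.ravel(full.var)[0] - 1e-12


def test_poe_huge_variance_expert_is_prior():
    fused = poe_fuse([(np.array([3.0]), np.array([1e8]))])
    assert abs(fused.mu[0] - 0.0) < 1e-4
    assert abs(fused.var[0] - 1.0) < 1e-4


# ------------------------------------------------------------------- sampling


def test_sample_latent_trivials():
    mu, var = np.array([0.5, -1.0, 2.0]), np.array([4.0, 1.0, 0.25])
    np.testing.assert_allclose(sample_latent(mu, var, np.zeros(3)), mu)
    np.testing.assert_allclose(sample_latent(np.zeros(3), np.ones(3), np.ones(3)),
                               np.ones(3))


def test_sample_latent_variance_matches(rng):
    mu, var = np.array([1.0, 0.0, -2.0]), np.array([0.5, 2.0, 1.3])
    eps = rng.standard_normal((100_000, 3))
    z = sample_latent(mu, var, eps)
    np.testing.assert_allclose(z.var(axis=0), var, rtol=0.02)


# ------------------------------------------------------------ outcome heads


def test_predict_outcomes_zero_weights():
    cfg = ModelConfig(shared_heads=True)
    params = init_response_params(cfg, seed=0)
    for k in params:
        if k.startswith("head."):
            params[k].data[:] = 0.0
    p, risk = predict_outcomes(np.zeros((4, 3)), np.eye(5)[:4], params)
    np.testing.assert_allclose(p.data, 0.5)
    np.testing.assert_allclose(risk.data, 0.0)


def test_predict_outcomes_regimen_conditioning():
    cfg = ModelConfig(shared_heads=True)
    params = init_response_params(cfg, seed=1)
    z = np.array([[0.3, -0.2, 0.1]])
    p1, r1 = predict_outcomes(z, np.eye(5)[0], params)
    p2, r2 = predict_outcomes(z, np.eye(5)[3], params)
    assert p1.data[0] != p2.data[0]
    assert r1.data[0] != r2.data[0]


def test_predict_outcomes_hand_oracle():
    """Single-layer head (W2 picks one hidden unit) against hand arithmetic."""
    cfg = ModelConfig(shared_heads=True, head_hidden=1)
    params = init_response_params(cfg, seed=0)
    w1 = np.zeros((8, 1))
    w1[0, 0] = 0.7  # reads z0 only
    params["head.pcr.W1"].data = w1.copy()
    params["head.pcr.b1"].data[:] = 0.0
    params["head.pcr.W2"].data = np.array([[2.0]])
    params["head.pcr.b2"].data = np.array([0.1])
    p, _ = predict_outcomes(np.array([[1.0, 0.0, 0.0]]), np.eye(5)[0], params)
    expected = 1.0 / (1.0 + np.exp(-(2.0 * np.tanh(0.7) + 0.1)))
    assert p.data[0] == pytest.approx(expected, rel=1e-12)


# ----------------------------------------------------------------- correction


def test_correct_prediction_endpoints_and_midpoint():
    assert correct_prediction(0.8, 0.4, 0.0) == pytest.approx(0.4)
    assert correct_prediction(0.8, 0.4, 1.0) == pytest.approx(0.8)
    assert correct_prediction(0.8, 0.4, 0.5) == pytest.approx(0.6)


def test_correct_prediction_rejects_bad_alpha():
    with pytest.raises(ValueError):
        correct_prediction(0.5, 0.5, 1.5)


# ------------------------------------------------------------------------- KL


def test_kl_trivials():
    assert kl_term(np.zeros(3), np.ones(3)) == pytest.approx(0.0)
    assert kl_term(np.array([1.0, 0, 0]), np.ones(3)) == pytest.approx(0.5)


def test_kl_matches_numerical_integration(rng):
    for _ in range(20):
        mu = rng.normal(0, 2)
        var = rng.uniform(0.1, 4.0)

        def integrand(x):
            q = np.exp(-0.5 * (x - mu) ** 2 / var) / np.sqrt(2 * np.pi * var)
            p = np.exp(-0.5 * x**2) / np.sqrt(2 * np.pi)
            return q * (np.log(q) - np.log(p))

        ref, _ = integrate.quad(integrand, mu - 12 * np.sqrt(var),
                                mu + 12 * np.sqrt(var))
        assert abs(kl_term(np.array([mu]), np.array([var])) - ref) < 1e-6


@given(st.floats(-10, 10), st.floats(0.01, 20))
def test_kl_nonnegative(mu, var):
    assert kl_term(np.array([mu]), np.array([var])) >= -1e-12


def test_gaussian_kl_reduces_to_prior_form(rng):
    mu, var = rng.normal(size=3), rng.uniform(0.2, 2.0, 3)
    assert gaussian_kl(mu, var, np.zeros(3), np.ones(3)) == pytest.approx(
        kl_term(mu, var))


# ------------------------------------------------------------------ pCR loss


def test_pcr_loss_examples():
    assert pcr_loss(np.array([0.5]), np.array([1.0])) == pytest.approx(np.log(2))
    assert pcr_loss(np.array([0.5]), np.array([0.0])) == pytest.approx(np.log(2))
    assert pcr_loss(np.array([1 - 1e-7]), np.array([1.0])) == pytest.approx(1e-7, rel=0.01)
    batch = pcr_loss(np.array([0.8, 0.3]), np.array([1.0, 0.0]))
    assert batch == pytest.approx((-np.log(0.8) - np.log(0.7)) / 2, abs=1e-6)


def test_pcr_loss_clips_exact_probabilities():
    with pytest.warns(UserWarning):
        val = pcr_loss(np.array([1.0]), np.array([1.0]))
    assert np.isfinite(val)


# ------------------------------------------------------------------- Cox loss


def test_cox_loss_hand_example():
    val = cox_loss(np.zeros(3), np.array([1.0, 2.0, 3.0]), np.array([1, 1, 0]))
    assert val == pytest.approx(np.log(3) + np.log(2))


def test_cox_loss_location_invariant(rng):
    s = rng.normal(size=20)
    t = rng.exponential(5, 20) + 0.01
    e = rng.integers(0, 2, 20)
    e[0] = 1
    a = cox_loss(s, t, e)
    b = cox_loss(s + 37.5, t, e)
    assert a == pytest.approx(b, abs=1e-8)


def test_cox_loss_zero_events_error():
    with pytest.raises(ValueError):
        cox_loss(np.zeros(3), np.ones(3), np.zeros(3))


def test_cox_loss_strict_risk_set():
    # strict convention excludes the index patient; hand computation for the
    # first event: denominator holds patients with T > 1 only
    val = cox_loss(np.zeros(3), np.array([1.0, 2.0, 3.0]), np.array([1, 0, 0]),
                   risk_set="strict")
    assert val == pytest.approx(np.log(2))
    with pytest.raises(ValueError):  # last event has an empty strict risk set
        cox_loss(np.zeros(2), np.array([1.0, 2.0]), np.array([0, 1]),
                 risk_set="strict")


def test_cox_loss_ties_breslow():
    # two events at the same time share the full risk-set denominator
    val = cox_loss(np.zeros(3), np.array([1.0, 1.0, 2.0]), np.array([1, 1, 0]))
    assert val == pytest.approx(2 * np.log(3))


def test_cox_coefficient_recovery(rng):
    """Minimizing the partial likelihood over a scalar coefficient recovers
    the true log-hazard slope of a simulated exponential cohort."""
    from scipy.optimize import minimize_scalar

    n = 2000
    x = rng.standard_normal(n)
    t = rng.exponential(1.0 / (0.1 * np.exp(1.0 * x)))
    c = rng.exponential(10.0, n)
    times = np.maximum(np.minimum(t, c), 1e-9)
    events = (t <= c).astype(float)
    res = minimize_scalar(lambda b: cox_loss(b * x, times, events),
                          bounds=(-3, 3), method="bounded")
    assert abs(res.x - 1.0) < 0.1


# --------------------------------------------------------------- total loss


def test_total_loss_assembly(rng):
    pcr = {s: rng.uniform(0, 1) for s in SOURCES}
    cox = {s: rng.uniform(0, 1) for s in SOURCES}
    kl = {s: rng.uniform(0, 1) for s in KL_SOURCES}
    total, bd = total_loss(pcr, cox, kl, lambda_kl=1.0)
    expected = sum(pcr.values()) + sum(cox.values()) + sum(kl.values())
    assert total == pytest.approx(expected)
    total0, _ = total_loss(pcr, cox, kl, lambda_kl=0.0)
    assert total0 == pytest.approx(sum(pcr.values()) + sum(cox.values()))
    zeros = {s: 0.0 for s in SOURCES}
    assert total_loss(zeros, zeros, {s: 0.0 for s in KL_SOURCES})[0] == 0.0
    with pytest.raises(ValueError):
        total_loss({k: v for k, v in pcr.items() if k != "tab"}, cox, kl)


# ------------------------------------------------------------ gradient checks


@pytest.mark.parametrize("loss_name", ["pcr", "cox", "kl", "infonce"])
def test_loss_gradients_match_finite_differences(loss_name, rng):
    n = 8
    if loss_name == "pcr":
        y = rng.integers(0, 2, n).astype(float)

        def f(logits):
            t = Tensor(logits, requires_grad=True)
            return pcr_loss(t.sigmoid(), y), t
    elif loss_name == "cox":
        times = rng.exponential(2, n) + 0.01
        events = rng.integers(0, 2, n).astype(float)
        events[0] = 1

        def f(scores):
            t = Tensor(scores, requires_grad=True)
            return cox_loss(t, times, events), t
    elif loss_name == "kl":
        def f(x):
            t = Tensor(x, requires_grad=True)
            mu, s = t[:, :2], t[:, 2:]
            return kl_term(mu, s.softplus() ** 2 + 1e-6), t
    else:
        from neoresp.encoders import contrastive_align

        def f(x):
            t = Tensor(x, requires_grad=True)
            a, b = t[:4], t[4:]
            return contrastive_align(a, b, temperature=0.5), t

    x0 = rng.normal(size=(n, 4)) if loss_name in ("kl", "infonce") else rng.normal(size=n)
    loss, t = f(x0)
    loss.backward()
    num = finite_diff_grad(lambda x: float(f(x)[0].data), x0)
    denom = max(np.abs(num).max(), 1e-8)
    assert np.abs(num - t.grad).max() / denom < 1e-4


# ----------------------------------------------------- fused forward contract


def _tiny_features(n, cfg, rng):
    d = cfg.encoder.d
    return {m: rng.normal(size=(n, d)) for m in ("tab", "img", "txt")}


def test_blank_report_equals_omitted_expert(rng):
    """A blank-report patient yields bit-identical fused posteriors and
    scores to an explicit txt-expert omission."""
    cfg = ModelConfig()
    params = init_response_params(cfg, seed=3)
    feats = _tiny_features(5, cfg, rng)
    R = np.eye(5)
    blank = np.array([0.0, 1.0, 0.0, 1.0, 0.0])
    fwd = forward_pass(feats, R, params, cfg, blank=blank)

    # the txt expert of a blank patient must be fully ignored: replacing the
    # blank rows' text features with anything else changes nothing, bit-exact
    feats2 = {m: v.copy() for m, v in feats.items()}
    feats2["txt"][blank == 1] = rng.normal(size=(2, cfg.encoder.d)) * 50
    fwd2 = forward_pass(feats2, R, params, cfg, blank=blank)
    for i in np.where(blank == 1)[0]:
        np.testing.assert_array_equal(fwd["mu"]["poe"].data[i], fwd2["mu"]["poe"].data[i])
        np.testing.assert_array_equal(fwd["var"]["poe"].data[i], fwd2["var"]["poe"].data[i])
        assert fwd["pcr"]["correct"].data[i] == fwd2["pcr"]["correct"].data[i]
        assert fwd["risk"]["correct"].data[i] == fwd2["risk"]["correct"].data[i]


def test_fused_variance_not_above_tab_variance(rng):
    cfg = ModelConfig()
    params = init_response_params(cfg, seed=4)
    feats = _tiny_features(6, cfg, rng)
    fwd = forward_pass(feats, np.tile(np.eye(5)[1], (6, 1)), params, cfg,
                       blank=np.zeros(6))
    assert np.all(fwd["var"]["poe"].data <= fwd["var"]["tab"].data + 1e-15)


def test_forward_deterministic(rng):
    cfg = ModelConfig()
    params = init_response_params(cfg, seed=5)
    feats = _tiny_features(4, cfg, rng)
    R = np.tile(np.eye(5)[2], (4, 1))
    a = forward_pass(feats, R, params, cfg, blank=np.zeros(4))
    b = forward_pass(feats, R, params, cfg, blank=np.zeros(4))
    np.testing.assert_array_equal(a["pcr"]["correct"].data, b["pcr"]["correct"].data)
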