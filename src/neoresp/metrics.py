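"""Evaluation statistics for response prediction and risk stratification.

Everything here is implemented from first principles (Mann-Whitney AUC,
Harrell's C, Kaplan-Meier, log-rank, univariable Cox hazard ratios, Youden
and quantile thresholds, harm-weighted net benefit, permutation importance,
posterior-shift diagnostics) so that the test suite can hold each function
against an independent oracle (exhaustive pair counting, closed forms, or
the standard survival packages).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "BinaryMetric",
    "SurvivalCurve",
    "NetBenefitCurve",
    "auc",
    "bootstrap_ci",
    "c_index",
    "km_estimate",
    "logrank",
    "hazard_ratio",
    "youden_threshold",
    "risk_cutoff",
    "assign_risk_groups",
    "net_benefit",
    "permutation_importance",
    "posterior_shift",
    "auc_difference_test",
]


@dataclass(frozen=True)
class BinaryMetric:
    estimate: float
    ci_low: float
    ci_high: float
    n_bootstrap: int = 1000
    seed: int = 0

    def __post_init__(self):
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")


@dataclass(frozen=True)
class SurvivalCurve:
    times: np.ndarray  # event-time grid
    survival: np.ndarray  # nonincreasing, starts below/at 1
    at_risk: np.ndarray
    n_events: np.ndarray


@dataclass(frozen=True)
class NetBenefitCurve:
    thresholds: np.ndarray
    model: np.ndarray
    treat_all: np.ndarray
    treat_none: np.ndarray = field(default=None)
    harm_weight: float = 1.0

    def __post_init__(self):
        if self.treat_none is None:
            object.__setattr__(self, "treat_none", np.zeros_like(self.thresholds))


# ------------------------------------------------------------------ ranks/AUC


def _average_ranks(x: np.ndarray) -> np.ndarray:
    """Midranks (ties get the average of their rank span); 1-based."""
    order = np.argsort(x, kind="stable")
    sx = x[order]
    new_group = np.concatenate([[True], sx[1:] != sx[:-1]])
    gid = np.cumsum(new_group) - 1
    counts = np.bincount(gid)
    ends = np.cumsum(counts)
    mid = (ends - counts + ends - 1) / 2.0 + 1.0
    ranks = np.empty(len(x))
    ranks[order] = mid[gid]
    return ranks


def auc(scores, labels) -> float:
    """Area under the ROC curve = Mann-Whitney U / (n1*n0), ties counted 1/2."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    n1 = int(np.sum(labels == 1))
    n0 = int(np.sum(labels == 0))
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes present")
    ranks = _average_ranks(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def bootstrap_ci(metric_fn, *arrays, n_bootstrap: int = 1000, seed: int = 0,
                 alpha: float = 0.05) -> BinaryMetric:
    """Percentile bootstrap CI with patient-level resampling.  Degenerate
    resamples (metric undefined, e.g. single-class) are skipped."""
    arrays = [np.asarray(a) for a in arrays]
    n = len(arrays[0])
    point = float(metric_fn(*arrays))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    vals = []
    for _ in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        try:
            vals.append(float(metric_fn(*(a[idx] for a in arrays))))
        except ValueError:
            continue
    lo, hi = np.percentile(vals, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    lo, hi = min(lo, point), max(hi, point)
    return BinaryMetric(point, float(lo), float(hi), n_bootstrap, seed)


def auc_difference_test(scores_a, scores_b, labels, n_bootstrap: int = 1000,
                        seed: int = 0) -> float:
    """Paired-bootstrap two-sided p-value for AUC(a) != AUC(b) on the same
    patients (used in place of the unusual t-test-on-ROC procedure)."""
    scores_a, scores_b = np.asarray(scores_a, float), np.asarray(scores_b, float)
    labels = np.asarray(labels)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 23]))
    n = len(labels)
    diffs = []
    for _ in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        try:
            diffs.append(auc(scores_a[idx], labels[idx]) - auc(scores_b[idx], labels[idx]))
        except ValueError:
            continue
    diffs = np.asarray(diffs)
    p = 2.0 * min(np.mean(diffs <= 0), np.mean(diffs >= 0))
    return float(min(p, 1.0))


# -------------------------------------------------------------------- C-index


def c_index(risk, times, events) -> float:
    """Harrell's concordance over usable pairs: the earlier time must be an
    observed event (tied times count when the event precedes a censoring);
    tied risk scores earn 1/2."""
    risk = np.asarray(risk, float)
    times = np.asarray(times, float)
    events = np.asarray(events).astype(bool)
    ti, tj = times[:, None], times[None, :]
    ei, ej = events[:, None], events[None, :]
    usable = (ei & (ti < tj)) | (ei & ~ej & (ti == tj))
    ri, rj = risk[:, None], risk[None, :]
    conc = np.where(ri > rj, 1.0, np.where(ri == rj, 0.5, 0.0))
    n_usable = usable.sum()
    if n_usable == 0:
        raise ValueError("no comparable pairs")
    return float((conc * usable).sum() / n_usable)


# ------------------------------------------------------------------- survival


def km_estimate(times, events) -> SurvivalCurve:
    """Product-limit (Kaplan-Meier) estimator on the event-time grid."""
    times = np.asarray(times, float)
    events = np.asarray(events).astype(int)
    if len(times) == 0:
        raise ValueError("empty group")
    grid = np.unique(times[events == 1])
    surv, at_risk, n_ev = [], [], []
    s = 1.0
    for t in grid:
        n_t = int(np.sum(times >= t))
        d_t = int(np.sum((times == t) & (events == 1)))
        s *= 1.0 - d_t / n_t
        grid_s = s
        surv.append(grid_s)
        at_risk.append(n_t)
        n_ev.append(d_t)
    return SurvivalCurve(times=grid, survival=np.asarray(surv),
                         at_risk=np.asarray(at_risk), n_events=np.asarray(n_ev))


def logrank(times, events, groups) -> tuple[float, float]:
    """Two-sided k-group log-rank test via hypergeometric expected counts.

    Returns (chi2, p) with k-1 degrees of freedom.
    """
    times = np.asarray(times, float)
    events = np.asarray(events).astype(int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    k = len(labels)
    if k < 2:
        raise ValueError("log-rank needs at least two groups")
    for g in labels:
        if np.sum(groups == g) == 0:
            raise ValueError("empty group")
    grid = np.unique(times[events == 1])
    obs = np.zeros(k)
    exp = np.zeros(k)
    var = np.zeros((k, k))
    for t in grid:
        at_risk = times >= t
        n_t = at_risk.sum()
        d_t = int(np.sum((times == t) & (events == 1)))
        n_g = np.array([np.sum(at_risk & (groups == g)) for g in labels], float)
        d_g = np.array([np.sum((times == t) & (events == 1) & (groups == g))
                        for g in labels], float)
        obs += d_g
        exp += d_t * n_g / n_t
        if n_t > 1:
            frac = n_g / n_t
            v = d_t * (n_t - d_t) / (n_t - 1)
            var += v * (np.diag(frac) - np.outer(frac, frac))
    z = (obs - exp)[:-1]
    v = var[:-1][:, :-1]
    if np.allclose(z, 0.0):
        return 0.0, 1.0
    chi2 = float(z @ np.linalg.pinv(v) @ z)
    p = float(stats.chi2.sf(chi2, df=k - 1))
    return chi2, p


def _cox_binary_derivs(beta: float, x: np.ndarray, times: np.ndarray,
                       events: np.ndarray) -> tuple[float, float, float]:
    """(loglik, score, information) for a univariable Cox model with Breslow
    ties; x is the binary group indicator."""
    order = np.argsort(times, kind="stable")
    t, e, xv = times[order], events[order], x[order]
    theta = np.exp(beta * xv)
    # suffix sums over risk sets T_j >= T_i
    s0 = np.cumsum(theta[::-1])[::-1]
    s1 = np.cumsum((theta * xv)[::-1])[::-1]
    idx = np.searchsorted(t, t, side="left")
    ll = score = info = 0.0
    ev = e == 1
    s0i, s1i = s0[idx[ev]], s1[idx[ev]]
    ll = float(np.sum(beta * xv[ev] - np.log(s0i)))
    score = float(np.sum(xv[ev] - s1i / s0i))
    info = float(np.sum(s1i / s0i - (s1i / s0i) ** 2))
    return ll, score, info


def hazard_ratio(group, times, events, alpha: float = 0.05) -> dict:
    """Univariable Cox hazard ratio exp(beta) for a binary group indicator,
    Newton-maximized partial likelihood, Wald CI.  Monotone likelihood
    (a group with no events) is flagged with an unbounded CI."""
    group = np.asarray(group).astype(float)
    times = np.asarray(times, float)
    events = np.asarray(events).astype(int)
    if set(np.unique(group)) - {0.0, 1.0}:
        raise ValueError("group indicator must be binary 0/1")
    ev1 = int(np.sum(events[group == 1]))
    ev0 = int(np.sum(events[group == 0]))
    if ev1 == 0 or ev0 == 0:
        hr = np.inf if ev0 == 0 else 0.0
        return {"hr": hr, "ci_low": 0.0, "ci_high": np.inf, "beta": np.log(hr) if hr > 0 else -np.inf,
                "se": np.inf, "p": 1.0, "monotone": True}
    beta = 0.0
    for _ in range(100):
        _, score, info = _cox_binary_derivs(beta, group, times, events)
        if info <= 0:
            break
        step = score / info
        beta += np.clip(step, -2.0, 2.0)
        if abs(step) < 1e-12:
            break
    _, _, info = _cox_binary_derivs(beta, group, times, events)
    se = float(np.sqrt(1.0 / info)) if info > 0 else np.inf
    zq = stats.norm.ppf(1 - alpha / 2)
    p = 2 * stats.norm.sf(abs(beta / se)) if np.isfinite(se) and se > 0 else 1.0
    return {"hr": float(np.exp(beta)), "ci_low": float(np.exp(beta - zq * se)),
            "ci_high": float(np.exp(beta + zq * se)), "beta": float(beta),
            "se": se, "p": float(p), "monotone": False}


# ----------------------------------------------------------------- thresholds


def youden_threshold(scores, labels) -> float:
    """Threshold maximizing J = sensitivity + specificity - 1, scanning the
    observed scores with the 'positive if score >= t' rule; ties resolve to
    the smallest qualifying observed score."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("Youden threshold requires both classes")
    pos, neg = scores[labels == 1], scores[labels == 0]
    best_j, best_t = -np.inf, None
    for t in np.unique(scores):
        j = np.mean(pos >= t) + np.mean(neg < t) - 1.0
        if j > best_j + 1e-12 or (abs(j - best_j) <= 1e-12 and (best_t is None or t < best_t)):
            best_j, best_t = j, float(t)
    return best_t


def risk_cutoff(neg_risk, quantile: float = 0.25) -> float:
    """Empirical quantile (linear interpolation) of the negated risk scores;
    patients strictly below it are high-risk."""
    neg_risk = np.asarray(neg_risk, float)
    if len(neg_risk) == 0:
        raise ValueError("empty scores")
    return float(np.quantile(neg_risk, quantile, method="linear"))


def assign_risk_groups(neg_risk, threshold: float) -> np.ndarray:
    """1 = high-risk (neg risk strictly below the cutoff); boundary ties are
    low-risk."""
    return (np.asarray(neg_risk, float) < threshold).astype(int)


# --------------------------------------------------------------- net benefit


def net_benefit(labels, thresholds, decisions=None, scores=None,
                harm_weight: float = 1.0, treat_below: bool = True) -> NetBenefitCurve:
    """Harm-weighted decision-curve net benefit.

        NB(p_t) = TP/n - w * (FP/n) * p_t / (1 - p_t)

    ``labels`` marks patients who benefit from treatment/escalation (1).
    Pass fixed binary ``decisions``, or ``scores`` with the policy
    "treat when score < p_t" (default, matching escalation on a low
    predicted-pCR score; set treat_below=False for the > rule).
    ``harm_weight`` multiplies the false-positive (overtreatment) term;
    w = 1 recovers the standard formula.
    """
    labels = np.asarray(labels).astype(int)
    thresholds = np.asarray(thresholds, float)
    if np.any(thresholds <= 0) or np.any(thresholds >= 1):
        raise ValueError("threshold probabilities must lie in (0, 1)")
    n = len(labels)
    nb_model = np.zeros_like(thresholds)
    nb_all = np.zeros_like(thresholds)
    for i, pt in enumerate(thresholds):
        odds = pt / (1.0 - pt)
        if decisions is not None:
            treat = np.asarray(decisions).astype(bool)
        elif scores is not None:
            s = np.asarray(scores, float)
            treat = s < pt if treat_below else s > pt
        else:
            raise ValueError("provide decisions or scores")
        tp = np.sum(treat & (labels == 1)) / n
        fp = np.sum(treat & (labels == 0)) / n
        nb_model[i] = tp - harm_weight * fp * odds
        pi = labels.mean()
        nb_all[i] = pi - harm_weight * (1 - pi) * odds
    return NetBenefitCurve(thresholds=thresholds, model=nb_model,
                           treat_all=nb_all, harm_weight=harm_weight)


# ------------------------------------------------------------- explainability


def permutation_importance(predict_fn, X, y, metric_fn, column, n_perm: int = 10,
                           seed: int = 0) -> tuple[float, float]:
    """Metric drop after permuting one column of X across patients,
    averaged over ``n_perm`` seeded permutations; returns (mean, sd).
    Constant columns give importance exactly 0."""
    X = np.array(X, float, copy=True)
    base = float(metric_fn(predict_fn(X), y))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 31]))
    col = X[:, column].copy()
    if np.all(col == col[0]):
        return 0.0, 0.0
    drops = []
    for _ in range(n_perm):
        Xp = X.copy()
        Xp[:, column] = rng.permutation(col)
        drops.append(base - float(metric_fn(predict_fn(Xp), y)))
    drops = np.asarray(drops)
    return float(drops.mean()), float(drops.std(ddof=1)) if n_perm > 1 else 0.0


def posterior_shift(mu_poe: np.ndarray, mu_tab: np.ndarray,
                    var_poe: np.ndarray, var_tab: np.ndarray) -> dict:
    """Posterior-shift diagnostics: delta_mu = mu_PoE - mu_tab per latent
    dimension, and the fused-over-clinical variance ratio (always <= 1 by
    precision additivity)."""
    return {
        "delta_mu": np.asarray(mu_poe, float) - np.asarray(mu_tab, float),
        "var_ratio": np.asarray(var_poe, float) / np.asarray(var_tab, float),
    }
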