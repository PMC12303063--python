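"""Probabilistic multi-modal response model.

The model treats a patient's prognosis as a 3-dimensional latent variable.
Each modality emits a regimen-conditioned diagonal-Gaussian expert over the
latent; experts are combined with a spherical N(0, I) prior by
Product-of-Experts (precisions add, means are precision-weighted).  A
reparameterized sample of the fused (or per-modality) posterior, together
with the regimen indicator, feeds two small heads predicting the pCR
probability (sigmoid) and a log-relative-hazard risk score (linear).  A
correction factor alpha, emitted from the fused mean, blends the PoE and
clinical-only predictions:

    y_correct = alpha * y_PoE + (1 - alpha) * y_tab

Training minimizes cross-entropy on pCR, the negative Cox log partial
likelihood on survival, and the KL of each emitted posterior against the
prior, for the five supervised sources {tab, img, txt, PoE, correct} and
four KL sources {tab, img, txt, PoE}, with balance weight lambda_KL
(default 1).

The public entry point is the statsmodels-style pair
:class:`ResponseModel` (constructed from patient records) whose ``fit``
returns a :class:`ResponseResults` carrying checkpoints, histories,
predictions and a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._autodiff import Tensor, concat
from . import encoders as enc
from .encoders import EncoderConfig, posterior_head
from .preprocess import ClinicalBounds, encode_clinical, ids_to_sequence
from .cohort import PatientRecord, REGIMENS, regimen_code

__all__ = [
    "ModalityPosterior",
    "FusedPosterior",
    "poe_fuse",
    "sample_latent",
    "predict_outcomes",
    "correct_prediction",
    "kl_term",
    "pcr_loss",
    "cox_loss",
    "total_loss",
    "ModelConfig",
    "ResponseModel",
    "ResponseResults",
    "init_response_params",
    "forward_pass",
]

PROB_EPS = 1e-7
SOURCES = ("tab", "img", "txt", "poe", "correct")
KL_SOURCES = ("tab", "img", "txt", "poe")


@dataclass(frozen=True)
class ModalityPosterior:
    mu: np.ndarray
    var: np.ndarray  # sigma^2, elementwise positive
    modality: str = ""
    regimen: np.ndarray | None = None

    def __post_init__(self):
        if np.any(np.asarray(self.var) <= 0):
            raise ValueError("posterior variance must be positive")


@dataclass(frozen=True)
class FusedPosterior:
    mu: np.ndarray
    var: np.ndarray
    experts_used: tuple = ("prior",)


# ------------------------------------------------------------ core operations


def poe_fuse(posteriors, prior_mu: float = 0.0, prior_var: float = 1.0) -> FusedPosterior:
    """Product-of-Experts fusion of diagonal Gaussians with the spherical
    prior always included: precisions add; means are precision-weighted.

    ``posteriors`` is a possibly-empty list of :class:`ModalityPosterior`
    or ``(mu, var)`` pairs (missing modalities are simply absent).
    """
    mus, vars_, used = [], [], ["prior"]
    for i, p in enumerate(posteriors):
        if isinstance(p, ModalityPosterior):
            mu, var, tag = p.mu, p.var, p.modality or f"expert{i}"
        else:
            mu, var = p
            tag = f"expert{i}"
        mu, var = np.asarray(mu, float), np.asarray(var, float)
        if np.any(var <= 0):
            raise ValueError("expert variance must be positive")
        mus.append(mu)
        vars_.append(var)
        used.append(tag)
    shape = mus[0].shape if mus else np.shape(prior_mu)
    prec = np.full(shape, 1.0 / prior_var) if shape else np.array(1.0 / prior_var)
    num = np.full(shape, prior_mu / prior_var) if shape else np.array(prior_mu / prior_var)
    for mu, var in zip(mus, vars_):
        prec = prec + 1.0 / var
        num = num + mu / var
    var_poe = 1.0 / prec
    return FusedPosterior(mu=num * var_poe, var=var_poe, experts_used=tuple(used))


def sample_latent(mu, var, eps):
    """Reparameterized draw z = mu + sqrt(var) * eps (works on Tensors or arrays)."""
    if isinstance(mu, Tensor) or isinstance(var, Tensor):
        var = var if isinstance(var, Tensor) else Tensor(var)
        mu = mu if isinstance(mu, Tensor) else Tensor(mu)
        return mu + var.sqrt() * Tensor(np.asarray(eps, float))
    return np.asarray(mu, float) + np.sqrt(np.asarray(var, float)) * np.asarray(eps, float)


def predict_outcomes(z, r, params: dict, source: str | None = None) -> tuple:
    """Outcome heads on (z ⊕ r): returns (pCR probability, risk score).

    The pCR head ends in a sigmoid; the risk head is an unbounded real on
    the log-relative-hazard scale.  ``source`` selects a per-source head
    ("tab"/"img"/"txt"/"poe"); None uses the shared head weights.
    """
    z = z if isinstance(z, Tensor) else Tensor(np.atleast_2d(z))
    if z.ndim == 1:
        z = z.reshape(1, z.shape[0])
    r = np.atleast_2d(np.asarray(r, float))
    if r.shape[0] == 1 and z.shape[0] > 1:
        r = np.repeat(r, z.shape[0], axis=0)
    zr = concat([z, Tensor(r)], axis=1)
    pre = "head." if source is None else f"head.{source}."
    h = (zr @ params[f"{pre}pcr.W1"] + params[f"{pre}pcr.b1"]).tanh()
    logit = h @ params[f"{pre}pcr.W2"] + params[f"{pre}pcr.b2"]
    p = logit.sigmoid().reshape(z.shape[0])
    hr = (zr @ params[f"{pre}risk.W1"] + params[f"{pre}risk.b1"]).tanh()
    risk = (hr @ params[f"{pre}risk.W2"] + params[f"{pre}risk.b2"]).reshape(z.shape[0])
    return p, risk


def correct_prediction(y_poe, y_tab, alpha, scale: str = "raw"):
    """Convex blend y_correct = alpha*y_poe + (1-alpha)*y_tab.

    ``scale='raw'`` blends the quantities as given (probabilities for pCR,
    real scores for risk, matching the printed equation); ``'logit'`` blends
    pCR on the log-odds scale.
    """
    a = alpha.data if isinstance(alpha, Tensor) else np.asarray(alpha, float)
    if np.any(a < 0) or np.any(a > 1):
        raise ValueError("correction factor alpha must lie in [0, 1]")
    if scale == "raw":
        return alpha * y_poe + (1.0 - alpha) * y_tab

    def _logit(p):
        p = p.clip(PROB_EPS, 1 - PROB_EPS) if isinstance(p, Tensor) else np.clip(p, PROB_EPS, 1 - PROB_EPS)
        return (p / (1.0 - p)).log() if isinstance(p, Tensor) else np.log(p / (1.0 - p))

    mix = alpha * _logit(y_poe) + (1.0 - alpha) * _logit(y_tab)
    return mix.sigmoid() if isinstance(mix, Tensor) else 1.0 / (1.0 + np.exp(-mix))


def gaussian_kl(mu_q, var_q, mu_p, var_p):
    """KL( N(mu_q, var_q) || N(mu_p, var_p) ) for diagonal Gaussians;
    batch mean for 2-D inputs (differentiable on Tensors)."""
    lift = lambda x: x if isinstance(x, Tensor) else Tensor(np.asarray(x, float))
    is_t = any(isinstance(x, Tensor) for x in (mu_q, var_q, mu_p, var_p))
    mu_q, var_q, mu_p, var_p = map(lift, (mu_q, var_q, mu_p, var_p))
    d = mu_q - mu_p
    per = ((var_p.log() - var_q.log() + (var_q + d * d) / var_p - 1.0).sum(axis=-1)
           * 0.5)
    out = per.mean() if per.ndim >= 1 else per
    return out if is_t else float(out.data)


def kl_term(mu, var):
    """KL( N(mu, diag var) || N(0, I) ) = 1/2 sum(var + mu^2 - 1 - ln var).

    1-D input: a single posterior, returns its KL.  2-D input: a batch,
    returns the batch mean.  Works on Tensors (differentiable) or arrays.
    """
    is_t = isinstance(mu, Tensor) or isinstance(var, Tensor)
    mu = mu if isinstance(mu, Tensor) else Tensor(np.asarray(mu, float))
    var = var if isinstance(var, Tensor) else Tensor(np.asarray(var, float))
    if np.any(var.data <= 0):
        raise ValueError("variance must be positive")
    per = (var + mu * mu - 1.0 - var.log()).sum(axis=-1) * 0.5
    out = per.mean() if per.ndim >= 1 else per
    return out if is_t else float(out.data)


def pcr_loss(y_hat, y):
    """Binary cross-entropy, averaged over the batch; exact 0/1 predictions
    are clipped at 1e-7 with a warning."""
    is_t = isinstance(y_hat, Tensor)
    raw = y_hat.data if is_t else np.asarray(y_hat, float)
    if np.any(raw <= 0.0) or np.any(raw >= 1.0):
        warnings.warn("pCR probabilities clipped away from {0,1}")
    y_hat = y_hat if is_t else Tensor(raw)
    y = np.asarray(y, float)
    p = y_hat.clip(PROB_EPS, 1.0 - PROB_EPS)
    out = -(Tensor(y) * p.log() + Tensor(1.0 - y) * (1.0 - p).log()).mean()
    return out if is_t else float(out.data)


def cox_loss(scores, times, events, risk_set: str = "geq"):
    """Negative Cox log partial likelihood.

        L = - sum_{i: E_i=1} [ s_i - log sum_{j in R(T_i)} exp(s_j) ]

    ``risk_set='geq'`` (default) uses the standard R(T_i) = {j: T_j >= T_i}
    with Breslow handling of ties; ``'strict'`` uses the nonstandard
    {j: T_j > T_i}, which is undefined for the last event.  Computed with a
    location-invariant log-sum-exp via suffix sums; O(n log n).
    """
    times = np.asarray(times, float)
    events = np.asarray(events, float)
    if times.ndim != 1 or np.any(times <= 0):
        raise ValueError("survival times must be a 1-D positive array")
    if events.sum() < 1:
        raise ValueError("Cox partial likelihood undefined with zero events")
    is_t = isinstance(scores, Tensor)
    s = scores if is_t else Tensor(np.asarray(scores, float))

    order = np.argsort(times, kind="stable")
    t_sorted = times[order]
    e_sorted = events[order]
    s_sorted = s[order]
    shift = float(np.max(s.data))
    suffix = (s_sorted - shift).exp().cumsum_reverse(axis=0)
    side = "left" if risk_set == "geq" else "right"
    idx = np.searchsorted(t_sorted, t_sorted, side=side)
    if risk_set == "strict" and np.any((idx >= len(t_sorted)) & (e_sorted > 0)):
        raise ValueError("strict risk set empty for the latest event")
    idx = np.minimum(idx, len(t_sorted) - 1)  # censored tail rows, weight 0
    log_den = suffix[idx].log() + shift
    out = -((s_sorted - log_den) * Tensor(e_sorted)).sum()
    return out if is_t else float(out.data)


def total_loss(pcr_losses: dict, cox_losses: dict, kl_losses: dict,
               lambda_kl: float = 1.0):
    """Assemble the joint objective

        L = sum_src L_pcr + sum_src L_cox + lambda_KL * sum_mod L_KL

    over supervised sources {tab, img, txt, poe, correct} and KL sources
    {tab, img, txt, poe}.  Returns ``(total, breakdown_dict)``.
    """
    for src in SOURCES:
        if src not in pcr_losses or src not in cox_losses:
            raise ValueError(f"missing supervised loss for source {src!r}")
    for src in KL_SOURCES:
        if src not in kl_losses:
            raise ValueError(f"missing KL loss for source {src!r}")
    total = None
    for term in [pcr_losses[s] for s in SOURCES] + [cox_losses[s] for s in SOURCES]:
        total = term if total is None else total + term
    for s in KL_SOURCES:
        total = total + lambda_kl * kl_losses[s]
    breakdown = {
        "pcr": {k: _scalar(v) for k, v in pcr_losses.items()},
        "cox": {k: _scalar(v) for k, v in cox_losses.items()},
        "kl": {k: _scalar(v) for k, v in kl_losses.items()},
        "lambda_kl": lambda_kl,
        "total": _scalar(total),
    }
    return total, breakdown


def _scalar(x) -> float:
    return float(x.data) if isinstance(x, Tensor) else float(x)


# --------------------------------------------------------------- model config


@dataclass(frozen=True)
class ModelConfig:
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    lambda_kl: float = 1.0
    risk_set: str = "geq"  # or "strict"
    correction_scale: str = "raw"  # or "logit"
    blank_txt_as_missing: bool = True  # blank reports drop the txt expert
    cox_normalization: str = "events"  # training-time scaling; "none" = printed form
    head_hidden: int = 16
    shared_heads: bool = False  # one outcome head per source by default
    # KL variant: "elbo" trains with an outcome-conditioned posterior
    # q(z|x,y,r) and penalizes KL(q || p(z|x,r)); "printed" penalizes each
    # emitted posterior against the spherical prior (the total-loss line as
    # printed).  Inference always uses p(z|x,r).
    posterior_variant: str = "elbo"


def init_response_params(config: ModelConfig, seed: int) -> dict:
    """Posterior heads + outcome heads + alpha head (everything trained in
    the response stage; encoders stay frozen)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    c = config.encoder
    params = {k: v for k, v in enc.init_posterior_params(c, seed).items()}
    zin = c.latent_dim + c.n_regimens
    h = config.head_hidden
    extra = {}
    prefixes = ["head."] if config.shared_heads else [f"head.{s}." for s in KL_SOURCES]
    for pre in prefixes:
        extra.update({
            f"{pre}pcr.W1": enc._glorot(rng, zin, h), f"{pre}pcr.b1": np.zeros(h),
            f"{pre}pcr.W2": enc._glorot(rng, h, 1), f"{pre}pcr.b2": np.zeros(1),
            f"{pre}risk.W1": enc._glorot(rng, zin, h), f"{pre}risk.b1": np.zeros(h),
            f"{pre}risk.W2": enc._glorot(rng, h, 1), f"{pre}risk.b2": np.zeros(1),
        })
    extra.update({
        "alpha.W": enc._glorot(rng, c.latent_dim, 1), "alpha.b": np.zeros(1),
    })
    if config.posterior_variant == "elbo":
        # outcome expert of the training-time posterior q(z|x,y,r)
        uin = 3 + c.n_regimens  # (y_pcr, log time, event) + regimen code
        extra.update({
            "outc.W1": enc._glorot(rng, uin, h), "outc.b1": np.zeros(h),
            "outc.Wmu": enc._glorot(rng, h, c.latent_dim),
            "outc.bmu": np.zeros(c.latent_dim),
            "outc.Ws": enc._glorot(rng, h, c.latent_dim),
            "outc.bs": np.zeros(c.latent_dim),
        })
    params.update({k: Tensor(v, requires_grad=True) for k, v in extra.items()})
    return params


def forward_pass(features: dict, R: np.ndarray, params: dict, config: ModelConfig,
                 blank: np.ndarray | None = None, eps: dict | None = None,
                 outcome: tuple | None = None) -> dict:
    """Differentiable forward pass on frozen features.

    features: modality -> (n, d) array; R: (n, 5) regimen indicators;
    blank: (n,) indicator of missing reports (dropped from fusion when
    configured); eps: modality/'poe' -> (n, latent_dim) noise (None = 0,
    i.e. posterior means, the evaluation mode).

    ``outcome=(y_pcr, times, events)`` activates the training-time
    outcome-conditioned posterior in the "elbo" variant: each source's
    latent is sampled from q = PoE(p(z|x,r), outcome expert) and the KL
    terms become KL(q || p).  Inference (outcome=None) always uses
    p(z|x,r) alone.
    Returns per-source posteriors, latents, pCR probabilities, risk scores,
    alpha, and (in training) per-source KL terms under ``"kl"``.
    """
    n = R.shape[0]
    out: dict = {"mu": {}, "var": {}, "z": {}, "pcr": {}, "risk": {}}

    prec_sum = Tensor(np.ones((n, config.encoder.latent_dim)))  # prior N(0, I)
    num_sum = Tensor(np.zeros((n, config.encoder.latent_dim)))
    for mod in ("tab", "img", "txt"):
        f = features[mod]
        f = f if isinstance(f, Tensor) else Tensor(np.asarray(f, float))
        mu, var = posterior_head(f, R, params, mod)
        out["mu"][mod], out["var"][mod] = mu, var
        include = np.ones((n, 1))
        if mod == "txt" and blank is not None and config.blank_txt_as_missing:
            include = (1.0 - np.asarray(blank, float))[:, None]
        inc = Tensor(include)
        prec_sum = prec_sum + inc * (1.0 / var)
        num_sum = num_sum + inc * (mu / var)
    var_poe = 1.0 / prec_sum
    mu_poe = num_sum * var_poe
    out["mu"]["poe"], out["var"]["poe"] = mu_poe, var_poe

    q_expert = None
    use_elbo = (config.posterior_variant == "elbo" and outcome is not None
                and eps is not None)
    if use_elbo:
        y_pcr, times, events = outcome
        u = np.column_stack([np.asarray(y_pcr, float),
                             np.log(np.asarray(times, float)),
                             np.asarray(events, float), R])
        hq = (Tensor(u) @ params["outc.W1"] + params["outc.b1"]).tanh()
        mu_y = hq @ params["outc.Wmu"] + params["outc.bmu"]
        var_y = (hq @ params["outc.Ws"] + params["outc.bs"]).softplus() ** 2 + 1e-6
        q_expert = (mu_y, var_y)
        out["kl"] = {}

    for src in KL_SOURCES:
        e = None if eps is None else eps.get(src)
        mu_p, var_p = out["mu"][src], out["var"][src]
        if use_elbo:
            mu_y, var_y = q_expert
            prec_q = 1.0 / var_p + 1.0 / var_y
            var_q = 1.0 / prec_q
            mu_q = (mu_p / var_p + mu_y / var_y) * var_q
            z = mu_q if e is None else sample_latent(mu_q, var_q, e)
            out["kl"][src] = gaussian_kl(mu_q, var_q, mu_p, var_p)
        else:
            z = mu_p if e is None else sample_latent(mu_p, var_p, e)
        out["z"][src] = z
        p, risk = predict_outcomes(z, R, params,
                                   source=None if config.shared_heads else src)
        out["pcr"][src], out["risk"][src] = p, risk

    alpha = (mu_poe @ params["alpha.W"] + params["alpha.b"]).sigmoid().reshape(n)
    out["alpha"] = alpha
    out["pcr"]["correct"] = correct_prediction(
        out["pcr"]["poe"], out["pcr"]["tab"], alpha, scale=config.correction_scale)
    out["risk"]["correct"] = correct_prediction(
        out["risk"]["poe"], out["risk"]["tab"], alpha, scale="raw")
    return out


def batch_loss(fwd: dict, y_pcr: np.ndarray, times: np.ndarray, events: np.ndarray,
               config: ModelConfig):
    """Total training loss for one forward pass; Cox terms optionally
    normalized by the event count (training-time balance; the printed
    objective is the unnormalized sum)."""
    n_ev = max(float(np.sum(events)), 1.0)
    scale = 1.0 / n_ev if config.cox_normalization == "events" else 1.0
    pcr_l = {s: pcr_loss(fwd["pcr"][s], y_pcr) for s in SOURCES}
    cox_l = {s: cox_loss(fwd["risk"][s], times, events, config.risk_set) * scale
             for s in SOURCES}
    if "kl" in fwd:  # outcome-conditioned variant: KL(q || p) per source
        kl_l = dict(fwd["kl"])
    else:  # printed variant: each emitted posterior against the prior
        kl_l = {s: kl_term(fwd["mu"][s], fwd["var"][s]) for s in KL_SOURCES}
    return total_loss(pcr_l, cox_l, kl_l, config.lambda_kl)


# ----------------------------------------------------------- Model / Results


class ResponseModel:
    """Multi-modal neoadjuvant response model bound to a cohort.

    Parameters
    ----------
    records : list of PatientRecord
    config : ModelConfig
    bounds : ClinicalBounds for the tabular encoding.

    ``fit`` runs the contrastive alignment stage, freezes the encoders,
    trains the response stage with stratified cross-validation, and returns
    a :class:`ResponseResults`.
    """

    def __init__(self, records: list[PatientRecord], config: ModelConfig = ModelConfig(),
                 bounds: ClinicalBounds = ClinicalBounds()):
        self.records = list(records)
        self.config = config
        self.bounds = bounds
        n = len(records)
        c = config.encoder
        self.patient_ids = [r.patient_id for r in records]
        self.x_tab = np.stack([encode_clinical(r.clinical_raw, bounds) for r in records]) \
            if n else np.zeros((0, c.clinical_dim))
        self.x_img = np.stack([enc.pool_volume(r.volume, r.mask, c.pool_grid)
                               for r in records]) if n else np.zeros((0, c.img_in_dim))
        self.seqs = [ids_to_sequence(r.report_tokens) for r in records]
        self.blank = np.array([float(s.blank) for s in self.seqs])
        self.R = np.stack([regimen_code(r.regimen) for r in records]) if n else np.zeros((0, 5))
        self.y_pcr = np.array([r.y_pcr for r in records], float)
        self.times = np.array([r.survival.time for r in records], float)
        self.events = np.array([r.survival.event for r in records], float)
        self.subtypes = np.array([r.subtype for r in records])

    def nobs(self) -> int:
        return len(self.records)

    def features(self, encoder_params: dict) -> dict:
        """Frozen feature vectors per modality (numpy; detached)."""
        return {
            "tab": enc.encode_tab(self.x_tab, encoder_params).data,
            "img": enc.encode_img(self.x_img, encoder_params).data,
            "txt": enc.encode_txt(self.seqs, encoder_params).data,
        }

    def fit(self, train_config=None) -> "ResponseResults":
        from .train import TrainConfig, train_alignment, cross_validate_ensemble

        cfg = train_config or TrainConfig()
        encoder_params, align_history = train_alignment(self, cfg)
        feats = self.features(encoder_params)
        checkpoints, fold_results = cross_validate_ensemble(self, feats, cfg)
        return ResponseResults(self, cfg, encoder_params, feats, checkpoints,
                               fold_results, align_history)


class ResponseResults:
    """Fitted response model: frozen encoders plus an ensemble of response
    checkpoints (one per cross-validation fold)."""

    def __init__(self, model: ResponseModel, train_config, encoder_params,
                 features, checkpoints, fold_results, align_history):
        self.model = model
        self.train_config = train_config
        self.encoder_params = encoder_params
        self.features = features
        self.checkpoints = checkpoints  # list of param dicts
        self.fold_results = fold_results
        self.align_history = align_history

    # ------------------------------------------------------------- prediction
    def _features_for(self, records) -> tuple[dict, np.ndarray, list]:
        if records is None:
            return self.features, self.model.blank, self.model.patient_ids
        sub = ResponseModel(records, self.model.config, self.model.bounds)
        return sub.features(self.encoder_params), sub.blank, sub.patient_ids

    def predict(self, records=None, regimen: str | None = None,
                checkpoint_metric: str = "pcr_auc") -> pd.DataFrame:
        """Ensemble predictions (mean over fold checkpoints) for the given
        records (default: the fitted cohort) under the factual regimen or a
        fixed counterfactual ``regimen`` ('r1'..'r5')."""
        feats, blank, pids = self._features_for(records)
        recs = self.model.records if records is None else records
        if regimen is None:
            R = np.stack([regimen_code(r.regimen) for r in recs])
            reg_label = [r.regimen for r in recs]
        else:
            R = np.repeat(regimen_code(regimen)[None, :], len(recs), axis=0)
            reg_label = [regimen] * len(recs)
        frames = []
        for ck in self.checkpoints:
            params = ck[checkpoint_metric] if isinstance(ck, dict) and checkpoint_metric in ck else ck
            fwd = forward_pass(feats, R, params, self.model.config, blank=blank)
            row = {"patient_id": pids, "regimen": reg_label,
                   "alpha": fwd["alpha"].data}
            for s in SOURCES:
                row[f"pcr_{s}"] = fwd["pcr"][s].data
                row[f"risk_{s}"] = fwd["risk"][s].data
            frames.append(pd.DataFrame(row))
        stacked = pd.concat(frames)
        num = stacked.groupby(level=0).mean(numeric_only=True)
        out = frames[0][["patient_id", "regimen"]].copy()
        for col in num.columns:
            out[col] = num[col].to_numpy()
        return out

    def posteriors(self, records=None, regimen: str | None = None,
                   checkpoint_index: int = 0, checkpoint_metric: str = "pcr_auc") -> dict:
        """Per-modality and fused posterior parameters (first checkpoint by
        default), for posterior-shift diagnostics."""
        feats, blank, _ = self._features_for(records)
        recs = self.model.records if records is None else records
        R = (np.stack([regimen_code(r.regimen) for r in recs]) if regimen is None
             else np.repeat(regimen_code(regimen)[None, :], len(recs), axis=0))
        ck = self.checkpoints[checkpoint_index]
        params = ck[checkpoint_metric] if isinstance(ck, dict) and checkpoint_metric in ck else ck
        fwd = forward_pass(feats, R, params, self.model.config, blank=blank)
        return {
            "mu": {k: v.data for k, v in fwd["mu"].items()},
            "var": {k: v.data for k, v in fwd["var"].items()},
            "alpha": fwd["alpha"].data,
        }

    # ------------------------------------------------------------ persistence
    def fold_histories(self) -> pd.DataFrame:
        frames = []
        for fr in self.fold_results:
            h = fr.history.copy()
            h.insert(0, "fold", fr.fold)
            frames.append(h)
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()

    def save(self, outdir) -> None:
        """Persist encoder weights, fold checkpoints and run metadata."""
        import dataclasses as dc
        import json
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cfg = self.model.config
        enc.save_weights(outdir / "encoders.npz", self.encoder_params,
                         cfg.encoder, self.train_config.seed)
        for k, ck in enumerate(self.checkpoints):
            for metric, params in ck.items():
                np.savez(outdir / f"checkpoint_f{k}_{metric}.npz",
                         **{name.replace(".", "__"): p.data
                            for name, p in params.items()})
        meta = {
            "model_config": dc.asdict(cfg),
            "train_config": dc.asdict(self.train_config),
            "n_folds": len(self.checkpoints),
            "folds": [fr.val_indices.tolist() for fr in self.fold_results],
            "best": [{"pcr_auc": fr.best_pcr_auc, "cindex": fr.best_cindex}
                     for fr in self.fold_results],
        }
        (outdir / "meta.json").write_text(json.dumps(meta, indent=2))

    @staticmethod
    def load(rundir, records) -> "ResponseResults":
        import json
        from pathlib import Path

        from .train import FoldResult, TrainConfig

        rundir = Path(rundir)
        meta = json.loads((rundir / "meta.json").read_text())
        mc = dict(meta["model_config"])
        ec = dict(mc.pop("encoder"))
        for key in ("pool_grid", "volume_shape"):
            ec[key] = tuple(ec[key])
        config = ModelConfig(encoder=EncoderConfig(**ec), **mc)
        train_config = TrainConfig(**meta["train_config"])
        model = ResponseModel(records, config)
        encoder_params, _ = enc.load_weights(rundir / "encoders.npz", config.encoder)
        checkpoints = []
        for k in range(meta["n_folds"]):
            ck = {}
            for metric in ("pcr_auc", "cindex"):
                with np.load(rundir / f"checkpoint_f{k}_{metric}.npz") as z:
                    ck[metric] = {name.replace("__", "."): Tensor(z[name].copy(),
                                                                  requires_grad=True)
                                  for name in z.files}
            checkpoints.append(ck)
        fold_results = [
            FoldResult(fold=k, val_indices=np.asarray(meta["folds"][k], int),
                       history=pd.DataFrame(), best_pcr_auc=b["pcr_auc"],
                       best_cindex=b["cindex"], best_step_auc=-1, best_step_cindex=-1)
            for k, b in enumerate(meta["best"])
        ]
        feats = model.features(encoder_params)
        return ResponseResults(model, train_config, encoder_params, feats,
                               checkpoints, fold_results, pd.DataFrame())

    # ---------------------------------------------------------------- summary
    def validation_metrics(self) -> pd.DataFrame:
        rows = []
        for fr in self.fold_results:
            rows.append({"fold": fr.fold, "best_pcr_auc": fr.best_pcr_auc,
                         "best_cindex": fr.best_cindex,
                         "best_step_auc": fr.best_step_auc,
                         "best_step_cindex": fr.best_step_cindex})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        vm = self.validation_metrics()
        lines = [
            "Multi-modal NAT Response Model Results",
            "=" * 54,
            f"No. patients:        {self.model.nobs()}",
            f"Latent dimension:    {self.model.config.encoder.latent_dim}",
            f"Feature dimension:   {self.model.config.encoder.d}",
            f"lambda_KL:           {self.model.config.lambda_kl}",
            f"Risk-set convention: {self.model.config.risk_set}",
            f"Folds / checkpoints: {len(self.checkpoints)}",
            "-" * 54,
            "Cross-validation (best checkpoint per fold):",
            f"{'fold':>6} {'val pCR AUC':>14} {'val C-index':>14}",
        ]
        for _, r in vm.iterrows():
            lines.append(f"{int(r['fold']):>6} {r['best_pcr_auc']:>14.3f} {r['best_cindex']:>14.3f}")
        lines.append("-" * 54)
        lines.append(f"{'mean':>6} {vm['best_pcr_auc'].mean():>14.3f} "
                     f"{vm['best_cindex'].mean():>14.3f}")
        pred = self.predict()
        lines.append(f"Mean correction factor alpha: {pred['alpha'].mean():.3f}")
        return "\n".join(lines)
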