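"""Optimization loop, cross-validation, checkpoint selection and ensembling.

Two stages mirror the intended workflow: (1) a contrastive alignment stage
optimizing the modality encoders with InfoNCE over (img, tab) and
(img, txt) pairs, after which encoder weights are frozen and features
cached; (2) a response stage optimizing the joint pCR + Cox + KL objective
with full-batch AdamW steps on the training split, evaluating validation
pCR AUC and C-index periodically and retaining the best checkpoint for
each metric separately (ties break to the earliest step).  Five-fold
cross-validation, stratified jointly on the pCR label and the event
indicator so no fold is event-free, yields the five-checkpoint ensemble
whose scores are arithmetically averaged at prediction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._autodiff import Tensor
from . import encoders as enc
from .metrics import auc, c_index
from .model import (ModelConfig, batch_loss, forward_pass, init_response_params,
                    SOURCES, KL_SOURCES)

__all__ = [
    "TrainConfig",
    "FoldResult",
    "AdamW",
    "train_alignment",
    "train_response",
    "stratified_folds",
    "cross_validate_ensemble",
    "ensemble_predict",
    "desk_config",
]


@dataclass(frozen=True)
class TrainConfig:
    optimizer: str = "adamw"
    learning_rate: float = 1e-4  # alignment stage
    response_lr: float = 1e-4  # response stage
    weight_decay: float = 1e-2
    align_epochs: int = 100
    align_batch: int = 16
    response_steps: int = 500
    response_batch: int | None = None  # None = full training split
    eval_every: int = 10
    n_draws: int = 1  # reparameterized draws averaged per step
    folds: int = 5
    seed: int = 0
    checkpoint_metric: str = "pcr_auc"  # or "cindex"
    skip_align: bool = False
    temperature: float = 0.07

    def __post_init__(self):
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.learning_rate <= 0 or self.response_lr <= 0:
            raise ValueError("learning rates must be positive")


def desk_config(seed: int = 0, **overrides) -> TrainConfig:
    """Desk-scale defaults: shorter alignment and a larger response-stage
    step size, suited to full-batch updates of ~10^3-parameter heads."""
    base = dict(learning_rate=1e-3, response_lr=1e-2, align_epochs=3,
                response_steps=400, eval_every=20, seed=seed)
    base.update(overrides)
    return TrainConfig(**base)


@dataclass
class FoldResult:
    fold: int
    val_indices: np.ndarray
    history: pd.DataFrame
    best_pcr_auc: float
    best_cindex: float
    best_step_auc: int
    best_step_cindex: int


class AdamW:
    """Decoupled weight-decay Adam on a name -> Tensor parameter dict."""

    def __init__(self, params: dict, lr: float, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-2):
        self.params = params
        self.lr, self.betas, self.eps, self.wd = lr, betas, eps, weight_decay
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.wd * p.data)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


# ------------------------------------------------------------------ alignment


def train_alignment(model, config: TrainConfig) -> tuple[dict, pd.DataFrame]:
    """Contrastive stage: optimize encoders on (img, tab) and (img, txt)
    InfoNCE; returns (frozen encoder params, per-epoch loss history)."""
    params = enc.init_encoder_params(model.config.encoder, config.seed)
    history = []
    if config.skip_align or config.align_epochs == 0 or model.nobs() < 2:
        return params, pd.DataFrame(history, columns=["epoch", "loss"])
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 404]))
    opt = AdamW(params, lr=config.learning_rate, weight_decay=config.weight_decay)
    n = model.nobs()
    for epoch in range(config.align_epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.align_batch):
            idx = order[start:start + config.align_batch]
            if len(idx) < 2:
                continue
            f_img = enc.encode_img(model.x_img[idx], params)
            f_tab = enc.encode_tab(model.x_tab[idx], params)
            loss = enc.contrastive_align(f_img, f_tab, config.temperature)
            live = idx[model.blank[idx] == 0]
            if len(live) >= 2:
                f_img2 = enc.encode_img(model.x_img[live], params)
                f_txt = enc.encode_txt([model.seqs[i] for i in live], params)
                loss = loss + enc.contrastive_align(f_img2, f_txt, config.temperature)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite alignment loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history.append({"epoch": epoch, "loss": float(np.mean(losses))})
    return params, pd.DataFrame(history)


# ------------------------------------------------------------------- response


def _clone(params: dict) -> dict:
    return {k: Tensor(v.data.copy(), requires_grad=True) for k, v in params.items()}


def _val_metrics(feats, model, params, idx) -> tuple[float, float]:
    sub_feats = {m: feats[m][idx] for m in feats}
    fwd = forward_pass(sub_feats, model.R[idx], params, model.config,
                       blank=model.blank[idx])
    pcr_auc = auc(fwd["pcr"]["correct"].data, model.y_pcr[idx])
    cindex = c_index(fwd["risk"]["correct"].data, model.times[idx], model.events[idx])
    return pcr_auc, cindex


def train_response(model, feats: dict, train_idx: np.ndarray, val_idx: np.ndarray,
                   config: TrainConfig, fold_seed: int = 0):
    """Optimize the response stage on one train/validation split.

    Returns ``(checkpoints, history)`` where checkpoints holds the best
    parameter snapshots under each selection metric
    ({'pcr_auc': ..., 'cindex': ...}).
    """
    if len(val_idx) == 0:
        raise ValueError("empty validation split")
    params = init_response_params(model.config, fold_seed)
    opt = AdamW(params, lr=config.response_lr, weight_decay=config.weight_decay)
    rng = np.random.default_rng(np.random.SeedSequence([fold_seed, 505]))
    ld = model.config.encoder.latent_dim
    tr_feats = {m: feats[m][train_idx] for m in feats}
    R_tr = model.R[train_idx]
    blank_tr = model.blank[train_idx]
    y_tr, t_tr, e_tr = model.y_pcr[train_idx], model.times[train_idx], model.events[train_idx]

    best = {"pcr_auc": (-np.inf, None, -1), "cindex": (-np.inf, None, -1)}
    rows = []
    if config.response_steps == 0:
        a, c = _val_metrics(feats, model, params, val_idx)
        best = {"pcr_auc": (a, _clone(params), 0), "cindex": (c, _clone(params), 0)}
        rows.append({"step": 0, "loss": np.nan, "val_pcr_auc": a, "val_cindex": c})
    for step in range(config.response_steps):
        if config.response_batch is not None and config.response_batch < len(train_idx):
            sub = rng.choice(len(train_idx), size=config.response_batch, replace=False)
        else:
            sub = np.arange(len(train_idx))
        sub_feats = {m: tr_feats[m][sub] for m in tr_feats}
        # average the loss over several reparameterized draws; one draw is an
        # unbiased but high-variance estimator that stalls desk-scale training
        draws = max(1, config.n_draws)
        loss = None
        for _ in range(draws):
            eps = {s: rng.standard_normal((len(sub), ld)) for s in KL_SOURCES}
            fwd = forward_pass(sub_feats, R_tr[sub], params, model.config,
                               blank=blank_tr[sub], eps=eps,
                               outcome=(y_tr[sub], t_tr[sub], e_tr[sub]))
            part, breakdown = batch_loss(fwd, y_tr[sub], t_tr[sub], e_tr[sub],
                                         model.config)
            loss = part if loss is None else loss + part
        loss = loss * (1.0 / draws)
        if not np.isfinite(loss.data) or abs(float(loss.data)) > 1e6:
            raise FloatingPointError(f"training diverged at step {step}: "
                                     f"loss={float(loss.data):.3g}")
        opt.zero_grad()
        loss.backward()
        opt.step()
        if (step + 1) % config.eval_every == 0 or step == config.response_steps - 1:
            a, c = _val_metrics(feats, model, params, val_idx)
            rows.append({"step": step + 1, "loss": float(loss.data),
                         "val_pcr_auc": a, "val_cindex": c})
            if a > best["pcr_auc"][0]:
                best["pcr_auc"] = (a, _clone(params), step + 1)
            if c > best["cindex"][0]:
                best["cindex"] = (c, _clone(params), step + 1)
    checkpoints = {"pcr_auc": best["pcr_auc"][1], "cindex": best["cindex"][1]}
    history = pd.DataFrame(rows)
    meta = {"best_pcr_auc": best["pcr_auc"][0], "best_cindex": best["cindex"][0],
            "best_step_auc": best["pcr_auc"][2], "best_step_cindex": best["cindex"][2]}
    return checkpoints, history, meta


# ------------------------------------------------------------ cross-validation


def stratified_folds(y_pcr, events, n_folds: int, seed: int = 0) -> list[np.ndarray]:
    """Patient-level fold assignment stratified jointly on (pCR label,
    event indicator); returns validation index arrays that partition the
    cohort with fold sizes within one patient of equality."""
    y = np.asarray(y_pcr).astype(int)
    e = np.asarray(events).astype(int)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 606]))
    buckets = [[] for _ in range(n_folds)]
    offset = 0
    for stratum in sorted(set(zip(y.tolist(), e.tolist()))):
        idx = np.where((y == stratum[0]) & (e == stratum[1]))[0]
        idx = rng.permutation(idx)
        for i, j in enumerate(idx):
            buckets[(i + offset) % n_folds].append(j)
        offset += len(idx)
    return [np.sort(np.asarray(b, dtype=int)) for b in buckets]


def cross_validate_ensemble(model, feats: dict, config: TrainConfig):
    """One best checkpoint per fold; returns (checkpoints, fold_results)."""
    n = model.nobs()
    val_folds = stratified_folds(model.y_pcr, model.events, config.folds, config.seed)
    assert sum(len(f) for f in val_folds) == n
    checkpoints, fold_results = [], []
    for k, val_idx in enumerate(val_folds):
        train_idx = np.setdiff1d(np.arange(n), val_idx)
        if model.events[train_idx].sum() == 0 or model.events[val_idx].sum() == 0:
            raise ValueError(f"fold {k} has no events despite stratification")
        cks, history, meta = train_response(model, feats, train_idx, val_idx,
                                            config, fold_seed=config.seed * 1000 + k)
        checkpoints.append(cks)
        fold_results.append(FoldResult(fold=k, val_indices=val_idx, history=history,
                                       **meta))
    return checkpoints, fold_results


def ensemble_predict(checkpoints: list, feats: dict, R: np.ndarray,
                     config: ModelConfig, blank: np.ndarray | None = None,
                     metric: str = "pcr_auc") -> dict:
    """Arithmetic mean of each score over the checkpoints."""
    if len(checkpoints) == 0:
        raise ValueError("need at least one checkpoint")
    acc: dict = {}
    for ck in checkpoints:
        params = ck[metric] if isinstance(ck, dict) and metric in ck else ck
        fwd = forward_pass(feats, R, params, config, blank=blank)
        for s in SOURCES:
            acc.setdefault(f"pcr_{s}", []).append(fwd["pcr"][s].data)
            acc.setdefault(f"risk_{s}", []).append(fwd["risk"][s].data)
        acc.setdefault("alpha", []).append(fwd["alpha"].data)
    return {k: np.mean(np.stack(v), axis=0) for k, v in acc.items()}
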