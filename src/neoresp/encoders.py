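"""Modality encoders, contrastive alignment, and posterior heads.

Each modality (clinical table, image volume, report tokens) is mapped to a
d-dimensional feature vector (default 256) by a deliberately small network:
a 2-layer MLP for the table, a patch-pooling MLP for the volume (the tumor
mask is concatenated as a second channel so location is available), and a
pad-masked embedding average for the text.  A contrastive (InfoNCE) stage
aligns the modalities pairwise; afterwards encoder weights are frozen and
features are cached.  Regimen-conditioned posterior heads then emit a
diagonal Gaussian (mu, sigma^2) over the 3-dimensional latent prognosis by
concatenating the 5-dim regimen indicator to the feature vector.

Variances are stored as variances throughout (sigma^2), produced by a
softplus-then-square transform floored at 1e-6, so positivity holds for all
finite inputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict

import numpy as np

from ._autodiff import Tensor, concat, logsumexp
from .preprocess import CLINICAL_LAYOUT, TokenSequence

__all__ = [
    "EncoderConfig",
    "init_encoder_params",
    "init_posterior_params",
    "encode_tab",
    "encode_img",
    "encode_txt",
    "pool_volume",
    "contrastive_align",
    "posterior_head",
    "save_weights",
    "load_weights",
]

VAR_FLOOR = 1e-6


@dataclass(frozen=True)
class EncoderConfig:
    d: int = 256  # feature dimension
    latent_dim: int = 3
    hidden: int = 64
    emb_dim: int = 32
    vocab_size: int = 64
    pool_grid: tuple = (4, 4, 4)
    volume_shape: tuple = (16, 32, 32)
    clinical_dim: int = len(CLINICAL_LAYOUT)
    n_regimens: int = 5

    @property
    def img_in_dim(self) -> int:
        return 2 * int(np.prod(self.pool_grid))

    def arch_hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


def _glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / (n_in + n_out)), size=(n_in, n_out))


def init_encoder_params(config: EncoderConfig, seed: int) -> dict:
    """Fresh encoder weights as a flat name -> Tensor dict."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    c = config
    p = {
        "tab.W1": _glorot(rng, c.clinical_dim, c.hidden),
        "tab.b1": np.zeros(c.hidden),
        "tab.W2": _glorot(rng, c.hidden, c.d),
        "tab.b2": np.zeros(c.d),
        "img.W1": _glorot(rng, c.img_in_dim, c.hidden),
        "img.b1": np.zeros(c.hidden),
        "img.W2": _glorot(rng, c.hidden, c.d),
        "img.b2": np.zeros(c.d),
        "txt.emb": rng.normal(0.0, 0.5, size=(c.vocab_size, c.emb_dim)),
        "txt.no_report": rng.normal(0.0, 0.5, size=c.emb_dim),
        "txt.W": _glorot(rng, c.emb_dim, c.d),
        "txt.b": np.zeros(c.d),
    }
    return {k: Tensor(v, requires_grad=True) for k, v in p.items()}


def init_posterior_params(config: EncoderConfig, seed: int) -> dict:
    """Regimen-conditioned posterior-head weights for the three modalities."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    c = config
    p = {}
    for mod in ("tab", "img", "txt"):
        p[f"{mod}.post.Wmu"] = _glorot(rng, c.d + c.n_regimens, c.latent_dim)
        p[f"{mod}.post.bmu"] = np.zeros(c.latent_dim)
        p[f"{mod}.post.Ws"] = _glorot(rng, c.d + c.n_regimens, c.latent_dim)
        p[f"{mod}.post.bs"] = np.zeros(c.latent_dim)
    return {k: Tensor(v, requires_grad=True) for k, v in p.items()}


# -------------------------------------------------------------------- encoders


def encode_tab(x_tab: np.ndarray, params: dict) -> Tensor:
    """Clinical MLP: (n, clinical_dim) -> (n, d)."""
    x = Tensor(np.atleast_2d(x_tab))
    if x.shape[1] != params["tab.W1"].shape[0]:
        raise ValueError(
            f"clinical schema mismatch: got {x.shape[1]} fields, "
            f"weights expect {params['tab.W1'].shape[0]}")
    h = (x @ params["tab.W1"] + params["tab.b1"]).tanh()
    return h @ params["tab.W2"] + params["tab.b2"]


def pool_volume(volume: np.ndarray, mask: np.ndarray, grid: tuple) -> np.ndarray:
    """Average-pool volume and mask onto `grid` blocks and flatten to the
    image-encoder input vector (shape-generic; block sizes from the ratio)."""
    feats = []
    for arr in (volume, mask):
        arr = np.asarray(arr, dtype=np.float64)
        if any(s % g for s, g in zip(arr.shape, grid)):
            raise ValueError(f"volume shape {arr.shape} not divisible by pool grid {grid}")
        b = [s // g for s, g in zip(arr.shape, grid)]
        pooled = arr.reshape(grid[0], b[0], grid[1], b[1], grid[2], b[2]).mean(axis=(1, 3, 5))
        feats.append(pooled.ravel())
    return np.concatenate(feats)


def encode_img(x_img: np.ndarray, params: dict) -> Tensor:
    """Patch-pooled image MLP on pre-pooled inputs: (n, 2*prod(grid)) -> (n, d)."""
    x = Tensor(np.atleast_2d(x_img))
    if x.shape[1] != params["img.W1"].shape[0]:
        raise ValueError(
            f"image shape mismatch: got {x.shape[1]} pooled features, "
            f"weights expect {params['img.W1'].shape[0]}")
    h = (x @ params["img.W1"] + params["img.b1"]).tanh()
    return h @ params["img.W2"] + params["img.b2"]


def token_counts(seqs: list[TokenSequence], vocab_size: int) -> tuple[np.ndarray, np.ndarray]:
    """Normalized token-count matrix (n, vocab) and blank indicator (n,).

    Row i holds count(token)/n_tokens over non-pad positions, so
    counts @ emb is exactly the pad-masked average embedding.
    """
    n = len(seqs)
    counts = np.zeros((n, vocab_size))
    blank = np.zeros(n)
    for i, s in enumerate(seqs):
        live = s.ids[s.ids != s.pad_id]
        if s.blank or len(live) == 0:
            blank[i] = 1.0
            continue
        if np.any(live >= vocab_size):
            raise ValueError("token id out of vocabulary range")
        np.add.at(counts[i], live, 1.0)
        counts[i] /= len(live)
    return counts, blank


def encode_txt(seqs: list[TokenSequence], params: dict,
               vocab_size: int | None = None) -> Tensor:
    """Pad-masked embedding average -> linear map; blank sequences map to the
    learned no-report vector."""
    vs = vocab_size or params["txt.emb"].shape[0]
    counts, blank = token_counts(seqs, vs)
    mean_emb = Tensor(counts) @ params["txt.emb"]
    mean_emb = mean_emb + Tensor(blank[:, None]) * params["txt.no_report"]
    return mean_emb @ params["txt.W"] + params["txt.b"]


# ------------------------------------------------------------------ alignment


def _transpose(t: Tensor) -> Tensor:
    out = Tensor._make(t.data.T, (t,), None)
    if out.requires_grad:
        out._backward = lambda g: t._accum(g.T)
    return out


def contrastive_align(feats_a: Tensor, feats_b: Tensor, temperature: float = 0.07) -> Tensor:
    """Symmetric InfoNCE over cosine-similarity logits of patient-paired
    feature batches; lower when matched pairs are the most similar.
    Invariant to any common rotation of both feature sets."""
    n = feats_a.shape[0]
    if n < 2:
        raise ValueError("contrastive alignment needs a batch of at least 2")

    def normalize(f: Tensor) -> Tensor:
        norm = ((f * f).sum(axis=1, keepdims=True) + 1e-24).sqrt()
        return f / norm

    a, b = normalize(feats_a), normalize(feats_b)
    logits = (a @ _transpose(b)) * (1.0 / temperature)
    diag = logits[np.arange(n), np.arange(n)]
    loss_ab = (logsumexp(logits, axis=1) - diag).mean()
    loss_ba = (logsumexp(_transpose(logits), axis=1) - diag).mean()
    return (loss_ab + loss_ba) * 0.5


# -------------------------------------------------------------- posterior head


def posterior_head(f: Tensor, r: np.ndarray, params: dict, modality: str) -> tuple[Tensor, Tensor]:
    """Emit (mu, sigma^2) for the latent prognosis, conditioned on the
    regimen by concatenating its 5-dim indicator to the features."""
    r = np.atleast_2d(r)
    if r.shape[0] == 1 and f.shape[0] > 1:
        r = np.repeat(r, f.shape[0], axis=0)
    fr = concat([f, Tensor(r)], axis=1)
    mu = fr @ params[f"{modality}.post.Wmu"] + params[f"{modality}.post.bmu"]
    s = fr @ params[f"{modality}.post.Ws"] + params[f"{modality}.post.bs"]
    var = s.softplus() ** 2 + VAR_FLOOR
    return mu, var


# ------------------------------------------------------------------ checkpoints


def save_weights(path, params: dict, config: EncoderConfig, seed: int) -> None:
    """Single-container checkpoint: npz of arrays + JSON header."""
    header = json.dumps({
        "arch_hash": config.arch_hash(), "d": config.d,
        "latent_dim": config.latent_dim, "seed": seed,
        "config": asdict(config),
    })
    arrays = {k.replace(".", "__"): v.data for k, v in params.items()}
    np.savez(path, __header__=np.frombuffer(header.encode(), dtype=np.uint8), **arrays)


def load_weights(path, expected_config: EncoderConfig | None = None) -> tuple[dict, dict]:
    with np.load(path) as z:
        header = json.loads(bytes(z["__header__"]).decode())
        params = {k.replace("__", "."): Tensor(z[k].copy(), requires_grad=True)
                  for k in z.files if k != "__header__"}
    if expected_config is not None and header["arch_hash"] != expected_config.arch_hash():
        raise ValueError("checkpoint architecture mismatch")
    return params, header
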