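"""Deterministic encoders from raw patient records to model-ready arrays.

Clinical fields are min-max / indicator encoded into a fixed, versioned
layout; volumes are resampled to an isotropic grid, center-cropped or
zero-padded, and percentile-normalized to [0,1]; reports are whitespace
tokenized, truncated and padded to a fixed length.  Missing values are
zero-filled with explicit missing-indicator columns — the generator treats
missingness as completely at random and the encoding makes no stronger
assumption.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "CLINICAL_LAYOUT",
    "ClinicalBounds",
    "encode_clinical",
    "preprocess_volume",
    "tokenize_report",
    "TokenSequence",
]

SCHEMA_VERSION = 1

# ordered, versioned layout of the encoded clinical vector
CLINICAL_LAYOUT = (
    "age_norm",
    "weight_norm",
    "menopause_pre", "menopause_peri", "menopause_post", "menopause_missing",
    "er_status", "er_percent",
    "pr_status", "pr_percent",
    "her2_status", "her2_level_0", "her2_level_1", "her2_level_3p",
    "mib1_status", "mib1_percent",
    "t_stage_1", "t_stage_2", "t_stage_3", "t_stage_4",
    "n_stage_0", "n_stage_1", "n_stage_2", "n_stage_3",
)

ER_PR_POSITIVE_THRESHOLD = 1.0  # percent
MIB1_POSITIVE_THRESHOLD = 14.0  # percent; common Ki-67 cut point


@dataclass(frozen=True)
class ClinicalBounds:
    """Min-max normalization bounds; fixed once from the training split."""

    age: tuple = (18.0, 90.0)
    weight: tuple = (40.0, 120.0)
    # how to map HER2 IHC 2+ reports: "sish" routes 2+ with positive SISH to
    # 3+ and 2+ without SISH to 1; "error" rejects 2+ at ingestion
    her2_2plus_policy: str = "sish"


def _minmax(x: float, lo: float, hi: float) -> float:
    return float(np.clip((x - lo) / (hi - lo), 0.0, 1.0))


def encode_clinical(raw: dict, bounds: ClinicalBounds = ClinicalBounds()) -> np.ndarray:
    """Encode a raw clinical map into the fixed CLINICAL_LAYOUT vector.

    ER/PR status is positive iff the stained percentage is >= 1%;
    percentages are carried as fractions in (0,1); HER2 level expands to a
    3-level indicator over {0, 1, 3+}; missing values zero-fill and set the
    matching missing indicator.
    """
    v = dict.fromkeys(CLINICAL_LAYOUT, 0.0)

    v["age_norm"] = _minmax(float(raw["age"]), *bounds.age)
    v["weight_norm"] = _minmax(float(raw["weight"]), *bounds.weight)

    men = str(raw.get("menopause", "missing")).lower()
    if men not in ("pre", "peri", "post", "missing"):
        raise ValueError(f"unknown menopause status {men!r}")
    v[f"menopause_{men}"] = 1.0

    for marker in ("er", "pr", "mib1"):
        pct = raw.get(f"{marker}_percent")
        if pct is None or (isinstance(pct, float) and np.isnan(pct)):
            continue  # zero-filled
        pct = float(pct)
        if not 0.0 <= pct <= 100.0:
            raise ValueError(f"{marker} percent {pct} outside [0, 100]")
        thr = ER_PR_POSITIVE_THRESHOLD if marker in ("er", "pr") else MIB1_POSITIVE_THRESHOLD
        v[f"{marker}_status"] = float(pct >= thr)
        v[f"{marker}_percent"] = pct / 100.0

    her2 = str(raw.get("her2_level", "")).strip()
    if her2:
        if her2 in ("2", "2+"):
            if bounds.her2_2plus_policy == "error":
                raise ValueError("HER2 2+ has no slot in the 3-level code")
            her2 = "3+" if raw.get("sish_positive") else "1"
        key = {"0": "her2_level_0", "1": "her2_level_1",
               "3+": "her2_level_3p", "3": "her2_level_3p"}.get(her2)
        if key is None:
            raise ValueError(f"unknown HER2 level {her2!r}")
        v[key] = 1.0
        v["her2_status"] = float(key == "her2_level_3p")

    t = raw.get("t_stage")
    if t is not None and not (isinstance(t, float) and np.isnan(t)):
        t = int(t)
        if not 1 <= t <= 4:
            raise ValueError(f"T stage {t} outside 1..4")
        v[f"t_stage_{t}"] = 1.0
    n = raw.get("n_stage")
    if n is not None and not (isinstance(n, float) and np.isnan(n)):
        n = int(n)
        if not 0 <= n <= 3:
            raise ValueError(f"N stage {n} outside 0..3")
        v[f"n_stage_{n}"] = 1.0

    return np.array([v[k] for k in CLINICAL_LAYOUT], dtype=np.float64)


# -------------------------------------------------------------------- volumes


def _crop_or_pad(arr: np.ndarray, target_shape: tuple) -> np.ndarray:
    """Center crop / symmetric zero-pad each axis; even offsets break toward
    the lower index."""
    out = arr
    for ax, tgt in enumerate(target_shape):
        cur = out.shape[ax]
        if cur > tgt:
            start = (cur - tgt) // 2
            sl = [slice(None)] * out.ndim
            sl[ax] = slice(start, start + tgt)
            out = out[tuple(sl)]
        elif cur < tgt:
            before = (tgt - cur) // 2
            pad = [(0, 0)] * out.ndim
            pad[ax] = (before, tgt - cur - before)
            out = np.pad(out, pad)
    return out


def preprocess_volume(volume: np.ndarray, spacing, mask: np.ndarray | None = None,
                      target_spacing=(2.0, 2.0, 2.0), target_shape=(16, 32, 32),
                      percentile: float = 99.5):
    """Resample (trilinear; nearest for the mask), center crop/pad, and
    percentile-normalize a volume to [0,1].

    Returns ``(volume, mask)``; mask is None when not supplied.
    """
    volume = np.asarray(volume, dtype=np.float64)
    if volume.size == 0:
        raise ValueError("empty volume")
    spacing = np.asarray(spacing, dtype=float)
    target_spacing = np.asarray(target_spacing, dtype=float)
    if np.any(spacing <= 0) or np.any(target_spacing <= 0):
        raise ValueError("voxel spacings must be positive")
    if not 0.0 < percentile <= 100.0:
        raise ValueError("percentile must lie in (0, 100]")

    zoom = spacing / target_spacing
    if not np.allclose(zoom, 1.0):
        volume = ndimage.zoom(volume, zoom, order=1)
        if mask is not None:
            mask = ndimage.zoom(np.asarray(mask, float), zoom, order=0)
    volume = _crop_or_pad(volume, tuple(target_shape))
    if mask is not None:
        mask = (_crop_or_pad(np.asarray(mask, float), tuple(target_shape)) > 0.5).astype(np.uint8)

    cut = np.percentile(volume, percentile)
    if cut <= 0:
        warnings.warn("constant-zero volume: skipping intensity normalization")
        out = np.zeros_like(volume)
    else:
        out = np.clip(volume, 0.0, cut) / cut
    return out, mask


# ---------------------------------------------------------------------- text

_TOKEN_RE = re.compile(r"[a-z0-9+]+")


@dataclass(frozen=True)
class TokenSequence:
    ids: np.ndarray  # fixed length
    blank: bool
    pad_id: int = field(default=0)

    def __post_init__(self):
        if self.blank and np.any(self.ids != self.pad_id):
            raise ValueError("blank sequence must be all pad")


def tokenize_report(text: str | None, vocabulary: dict, max_len: int = 512,
                    pad_id: int = 0, unk_id: int = 1) -> TokenSequence:
    """Whitespace/punctuation tokenize, truncate to ``max_len``, pad with
    ``pad_id``; missing or empty text yields an all-pad blank sequence."""
    if text is None or not str(text).strip():
        return TokenSequence(ids=np.full(max_len, pad_id, dtype=int), blank=True,
                             pad_id=pad_id)
    tokens = _TOKEN_RE.findall(str(text).lower())[:max_len]
    ids = np.full(max_len, pad_id, dtype=int)
    ids[: len(tokens)] = [vocabulary.get(t, unk_id) for t in tokens]
    return TokenSequence(ids=ids, blank=False, pad_id=pad_id)


def ids_to_sequence(ids: np.ndarray, max_len: int = 512, pad_id: int = 0) -> TokenSequence:
    """Wrap pre-tokenized ids (as produced by the cohort generator)."""
    ids = np.asarray(ids, dtype=int)
    if len(ids) == 0:
        return TokenSequence(ids=np.full(max_len, pad_id, dtype=int), blank=True,
                             pad_id=pad_id)
    out = np.full(max_len, pad_id, dtype=int)
    out[: min(len(ids), max_len)] = ids[:max_len]
    return TokenSequence(ids=out, blank=False, pad_id=pad_id)
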