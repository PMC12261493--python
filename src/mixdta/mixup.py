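"""Mixup interpolation of representations and affinity labels.

A virtual training sample is the convex combination of two real samples,

    x_mix = lam * x_i + (1 - lam) * x_j,
    y_mix = lam * y_i + (1 - lam) * y_j,

with ``lam ~ Beta(alpha, alpha)``.  Mixing happens by default in the
pooled-representation space (fixed-length vectors after cross-encoding),
because raw token matrices of two pairs have different lengths; a
``padded_token`` mode (zero-pad to the longer length, then mix token-wise)
is available for experimentation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = ["MixupConfig", "MixupSample", "sample_lambda", "mix_pair", "pad_to"]

MIX_SPACES = ("pooled_representation", "padded_token")


@dataclass(frozen=True)
class MixupConfig:
    """alpha > 0 is the Beta concentration; alpha -> 0 gives near-endpoint
    draws, alpha = 1 is uniform, large alpha concentrates at 1/2."""

    alpha: float = 0.5
    mix_space: str = "pooled_representation"
    per_sample: bool = True

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.mix_space not in MIX_SPACES:
            raise ValueError(f"mix_space must be one of {MIX_SPACES}")


@dataclass(frozen=True)
class MixupSample:
    rep: np.ndarray
    label: float
    lam: float
    source_ids: tuple[int, Optional[int]]


def sample_lambda(cfg: MixupConfig, rng: np.random.Generator) -> float:
    return float(rng.beta(cfg.alpha, cfg.alpha))


def mix_pair(
    rep_i: np.ndarray,
    rep_j: np.ndarray,
    y_i: float,
    y_j: float,
    lam: float,
    source_ids: tuple[int, Optional[int]] = (-1, -1),
) -> MixupSample:
    """Convex combination of two representations and their labels."""
    rep_i = np.asarray(rep_i, dtype=np.float64)
    rep_j = np.asarray(rep_j, dtype=np.float64)
    if rep_i.shape != rep_j.shape:
        raise ValueError(f"shape mismatch: {rep_i.shape} vs {rep_j.shape}")
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lam must be in [0, 1], got {lam}")
    if lam == 1.0:  # exact endpoints, no float residue from (1 - lam) * x_j
        rep, label = rep_i.copy(), float(y_i)
    elif lam == 0.0:
        rep, label = rep_j.copy(), float(y_j)
    else:
        rep = lam * rep_i + (1.0 - lam) * rep_j
        label = lam * float(y_i) + (1.0 - lam) * float(y_j)
    return MixupSample(rep=rep, label=label, lam=float(lam), source_ids=source_ids)


def pad_to(tokens: np.ndarray, n_rows: int) -> np.ndarray:
    """Zero-pad a (T, d) token matrix to ``n_rows`` rows (padded_token mode)."""
    if tokens.shape[0] > n_rows:
        raise ValueError("cannot pad to fewer rows than present")
    if tokens.shape[0] == n_rows:
        return tokens
    pad = np.zeros((n_rows - tokens.shape[0], tokens.shape[1]), dtype=tokens.dtype)
    return np.vstack([tokens, pad])
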