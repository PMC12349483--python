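"""Sparsity and orthogonality penalties on the learned basis functions.

Two penalties, following the adaptive-basis construction this architecture
extends: R1 is the mean L1 norm of (a subsample of) the basis functions,
pushing each basis toward localized support; R2 is the mean squared cosine
similarity over (a subsample of) basis pairs, pushing bases within a channel
toward mutual orthogonality.  Both integrals use the trapezoid rule on the
model grid.  Subsampling — kR1 bases and kR2 bases per channel, redrawn
uniformly without replacement at every optimization step from a dedicated
seeded stream — keeps the pairwise term affordable at large K without
breaking run-to-run reproducibility.

Penalties are averaged per channel so their scale does not grow with F;
channel counts in practice span two orders of magnitude and shared default
strengths should transfer across them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .autodiff import Tensor
from .grid import TimeGrid

__all__ = ["RegularizationConfig", "sparsity_penalty", "orthogonality_penalty"]


@dataclass(frozen=True)
class RegularizationConfig:
    """Strengths and subsample sizes; ``per_channel=False`` pools the F·K
    bases before subsampling instead of drawing within each channel."""

    lambda1: float = 0.0
    lambda2: float = 0.0
    kR1: int = 1
    kR2: int = 2
    subsample_seed: int = 0
    per_channel: bool = True

    def __post_init__(self):
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("penalty strengths must be non-negative")
        if not (np.isfinite(self.lambda1) and np.isfinite(self.lambda2)):
            raise ValueError("penalty strengths must be finite")
        if self.kR1 < 1:
            raise ValueError("kR1 must be >= 1")
        if self.kR2 < 2:
            raise ValueError("kR2 must be >= 2")


def _check_k(k: int, K: int, name: str) -> None:
    if k > K:
        raise ValueError(f"{name}={k} exceeds the number of bases K={K}")


def _subsample(rng: np.random.Generator | None, K: int, k: int) -> np.ndarray:
    if rng is None or k >= K:
        return np.arange(K)
    return np.sort(rng.choice(K, size=k, replace=False))


def sparsity_penalty(bases: Tensor | np.ndarray, grid: TimeGrid,
                     cfg: RegularizationConfig,
                     rng: np.random.Generator | None = None) -> Tensor:
    """R1: mean trapezoid L1 norm over kR1 subsampled bases per channel.

    Accepts the (F, K, J) basis tensor either inside the autodiff graph
    (during training) or as a plain array (diagnostics).  Without an ``rng``
    the subsample degenerates to all K bases.
    """
    if not isinstance(bases, Tensor):
        bases = Tensor(bases)
    F, K, J = bases.shape
    _check_k(cfg.kR1, K, "kR1")
    w = Tensor(grid.weights)
    if cfg.per_channel:
        terms = []
        for f in range(F):
            idx = _subsample(rng, K, cfg.kR1)
            sub = bases[f, idx, :]  # (kR1, J)
            terms.append((sub.abs() * w).sum(axis=1).mean())
        total = terms[0]
        for t in terms[1:]:
            total = total + t
        return total * (1.0 / F)
    flat = bases.reshape(F * K, J)
    idx = _subsample(rng, F * K, min(cfg.kR1 * F, F * K))
    return (flat[idx, :].abs() * w).sum(axis=1).mean()


def orthogonality_penalty(bases: Tensor | np.ndarray, grid: TimeGrid,
                          cfg: RegularizationConfig,
                          rng: np.random.Generator | None = None) -> Tensor:
    """R2: mean squared cosine similarity over pairs of kR2 subsampled bases.

    A pair involving a basis with zero norm on the grid contributes 0 (with
    a warning): the direction of an identically-zero basis is undefined and
    the sparsity penalty already governs it.
    """
    if not isinstance(bases, Tensor):
        bases = Tensor(bases)
    F, K, J = bases.shape
    if K < 2:
        return Tensor(0.0)
    _check_k(cfg.kR2, K, "kR2")
    w = grid.weights

    def channel_term(sub: Tensor) -> Tensor:
        k = sub.shape[0]
        gram = (sub * Tensor(w)) @ sub.transpose((1, 0))  # (k, k) trapezoid Gram
        degenerate = np.diag(gram.data) <= 1e-300
        if degenerate.any():
            warnings.warn("zero-norm basis encountered in orthogonality penalty")
        pair_terms = []
        for i, j in combinations(range(k), 2):
            if degenerate[i] or degenerate[j]:
                continue
            cos2 = gram[i, j] ** 2 / (gram[i, i] * gram[j, j])
            pair_terms.append(cos2)
        n_pairs = k * (k - 1) // 2
        if not pair_terms:
            return Tensor(0.0)
        total = pair_terms[0]
        for t in pair_terms[1:]:
            total = total + t
        return total * (1.0 / n_pairs)

    if cfg.per_channel:
        terms = []
        for f in range(F):
            idx = _subsample(rng, K, cfg.kR2)
            terms.append(channel_term(bases[f, idx, :]))
        total = terms[0]
        for t in terms[1:]:
            total = total + t
        return total * (1.0 / F)
    flat = bases.reshape(F * K, J)
    idx = _subsample(rng, F * K, min(cfg.kR2, F * K))
    return channel_term(flat[idx, :])
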