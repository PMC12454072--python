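"""Contribution metrics and fair aggregation weights.

A center's contribution has two components: data richness D (the normalized
size of its core set after redundancy pruning — richer, less redundant data
means a larger core) and model quality Q (its local model's accuracy this
round on held-out probe-validation samples). The server combines the two
into simplex weights w used for contribution-weighted aggregation; the
default is the convex mix

    w_k = lambda * D_k + (1 - lambda) * Q_k / sum_j Q_j,

with ``lambda_mix = 0.5``. A multiplicative variant (w_k proportional to
D_k * Q_k) is available for ablations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .mcdem import PrunePartition

__all__ = ["ContributionRecord", "compute_richness", "compute_quality", "compute_weights"]


@dataclass(frozen=True)
class ContributionRecord:
    """Per-round snapshot of D, Q and the resulting weights."""

    round: int
    D: tuple[float, ...]
    Q: tuple[float, ...]
    w: tuple[float, ...]
    lambda_mix: float

    def __post_init__(self):
        if abs(sum(self.w) - 1.0) > 1e-9:
            raise ValueError("aggregation weights must sum to 1")
        if any(wk < 0 for wk in self.w):
            raise ValueError("aggregation weights must be non-negative")
        if abs(sum(self.D) - 1.0) > 1e-9:
            raise ValueError("richness D must be normalized to sum 1")


def compute_richness(partitions: Sequence[PrunePartition]) -> np.ndarray:
    """Normalized core-set sizes: D_k = |C_k| / sum_j |C_j|."""
    if len(partitions) == 0:
        raise ValueError("need at least one center")
    sizes = np.array([len(p.core) for p in partitions], dtype=np.float64)
    if np.any(sizes == 0):
        raise ValueError("every center must retain a non-empty core set")
    return sizes / sizes.sum()


def compute_quality(probs: np.ndarray, labels: np.ndarray, cutoff: float = 0.5) -> float:
    """Local-model accuracy at the probability cutoff (prediction 1 iff p >= cutoff)."""
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels)
    if probs.size == 0:
        raise ValueError("evaluation samples must be non-empty")
    pred = (probs >= cutoff).astype(int)
    return float(np.mean(pred == labels))


def compute_weights(
    D: Sequence[float],
    Q: Sequence[float],
    lambda_mix: float = 0.5,
    scheme: str = "convex",
) -> np.ndarray:
    """Contribution-fair aggregation weights on the simplex.

    convex (default): w = lambda * D + (1 - lambda) * Q / sum(Q);
    multiplicative:   w proportional to D * Q (lambda_mix ignored).
    If every Q is zero the quality signal is uninformative and w falls back
    to D, with a warning.
    """
    D = np.asarray(D, dtype=np.float64)
    Q = np.asarray(Q, dtype=np.float64)
    if D.shape != Q.shape:
        raise ValueError("D and Q must have one entry per center")
    if not np.isclose(D.sum(), 1.0, atol=1e-9):
        raise ValueError("D must be normalized (sum to 1)")
    if np.any((Q < 0) | (Q > 1)):
        raise ValueError("Q entries must lie in [0, 1]")
    if not (0.0 <= lambda_mix <= 1.0):
        raise ValueError("lambda_mix must lie in [0, 1]")
    if Q.sum() == 0:
        warnings.warn("all center qualities are 0; falling back to w = D", stacklevel=2)
        return D.copy()
    if scheme == "convex":
        w = lambda_mix * D + (1.0 - lambda_mix) * Q / Q.sum()
    elif scheme == "multiplicative":
        prod = D * Q
        if prod.sum() == 0:
            warnings.warn("D*Q degenerate; falling back to w = D", stacklevel=2)
            return D.copy()
        w = prod / prod.sum()
    else:
        raise ValueError(f"unknown weighting scheme {scheme!r}")
    return w / w.sum()  # guard against rounding drift
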