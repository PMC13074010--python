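"""Clinical-entropy guidance.

A federated client's "clinical entropy" is the Shannon entropy (in bits)
of its local diagnostic class distribution.  Heterogeneous clinics —
tertiary referral centres seeing a broad case mix versus screening units
dominated by one or two findings — differ widely in this quantity, and
the optimizer uses it as a scalar control signal: diverse (high-entropy)
clients get a larger evolutionary population and a smaller, more
conservative rotation step, while specialised (low-entropy) clients get
the opposite.  The same entropies weight each client's vote when token
masks are fused at the server.

All entropies are in bits (log base 2); the maximum attainable entropy
for ``C`` classes is ``log2 C``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ClassDistribution",
    "EntropyProfile",
    "shannon_entropy",
    "population_size",
    "rotation_step",
    "entropy_weights",
]


class InvalidDistributionError(ValueError):
    """Raised when class counts cannot form a probability distribution."""


@dataclass(frozen=True)
class ClassDistribution:
    """Per-class sample counts and the derived proportions.

    Parameters
    ----------
    counts
        Non-negative integer count per diagnostic class, length ``C >= 1``.
    """

    counts: np.ndarray

    def __init__(self, counts) -> None:
        arr = np.asarray(counts)
        if arr.ndim != 1 or arr.size < 1:
            raise InvalidDistributionError("counts must be a 1-D sequence of length >= 1")
        if np.any(arr < 0):
            raise InvalidDistributionError("counts must be non-negative")
        if arr.sum() <= 0:
            raise InvalidDistributionError("at least one class must have a positive count")
        object.__setattr__(self, "counts", arr.astype(np.int64))

    @property
    def n_classes(self) -> int:
        return int(self.counts.size)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def proportions(self) -> np.ndarray:
        """Relative class frequencies ``p_j = n_j / n`` (sum to 1)."""
        return self.counts / self.counts.sum()

    @classmethod
    def from_labels(cls, labels, n_classes: int | None = None) -> "ClassDistribution":
        labels = np.asarray(labels, dtype=np.int64)
        if n_classes is None:
            n_classes = int(labels.max()) + 1 if labels.size else 1
        return cls(np.bincount(labels, minlength=n_classes))


@dataclass(frozen=True)
class EntropyProfile:
    """Shannon entropy of a class distribution, with its ceiling.

    ``normalized_entropy`` is ``H / H_max`` in [0, 1]; for a single-class
    distribution (``C == 1``) both ``H`` and ``H_max`` are zero and the
    normalized value is defined as 0.
    """

    entropy_bits: float
    max_entropy_bits: float

    def __post_init__(self) -> None:
        if not (-1e-12 <= self.entropy_bits <= self.max_entropy_bits + 1e-9):
            raise ValueError(
                f"entropy {self.entropy_bits} outside [0, {self.max_entropy_bits}]"
            )

    @property
    def normalized_entropy(self) -> float:
        if self.max_entropy_bits == 0.0:
            return 0.0
        return min(1.0, self.entropy_bits / self.max_entropy_bits)


def shannon_entropy(dist: ClassDistribution) -> EntropyProfile:
    """Shannon entropy ``H = -sum_j p_j log2 p_j`` of a class distribution.

    Empty classes (``p_j = 0``) contribute nothing, by the usual
    continuity convention ``0 log 0 = 0``.

    Examples
    --------
    >>> shannon_entropy(ClassDistribution([1] * 16)).entropy_bits
    4.0
    """
    p = dist.proportions
    p = p[p > 0]
    h = float(-(p * np.log2(p)).sum())
    # -0.0 and tiny negatives from rounding clamp to 0
    h = max(h, 0.0)
    return EntropyProfile(entropy_bits=h, max_entropy_bits=float(np.log2(dist.n_classes)))


def population_size(profile: EntropyProfile, base_size: int, scale: float = 0.3) -> int:
    """Entropy-scaled evolutionary population size.

    ``P_k = round( P_B * (1 + scale * H_k / H_max) )``, guaranteed to lie
    in ``[P_B, round((1 + scale) * P_B)]``: high-diversity clients search
    with a larger population.

    Parameters
    ----------
    base_size
        Base population ``P_B`` shared by all clients (>= 2).
    scale
        Expansion factor in [0, 1]; 0 disables entropy scaling.
    """
    if base_size < 2:
        raise ValueError("base_size must be >= 2")
    if not 0.0 <= scale <= 1.0:
        raise ValueError(f"population entropy scale must be in [0, 1], got {scale}")
    raw = base_size * (1.0 + scale * profile.normalized_entropy)
    return max(base_size, int(round(raw)))


def rotation_step(profile: EntropyProfile, base_step: float = 0.05, scale: float = 0.3) -> float:
    """Entropy-aware quantum rotation step in radians.

    ``delta_k = delta_base * (1 + scale * (1 - H_k / H_max))``: low-entropy
    (specialised) clients take larger steps and converge aggressively;
    high-entropy clients rotate conservatively, preserving diversity.
    Result lies in ``[delta_base, (1 + scale) * delta_base]``.
    """
    if base_step <= 0:
        raise ValueError("base_step must be positive")
    if not 0.0 <= scale <= 0.5:
        raise ValueError(f"rotation entropy scale must be in [0, 0.5], got {scale}")
    return base_step * (1.0 + scale * (1.0 - profile.normalized_entropy))


def entropy_weights(entropies) -> np.ndarray:
    """Normalised aggregation weights ``w_k = H_k / sum_l H_l``.

    Used by the server to weight each client's mask vote by its clinical
    diversity.  If every client has zero entropy (all single-class), the
    weights fall back to uniform so the federation still aggregates.
    """
    h = np.asarray(entropies, dtype=float)
    if h.size == 0:
        raise ValueError("entropies must be non-empty")
    if np.any(h < 0):
        raise ValueError("entropies must be non-negative")
    total = h.sum()
    if total == 0.0:
        return np.full(h.size, 1.0 / h.size)
    return h / total
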