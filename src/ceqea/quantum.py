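"""Quantum-inspired population primitives for binary token masks.

Each decision bit (keep / drop a token) is encoded as a qubit with a
real amplitude pair ``(alpha_j, beta_j)``, ``alpha_j^2 + beta_j^2 = 1``.
Observation collapses a chromosome to a binary mask with
``P(bit_j = 1) = beta_j^2``; a rotation gate steers amplitudes toward
the best-so-far solution, and a phase-flip (Z) mutation negates ``beta``
without changing observation probabilities.  Amplitudes are real, as in
classical quantum-inspired evolutionary practice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "QubitChromosome",
    "BinaryMask",
    "StabilityScores",
    "init_population",
    "observe",
    "rotation_sign",
    "rotate",
    "phase_flip",
    "mutation_probability",
    "stability_scores",
]

_NORM_TOL = 1e-9


@dataclass
class QubitChromosome:
    """Amplitude pairs for ``N`` token positions.

    Invariant: ``alpha[j]**2 + beta[j]**2 == 1`` within 1e-9 at every
    position (renormalised on construction if drift exceeds that).
    """

    alpha: np.ndarray
    beta: np.ndarray

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.alpha.shape != self.beta.shape or self.alpha.ndim != 1:
            raise ValueError("alpha and beta must be 1-D arrays of equal length")
        norm = self.alpha**2 + self.beta**2
        if np.any(np.abs(norm - 1.0) > _NORM_TOL):
            r = np.sqrt(norm)
            if np.any(r == 0):
                raise ValueError("zero-amplitude qubit cannot be normalised")
            self.alpha = self.alpha / r
            self.beta = self.beta / r

    def __len__(self) -> int:
        return self.alpha.size

    @property
    def p_one(self) -> np.ndarray:
        """Per-position probability of observing bit 1 (``beta^2``)."""
        return self.beta**2

    def copy(self) -> "QubitChromosome":
        return QubitChromosome(self.alpha.copy(), self.beta.copy())

    def to_array(self) -> np.ndarray:
        """Two-row array ``[alpha; beta]`` for checkpointing."""
        return np.vstack([self.alpha, self.beta])

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "QubitChromosome":
        arr = np.asarray(arr, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != 2:
            raise ValueError("expected a 2 x N array")
        return cls(arr[0], arr[1])


@dataclass
class BinaryMask:
    """Length-``N`` 0/1 token-retention vector.

    Position 0 is the class-token slot; in token mode it must stay 1
    (the class token is never pruned).
    """

    bits: np.ndarray

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits)
        if bits.ndim != 1:
            raise ValueError("bits must be 1-D")
        if not np.all((bits == 0) | (bits == 1)):
            raise ValueError("mask bits must be 0 or 1")
        self.bits = bits.astype(np.int8)

    def __len__(self) -> int:
        return self.bits.size

    @property
    def n_tokens(self) -> int:
        return self.bits.size

    @property
    def retained_count(self) -> int:
        return int(self.bits.sum())

    @property
    def retained_indices(self) -> np.ndarray:
        return np.flatnonzero(self.bits)

    def jaccard(self, other: "BinaryMask") -> float:
        """Jaccard similarity of the retained index sets."""
        a = set(self.retained_indices.tolist())
        b = set(other.retained_indices.tolist())
        if not a and not b:
            return 1.0
        return len(a & b) / len(a | b)

    @classmethod
    def from_indices(cls, n_tokens: int, indices) -> "BinaryMask":
        bits = np.zeros(n_tokens, dtype=np.int8)
        idx = np.asarray(list(indices), dtype=np.int64)
        if idx.size and (idx.min() < 0 or idx.max() >= n_tokens):
            raise ValueError("retained index out of range")
        bits[idx] = 1
        return cls(bits)


@dataclass
class StabilityScores:
    """Per-token selection-frequency scores ``S_j`` in [0, 1].

    A token's stability is the cross-client mean of the fraction of
    high-fitness (elite) masks that retain it; stable tokens are ones the
    federation keeps agreeing on.
    """

    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if np.any((self.scores < -1e-12) | (self.scores > 1 + 1e-12)):
            raise ValueError("stability scores must lie in [0, 1]")
        self.scores = np.clip(self.scores, 0.0, 1.0)

    @classmethod
    def ones(cls, n_tokens: int) -> "StabilityScores":
        return cls(np.ones(n_tokens))


def init_population(size: int, n_tokens: int, seed=None) -> list[QubitChromosome]:
    """Unbiased initial population: every qubit at ``(1/sqrt2, 1/sqrt2)``.

    Observation of a fresh chromosome retains each token with
    probability 1/2.  The population is deterministic; ``seed`` is
    accepted for interface symmetry with the stochastic operators.
    """
    if size < 2:
        raise ValueError("population size must be >= 2")
    if n_tokens < 1:
        raise ValueError("n_tokens must be >= 1")
    amp = 1.0 / np.sqrt(2.0)
    return [
        QubitChromosome(np.full(n_tokens, amp), np.full(n_tokens, amp))
        for _ in range(size)
    ]


def observe(chrom: QubitChromosome, rng: np.random.Generator, force_first: bool = True) -> BinaryMask:
    """Collapse a chromosome to a binary mask.

    Per position ``j`` draw ``r ~ U(0,1)`` and set the bit to 0 when
    ``r < alpha_j^2``, else 1 — so ``P(bit=1) = beta_j^2``.  With
    ``force_first`` the class-token position 0 is set to 1 after
    sampling.
    """
    r = rng.random(len(chrom))
    bits = (r >= chrom.alpha**2).astype(np.int8)
    if force_first:
        bits[0] = 1
    return BinaryMask(bits)


def rotation_sign(bit: int, best_bit: int, fitness: float, best_fitness: float) -> int:
    """Rotation direction for one qubit, from the five-case lookup.

    +1 pushes the amplitude toward bit 1, -1 toward bit 0, 0 leaves the
    qubit alone (whenever the individual already agrees with the best
    solution at that position).
    """
    if bit == best_bit:
        return 0
    if (bit, best_bit) == (0, 1):
        return +1 if fitness < best_fitness else -1
    # (bit, best_bit) == (1, 0)
    return +1 if fitness >= best_fitness else -1


_SIGN_TABLE = np.zeros((2, 2, 2), dtype=np.int8)  # [bit, best_bit, worse_than_best]
_SIGN_TABLE[0, 1, 1] = +1
_SIGN_TABLE[0, 1, 0] = -1
_SIGN_TABLE[1, 0, 0] = +1
_SIGN_TABLE[1, 0, 1] = -1


def rotate(
    chrom: QubitChromosome,
    own_mask: BinaryMask,
    best_mask: BinaryMask,
    fitness: float,
    best_fitness: float,
    step: float,
) -> QubitChromosome:
    """Fitness-adaptive rotation toward the best-so-far mask.

    Per position the angle is ``step * sign(...)`` and the amplitude
    pair is rotated by the 2x2 cosine/sine gate
    ``(a', b') = (cos t * a - sin t * b, sin t * a + cos t * b)``.
    Normalisation is preserved exactly by the gate; accumulated
    floating-point drift is renormalised.
    """
    n = len(chrom)
    if len(own_mask) != n or len(best_mask) != n:
        raise ValueError("mask length must match chromosome length")
    worse = int(fitness < best_fitness)
    signs = _SIGN_TABLE[own_mask.bits, best_mask.bits, worse]
    theta = step * signs
    c, s = np.cos(theta), np.sin(theta)
    alpha = c * chrom.alpha - s * chrom.beta
    beta = s * chrom.alpha + c * chrom.beta
    return QubitChromosome(alpha, beta)


def phase_flip(chrom: QubitChromosome, position: int) -> QubitChromosome:
    """Z-gate mutation at one position: ``(a, b) -> (a, -b)``.

    Observation probabilities are unchanged (``|-b|^2 = |b|^2``); the
    flip perturbs the phase so that subsequent rotations move the qubit
    differently, which is the exploratory effect of this mutation.
    """
    n = len(chrom)
    if not 0 <= position < n:
        raise IndexError(f"position {position} out of range for {n} qubits")
    out = chrom.copy()
    out.beta[position] = -out.beta[position]
    return out


def mutation_probability(
    base_rate: float,
    fitness: float,
    max_fitness: float,
    entropy,  # EntropyProfile
    stability: float,
    invert_stability: bool = False,
) -> float:
    """Entropy- and fitness-scaled mutation probability for one qubit.

    ``P_mut = eta * (1 - F_i/F_max) * (1 - H_k/H_max) * S_j`` — the best
    individual never mutates, high-entropy clients mutate less, and the
    token stability score modulates per position.  When ``F_max == 0``
    (degenerate all-zero-fitness generation) the fitness factor is
    dropped.  ``invert_stability`` replaces ``S_j`` with ``1 - S_j`` for
    sensitivity analysis (so unstable tokens mutate more).
    """
    if not 0.0 <= base_rate <= 0.3:
        raise ValueError(f"base mutation rate must be in [0, 0.3], got {base_rate}")
    if not 0.0 <= stability <= 1.0:
        raise ValueError("stability score must be in [0, 1]")
    s = (1.0 - stability) if invert_stability else stability
    ent_factor = 1.0 - entropy.normalized_entropy
    if max_fitness == 0.0:
        return base_rate * ent_factor * s
    if not 0.0 <= fitness <= max_fitness:
        raise ValueError("fitness must lie in [0, max_fitness]")
    return base_rate * (1.0 - fitness / max_fitness) * ent_factor * s


def stability_scores(elite_masks_per_client: list[list[BinaryMask]], n_tokens: int | None = None) -> StabilityScores:
    """Token stability from federated elite-mask selection frequencies.

    ``S_j`` averages, over clients that uploaded at least one elite
    mask, the fraction of that client's elite masks retaining token
    ``j``.  With no elite masks anywhere all scores default to 1
    (maximally stable, i.e. mutation is not suppressed by staleness).
    """
    fractions = []
    for masks in elite_masks_per_client:
        if not masks:
            continue
        bits = np.stack([m.bits for m in masks])
        if n_tokens is None:
            n_tokens = bits.shape[1]
        fractions.append(bits.mean(axis=0))
    if not fractions:
        if n_tokens is None:
            raise ValueError("n_tokens required when no elite masks are given")
        return StabilityScores.ones(n_tokens)
    return StabilityScores(np.mean(fractions, axis=0))
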