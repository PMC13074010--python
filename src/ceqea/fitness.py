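"""Composite accuracy-sparsity fitness and mask evaluators.

The fitness of a candidate mask trades off two objectives:

    f(m) = w1 * A(m) + w2 * (1 - ||m||_0 / N),      w2 = 1 - w1

where ``A(m)`` is the classification accuracy reachable with the
retained tokens and the second term rewards aggressive pruning.  The
accuracy oracle is pluggable: any callable ``(mask, context) ->
accuracy in [0, 1]`` conforms.  Two evaluators ship here:

* :class:`MLPProxyEvaluator` — the lightweight two-layer GELU/dropout
  network trained for a few epochs on masked class-token features, the
  proxy used during real optimisation;
* :class:`PlantedOracleEvaluator` — a deterministic oracle scoring the
  fraction of planted informative tokens a mask retains, used to make
  optimizer behaviour exactly checkable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import erf

from .quantum import BinaryMask

__all__ = [
    "FitnessConfig",
    "FitnessRecord",
    "sparsity_term",
    "composite_fitness",
    "MLPProxyEvaluator",
    "PlantedOracleEvaluator",
    "mlp_proxy_accuracy",
    "planted_oracle_accuracy",
]


@dataclass(frozen=True)
class FitnessConfig:
    """Weights of the accuracy-sparsity trade-off.

    ``accuracy_weight`` (w1, default 0.7) prioritises diagnostic
    accuracy; the sparsity weight is its complement.
    """

    accuracy_weight: float = 0.7
    n_tokens: int = 197

    def __post_init__(self) -> None:
        if not 0.0 <= self.accuracy_weight <= 1.0:
            raise ValueError("accuracy_weight must be in [0, 1]")
        if self.n_tokens < 1:
            raise ValueError("n_tokens must be positive")

    @property
    def sparsity_weight(self) -> float:
        return 1.0 - self.accuracy_weight

    @property
    def max_attainable(self) -> float:
        """Fitness ceiling: perfect accuracy with only the class token kept."""
        return self.accuracy_weight + self.sparsity_weight * (1.0 - 1.0 / self.n_tokens)


@dataclass(frozen=True)
class FitnessRecord:
    """One evaluated individual: mask, accuracy, composite fitness."""

    mask: BinaryMask
    accuracy: float
    fitness: float


def sparsity_term(mask: BinaryMask) -> float:
    """Pruning reward ``1 - ||m||_0 / N`` (0 for all-ones, 1 for empty)."""
    return 1.0 - mask.retained_count / mask.n_tokens


def composite_fitness(accuracy: float, mask: BinaryMask, cfg: FitnessConfig) -> float:
    """``w1 * A + w2 * (1 - retained/N)``, in [0, 1]."""
    if not 0.0 <= accuracy <= 1.0:
        raise ValueError(f"accuracy must be in [0, 1], got {accuracy}")
    return cfg.accuracy_weight * accuracy + cfg.sparsity_weight * sparsity_term(mask)


# ---------------------------------------------------------------------------
# Deterministic planted-subset oracle
# ---------------------------------------------------------------------------


class PlantedOracleEvaluator:
    """Accuracy oracle for planted problems: |mask ∩ planted| / |planted|.

    On synthetic data whose class signal lives in a known token subset,
    retaining a fraction q of the planted tokens caps the reachable
    accuracy at roughly q; this oracle makes that cap exact, so the
    fitness landscape is fully enumerable and the optimizer can be
    tested against brute force.
    """

    def __init__(self, planted: set[int] | list[int]):
        planted = set(int(i) for i in planted)
        if not planted:
            raise ValueError("planted token set must be non-empty")
        self.planted = planted

    def __call__(self, mask: BinaryMask, context=None) -> float:
        retained = set(mask.retained_indices.tolist())
        return len(retained & self.planted) / len(self.planted)


def planted_oracle_accuracy(mask: BinaryMask, planted) -> float:
    return PlantedOracleEvaluator(planted)(mask)


# ---------------------------------------------------------------------------
# Lightweight MLP proxy
# ---------------------------------------------------------------------------


def _gelu(x: np.ndarray) -> np.ndarray:
    return 0.5 * x * (1.0 + erf(x / np.sqrt(2.0)))


def _gelu_grad(x: np.ndarray) -> np.ndarray:
    phi = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
    return 0.5 * (1.0 + erf(x / np.sqrt(2.0))) + x * phi


def _cls_representation(features: np.ndarray, mask: BinaryMask, mode: str = "drop") -> np.ndarray:
    """Masked class-token representation per sample.

    ``features`` is (n_samples, N, d) token embeddings with the class
    token at row 0.  The class-token representation is formed by one
    parameter-free uniform-attention step: the mean of the retained
    token rows (class token included).  In ``zero`` mode masked rows are
    zeroed but still counted, the literal element-wise-multiplication
    reading; in ``drop`` mode (default) they are removed before pooling.
    """
    if mask.bits[0] != 1:
        raise ValueError("class token (position 0) must be retained")
    if features.shape[1] != mask.n_tokens:
        raise ValueError("mask length does not match token count")
    if mode == "drop":
        return features[:, mask.retained_indices, :].mean(axis=1)
    if mode == "zero":
        return (features * mask.bits[None, :, None]).mean(axis=1)
    raise ValueError(f"unknown mask mode {mode!r}")


class MLPProxyEvaluator:
    """Two-layer GELU/dropout network as a fast accuracy proxy.

    Trains ``d -> hidden -> C`` (GELU between, dropout after the hidden
    activation) for 1-3 epochs on the masked class-token features of the
    training split and reports held-out accuracy.  Deterministic under a
    fixed seed.

    Parameters
    ----------
    features : (n_samples, N, d) token-sequence embeddings.
    labels : (n_samples,) integer class labels.
    hidden : hidden width (default 256).
    epochs : training epochs, 1-3.
    dropout : dropout rate after the hidden layer (default 0.1).
    val_fraction : held-out fraction (default 0.2, an 80:20 split).
    mode : ``drop`` (default) or ``zero`` masking of token rows.
    """

    def __init__(
        self,
        features: np.ndarray,
        labels: np.ndarray,
        n_classes: int | None = None,
        hidden: int = 256,
        epochs: int = 3,
        dropout: float = 0.1,
        lr: float = 0.01,
        batch_size: int = 8,
        val_fraction: float = 0.2,
        n_splits: int = 1,
        mode: str = "drop",
        seed: int = 0,
    ):
        if not 1 <= epochs <= 3:
            raise ValueError("proxy epochs must be 1-3")
        self.features = np.asarray(features, dtype=float)
        self.labels = np.asarray(labels, dtype=np.int64)
        self.n_classes = int(n_classes if n_classes is not None else self.labels.max() + 1)
        self.hidden = hidden
        self.epochs = epochs
        self.dropout = dropout
        self.lr = lr
        self.batch_size = batch_size
        self.mode = mode
        self.seed = seed
        # fixed hold-out splits shared across all mask evaluations;
        # n_splits > 1 averages repeated 80:20 hold-outs for a less
        # noisy accuracy estimate on small client datasets
        rng = np.random.default_rng(seed)
        n = self.features.shape[0]
        n_val = max(1, int(round(val_fraction * n)))
        self.splits = []
        for _ in range(max(1, n_splits)):
            order = rng.permutation(n)
            self.splits.append((order[n_val:], order[:n_val]))

    def __call__(self, mask: BinaryMask, context=None) -> float:
        x = _cls_representation(self.features, mask, self.mode)
        return float(
            np.mean(
                [
                    self._train_and_score(x, tr, va, self.seed + 977 * i)
                    for i, (tr, va) in enumerate(self.splits)
                ]
            )
        )

    def _train_and_score(self, x: np.ndarray, train_idx, val_idx, seed: int) -> float:
        xtr, ytr = x[train_idx], self.labels[train_idx]
        xva, yva = x[val_idx], self.labels[val_idx]
        classes = np.unique(ytr)
        if classes.size < 2:
            warnings.warn("single-class training split; returning majority-class accuracy")
            return float((yva == classes[0]).mean())
        # standardize on train-split statistics so the few permitted
        # epochs start in a well-conditioned regime
        mu, sd = xtr.mean(0), xtr.std(0) + 1e-9
        xtr = (xtr - mu) / sd
        xva = (xva - mu) / sd

        rng = np.random.default_rng(seed + 1)
        d, h, c = x.shape[1], self.hidden, self.n_classes
        w1 = rng.normal(0, np.sqrt(2.0 / d), (d, h))
        b1 = np.zeros(h)
        w2 = rng.normal(0, np.sqrt(2.0 / h), (h, c))
        b2 = np.zeros(c)
        # Adam state: converges within the permitted handful of epochs
        m_ = [np.zeros_like(p) for p in (w1, b1, w2, b2)]
        v_ = [np.zeros_like(p) for p in (w1, b1, w2, b2)]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0

        n = xtr.shape[0]
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb = xtr[idx], ytr[idx]
                z1 = xb @ w1 + b1
                a1 = _gelu(z1)
                if self.dropout > 0:
                    keep = rng.random(a1.shape) >= self.dropout
                    a1d = a1 * keep / (1.0 - self.dropout)
                else:
                    a1d = a1
                logits = a1d @ w2 + b2
                logits -= logits.max(axis=1, keepdims=True)
                p = np.exp(logits)
                p /= p.sum(axis=1, keepdims=True)
                g = p.copy()
                g[np.arange(len(yb)), yb] -= 1.0
                g /= len(yb)
                gw2 = a1d.T @ g
                gb2 = g.sum(axis=0)
                ga1 = g @ w2.T
                if self.dropout > 0:
                    ga1 = ga1 * keep / (1.0 - self.dropout)
                gz1 = ga1 * _gelu_grad(z1)
                gw1 = xb.T @ gz1
                gb1 = gz1.sum(axis=0)
                params = [w1, b1, w2, b2]
                grads = [gw1, gb1, gw2, gb2]
                t += 1
                for i, (p_, g_) in enumerate(zip(params, grads)):
                    m_[i] = beta1 * m_[i] + (1 - beta1) * g_
                    v_[i] = beta2 * v_[i] + (1 - beta2) * g_ * g_
                    mhat = m_[i] / (1 - beta1**t)
                    vhat = v_[i] / (1 - beta2**t)
                    p_ -= self.lr * mhat / (np.sqrt(vhat) + eps)

        z1 = _gelu(xva @ w1 + b1)
        pred = (z1 @ w2 + b2).argmax(axis=1)
        return float((pred == yva).mean())


def mlp_proxy_accuracy(
    features: np.ndarray,
    labels: np.ndarray,
    mask: BinaryMask,
    epochs: int = 3,
    seed: int = 0,
    **kwargs,
) -> float:
    """Functional wrapper around :class:`MLPProxyEvaluator`."""
    return MLPProxyEvaluator(features, labels, epochs=epochs, seed=seed, **kwargs)(mask)
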