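"""Synthetic endoscopy-like images with a planted, patch-confined class signal.

Real endoscopic benchmarks cannot ship with a desk-scale package, so
testing relies on images generated here: a Gaussian-noise background in
which each class writes a deterministic texture motif into a known set
of patch positions.  By construction the mutual information between the
label and any patch outside the planted set is zero, so the optimal
pruning mask is exactly the planted patches plus the class token — the
property that makes token-recovery experiments meaningful.

Per-client class imbalance is controlled either by explicit priors or
by a Dirichlet draw, mirroring the label-skew protocol used in
federated-learning benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .entropy import ClassDistribution, EntropyProfile, shannon_entropy

__all__ = [
    "SynthConfig",
    "LabeledImageSet",
    "generate_client_dataset",
    "preset_upper_gi_profile",
    "UPPER_GI_COUNTS",
]

UPPER_GI_COUNTS = (999, 932, 764, 403, 260)
"""Per-class image counts of an upper-GI endoscopy corpus (5 classes:
pylorus, z-line, retroflex-stomach, esophagitis grade A, esophagitis
grades B-D), used as an entropy-realism preset (H = 2.172 bits)."""


@dataclass(frozen=True)
class SynthConfig:
    """Geometry and signal parameters of the generator.

    Defaults give the desk-scale geometry: 32x32 images with 8-pixel
    patches, i.e. 16 patch tokens plus the class token (17 tokens).
    ``planted_patches`` are patch indices (0-based, row-major); the
    corresponding token indices are shifted by +1 for the class-token
    offset.  ``noise_sigma`` is the background standard deviation around
    mid-gray, ``signal_amplitude`` the motif contrast.
    """

    image_size: int = 32
    patch_size: int = 8
    n_classes: int = 5
    planted_patches: tuple = (2, 7, 8, 13)
    signal_amplitude: float = 1.0
    noise_sigma: float = 0.3
    n_samples: int = 120
    class_priors: tuple | None = None  # uniform when None

    def __post_init__(self) -> None:
        if self.image_size % self.patch_size != 0:
            raise ValueError("image_size must be divisible by patch_size")
        n_patches = (self.image_size // self.patch_size) ** 2
        if len(self.planted_patches) == 0:
            raise ValueError("planted patch set must be non-empty")
        if any(not 0 <= i < n_patches for i in self.planted_patches):
            raise ValueError("planted patch index out of range")
        if self.class_priors is not None:
            pr = np.asarray(self.class_priors, dtype=float)
            if pr.size != self.n_classes or abs(pr.sum() - 1.0) > 1e-9 or np.any(pr < 0):
                raise ValueError("class_priors must be a length-C simplex vector")

    @property
    def n_patches(self) -> int:
        return (self.image_size // self.patch_size) ** 2

    @property
    def n_tokens(self) -> int:
        return self.n_patches + 1

    @property
    def planted_tokens(self) -> tuple:
        """Planted patch indices shifted to token positions (>= 1)."""
        return tuple(i + 1 for i in self.planted_patches)


@dataclass
class LabeledImageSet:
    """Images, labels and the ground-truth informative token indices."""

    images: np.ndarray  # (n, S, S, 3) floats
    labels: np.ndarray  # (n,) ints in [0, C)
    planted_tokens: tuple
    config: SynthConfig

    def __len__(self) -> int:
        return self.images.shape[0]

    def entropy_profile(self) -> EntropyProfile:
        dist = ClassDistribution.from_labels(self.labels, self.config.n_classes)
        return shannon_entropy(dist)

    def save(self, path) -> None:
        np.savez(
            path,
            images=self.images,
            labels=self.labels,
            planted_tokens=np.asarray(self.planted_tokens),
        )


def _patch_pattern(slot: int, patch_size: int) -> np.ndarray:
    """Deterministic zero-mean texture for one planted slot (p x p x 3).

    Each planted slot gets its own oriented pattern and channel tilt so
    the slots contribute linearly independent feature directions.
    """
    p = patch_size
    yy, xx = np.mgrid[0:p, 0:p] / max(p - 1, 1)
    patterns = [
        xx - 0.5,  # horizontal gradient
        yy - 0.5,  # vertical gradient
        (xx + yy) / 2 - 0.5,  # diagonal
        (np.mgrid[0:p, 0:p].sum(axis=0) % 2) - 0.5,  # checkerboard
        (xx - yy) / 2,  # anti-diagonal
        np.cos(2 * np.pi * xx) / 2,  # vertical stripes
    ]
    base = patterns[slot % len(patterns)]
    tilt = np.array(
        [1.0, 0.8 + 0.1 * (slot % 3), 0.6 + 0.15 * ((slot // 3) % 3)]
    )
    return base[:, :, None] * tilt[None, None, :]


def _sign_code(n_classes: int, n_slots: int) -> np.ndarray:
    """(C x m) +-1 code giving every planted slot discriminative weight.

    Canonical construction for ``C <= m + 1``: class 0 is all +1 and
    class ``c`` flips slot ``c - 1``, so classes 0 and ``c`` differ only
    at that slot — dropping any planted patch merges a class pair and
    measurably costs accuracy.  For larger C the remaining rows are
    filled with distinct deterministic +-1 rows.
    """
    code = np.ones((n_classes, n_slots))
    for c in range(1, min(n_classes, n_slots + 1)):
        code[c, c - 1] = -1.0
    if n_classes > n_slots + 1:
        rng = np.random.default_rng(12345)
        seen = {tuple(row) for row in code}
        for c in range(n_slots + 1, n_classes):
            while True:
                row = rng.choice([-1.0, 1.0], size=n_slots)
                if tuple(row) not in seen:
                    seen.add(tuple(row))
                    code[c] = row
                    break
    return code


def generate_client_dataset(cfg: SynthConfig, rng: np.random.Generator) -> LabeledImageSet:
    """Draw one client's labeled image set.

    Background pixels are ``0.5 + N(0, sigma)``; each planted patch adds
    its slot pattern multiplied by the class's +-1 code entry and the
    signal amplitude.  The code makes the planted set jointly
    informative: every planted patch separates at least one class pair
    that the remaining patches cannot.  Labels are multinomial draws
    from the client's prior.  Fully reproducible from the generator
    state; the motifs themselves are deterministic.
    """
    priors = (
        np.full(cfg.n_classes, 1.0 / cfg.n_classes)
        if cfg.class_priors is None
        else np.asarray(cfg.class_priors, dtype=float)
    )
    labels = rng.choice(cfg.n_classes, size=cfg.n_samples, p=priors)
    s, p = cfg.image_size, cfg.patch_size
    g = s // p
    images = 0.5 + cfg.noise_sigma * rng.standard_normal((cfg.n_samples, s, s, 3))
    code = _sign_code(cfg.n_classes, len(cfg.planted_patches))
    patterns = [
        cfg.signal_amplitude * _patch_pattern(slot, p)
        for slot in range(len(cfg.planted_patches))
    ]
    for i, lab in enumerate(labels):
        for slot, patch_idx in enumerate(cfg.planted_patches):
            r, c = divmod(patch_idx, g)
            images[i, r * p : (r + 1) * p, c * p : (c + 1) * p, :] += (
                code[lab, slot] * patterns[slot]
            )
    return LabeledImageSet(images, labels.astype(np.int64), cfg.planted_tokens, cfg)


def preset_upper_gi_profile() -> ClassDistribution:
    """Class-count preset matching an imbalanced 5-class upper-GI corpus."""
    return ClassDistribution(np.asarray(UPPER_GI_COUNTS))
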