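"""Image preprocessing, patch tokenization and a configurable transformer encoder.

The pipeline mirrors a standard vision transformer: bilinear
aspect-preserving resize with zero padding, channel normalization,
non-overlapping ``p x p`` patch extraction, linear patch embedding with
a prepended class token and sinusoidal positional embeddings, then a
stack of pre-norm encoder layers (multi-head self-attention + GELU FFN,
residual connections) whose final class-token representation feeds a
softmax classification head.

All dimensions are configurable; the ``vit16b`` preset names the
full-scale geometry (224x224 images, 16-pixel patches, d=768, L=12
layers, H=12 heads, 197 tokens).  Everything runs in numpy, with manual
reverse-mode gradients so the tiny configurations used at desk scale
are trainable end to end.

Token masks can be applied in two modes: ``zero`` multiplies masked
rows by zero (the literal element-wise product) and keeps the sequence
length; ``drop`` removes masked rows, which is the mode under which
self-attention cost actually falls to ``K^2`` for ``K`` retained
tokens.  Positional embeddings are always added before dropping, so a
retained token keeps its original positional identity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter
from scipy.special import erf

from .quantum import BinaryMask

__all__ = [
    "PreprocessConfig",
    "EncoderConfig",
    "preprocess",
    "augment",
    "elastic_deform",
    "patchify",
    "sinusoidal_positions",
    "EncoderParams",
    "build_sequence",
    "apply_mask",
    "encoder_forward",
    "classify",
    "cross_entropy",
    "TinyViTClassifier",
    "VIT16B",
]

IMAGENET_MEAN = (0.485, 0.456, 0.406)
IMAGENET_STD = (0.229, 0.224, 0.225)


@dataclass(frozen=True)
class PreprocessConfig:
    """Resize / normalization / augmentation ranges.

    Augmentation jitter bounds follow common endoscopic practice:
    brightness +-20%, contrast +-15%, saturation +-10%, Gaussian blur
    with sigma up to 1.0.
    """

    target_size: int = 224
    patch_size: int = 16
    mean: tuple = IMAGENET_MEAN
    std: tuple = IMAGENET_STD
    brightness: float = 0.20
    contrast: float = 0.15
    saturation: float = 0.10
    blur_sigma_max: float = 1.0
    flip: bool = True
    rotate90: bool = True

    def __post_init__(self) -> None:
        if self.target_size % self.patch_size != 0:
            raise ValueError("target_size must be divisible by patch_size")

    @property
    def n_patches(self) -> int:
        return (self.target_size // self.patch_size) ** 2


def _as_float01(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB image")
    if image.dtype == np.uint8:
        return image.astype(np.float64) / 255.0
    return image.astype(np.float64)


def preprocess(image: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Aspect-preserving resize, zero pad to square, scale, normalize.

    The longer side is scaled to ``target_size`` with bilinear
    interpolation; the shorter side is zero-padded symmetrically so no
    anatomical distortion is introduced.  Output channels are
    ``(x - mean) / std``.
    """
    cfg = cfg or PreprocessConfig()
    img = _as_float01(image)
    h, w = img.shape[:2]
    if h <= 0 or w <= 0:
        raise ValueError("image must have positive dimensions")
    scale = cfg.target_size / max(h, w)
    new_h, new_w = max(1, round(h * scale)), max(1, round(w * scale))
    resized = np.stack(
        [
            np.asarray(
                Image.fromarray(img[:, :, c].astype(np.float32), mode="F").resize(
                    (new_w, new_h), resample=Image.BILINEAR
                )
            )
            for c in range(3)
        ],
        axis=2,
    ).astype(np.float64)
    out = np.zeros((cfg.target_size, cfg.target_size, 3))
    top = (cfg.target_size - new_h) // 2
    left = (cfg.target_size - new_w) // 2
    out[top : top + new_h, left : left + new_w] = resized
    mean = np.asarray(cfg.mean)
    std = np.asarray(cfg.std)
    return (out - mean) / std


def augment(image: np.ndarray, cfg: PreprocessConfig, rng: np.random.Generator) -> np.ndarray:
    """Random flip/rotation and photometric jitter on a [0, 1] image.

    With all jitter ranges zero and flips/rotations disabled this is
    the identity.  Output is clipped back to [0, 1].
    """
    img = _as_float01(image)
    if cfg.flip and rng.random() < 0.5:
        img = img[:, ::-1]
    if cfg.flip and rng.random() < 0.5:
        img = img[::-1, :]
    if cfg.rotate90:
        img = np.rot90(img, k=int(rng.integers(0, 4)))
    if cfg.brightness > 0:
        img = img * rng.uniform(1 - cfg.brightness, 1 + cfg.brightness)
    if cfg.contrast > 0:
        m = img.mean()
        img = m + rng.uniform(1 - cfg.contrast, 1 + cfg.contrast) * (img - m)
    if cfg.saturation > 0:
        gray = img.mean(axis=2, keepdims=True)
        img = gray + rng.uniform(1 - cfg.saturation, 1 + cfg.saturation) * (img - gray)
    if cfg.blur_sigma_max > 0:
        sigma = rng.uniform(0.0, cfg.blur_sigma_max)
        if sigma > 1e-3:
            img = gaussian_filter(img, sigma=(sigma, sigma, 0))
    return np.clip(np.ascontiguousarray(img), 0.0, 1.0)


def elastic_deform(image: np.ndarray) -> np.ndarray:
    """Placeholder for elastic deformation; currently the identity."""
    warnings.warn("elastic deformation is not implemented; returning image unchanged")
    return np.asarray(image)


def patchify(image: np.ndarray, patch_size: int) -> np.ndarray:
    """Row-major non-overlapping patches, each flattened to ``p*p*3``.

    A 224x224 image with 16-pixel patches yields 196 patch vectors of
    length 768.  Reassembling the patches reproduces the image exactly.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an H x W x 3 image")
    side = img.shape[0]
    if img.shape[1] != side:
        raise ValueError("image must be square")
    if side % patch_size != 0:
        raise ValueError(f"side {side} not divisible by patch size {patch_size}")
    g = side // patch_size
    patches = img.reshape(g, patch_size, g, patch_size, 3).transpose(0, 2, 1, 3, 4)
    return patches.reshape(g * g, patch_size * patch_size * 3)


def unpatchify(patches: np.ndarray, side: int, patch_size: int) -> np.ndarray:
    """Inverse of :func:`patchify` (partition property)."""
    g = side // patch_size
    p = patches.reshape(g, g, patch_size, patch_size, 3).transpose(0, 2, 1, 3, 4)
    return p.reshape(side, side, 3)


def sinusoidal_positions(n_positions: int, d: int) -> np.ndarray:
    """Fixed sine/cosine positional table (n_positions, d)."""
    pos = np.arange(n_positions)[:, None]
    i = np.arange(d)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d)
    table = np.zeros((n_positions, d))
    table[:, 0::2] = np.sin(angle[:, 0::2])
    table[:, 1::2] = np.cos(angle[:, 1::2])
    return table


# ---------------------------------------------------------------------------
# Encoder parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture dimensions.

    ``d`` embedding width, ``n_layers`` encoder depth, ``n_heads``
    attention heads (``d`` divisible by ``n_heads``; head width
    ``d / n_heads``), FFN hidden width fixed at ``4 d``.
    """

    d: int = 32
    n_layers: int = 2
    n_heads: int = 4
    patch_dim: int = 192  # 8 * 8 * 3
    n_tokens: int = 17  # patches + class token
    n_classes: int = 2
    learnable_positions: bool = False

    def __post_init__(self) -> None:
        if self.d % self.n_heads != 0:
            raise ValueError("d must be divisible by n_heads")

    @property
    def head_dim(self) -> int:
        return self.d // self.n_heads

    @property
    def ffn_dim(self) -> int:
        return 4 * self.d


VIT16B = EncoderConfig(d=768, n_layers=12, n_heads=12, patch_dim=768, n_tokens=197, n_classes=16)
"""The full-scale preset: 224x224 / 16-pixel patches / 768-d / 12x12."""


class EncoderParams:
    """Flat dict of numpy parameter arrays plus the positional table."""

    def __init__(self, cfg: EncoderConfig, seed: int | None = 0, scale: float | None = None):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        d, pd_, C = cfg.d, cfg.patch_dim, cfg.n_classes
        s_embed = scale if scale is not None else 1.0 / np.sqrt(pd_)
        s_attn = scale if scale is not None else 1.0 / np.sqrt(d)
        p: dict[str, np.ndarray] = {
            "embed_W": rng.normal(0, s_embed, (pd_, d)),
            "embed_b": np.zeros(d),
            "cls": rng.normal(0, 0.02, d),
            "head_W": rng.normal(0, s_attn, (d, C)),
            "head_b": np.zeros(C),
        }
        for l in range(cfg.n_layers):
            p[f"ln1_g_{l}"] = np.ones(d)
            p[f"ln1_b_{l}"] = np.zeros(d)
            p[f"Wq_{l}"] = rng.normal(0, s_attn, (d, d))
            p[f"Wk_{l}"] = rng.normal(0, s_attn, (d, d))
            p[f"Wv_{l}"] = rng.normal(0, s_attn, (d, d))
            p[f"Wo_{l}"] = rng.normal(0, s_attn, (d, d))
            p[f"ln2_g_{l}"] = np.ones(d)
            p[f"ln2_b_{l}"] = np.zeros(d)
            p[f"W1_{l}"] = rng.normal(0, s_attn, (d, cfg.ffn_dim))
            p[f"b1_{l}"] = np.zeros(cfg.ffn_dim)
            p[f"W2_{l}"] = rng.normal(0, 1.0 / np.sqrt(cfg.ffn_dim), (cfg.ffn_dim, d))
            p[f"b2_{l}"] = np.zeros(d)
        if cfg.learnable_positions:
            p["pos"] = rng.normal(0, 0.02, (cfg.n_tokens, d))
        self.params = p
        self._fixed_pos = sinusoidal_positions(cfg.n_tokens, d)

    @property
    def positions(self) -> np.ndarray:
        return self.params.get("pos", self._fixed_pos)

    def zeros_like(self) -> dict[str, np.ndarray]:
        return {k: np.zeros_like(v) for k, v in self.params.items()}

    def save(self, path) -> None:
        np.savez(path, **self.params)

    @classmethod
    def load(cls, path, cfg: EncoderConfig) -> "EncoderParams":
        out = cls(cfg, seed=0)
        with np.load(path) as data:
            out.params = {k: data[k] for k in data.files}
        return out


# ---------------------------------------------------------------------------
# Forward pieces
# ---------------------------------------------------------------------------


def _gelu(x):
    return 0.5 * x * (1.0 + erf(x / np.sqrt(2.0)))


def _gelu_grad(x):
    return 0.5 * (1.0 + erf(x / np.sqrt(2.0))) + x * np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)


def build_sequence(patches: np.ndarray, params: EncoderParams) -> np.ndarray:
    """Embed patches, prepend the class token, add positional terms.

    ``patches``: (n_patches, patch_dim) or a batch
    (B, n_patches, patch_dim).  Returns (n_patches + 1, d) or the
    batched equivalent, class token at row 0.  Positional embeddings
    are added to patch tokens (rows 1..N).
    """
    cfg = params.cfg
    x = np.asarray(patches, dtype=np.float64)
    squeeze = x.ndim == 2
    if squeeze:
        x = x[None]
    if x.shape[2] != cfg.patch_dim:
        raise ValueError(f"patch dim {x.shape[2]} != configured {cfg.patch_dim}")
    if x.shape[1] + 1 != cfg.n_tokens:
        raise ValueError(f"{x.shape[1]} patches incompatible with {cfg.n_tokens} tokens")
    z = x @ params.params["embed_W"] + params.params["embed_b"]
    pos = params.positions
    seq = np.concatenate(
        [np.broadcast_to(params.params["cls"], (x.shape[0], 1, cfg.d)), z + pos[1:]], axis=1
    )
    return seq[0] if squeeze else seq


def apply_mask(seq: np.ndarray, mask: BinaryMask, mode: str = "drop") -> np.ndarray:
    """Apply a retention mask to a token sequence (single or batched).

    ``zero``: masked rows multiplied by 0, length preserved.
    ``drop``: masked rows removed, retained rows keep their order.
    The class token (position 0) must be retained.
    """
    seq = np.asarray(seq)
    n = seq.shape[-2]
    if mask.n_tokens != n:
        raise ValueError("mask length must equal sequence length")
    if mask.bits[0] != 1:
        raise ValueError("class token (position 0) must be retained")
    if mode == "zero":
        return seq * mask.bits[..., :, None]
    if mode == "drop":
        return seq[..., mask.retained_indices, :]
    raise ValueError(f"unknown mask mode {mode!r}")


def _layernorm_fwd(x, g, b, eps=1e-5):
    mu = x.mean(-1, keepdims=True)
    xc = x - mu
    var = (xc**2).mean(-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    return g * xhat + b, (xhat, inv, g)


def _layernorm_bwd(dy, cache):
    xhat, inv, g = cache
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    dx = inv * (
        dxhat
        - dxhat.mean(-1, keepdims=True)
        - xhat * (dxhat * xhat).mean(-1, keepdims=True)
    )
    return dx, dg, db


def _split_heads(x, n_heads):
    b, k, d = x.shape
    return x.reshape(b, k, n_heads, d // n_heads).transpose(0, 2, 1, 3)


def _merge_heads(x):
    b, h, k, dh = x.shape
    return x.transpose(0, 2, 1, 3).reshape(b, k, h * dh)


def encoder_forward(
    seq: np.ndarray,
    params: EncoderParams,
    return_cache: bool = False,
    op_counter: list | None = None,
):
    """Run the pre-norm encoder stack; shape preserved.

    ``op_counter``, if given, accumulates one entry per (layer, head)
    with the number of pairwise attention scores computed (``K^2``).
    Every attention row is an exact softmax and sums to 1.
    """
    cfg = params.cfg
    x = np.asarray(seq, dtype=np.float64)
    squeeze = x.ndim == 2
    if squeeze:
        x = x[None]
    if x.shape[2] != cfg.d:
        raise ValueError("sequence width must equal encoder d")
    p = params.params
    caches = []
    for l in range(cfg.n_layers):
        # MHSA sublayer
        xn, ln1_cache = _layernorm_fwd(x, p[f"ln1_g_{l}"], p[f"ln1_b_{l}"])
        q = _split_heads(xn @ p[f"Wq_{l}"], cfg.n_heads)
        k = _split_heads(xn @ p[f"Wk_{l}"], cfg.n_heads)
        v = _split_heads(xn @ p[f"Wv_{l}"], cfg.n_heads)
        scores = q @ k.transpose(0, 1, 3, 2) / np.sqrt(cfg.head_dim)
        scores -= scores.max(-1, keepdims=True)
        attn = np.exp(scores)
        attn /= attn.sum(-1, keepdims=True)
        if op_counter is not None:
            kk = x.shape[1]
            for h in range(cfg.n_heads):
                op_counter.append((l, h, kk * kk))
        heads = attn @ v
        mhsa = _merge_heads(heads) @ p[f"Wo_{l}"]
        x1 = x + mhsa
        # FFN sublayer
        x1n, ln2_cache = _layernorm_fwd(x1, p[f"ln2_g_{l}"], p[f"ln2_b_{l}"])
        h1 = x1n @ p[f"W1_{l}"] + p[f"b1_{l}"]
        a1 = _gelu(h1)
        ffn = a1 @ p[f"W2_{l}"] + p[f"b2_{l}"]
        x2 = x1 + ffn
        caches.append((xn, ln1_cache, q, k, v, attn, heads, x1, x1n, ln2_cache, h1, a1))
        x = x2
    out = x[0] if squeeze else x
    if return_cache:
        return out, caches
    return out


def classify(seq: np.ndarray, params: EncoderParams) -> np.ndarray:
    """Softmax class probabilities from the class-token row."""
    seq = np.asarray(seq)
    cls = seq[..., 0, :]
    logits = cls @ params.params["head_W"] + params.params["head_b"]
    logits = logits - logits.max(-1, keepdims=True)
    p = np.exp(logits)
    return p / p.sum(-1, keepdims=True)


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean categorical cross-entropy, natural log."""
    probs = np.atleast_2d(probs)
    labels = np.atleast_1d(labels)
    eps = 1e-12
    return float(-np.log(probs[np.arange(len(labels)), labels] + eps).mean())


# ---------------------------------------------------------------------------
# Trainable classifier
# ---------------------------------------------------------------------------


class TinyViTClassifier:
    """A trainable (numpy) vision-transformer classifier.

    Wraps :class:`EncoderParams` with a full manual backward pass so
    that desk-scale configurations can be gradient-trained, and with a
    cheap head-only update for federated fine-tuning.  Gradients are
    exact (verified against finite differences in the test suite).
    """

    def __init__(self, cfg: EncoderConfig, seed: int = 0):
        self.cfg = cfg
        self.params = EncoderParams(cfg, seed=seed)

    # -- forward -----------------------------------------------------------

    def forward(self, patches: np.ndarray, mask: BinaryMask | None = None, mode: str = "drop"):
        """patches (B, n_patches, patch_dim) -> class probabilities (B, C)."""
        seq = build_sequence(patches, self.params)
        if mask is not None:
            seq = apply_mask(seq, mask, mode)
        out = encoder_forward(seq, self.params)
        return classify(out, self.params)

    def loss(self, patches, labels, mask=None, mode="drop") -> float:
        return cross_entropy(self.forward(patches, mask, mode), labels)

    def accuracy(self, patches, labels, mask=None, mode="drop") -> float:
        pred = self.forward(patches, mask, mode).argmax(-1)
        return float((pred == np.asarray(labels)).mean())

    # -- backward ----------------------------------------------------------

    def loss_and_grads(self, patches, labels, mask: BinaryMask | None = None):
        """Mean cross-entropy and exact gradients for every parameter.

        Mask application uses drop mode; gradients for dropped rows are
        scattered back to zero contributions.
        """
        cfg = self.cfg
        p = self.params.params
        patches = np.asarray(patches, dtype=np.float64)
        labels = np.asarray(labels, dtype=np.int64)
        B = patches.shape[0]

        seq_full = build_sequence(patches, self.params)
        retained = np.arange(cfg.n_tokens) if mask is None else mask.retained_indices
        seq = seq_full[:, retained, :]
        out, caches = encoder_forward(seq, self.params, return_cache=True)

        cls = out[:, 0, :]
        logits = cls @ p["head_W"] + p["head_b"]
        logits -= logits.max(-1, keepdims=True)
        probs = np.exp(logits)
        probs /= probs.sum(-1, keepdims=True)
        loss = cross_entropy(probs, labels)

        grads = {k: np.zeros_like(v) for k, v in p.items()}
        dlogits = probs.copy()
        dlogits[np.arange(B), labels] -= 1.0
        dlogits /= B
        grads["head_W"] = cls.T @ dlogits
        grads["head_b"] = dlogits.sum(0)
        dout = np.zeros_like(out)
        dout[:, 0, :] = dlogits @ p["head_W"].T

        dx = dout
        for l in reversed(range(cfg.n_layers)):
            xn, ln1_cache, q, k, v, attn, heads, x1, x1n, ln2_cache, h1, a1 = caches[l]
            # FFN sublayer backward (x2 = x1 + ffn(ln2(x1)))
            dffn = dx
            da1 = dffn @ p[f"W2_{l}"].T
            grads[f"W2_{l}"] += np.einsum("bkh,bkd->hd", a1, dffn)
            grads[f"b2_{l}"] += dffn.sum((0, 1))
            dh1 = da1 * _gelu_grad(h1)
            grads[f"W1_{l}"] += np.einsum("bkd,bkh->dh", x1n, dh1)
            grads[f"b1_{l}"] += dh1.sum((0, 1))
            dx1n = dh1 @ p[f"W1_{l}"].T
            dx1_ln, dg2, db2 = _layernorm_bwd(dx1n, ln2_cache)
            grads[f"ln2_g_{l}"] += dg2
            grads[f"ln2_b_{l}"] += db2
            dx1 = dx + dx1_ln
            # MHSA sublayer backward (x1 = x + mhsa(ln1(x)))
            dmhsa = dx1
            dmerge = dmhsa @ p[f"Wo_{l}"].T
            grads[f"Wo_{l}"] += np.einsum("bkd,bke->de", _merge_heads(heads), dmhsa)
            dheads = _split_heads(dmerge, cfg.n_heads)
            dattn = dheads @ v.transpose(0, 1, 3, 2)
            dv = attn.transpose(0, 1, 3, 2) @ dheads
            dscores = attn * (dattn - (dattn * attn).sum(-1, keepdims=True))
            dscores /= np.sqrt(cfg.head_dim)
            dq = dscores @ k
            dk = dscores.transpose(0, 1, 3, 2) @ q
            dxn = (
                _merge_heads(dq) @ p[f"Wq_{l}"].T
                + _merge_heads(dk) @ p[f"Wk_{l}"].T
                + _merge_heads(dv) @ p[f"Wv_{l}"].T
            )
            grads[f"Wq_{l}"] += np.einsum("bkd,bke->de", xn, _merge_heads(dq))
            grads[f"Wk_{l}"] += np.einsum("bkd,bke->de", xn, _merge_heads(dk))
            grads[f"Wv_{l}"] += np.einsum("bkd,bke->de", xn, _merge_heads(dv))
            dx_ln, dg1, db1 = _layernorm_bwd(dxn, ln1_cache)
            grads[f"ln1_g_{l}"] += dg1
            grads[f"ln1_b_{l}"] += db1
            dx = dx1 + dx_ln

        # scatter back through masking, then through the embedding
        dseq_full = np.zeros_like(seq_full)
        dseq_full[:, retained, :] = dx
        grads["cls"] += dseq_full[:, 0, :].sum(0)
        dz = dseq_full[:, 1:, :]
        grads["embed_W"] += np.einsum("bnp,bnd->pd", patches, dz)
        grads["embed_b"] += dz.sum((0, 1))
        if "pos" in p:
            grads["pos"][1:] += dz.sum(0)
        return loss, grads

    # -- training ----------------------------------------------------------

    def train(
        self,
        patches,
        labels,
        steps: int = 200,
        batch_size: int = 16,
        lr: float = 1e-2,
        momentum: float = 0.9,
        mask: BinaryMask | None = None,
        head_only: bool = False,
        seed: int = 0,
    ) -> list[float]:
        """SGD with momentum; returns the per-step loss curve.

        With ``head_only`` only the classification head is updated (the
        federated fine-tuning regime); otherwise all parameters train.
        """
        rng = np.random.default_rng(seed)
        patches = np.asarray(patches, dtype=np.float64)
        labels = np.asarray(labels, dtype=np.int64)
        n = patches.shape[0]
        vel = {k: np.zeros_like(v) for k, v in self.params.params.items()}
        losses = []
        trained = {"head_W", "head_b"} if head_only else set(self.params.params)
        for _ in range(steps):
            idx = rng.choice(n, size=min(batch_size, n), replace=False)
            loss, grads = self.loss_and_grads(patches[idx], labels[idx], mask)
            for key in trained:
                vel[key] = momentum * vel[key] - lr * grads[key]
                self.params.params[key] += vel[key]
            losses.append(loss)
        return losses

    def get_param_vector(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.params.items()}

    def set_param_vector(self, params: dict[str, np.ndarray]) -> None:
        for k, v in params.items():
            self.params.params[k] = v.copy()
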