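"""Frozen feature-extractor contract and the bundled tiny vision transformer.

The package attacks *frozen* encoders: models whose weights never change and
whose only role is to map an image to a feature vector (the CLS token) plus
per-tile patch tokens.  Real pathology foundation models are ViTs with
hundreds of millions of parameters; the bundled :class:`TinyViT` is a
structurally faithful, randomly initialised stand-in small enough for CPU
work — patch embedding, learned CLS token and positional embeddings, and
transformer blocks with multi-head self-attention, an MLP, LayerNorm and
residual connections.

The forward *and* backward passes are written directly in numpy.  Owning the
backward pass is what makes the "pay no attention" (PNA) regularisation
expressible as an exact contract: with ``bypass_attention_grad`` set, the
post-softmax attention weights are treated as constants during
differentiation — no gradient flows into the query/key path — while the
value path and every other layer differentiate normally.  Forward outputs
are bit-identical with the flag on or off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erf

__all__ = [
    "EncoderSpec",
    "FeatureBundle",
    "preprocess",
    "TinyViT",
    "build_tiny_vit",
    "extract_features",
    "register_encoder",
    "get_encoder",
    "ENCODER_REGISTRY",
]

_SQRT2 = np.float32(np.sqrt(2.0))
_LN_EPS = np.float32(1e-6)


class EncoderError(RuntimeError):
    """Raised on shape mismatches or non-finite activations inside an encoder."""


@dataclass(frozen=True)
class EncoderSpec:
    """Static contract of a frozen encoder.

    ``mean`` and ``scale`` define the preprocess 𝒯 applied after division by
    255: ``t = (x/255 - mean) / scale`` channel-wise.
    """

    name: str
    patch_size: int = 14
    input_size: int = 224
    feature_dim: int = 192
    mean: tuple[float, float, float] = (0.5, 0.5, 0.5)
    scale: tuple[float, float, float] = (0.5, 0.5, 0.5)
    deterministic: bool = True

    def __post_init__(self) -> None:
        if self.input_size % self.patch_size != 0:
            raise ValueError(
                f"input_size {self.input_size} not divisible by patch_size {self.patch_size}"
            )
        if any(s == 0 for s in self.scale):
            raise ValueError("preprocess scale must be non-zero in every channel")

    @property
    def grid_side(self) -> int:
        return self.input_size // self.patch_size

    @property
    def n_patch_tokens(self) -> int:
        return self.grid_side**2


@dataclass
class FeatureBundle:
    """CLS vector plus the patch-token matrix for one image."""

    cls: np.ndarray          # (feature_dim,)
    patch_tokens: np.ndarray  # (n_patch_tokens, token_dim)

    def __post_init__(self) -> None:
        if not (np.isfinite(self.cls).all() and np.isfinite(self.patch_tokens).all()):
            raise EncoderError("non-finite entries in feature bundle")


def preprocess(images: np.ndarray, spec: EncoderSpec) -> np.ndarray:
    """Apply the encoder's preprocess 𝒯 to a batch of 8-bit-scale images.

    Parameters
    ----------
    images
        ``(B, H, W, 3)`` (or ``(H, W, 3)``) array with values in [0, 255].

    Returns
    -------
    float32 array of the same shape: ``((images/255) - mean) / scale``.
    """
    x = np.asarray(images, dtype=np.float32) / np.float32(255.0)
    return normalize01(x, spec)


def normalize01(x01: np.ndarray, spec: EncoderSpec) -> np.ndarray:
    """Normalize images already on the [0, 1] intensity scale."""
    mean = np.asarray(spec.mean, dtype=np.float32)
    scale = np.asarray(spec.scale, dtype=np.float32)
    return (np.asarray(x01, dtype=np.float32) - mean) / scale


def _gelu(x: np.ndarray) -> np.ndarray:
    # exact (erf) form; dtype-preserving
    return 0.5 * x * (1.0 + erf(x / _SQRT2))


def _gelu_grad(x: np.ndarray) -> np.ndarray:
    phi = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
    cdf = 0.5 * (1.0 + erf(x / _SQRT2))
    return cdf + x * phi


def _layernorm_forward(x, gamma, beta):
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = xc * inv
    return xhat * gamma + beta, (xhat, inv)


def _layernorm_backward(dy, cache, gamma):
    xhat, inv = cache
    dxhat = dy * gamma
    m1 = dxhat.mean(axis=-1, keepdims=True)
    m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
    return (dxhat - m1 - xhat * m2) * inv


class TinyViT:
    """A small frozen vision transformer with an explicit numpy backward pass.

    Weights are drawn once from a seeded generator and never updated; the
    instance is a pure function of (weights, input).  ``forward`` returns CLS
    and patch tokens; ``backward`` propagates a cotangent of those outputs to
    the normalized input pixels, optionally with the PNA attention-gradient
    bypass.
    """

    def __init__(
        self,
        spec: EncoderSpec,
        seed: int,
        depth: int = 2,
        n_heads: int = 3,
        mlp_ratio: int = 4,
        dtype=np.float32,
    ) -> None:
        if spec.feature_dim % n_heads != 0:
            raise ValueError("feature_dim must be divisible by n_heads")
        self.spec = spec
        self.depth = depth
        self.n_heads = n_heads
        self.head_dim = spec.feature_dim // n_heads
        self.seed = seed
        self.dtype = np.dtype(dtype)
        d = spec.feature_dim
        hidden = mlp_ratio * d
        p = spec.patch_size
        rng = np.random.default_rng(seed)

        def w(*shape, std=0.02):
            return rng.normal(0.0, std, size=shape).astype(dtype)

        self.w_embed = w(p * p * 3, d)
        self.b_embed = np.zeros(d, dtype=dtype)
        self.cls_token = w(d)
        self.pos_emb = w(spec.n_patch_tokens + 1, d)
        self.blocks = []
        for _ in range(depth):
            self.blocks.append(
                {
                    "ln1_g": np.ones(d, dtype), "ln1_b": np.zeros(d, dtype),
                    "w_qkv": w(d, 3 * d), "b_qkv": np.zeros(3 * d, dtype),
                    "w_proj": w(d, d), "b_proj": np.zeros(d, dtype),
                    "ln2_g": np.ones(d, dtype), "ln2_b": np.zeros(d, dtype),
                    "w_fc1": w(d, hidden), "b_fc1": np.zeros(hidden, dtype),
                    "w_fc2": w(hidden, d), "b_fc2": np.zeros(d, dtype),
                }
            )
        self.lnf_g = np.ones(d, dtype)
        self.lnf_b = np.zeros(d, dtype)

    # ---- patchify -------------------------------------------------------

    def _patchify(self, x: np.ndarray) -> np.ndarray:
        b = x.shape[0]
        g, p = self.spec.grid_side, self.spec.patch_size
        x = x.reshape(b, g, p, g, p, 3)
        x = x.transpose(0, 1, 3, 2, 4, 5)  # (B, g, g, p, p, 3), row-major tiles
        return x.reshape(b, g * g, p * p * 3)

    def _unpatchify(self, t: np.ndarray) -> np.ndarray:
        b = t.shape[0]
        g, p = self.spec.grid_side, self.spec.patch_size
        x = t.reshape(b, g, g, p, p, 3).transpose(0, 1, 3, 2, 4, 5)
        return x.reshape(b, g * p, g * p, 3)

    # ---- forward --------------------------------------------------------

    def forward(
        self, x_norm: np.ndarray, want_cache: bool = False
    ) -> tuple[np.ndarray, np.ndarray, dict | None]:
        """Run the frozen forward pass on a normalized batch.

        Returns ``(cls, patch_tokens, cache)`` with shapes ``(B, D)`` and
        ``(B, T, D)``; ``cache`` is ``None`` unless ``want_cache``.
        """
        s = self.spec
        x_norm = np.ascontiguousarray(x_norm, dtype=self.dtype)
        if x_norm.ndim == 3:
            x_norm = x_norm[None]
        if x_norm.shape[1:] != (s.input_size, s.input_size, 3):
            raise EncoderError(
                f"expected batch of {s.input_size}x{s.input_size}x3, got {x_norm.shape}"
            )
        b = x_norm.shape[0]
        patches = self._patchify(x_norm)
        tok = patches @ self.w_embed + self.b_embed
        x = np.concatenate(
            [np.broadcast_to(self.cls_token, (b, 1, s.feature_dim)), tok[:, :, :]], axis=1
        ) + self.pos_emb
        cache: dict | None = {"blocks": []} if want_cache else None
        h, hd = self.n_heads, self.head_dim
        t1 = x.shape[1]
        inv_sqrt = self.dtype.type(1.0 / np.sqrt(hd))
        for blk in self.blocks:
            x_ln, ln1c = _layernorm_forward(x, blk["ln1_g"], blk["ln1_b"])
            qkv = x_ln @ blk["w_qkv"] + blk["b_qkv"]
            qkv = qkv.reshape(b, t1, 3, h, hd).transpose(2, 0, 3, 1, 4)  # (3,B,h,T,hd)
            q, k, v = qkv[0], qkv[1], qkv[2]
            scores = (q @ k.transpose(0, 1, 3, 2)) * inv_sqrt
            scores -= scores.max(axis=-1, keepdims=True)
            attn = np.exp(scores)
            attn /= attn.sum(axis=-1, keepdims=True)
            out_h = attn @ v  # (B,h,T,hd)
            out = out_h.transpose(0, 2, 1, 3).reshape(b, t1, h * hd)
            attn_out = out @ blk["w_proj"] + blk["b_proj"]
            x2 = x + attn_out
            x2_ln, ln2c = _layernorm_forward(x2, blk["ln2_g"], blk["ln2_b"])
            pre = x2_ln @ blk["w_fc1"] + blk["b_fc1"]
            act = _gelu(pre)
            mlp_out = act @ blk["w_fc2"] + blk["b_fc2"]
            x_next = x2 + mlp_out
            if want_cache:
                cache["blocks"].append(
                    {"ln1c": ln1c, "q": q, "k": k, "v": v, "attn": attn,
                     "x_ln": x_ln, "out": out, "ln2c": ln2c, "x2_ln": x2_ln, "pre": pre}
                )
            x = x_next
        y, lnfc = _layernorm_forward(x, self.lnf_g, self.lnf_b)
        if not np.isfinite(y).all():
            raise EncoderError("non-finite activations in encoder forward pass")
        if want_cache:
            cache["lnfc"] = lnfc
            cache["batch"] = b
        return y[:, 0, :], y[:, 1:, :], cache

    # ---- backward -------------------------------------------------------

    def backward(
        self,
        cache: dict,
        d_cls: np.ndarray,
        d_patch_tokens: np.ndarray | None = None,
        bypass_attention_grad: bool = False,
    ) -> np.ndarray:
        """Propagate output cotangents to the normalized input pixels.

        With ``bypass_attention_grad`` the post-softmax attention weights are
        held constant (PNA): the query/key branch receives zero gradient while
        the value branch differentiates normally.
        """
        s = self.spec
        b = cache["batch"]
        t1 = s.n_patch_tokens + 1
        d = s.feature_dim
        dy = np.zeros((b, t1, d), dtype=self.dtype)
        dy[:, 0, :] = d_cls
        if d_patch_tokens is not None:
            dy[:, 1:, :] = d_patch_tokens
        dx = _layernorm_backward(dy, cache["lnfc"], self.lnf_g)
        h, hd = self.n_heads, self.head_dim
        inv_sqrt = self.dtype.type(1.0 / np.sqrt(hd))
        for blk, c in zip(reversed(self.blocks), reversed(cache["blocks"])):
            # MLP branch
            d_mlp_out = dx
            d_act = d_mlp_out @ blk["w_fc2"].T
            d_pre = d_act * _gelu_grad(c["pre"])
            d_x2_ln = d_pre @ blk["w_fc1"].T
            d_x2 = dx + _layernorm_backward(d_x2_ln, c["ln2c"], blk["ln2_g"])
            # attention branch
            d_attn_out = d_x2
            d_out = d_attn_out @ blk["w_proj"].T
            d_out_h = d_out.reshape(b, t1, h, hd).transpose(0, 2, 1, 3)
            attn, v = c["attn"], c["v"]
            d_v = attn.transpose(0, 1, 3, 2) @ d_out_h
            if bypass_attention_grad:
                d_q = d_k = None
            else:
                d_attn = d_out_h @ v.transpose(0, 1, 3, 2)
                d_scores = attn * (d_attn - (d_attn * attn).sum(axis=-1, keepdims=True))
                d_q = (d_scores @ c["k"]) * inv_sqrt
                d_k = (d_scores.transpose(0, 1, 3, 2) @ c["q"]) * inv_sqrt
            d_qkv = np.zeros((3, b, h, t1, hd), dtype=self.dtype)
            d_qkv[2] = d_v
            if d_q is not None:
                d_qkv[0] = d_q
                d_qkv[1] = d_k
            d_qkv = d_qkv.transpose(1, 3, 0, 2, 4).reshape(b, t1, 3 * h * hd)
            d_x_ln = d_qkv @ blk["w_qkv"].T
            dx = d_x2 + _layernorm_backward(d_x_ln, c["ln1c"], blk["ln1_g"])
        d_tok = dx[:, 1:, :]
        d_patches = d_tok @ self.w_embed.T
        return self._unpatchify(d_patches)

    # ---- convenience ----------------------------------------------------

    def encode(self, images: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Preprocess 8-bit-scale images and return ``(cls, patch_tokens)``."""
        cls, tokens, _ = self.forward(preprocess(images, self.spec))
        return cls, tokens


def build_tiny_vit(
    seed: int,
    *,
    name: str | None = None,
    input_size: int = 224,
    patch_size: int = 14,
    feature_dim: int = 192,
    depth: int = 2,
    n_heads: int = 3,
    mlp_ratio: int = 4,
    dtype=np.float32,
) -> TinyViT:
    """Build the bundled frozen tiny ViT with seed-deterministic weights."""
    spec = EncoderSpec(
        name=name or f"tiny-vit-s{seed}",
        patch_size=patch_size,
        input_size=input_size,
        feature_dim=feature_dim,
    )
    return TinyViT(spec, seed=seed, depth=depth, n_heads=n_heads, mlp_ratio=mlp_ratio, dtype=dtype)


def extract_features(
    normalized: np.ndarray,
    encoder: TinyViT,
    bypass_attention_grad: bool = False,
) -> list[FeatureBundle]:
    """Extract per-image feature bundles from a normalized batch.

    The bypass flag is accepted for interface symmetry with the attack loop;
    it affects only derivatives, never the returned values.
    """
    del bypass_attention_grad  # forward values are identical either way
    cls, tokens, _ = encoder.forward(normalized)
    return [FeatureBundle(cls=c, patch_tokens=t) for c, t in zip(cls, tokens)]


# ---- registry -----------------------------------------------------------

ENCODER_REGISTRY: dict[str, TinyViT] = {}


def register_encoder(encoder) -> None:
    """Register a frozen encoder (anything exposing .spec/.forward/.backward)."""
    ENCODER_REGISTRY[encoder.spec.name] = encoder


def get_encoder(name: str):
    try:
        return ENCODER_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"no encoder named {name!r}; registered: {sorted(ENCODER_REGISTRY)}"
        ) from None
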