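"""Adversarial perturbation training: UTAP, PSAP, CSAP and the FGSM baseline.

UTAP (universal and transferable adversarial perturbation) optimizes a single
fixed noise pattern ``p``, bounded in L∞ by ε (in 8-bit units), that corrupts
a frozen encoder's feature representation of *any* input image.  The training
loop is projected gradient descent with a signed step: at every step a fresh
random tile mask restricts the update to ≈51% of the 14×14 tiles, the
attacked branch is differentiated with the attention-gradient bypass (PNA),
and the objective is the batch-mean cosine similarity between clean and
attacked CLS features, driven as low as possible.

PSAP and CSAP are the specific counterparts: per-image and per-class
perturbations optimized by *maximizing* the cross-entropy of a frozen linear
probe.  FGSM is the classic one-step signed-gradient baseline.

Conventions: perturbations live on the normalized [0, 1] intensity scale
(ε is converted as ε/255); during training attacked intensities are left
continuous, and 8-bit rounding/clipping happens only when a perturbation is
applied for evaluation (:func:`apply_perturbation`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import ImagePatchSet
from .encoder import normalize01

__all__ = [
    "Perturbation",
    "TileMask",
    "AttackConfig",
    "LossTrace",
    "compute_step_size",
    "random_tile_mask",
    "cosine_similarity",
    "cross_entropy_onehot",
    "apply_perturbation",
    "utap_train",
    "psap_train",
    "csap_train",
    "fgsm",
]


@dataclass
class Perturbation:
    """Trainable noise pattern in normalized intensity units with an L∞ bound."""

    values: np.ndarray          # (H, W, 3) float32, |values| <= epsilon_8bit/255
    epsilon_8bit: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3 or self.values.shape[-1] != 3:
            raise ValueError(f"perturbation must be (H, W, 3), got {self.values.shape}")

    @property
    def bound(self) -> float:
        """The L∞ bound on the normalized scale, ε/255."""
        return float(self.epsilon_8bit) / 255.0

    def check_bound(self, atol: float = 1e-7) -> bool:
        return float(np.abs(self.values).max(initial=0.0)) <= self.bound + atol


@dataclass
class TileMask:
    """Binary tile-aligned mask: a grid of tile indicators expanded to pixels."""

    grid: np.ndarray       # (G, G) uint8 in {0, 1}
    tile_size: int = 14

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.uint8)
        if self.grid.ndim != 2 or self.grid.shape[0] != self.grid.shape[1]:
            raise ValueError("tile grid must be square")

    @property
    def n_tiles_on(self) -> int:
        return int(self.grid.sum())

    @property
    def pixels(self) -> np.ndarray:
        """(H, W) binary expansion; each grid cell becomes a tile_size² block."""
        return np.kron(self.grid, np.ones((self.tile_size, self.tile_size), np.uint8))


def random_tile_mask(
    n_mask: int, rng: np.random.Generator, grid_side: int = 16, tile_size: int = 14
) -> TileMask:
    """Draw ``n_mask`` distinct tiles uniformly without replacement."""
    n_tiles = grid_side * grid_side
    if not 0 <= n_mask <= n_tiles:
        raise ValueError(f"n_mask must be in [0, {n_tiles}], got {n_mask}")
    grid = np.zeros(n_tiles, dtype=np.uint8)
    grid[rng.choice(n_tiles, size=n_mask, replace=False)] = 1
    return TileMask(grid=grid.reshape(grid_side, grid_side), tile_size=tile_size)


def compute_step_size(
    epsilon_8bit: float, theta: float, batch: int, epochs: int, n_train: int
) -> float:
    """PGD step size α = ε·θ·B / (255·L·N) in normalized units per step."""
    if epochs <= 0 or n_train <= 0:
        raise ValueError("epochs and n_train must be positive")
    if epsilon_8bit < 0 or theta < 0 or batch <= 0:
        raise ValueError("epsilon, theta must be >= 0 and batch > 0")
    return float(epsilon_8bit) * theta * batch / (255.0 * epochs * n_train)


def cosine_similarity(f1: np.ndarray, f2: np.ndarray) -> float:
    """CosSim(f1, f2) = f1·f2 / (‖f1‖‖f2‖); undefined for zero vectors."""
    f1 = np.asarray(f1, dtype=np.float64).ravel()
    f2 = np.asarray(f2, dtype=np.float64).ravel()
    n1, n2 = np.linalg.norm(f1), np.linalg.norm(f2)
    if n1 == 0.0 or n2 == 0.0:
        raise ValueError("cosine similarity undefined for zero-norm vectors")
    return float(f1 @ f2 / (n1 * n2))


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_onehot(gt: np.ndarray, logits: np.ndarray) -> float:
    """CE(gt, logits) = −∑ᵢ gtᵢ·log Softmax(logits)ᵢ, in the stable log-sum-exp form."""
    gt = np.asarray(gt, dtype=np.float64)
    logits = np.asarray(logits, dtype=np.float64)
    if gt.shape != logits.shape:
        raise ValueError("gt and logits must have the same shape")
    onehot = np.isclose(gt.sum(), 1.0) and np.all((gt == 0) | (gt == 1))
    if not onehot:
        raise ValueError("gt must be a one-hot vector")
    if not np.isfinite(logits).all():
        raise ValueError("logits must be finite")
    z = logits - logits.max()
    lse = np.log(np.exp(z).sum())
    return float(lse - z[np.argmax(gt)])


def apply_perturbation(images, p: Perturbation, mask: TileMask | None = None):
    """Apply ``p`` (optionally tile-masked) to 8-bit images for evaluation.

    attacked = round(clamp(I/255 + p⊙M, 0, 1)·255), round-half-to-even.
    Accepts an :class:`ImagePatchSet` or a uint8 array and returns the same
    kind.
    """
    patchset = images if isinstance(images, ImagePatchSet) else None
    arr = patchset.images if patchset is not None else np.asarray(images)
    single = arr.ndim == 3
    if single:
        arr = arr[None]
    if arr.shape[1:3] != p.values.shape[:2]:
        raise ValueError(f"image size {arr.shape[1:3]} does not match perturbation {p.values.shape[:2]}")
    delta = p.values if mask is None else p.values * mask.pixels[..., None]
    att01 = np.clip(arr.astype(np.float32) / 255.0 + delta, 0.0, 1.0)
    att = np.round(att01 * 255.0).astype(np.uint8)
    if single:
        att = att[0]
    if patchset is not None:
        return ImagePatchSet(
            images=att, labels=patchset.labels, class_names=list(patchset.class_names),
            ids=list(patchset.ids),
        )
    return att


@dataclass
class AttackConfig:
    """Hyperparameters of UTAP training (defaults are the study conditions)."""

    epsilon_8bit: float = 20.0   # ε: L∞ bound in 8-bit units
    theta: float = 10.0          # θ: step-size scaling factor
    epochs: int = 10             # L
    batch: int = 5               # B
    n_train: int = 900           # N
    n_mask: int = 130            # n_M tiles kept per step (≈51% of 256)
    seed: int = 0
    objective: str = "cosine"    # {"cosine", "cross_entropy"}
    update_rule: str = "sign"
    lpf_in_loop: object | None = None   # LPFConfig → LPF-resilient training
    pool: list[str] | None = None
    switch_interval: int = 8

    def __post_init__(self) -> None:
        if min(self.epochs, self.batch, self.n_train, self.switch_interval) <= 0:
            raise ValueError("all counts must be positive")
        if not 0 <= self.n_mask <= 256:
            raise ValueError("n_mask must be in [0, 256]")
        if self.batch > self.n_train:
            raise ValueError("batch must not exceed n_train")
        if self.objective not in ("cosine", "cross_entropy"):
            raise ValueError(f"unknown objective {self.objective!r}")
        if self.update_rule != "sign":
            raise ValueError("only the signed L-infinity update rule is supported")

    @property
    def total_steps(self) -> int:
        return self.epochs * (self.n_train // self.batch)


@dataclass
class LossTrace:
    """Per-step objective values, perturbation magnitude and active encoder."""

    objective: list[float] = field(default_factory=list)
    max_abs_p: list[float] = field(default_factory=list)
    encoder: list[str] = field(default_factory=list)

    def append(self, obj: float, max_p: float, enc: str) -> None:
        self.objective.append(obj)
        self.max_abs_p.append(max_p)
        self.encoder.append(enc)

    def __len__(self) -> int:
        return len(self.objective)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"step": np.arange(len(self)), "objective": self.objective,
             "max_abs_p": self.max_abs_p, "encoder": self.encoder}
        )


def _cosine_batch_and_grad(f_ori: np.ndarray, f_atk: np.ndarray):
    """Mean cosine similarity over a batch and its gradient w.r.t. f_atk."""
    u = f_ori.astype(np.float64)
    v = f_atk.astype(np.float64)
    nu = np.linalg.norm(u, axis=1, keepdims=True)
    nv = np.linalg.norm(v, axis=1, keepdims=True)
    cos = (u * v).sum(axis=1, keepdims=True) / (nu * nv)
    grad = (u / (nu * nv) - cos * v / (nv * nv)) / len(u)
    return float(cos.mean()), grad.astype(np.float32)


def _ce_batch_and_grad(labels: np.ndarray, cls: np.ndarray, probe):
    """Mean probe cross-entropy over a batch and its gradient w.r.t. CLS features."""
    w = np.asarray(probe.weights)   # (C, D)
    b = np.asarray(probe.bias)
    logits = cls @ w.T + b
    prob = _softmax(logits)
    n = len(labels)
    ce = float(-np.log(np.clip(prob[np.arange(n), labels], 1e-30, None)).mean())
    d_logits = prob.copy()
    d_logits[np.arange(n), labels] -= 1.0
    d_cls = (d_logits / n) @ w
    return ce, d_cls.astype(np.float32)


def _clean_cls_features(encoder, x01: np.ndarray, chunk: int = 32) -> np.ndarray:
    out = []
    for i in range(0, len(x01), chunk):
        cls, _, _ = encoder.forward(normalize01(x01[i : i + chunk], encoder.spec))
        out.append(cls)
    return np.concatenate(out, axis=0)


def utap_train(
    dataset: ImagePatchSet,
    encoders,
    config: AttackConfig,
    probe=None,
) -> tuple[Perturbation, LossTrace]:
    """Train a universal perturbation against one frozen encoder or a pool.

    Implements the adaptive-PGD loop: ``p`` starts at zero; each step draws a
    batch of B images and a fresh random tile mask, forms the attacked batch
    ``I/255 + p⊙M`` (through the low-pass filter if ``config.lpf_in_loop``
    is set), extracts clean and attacked CLS features, and takes a signed
    gradient step of size α = εθB/(255LN) on the masked pixels, clamping to
    ±ε/255.  The attacked branch is differentiated with the PNA bypass.

    With a pool of encoders the active one is re-drawn uniformly every
    ``switch_interval`` steps.  ``probe`` is required only for the
    cross-entropy objective ablation.
    """
    pool = encoders if isinstance(encoders, (list, tuple)) else [encoders]
    if len(dataset) < config.n_train:
        raise ValueError(f"dataset has {len(dataset)} images; n_train={config.n_train} required")
    if config.objective == "cross_entropy" and probe is None:
        raise ValueError("cross-entropy objective requires a pretrained probe")
    spec0 = pool[0].spec
    grid_side = spec0.grid_side
    if config.n_mask > grid_side**2:
        raise ValueError(f"n_mask {config.n_mask} exceeds {grid_side**2} tiles")

    rng = np.random.default_rng(config.seed)
    x01 = dataset.images[: config.n_train].astype(np.float32) / np.float32(255.0)
    labels = dataset.labels[: config.n_train]
    alpha = np.float32(
        compute_step_size(config.epsilon_8bit, config.theta, config.batch,
                          config.epochs, config.n_train)
    )
    bound = np.float32(config.epsilon_8bit / 255.0)

    lpf_k = None
    if config.lpf_in_loop is not None:
        from .defenses import lpf_project

        lpf_k = config.lpf_in_loop.kernel_size
        if lpf_k >= spec0.input_size:
            lpf_k = None  # full window is the exact identity; skip the FFT

    clean_cache: dict[str, np.ndarray] = {}

    def clean_features(enc):
        if enc.spec.name not in clean_cache:
            clean_cache[enc.spec.name] = _clean_cls_features(enc, x01)
        return clean_cache[enc.spec.name]

    p = np.zeros((spec0.input_size, spec0.input_size, 3), dtype=np.float32)
    trace = LossTrace()
    active = pool[0]
    step = 0
    scale = np.asarray(spec0.scale, dtype=np.float32)
    try:
        for _ in range(config.epochs):
            perm = rng.permutation(config.n_train)
            for start in range(0, config.n_train - config.batch + 1, config.batch):
                if len(pool) > 1 and step % config.switch_interval == 0:
                    active = pool[int(rng.integers(len(pool)))]
                    scale = np.asarray(active.spec.scale, dtype=np.float32)
                idx = perm[start : start + config.batch]
                mask = random_tile_mask(config.n_mask, rng, grid_side, active.spec.patch_size)
                mpx = mask.pixels.astype(np.float32)[..., None]
                x_atk = x01[idx] + p * mpx
                x_fwd = lpf_project(x_atk, lpf_k) if lpf_k is not None else x_atk
                cls, _, cache = active.forward(
                    normalize01(x_fwd, active.spec), want_cache=True
                )
                if config.objective == "cosine":
                    obj, d_cls = _cosine_batch_and_grad(clean_features(active)[idx], cls)
                else:
                    ce, d_cls = _ce_batch_and_grad(labels[idx], cls, probe)
                    obj, d_cls = -ce, -d_cls  # maximize CE == minimize −CE
                d_norm = active.backward(cache, d_cls, bypass_attention_grad=True)
                d_x01 = d_norm / scale
                if lpf_k is not None:
                    d_x01 = lpf_project(d_x01, lpf_k)  # ideal LPF is self-adjoint
                grad_p = (d_x01.sum(axis=0)) * mpx
                p = np.clip(p - alpha * np.sign(grad_p), -bound, bound)
                trace.append(obj, float(np.abs(p).max()), active.spec.name)
                step += 1
    except Exception as exc:
        if len(trace):
            err = RuntimeError(
                f"attack aborted after {len(trace)} steps; partial trace attached"
            )
            err.partial_trace = trace  # post-mortem inspection
            raise err from exc
        raise
    provenance = {
        "encoders": [e.spec.name for e in pool],
        "config": {k: (None if k == "lpf_in_loop" and config.lpf_in_loop is None
                       else getattr(config, k)) for k in
                   ("epsilon_8bit", "theta", "epochs", "batch", "n_train",
                    "n_mask", "seed", "objective", "switch_interval")},
        "lpf_in_loop": None if config.lpf_in_loop is None
        else int(config.lpf_in_loop.kernel_size),
    }
    return Perturbation(values=p, epsilon_8bit=config.epsilon_8bit, provenance=provenance), trace


def _probe_ce_grad_wrt_x01(encoder, probe, x01: np.ndarray, labels: np.ndarray):
    """Mean probe CE over a batch and its gradient w.r.t. [0,1] intensities."""
    cls, _, cache = encoder.forward(normalize01(x01, encoder.spec), want_cache=True)
    ce, d_cls = _ce_batch_and_grad(labels, cls, probe)
    d_norm = encoder.backward(cache, d_cls)
    return ce, d_norm / np.asarray(encoder.spec.scale, dtype=np.float32)


def psap_train(
    image: np.ndarray,
    label: int,
    encoder,
    probe,
    steps: int = 100,
    step_size: float = 0.01,
    bound: float = 20.0,
) -> Perturbation:
    """Patch-specific perturbation: signed gradient ascent on probe CE.

    ``image`` is one 8-bit patch; the returned perturbation is specific to
    it.  ``bound`` is the L∞ budget in 8-bit units.
    """
    x01 = np.asarray(image, dtype=np.float32)[None] / np.float32(255.0)
    lab = np.asarray([label])
    b = np.float32(bound / 255.0)
    p = np.zeros(x01.shape[1:], dtype=np.float32)
    for _ in range(steps):
        _, g = _probe_ce_grad_wrt_x01(encoder, probe, x01 + p, lab)
        p = np.clip(p + np.float32(step_size) * np.sign(g[0]), -b, b)
    return Perturbation(
        values=p, epsilon_8bit=bound,
        provenance={"attack": "psap", "encoder": encoder.spec.name,
                    "steps": steps, "step_size": step_size},
    )


def csap_train(
    class_images: np.ndarray,
    class_label: int,
    encoder,
    probe,
    steps: int = 100,
    step_size: float = 0.01,
    bound: float = 20.0,
    batch: int = 5,
    seed: int = 0,
) -> Perturbation:
    """Class-specific perturbation shared by all images of one class.

    Maximizes the mean probe cross-entropy over the class set by signed
    gradient ascent, iterating over seeded batch permutations; same update
    rule and bound as :func:`psap_train` (a class set of one image reduces
    to it exactly).
    """
    imgs = np.asarray(class_images)
    if imgs.ndim == 3:
        imgs = imgs[None]
    if len(imgs) == 0:
        raise ValueError("class set must contain at least one image")
    x01 = imgs.astype(np.float32) / np.float32(255.0)
    n = len(x01)
    bsz = min(batch, n)
    rng = np.random.default_rng(seed)
    labs = np.full(bsz, class_label)
    b = np.float32(bound / 255.0)
    p = np.zeros(x01.shape[1:], dtype=np.float32)
    order = rng.permutation(n)
    pos = 0
    for _ in range(steps):
        if pos + bsz > n:
            order = rng.permutation(n)
            pos = 0
        idx = order[pos : pos + bsz]
        pos += bsz
        _, g = _probe_ce_grad_wrt_x01(encoder, probe, x01[idx] + p, labs[: len(idx)])
        p = np.clip(p + np.float32(step_size) * np.sign(g.sum(axis=0)), -b, b)
    return Perturbation(
        values=p, epsilon_8bit=bound,
        provenance={"attack": "csap", "encoder": encoder.spec.name,
                    "class_label": int(class_label), "steps": steps, "seed": seed},
    )


def fgsm(image: np.ndarray, label: int, encoder, probe, magnitude: float) -> np.ndarray:
    """One-step signed-gradient attack; returns the attacked image on [0, 1].

    attacked = clamp(image/255 + magnitude·sign(∇ CE), 0, 1).
    """
    x01 = np.asarray(image, dtype=np.float32)[None] / np.float32(255.0)
    _, g = _probe_ce_grad_wrt_x01(encoder, probe, x01, np.asarray([label]))
    return np.clip(x01[0] + np.float32(magnitude) * np.sign(g[0]), 0.0, 1.0)
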