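"""Defenses: Fourier low-pass filtering, its adaptive bypass, and detection.

The low-pass filter (LPF) defense zeroes all spatial-frequency components of
an input image outside a central k×k window of the centered 2-D spectrum
before feature extraction.  Physically this is equivalent to imaging with a
reduced numerical aperture: for a field of H pixels at Δx µm/pixel and
wavelength λ, the retained half-bandwidth k/2 cycles per field corresponds
to NA = λ·(k/2)/(H·Δx) — so the defense trades adversarial robustness
against optical resolution.

An adaptive attacker bypasses the defense by placing the same filter inside
the attack's forward pass (:func:`lpf_resilient_utap`), forcing the
perturbation's useful energy into the retained band.

The detection network is a small strided-patch convolutional classifier
(clean = negative, attacked = positive) trained with binary cross-entropy;
two sizes are provided under explicit parameter budgets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .attacks import AttackConfig, utap_train
from .data import ImagePatchSet

__all__ = [
    "LPFConfig",
    "fourier_lpf",
    "lpf_project",
    "effective_na",
    "lpf_resilient_utap",
    "DetectorModel",
    "detector_train",
    "detector_eval",
]


@dataclass(frozen=True)
class LPFConfig:
    """Retained-frequency window size plus the physical pixel bookkeeping."""

    kernel_size: int                 # k, side of the retained central window
    pixel_size_um: float = 0.5       # Δx, physical pixel pitch
    wavelength_um: float = 0.55      # λ, assumed illumination wavelength
    window_shape: str = "square"

    def __post_init__(self) -> None:
        if self.kernel_size <= 0:
            raise ValueError("kernel_size must be positive")
        if self.pixel_size_um <= 0 or self.wavelength_um <= 0:
            raise ValueError("physical parameters must be positive")
        if self.window_shape != "square":
            raise ValueError("only the square window is implemented")


def _freq_window(n: int, k: int) -> np.ndarray:
    """1-D binary retained-frequency window in fftshifted order.

    The window covers shifted indices [c−⌊k/2⌋, c+⌈k/2⌉) with c = n//2 and
    is then symmetrized (a bin is kept only if its conjugate bin is kept) so
    that filtering a real image yields an exactly real, idempotent
    projection.
    """
    if k > n:
        raise ValueError(f"kernel_size {k} exceeds image size {n}")
    c = n // 2
    w = np.zeros(n, dtype=bool)
    w[c - k // 2 : c + (k + 1) // 2] = True
    idx = np.arange(n)
    conj = (2 * c - idx) % n
    return w & w[conj]


def lpf_project(x: np.ndarray, k: int) -> np.ndarray:
    """Ideal spectral projection (no clipping); linear, idempotent, self-adjoint.

    Operates on the two spatial axes of ``(..., H, W, C)`` arrays and
    returns a float array of the same shape.  Used inside attack training,
    where gradients must flow through the filter.
    """
    x = np.asarray(x)
    h, w = x.shape[-3], x.shape[-2]
    mask = np.outer(_freq_window(h, k), _freq_window(w, k))
    spec = np.fft.fftshift(np.fft.fft2(x, axes=(-3, -2)), axes=(-3, -2))
    spec *= mask[..., None]
    out = np.fft.ifft2(np.fft.ifftshift(spec, axes=(-3, -2)), axes=(-3, -2)).real
    return out.astype(np.result_type(x, np.float32))


def fourier_lpf(image: np.ndarray, cfg: LPFConfig) -> np.ndarray:
    """Low-pass-filter an 8-bit-scale image for the defense pipeline.

    Per channel: centered DFT, zero everything outside the central k×k
    window, invert, clip to [0, 255].  Returns a float image on the
    [0, 255] scale (feed directly to the encoder preprocess).
    """
    image = np.asarray(image, dtype=np.float64)
    out = lpf_project(image, cfg.kernel_size)
    return np.clip(out, 0.0, 255.0)


def effective_na(cfg: LPFConfig, field_pixels: int = 224) -> float:
    """Effective numerical aperture implied by the retained window.

    NA = λ·(k/2)/(H·Δx), reported to 3 significant figures.
    """
    na = cfg.wavelength_um * (cfg.kernel_size / 2.0) / (field_pixels * cfg.pixel_size_um)
    return float(f"{na:.3g}")


def lpf_resilient_utap(dataset, encoder, config: AttackConfig, probe=None):
    """UTAP training with the LPF inside the attacked branch's forward pass.

    ``config.lpf_in_loop`` must carry the :class:`LPFConfig` the defender is
    assumed to deploy; with k equal to the image size this reduces exactly
    to plain :func:`utap_train`.
    """
    if config.lpf_in_loop is None:
        raise ValueError("config.lpf_in_loop must be set for LPF-resilient training")
    return utap_train(dataset, encoder, config, probe=probe)


# ---- attack detection ----------------------------------------------------

_VARIANTS = {
    # widths of the strided-patch embedding and hidden layer
    "light": {"width": 128, "budget": 700_000},
    "large": {"width": 2048, "budget": 17_500_000},
}
_PATCH = 16


@dataclass
class DetectorModel:
    """Binary clean-vs-attacked classifier (strided 16×16 patch conv stack).

    Architecture: non-overlapping 16×16 patch embedding (equivalent to a
    stride-16 convolution) → ReLU → hidden linear → ReLU → global average
    pool → linear logit.  ``params`` maps names to float32 arrays.
    """

    variant: str
    params: dict = field(default_factory=dict)
    training_meta: dict = field(default_factory=dict)

    @property
    def parameter_count(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def _features(self, images: np.ndarray):
        x = images.astype(np.float32) / np.float32(255.0) - np.float32(0.5)
        b, h, w, c = x.shape
        g = h // _PATCH
        patches = (
            x.reshape(b, g, _PATCH, g, _PATCH, c)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(b, g * g, _PATCH * _PATCH * c)
        )
        p = self.params
        h1 = patches @ p["w1"] + p["b1"]
        a1 = np.maximum(h1, 0.0)
        h2 = a1 @ p["w2"] + p["b2"]
        a2 = np.maximum(h2, 0.0)
        pooled = a2.mean(axis=1)
        logit = pooled @ p["w3"] + p["b3"]
        return logit[:, 0], (patches, h1, a1, h2, a2, pooled)

    def decision_function(self, images: np.ndarray) -> np.ndarray:
        """Raw logits; positive means 'attacked'."""
        logits, _ = self._features(np.asarray(images))
        return logits

    def predict(self, images: np.ndarray) -> np.ndarray:
        """1 = attacked (positive), 0 = clean (negative)."""
        return (self.decision_function(images) > 0).astype(int)

    def save(self, path) -> None:
        import json
        from pathlib import Path

        path = Path(path)
        np.savez(path, **self.params)
        meta = {"variant": self.variant, "training_meta": self.training_meta}
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=2, default=str))

    @classmethod
    def load(cls, path) -> "DetectorModel":
        import json
        from pathlib import Path

        with np.load(path) as z:
            params = {k: z[k] for k in z.files}
        meta = json.loads(Path(str(path) + ".json").read_text())
        return cls(variant=meta["variant"], params=params,
                   training_meta=meta.get("training_meta", {}))


def _init_detector(variant: str, n_input: int, rng: np.random.Generator) -> dict:
    width = _VARIANTS[variant]["width"]
    def he(m, n):
        return (rng.normal(0, np.sqrt(2.0 / m), size=(m, n))).astype(np.float32)
    return {
        "w1": he(n_input, width), "b1": np.zeros(width, np.float32),
        "w2": he(width, width), "b2": np.zeros(width, np.float32),
        "w3": he(width, 1), "b3": np.zeros(1, np.float32),
    }


def detector_train(
    clean: ImagePatchSet,
    attacked: ImagePatchSet,
    variant: str = "light",
    seed: int = 0,
    epochs: int = 30,
    batch_size: int = 32,
    lr: float = 1e-3,
    val_fraction: float = 0.15,
    patience: int = 5,
) -> DetectorModel:
    """Train a clean-vs-attacked detector with Adam + binary cross-entropy.

    Training is seeded and early-stops on a held-out validation split; the
    parameters with the best validation loss are kept.
    """
    if variant not in _VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    if len(clean) == 0 or len(attacked) == 0:
        raise ValueError("training needs both clean and attacked examples")
    x = np.concatenate([clean.images, attacked.images])
    y = np.concatenate([np.zeros(len(clean)), np.ones(len(attacked))]).astype(np.float32)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(x))
    x, y = x[order], y[order]
    n_val = max(2, int(len(x) * val_fraction))
    x_val, y_val = x[:n_val], y[:n_val]
    x_tr, y_tr = x[n_val:], y[n_val:]

    n_input = _PATCH * _PATCH * 3
    model = DetectorModel(variant=variant, params=_init_detector(variant, n_input, rng))
    budget = _VARIANTS[variant]["budget"]
    assert model.parameter_count <= budget, "detector exceeds its parameter budget"

    m = {k: np.zeros_like(v) for k, v in model.params.items()}
    v = {k: np.zeros_like(vv) for k, vv in model.params.items()}
    b1m, b2m, eps = 0.9, 0.999, 1e-8
    t = 0
    best = (np.inf, {k: p.copy() for k, p in model.params.items()})
    stale = 0

    def val_loss() -> float:
        logits = model.decision_function(x_val)
        return float(np.mean(np.logaddexp(0.0, logits) - y_val * logits))

    for _ in range(epochs):
        perm = rng.permutation(len(x_tr))
        for start in range(0, len(x_tr) - 1, batch_size):
            idx = perm[start : start + batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            logits, (patches, h1, a1, h2, a2, pooled) = model._features(xb)
            prob = 1.0 / (1.0 + np.exp(-logits))
            d_logit = (prob - yb)[:, None] / len(yb)
            p = model.params
            grads = {}
            grads["w3"] = pooled.T @ d_logit
            grads["b3"] = d_logit.sum(axis=0)
            d_pooled = d_logit @ p["w3"].T
            d_a2 = np.repeat(d_pooled[:, None, :], a2.shape[1], axis=1) / a2.shape[1]
            d_h2 = d_a2 * (h2 > 0)
            grads["w2"] = np.einsum("bti,btj->ij", a1, d_h2)
            grads["b2"] = d_h2.sum(axis=(0, 1))
            d_a1 = d_h2 @ p["w2"].T
            d_h1 = d_a1 * (h1 > 0)
            grads["w1"] = np.einsum("bti,btj->ij", patches, d_h1)
            grads["b1"] = d_h1.sum(axis=(0, 1))
            t += 1
            for k in p:
                g = grads[k].astype(np.float32)
                m[k] = b1m * m[k] + (1 - b1m) * g
                v[k] = b2m * v[k] + (1 - b2m) * g * g
                mhat = m[k] / (1 - b1m**t)
                vhat = v[k] / (1 - b2m**t)
                p[k] -= np.float32(lr) * mhat / (np.sqrt(vhat) + eps)
        vl = val_loss()
        if vl < best[0] - 1e-6:
            best = (vl, {k: pp.copy() for k, pp in model.params.items()})
            stale = 0
        else:
            stale += 1
            if stale >= patience:
                break
    model.params = best[1]
    model.training_meta = {
        "seed": seed, "epochs": epochs, "lr": lr,
        "n_clean": len(clean), "n_attacked": len(attacked),
        "best_val_loss": best[0],
    }
    return model


def detector_eval(model: DetectorModel, clean: ImagePatchSet, attacked: ImagePatchSet) -> dict:
    """Confusion counts plus TNR = TN/(TN+FP) and TPR = TP/(TP+FN), in percent."""
    pred_clean = model.predict(clean.images)
    pred_att = model.predict(attacked.images)
    tn = int((pred_clean == 0).sum())
    fp = int((pred_clean == 1).sum())
    tp = int((pred_att == 1).sum())
    fn = int((pred_att == 0).sum())
    return {
        "tn": tn, "fp": fp, "tp": tp, "fn": fn,
        "tnr": 100.0 * tn / max(tn + fp, 1),
        "tpr": 100.0 * tp / max(tp + fn, 1),
    }
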