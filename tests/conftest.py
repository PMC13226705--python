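"""Shared fixtures: the synthetic testbed, frozen encoders and trained attacks.

The expensive artifacts (the 9-class patch set, UTAP perturbations, the
detector) are session-scoped so the whole suite trains each of them once.
The testbed scale — 9 classes x 40 patches, 270 training / 90 held-out
images, UTAP defaults otherwise — is the package's desk-scale configuration
(see docs/methods.md).
"""

from __future__ import annotations

import numpy as np
import pytest

from utap.attacks import AttackConfig, apply_perturbation, utap_train
from utap.data import SynthesisConfig, generate_synthetic_patches
from utap.defenses import LPFConfig
from utap.encoder import EncoderSpec, TinyViT, build_tiny_vit
from utap.evaluation import encode_patchset, train_linear_probe


@pytest.fixture(scope="session")
def testbed():
    """9-class synthetic H&E-like patch set, shuffled, 40 patches per class."""
    return generate_synthetic_patches(SynthesisConfig(n_classes=9, per_class=40, seed=7))


@pytest.fixture(scope="session")
def split(testbed):
    """(train_idx, test_idx): 270 training and 90 held-out patches."""
    return np.arange(0, 270), np.arange(270, 360)


@pytest.fixture(scope="session")
def tiny_encoder():
    return build_tiny_vit(0)


@pytest.fixture(scope="session")
def clean_features(testbed, tiny_encoder):
    return encode_patchset(tiny_encoder, testbed)


@pytest.fixture(scope="session")
def probe(clean_features, testbed, split):
    tr, _ = split
    return train_linear_probe(clean_features[tr], testbed.labels[tr])


@pytest.fixture(scope="session")
def attack_config():
    """UTAP study conditions at desk scale: defaults except N (=270)."""
    return AttackConfig(n_train=270, seed=3)


@pytest.fixture(scope="session")
def utap_perturbation(testbed, split, tiny_encoder, attack_config):
    tr, _ = split
    pert, trace = utap_train(testbed.subset(tr), tiny_encoder, attack_config)
    pert.trace = trace  # tests inspect the trace without retraining
    return pert


@pytest.fixture(scope="session")
def lpf_resilient_perturbation(testbed, split, tiny_encoder):
    from utap.defenses import lpf_resilient_utap

    tr, _ = split
    cfg = AttackConfig(n_train=270, seed=3, lpf_in_loop=LPFConfig(kernel_size=50))
    pert, _ = lpf_resilient_utap(testbed.subset(tr), tiny_encoder, cfg)
    return pert


# ---- a tiny linear "encoder" used by the finite-difference oracles -------


class ToyLinearEncoder:
    """f(x) = W·vec(x): an attention-free stand-in satisfying the encoder contract.

    8x8 RGB input, patch size 4 (2x2 tile grid); the Jacobian is the constant
    matrix W, so central finite differences are an exact independent oracle.
    """

    def __init__(self, seed: int = 0, input_size: int = 8, feature_dim: int = 16):
        self.spec = EncoderSpec(
            name=f"toy-linear-{seed}", patch_size=4, input_size=input_size,
            feature_dim=feature_dim,
        )
        rng = np.random.default_rng(seed)
        n = input_size * input_size * 3
        self.w = rng.normal(0, 1.0 / np.sqrt(n), size=(n, feature_dim)).astype(np.float32)

    def forward(self, x_norm, want_cache=False):
        x_norm = np.asarray(x_norm, dtype=np.float32)
        if x_norm.ndim == 3:
            x_norm = x_norm[None]
        b = x_norm.shape[0]
        cls = x_norm.reshape(b, -1) @ self.w
        tokens = np.repeat(cls[:, None, :], self.spec.n_patch_tokens, axis=1)
        cache = {"batch": b} if want_cache else None
        return cls, tokens, cache

    def backward(self, cache, d_cls, d_patch_tokens=None, bypass_attention_grad=False):
        b = cache["batch"]
        s = self.spec.input_size
        return (np.asarray(d_cls, np.float32) @ self.w.T).reshape(b, s, s, 3)


@pytest.fixture()
def toy_encoder():
    return ToyLinearEncoder(seed=0)


@pytest.fixture()
def toy_encoder_factory():
    return ToyLinearEncoder


@pytest.fixture(scope="session")
def toy_patchset():
    """Tiny 8x8 2-class patch set matching the toy encoder's input size."""
    rng = np.random.default_rng(42)
    images = rng.integers(40, 216, size=(12, 8, 8, 3), dtype=np.uint8)
    from utap.data import ImagePatchSet

    return ImagePatchSet(
        images=np.asarray(images, np.uint8),
        labels=np.arange(12) % 2,
        class_names=["a", "b"],
        ids=[f"toy{i}" for i in range(12)],
    )


@pytest.fixture(scope="session")
def small_vit():
    """Reduced 28-pixel encoder (4 patch tokens) in float64 for gradient checks."""
    return build_tiny_vit(1, input_size=28, feature_dim=48, n_heads=3, dtype=np.float64)


@pytest.fixture(scope="session")
def detector_assets(testbed, utap_perturbation):
    """Separate synthetic pool split into train/held-out clean+attacked sets."""
    pool = generate_synthetic_patches(SynthesisConfig(n_classes=9, per_class=67, seed=11))
    attacked = apply_perturbation(pool, utap_perturbation)
    train_clean, train_att = pool.subset(np.arange(400)), attacked.subset(np.arange(400))
    held_clean = pool.subset(np.arange(400, 600))
    held_att = attacked.subset(np.arange(400, 600))
    return train_clean, train_att, held_clean, held_att
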