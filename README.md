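# utap

Universal and transferable adversarial perturbations for frozen image
feature extractors — with the defenses that (partly) stop them and the
evaluation harness that measures both.

Foundation models for digital pathology are used as *frozen* feature
extractors: a ViT encoder maps each 224×224 tissue patch to a CLS feature
vector, and lightweight linear probes do the diagnostic work downstream.
This package implements the corresponding threat model end to end, at a
scale that runs on one CPU core:

* **UTAP** — a single fixed noise pattern `p`, bounded by ‖p‖∞ ≤ ε/255,
  trained by projected gradient descent to minimize the cosine similarity
  `CosSim(f_ori, f_atk) = f_ori·f_atk / (‖f_ori‖‖f_atk‖)` between clean and
  attacked features, with two transferability devices: a fresh random tile
  mask each step (n_M of 256 tiles, ≈51%) and an attention-gradient bypass
  that treats post-softmax attention weights as constants during
  backpropagation. Step size α = ε·θ·B/(255·L·N); the update is
  `p ← Clamp(p − α·sign(∇_p CosSim), −ε/255, +ε/255)`.
* **PSAP / CSAP / FGSM** — per-image and per-class perturbations trained by
  maximizing probe cross-entropy, and the classic one-step signed-gradient
  baseline, for contrast with the universal attack.
* **Defenses** — a Fourier low-pass filter (retain a central k×k frequency
  window; equivalent to imaging at NA = λ·(k/2)/(H·Δx)), the adaptive
  attack that trains straight through it, and a small clean-vs-attacked
  detection network under explicit parameter budgets.
* **Evaluation** — deterministic L-BFGS linear probing of frozen CLS
  features, accuracy-drop metrics, cross-model transfer matrices,
  CLS-vs-patch-token attention heatmaps, UMAP/PCA feature projections and
  perturbation rendering.

Everything is testable against a bundled tiny frozen ViT (2 blocks, width
192, patch 14 — numpy forward *and* backward, so the attention bypass is an
exact, finite-difference-verified contract) and a synthetic generator of
H&E-like labeled patches that are linearly separable in the encoder's
feature space. Real encoder weights are deliberately not bundled; external
models plug in through the same forward/backward contract.

## Worked example

Train a universal perturbation against the bundled encoder on the synthetic
testbed and measure its effect on a held-out linear probe (about four
minutes on one core):

```python
import numpy as np
from utap.data import SynthesisConfig, generate_synthetic_patches
from utap.encoder import build_tiny_vit
from utap.evaluation import encode_patchset, train_linear_probe, evaluate_probe
from utap.attacks import AttackConfig, utap_train, apply_perturbation

ds = generate_synthetic_patches(SynthesisConfig(n_classes=9, per_class=40, seed=7))
train, test = ds.subset(range(270)), ds.subset(range(270, 360))
encoder = build_tiny_vit(0)
probe = train_linear_probe(encode_patchset(encoder, train), train.labels)
clean_acc = evaluate_probe(probe, encode_patchset(encoder, test), test.labels)

cfg = AttackConfig(n_train=270, epochs=10, seed=3)   # ε=20, θ=10, B=5, n_M=130
perturbation, trace = utap_train(train, encoder, cfg)
attacked = apply_perturbation(test, perturbation)
attacked_acc = evaluate_probe(probe, encode_patchset(encoder, attacked), test.labels)
print(f"clean accuracy:    {clean_acc:.2f}%")
print(f"attacked accuracy: {attacked_acc:.2f}%")
print(f"accuracy drop:     {clean_acc - attacked_acc:.2f} points")
print(f"final cosine objective: {np.mean(trace.objective[-50:]):.3f}")
print(f"max |p|: {np.abs(perturbation.values).max()*255:.1f} (8-bit units)")
```

```
clean accuracy:    100.00%
attacked accuracy: 46.67%
accuracy drop:     53.33 points
final cosine objective: 0.829
max |p|: 20.0 (8-bit units)
```

The probe separates the nine synthetic classes perfectly on clean patches;
the same fixed pattern — never larger than 20 of 255 intensity levels per
pixel, visually near-imperceptible — halves held-out accuracy by corrupting
the features themselves (the cosine between clean and attacked features
falls from 1.0), while uniform random noise at the same ε budget leaves
accuracy unchanged. Applying the k=50 low-pass defense before feature
extraction restores the lost accuracy; retraining the attack with the
filter inside its forward pass defeats part of the defense again — at the
cost, for the defender, of imaging at an effective NA of ~0.123 instead of
a standard objective. `docs/methods.md`
documents the procedure, parameter conventions and the limits of the
synthetic testbed.

## Command line

Each subcommand validates its configuration before any compute, writes a
replayable `config.yaml` plus a `run.json` provenance manifest, and is
seeded explicitly:

```bash
utap synth --n-classes 9 --per-class 100 --seed 7 --out runs/data
utap attack utap --manifest runs/data/manifest.csv --encoder tiny:0 \
     --epsilon 20 --theta 10 --epochs 10 --batch 5 --n-train 900 \
     --n-mask 130 --seed 3 --out runs/attack
utap defend --k 50 --manifest runs/data/manifest.csv --seed 0 --out runs/lpf
utap probe train --manifest runs/data/manifest.csv --seed 0 --out runs/probe
utap viz perturbation --perturbation runs/attack/perturbation.tiff --seed 0 --out runs/viz
utap replay runs/attack/config.yaml
```

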