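# Methods

This note documents the models, procedures and numerical conventions behind
`utap`, and what the bundled synthetic testbed can and cannot show.

## Threat model and training procedure

The object of study is a *universal, transferable adversarial perturbation*:
a single fixed noise pattern `p` (H×W×3, on the normalized [0, 1] intensity
scale) with an L∞ budget of ε 8-bit units, added to any input image of a
frozen feature extractor to corrupt its representation. The attack never
touches model weights and needs no knowledge of the downstream task.

Training is projected gradient descent with a signed step. Per optimization
step:

1. draw a batch of B images from the N training patches (epoch-wise seeded
   permutation);
2. draw a fresh random tile mask `M`: the 224×224 field is partitioned into
   a 16×16 grid of 14×14 tiles (matching the encoder's patch embedding) and
   n_M of the 256 tiles are chosen uniformly without replacement
   (n_M = 130 ≈ 51% by default);
3. form attacked intensities `I/255 + p⊙M` — left continuous during
   training; 8-bit rounding (half-to-even) and [0, 255] clipping happen only
   when a finished perturbation is applied for evaluation;
4. extract clean and attacked CLS features and evaluate the objective — the
   batch-mean cosine similarity `CosSim(f_ori, f_atk)`, to be minimized;
5. backpropagate to the input with the attention-gradient bypass active
   (below), mask the gradient, and update
   `p ← Clamp(p − α·sign(∇_p), −ε/255, +ε/255)` with
   `α = ε·θ·B / (255·L·N)`.

Defaults are the study conditions: ε = 20, θ = 10, L = 10 epochs, B = 5,
N = 900, n_M = 130, giving α ≈ 4.36×10⁻⁴ and 1800 steps. Note that the
total signed travel per pixel, steps × α = θ·ε/255, is independent of L, N
and B — scaled-down runs keep the same saturation dynamics, which is why the
perturbation histogram develops its characteristic spikes at ±ε for θ ≳ 10.
The clean-branch features are computed once per encoder and cached; this is
exact because the clean branch does not depend on `p`.

`sign(0) = 0` by convention, so pixels with exactly zero gradient (in
particular everything outside the current mask) receive no update. The clamp
is the last operation of every step, so the bound invariant holds after
every update, not just at the end.

With a *pool* of source encoders, the active encoder is re-drawn uniformly
every `switch_interval` (default 8) steps; everything else is unchanged.

### Attention-gradient bypass ("pay no attention")

Transfer to unseen encoders improves when the attack is prevented from
exploiting model-specific attention patterns. During the attacked branch's
backward pass, the post-softmax attention-weight tensors are treated as
constants: the query/key branch receives zero gradient while the value path
and all other layers (LayerNorm, MLP, projections, patch embedding)
differentiate normally. Forward values are bit-identical with the flag on or
off. The contract freezes exactly the post-softmax weights — not the Q/K
projections' forward values, and not LayerNorm statistics — which keeps the
"frozen mixing matrix" semantics testable: with attention frozen the block
is linear in the value path, and the bypass gradient must equal the
derivative of that partially-frozen network (verified against central
finite differences).

### Patch-, class-specific attacks and FGSM

PSAP optimizes one perturbation per image and CSAP one per class, both by
*maximizing* the cross-entropy of a frozen linear probe via signed gradient
ascent (100 steps, step size 0.01, same ±ε/255 clamp; the bound defaults to
the UTAP ε because no separate value is prescribed, and is configurable).
CSAP iterates over seeded batches of the class set; with a single-image
class it reduces exactly to PSAP. FGSM is the one-step baseline:
`clamp(I/255 + magnitude·sign(∇CE), 0, 1)`, default magnitude ε/255 for a
budget-matched comparison. These attacks differentiate without the
attention bypass (it is a transferability device of the universal attack).

## The numerical engine

No tensor-autodiff framework is used: the bundled encoder is a numpy
implementation of a small vision transformer with hand-written analytic
backward passes (patch embedding, learned CLS token and positional
embeddings, pre-norm blocks with multi-head self-attention, GELU MLP,
residuals, final LayerNorm). Owning the backward pass is what makes the
attention-bypass contract exact rather than a framework-dependent hook.
Defaults: 2 blocks, 3 heads, width 192, patch 14, input 224, weights drawn
N(0, 0.02²) from a seeded generator and frozen. All computation is float32;
a float64 mode exists because finite-difference validation to 1e-3 relative
tolerance is impossible at float32 resolution. Gradient correctness is
tested two ways: central differences on a reduced 28-pixel encoder (flag
off), and the frozen-attention oracle described above (flag on).

The bundled encoder is *randomly initialized*, not trained. Random features
of well-separated textures are linearly separable, which is all the probing
protocol needs; see "What the testbed does not show" for the consequences.

## Linear probing protocol

Downstream quality is measured by multinomial logistic regression on the
frozen encoder's CLS features of *clean* training images only: objective =
mean cross-entropy + λ‖W‖², optimized by L-BFGS (scipy's implementation,
whose line search enforces the strong Wolfe conditions) from zero
initialization, at most 100 iterations — hence deterministic. λ defaults to
1/n_samples so the penalty stays commensurate with the mean loss; the value
is exposed because no canonical constant exists. Features are not
standardized (the encoder's final LayerNorm already fixes their scale).
Attack efficacy is the accuracy drop, clean minus attacked, in percentage
points, always measured on patches unseen by both the probe and the attack.
Argmax ties break to the lowest class index.

## Low-pass-filter defense and effective NA

The defense zeroes all coefficients of the centered 2-D DFT outside a
central k×k window, per channel, before feature extraction. The window
covers shifted indices [c−⌊k/2⌋, c+⌈k/2⌉) per axis (c = n//2) and is then
*symmetrized* — a frequency bin is retained only if its conjugate bin is —
so the operator is an exactly real-valued, idempotent, self-adjoint
orthogonal projection. For even k this drops the single unpaired −k/2
row/column; for k = n the operator is the identity. Self-adjointness is what
lets LPF-resilient training backpropagate through the filter by applying the
same projection to the gradient. Physically, retaining half-bandwidth k/2
cycles per field of H pixels at Δx µm/pixel corresponds to an imaging
numerical aperture NA = λ·(k/2)/(H·Δx); with λ = 0.55 µm (visible mid-band,
configurable — the convention maps the three reference window sizes
50/20/10 → NA 0.123/0.0491/0.0246 with a single λ) the defense's resolution
cost can be stated in optical terms.

LPF-resilient training inserts the projection into the attacked branch's
forward pass (training-time intensities are not clipped, so the filter is
exactly linear there); kernel ≥ image size short-circuits to plain training.

## Attack detection

The detector is a binary classifier (clean = negative, attacked = positive)
built from a strided-patch convolutional stack: non-overlapping 16×16 patch
embedding (a stride-16 convolution), ReLU, a hidden linear layer, global
average pooling, and a linear logit. Two sizes are provided under explicit
parameter budgets — "light" (width 128, ≈0.115M parameters, budget ≤0.70M)
and "large" (width 2048, ≈5.8M, budget ≤17.5M). Training is Adam on binary
cross-entropy, seeded, with early stopping on a held-out validation split
(best-validation weights kept). Against a fixed universal perturbation the
task is nearly linearly separable, so the light variant suffices; the
budgets are contracts, not tuning targets.

## The synthetic testbed

`generate_synthetic_patches` renders H&E-like 8-bit RGB patches: a
class-conditional background color, Poisson-many nucleus-like elliptical
blobs (class-conditional density range, radius range and color) with
Gaussian-smoothed edges, plus i.i.d. Gaussian pixel noise (σ = 4 by
default). A single seeded generator drives blob placement, noise and the
final shuffle, so generation is a pure function of its configuration. Ids
encode the class of origin; per-image blob counts are kept as metadata. The
default palette separates the nine class-mean colors far enough that a
linear probe on frozen random-ViT features exceeds 95% held-out accuracy,
while uniform noise at the attack's own ε budget moves accuracy by ≤5
points — the two premises every attack experiment rests on.

Desk-scale study conditions used by the test suite: 9 classes × 40 patches
(270 training / 90 held-out images), UTAP defaults otherwise. A full
N = 270, L = 10 run takes a few minutes on one CPU core.

### What the testbed does not show

The generator emulates class-separable texture, not histology: no staining
physics, no spatial tissue architecture, no scanner noise, no
stain-normalization interaction (untested here by design). More
fundamentally, the bundled encoder is randomly initialized, and random
shallow ViTs are close to linear in their input: the Jacobian varies only
weakly across images. Two consequences:

* Universal attacks (UTAP) and their defenses behave qualitatively as they
  do against large trained encoders — these results are meaningful at desk
  scale.
* The *accuracy* collapse is reproduced, but the *geometric* collapse of
  feature clusters is not: here the universal perturbation displaces each
  class's features coherently, carrying whole clusters across the frozen
  probe's decision boundaries while silhouette-style separability (which is
  invariant to coherent translation) stays intact or even rises. Against
  trained encoders the same objective scatters features image-dependently.
* *Specificity* phenomena are not reproduced: a perturbation optimized by
  cross-entropy ascent for a single image or class finds a near-universal
  attack direction here, so PSAP/CSAP damage unseen images and non-target
  classes far more than they would against a trained foundation model,
  whose per-image Jacobians decorrelate. Scans over initialization scale
  (0.02–0.5), depth (2–4) and attack budget (ε = 2–20) confirm that
  regimes nonlinear enough to localize PSAP also destroy the clean-probe
  and noise-control premises. Conclusions about patch- or class-specific
  attack locality therefore require trained encoder weights, which this
  package deliberately does not bundle.

## Numerical conventions and degenerate inputs

* Pixels are row-major, origin top-left, 0-based; tile grids likewise.
* 8-bit quantization uses round-half-to-even; images are clipped to
  [0, 255] before quantization.
* Cosine similarity is undefined (raises) for zero-norm vectors; attention
  heatmaps map zero-norm tokens to 0 with a warning instead, so one dead
  token cannot abort a visualization.
* Perturbation files (32-bit float TIFF + JSON sidecar) re-verify the
  recorded L∞ bound on load (tolerance 1e-7 for float32 round-off) and
  refuse an ε context that contradicts their metadata.
* An empty manifest yields an empty patch set with zero classes and a
  warning; a missing image file or out-of-range label is an error naming
  the offending row.
* PCA projections fix each component's sign (largest-magnitude loading
  positive); UMAP runs with a fixed random state. Silhouette score
  (Euclidean) is the quantitative stand-in for "class clusters collapse".
* Reproducibility contract: a saved run configuration replayed in
  single-threaded mode yields byte-identical artifacts; every run directory
  records its config hash, seed and library versions.

## Known limitations

* The step-size rule is the printed constant-α formula; no per-step decay
  schedule is implemented (the loop is structured so one could be added).
* The encoder registry bundles only the tiny ViT; external models integrate
  through the same forward/backward contract, but CNN adapters ship without
  a bundled CNN.
* Detector training assumes one attack family per model; robustness across
  unseen perturbation instances is not claimed.
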