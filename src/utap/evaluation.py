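"""Linear probing, attack-efficacy metrics, transfer matrices and visuals.

The downstream task throughout is linear probing: a multinomial logistic
regression trained on the frozen encoder's CLS features of *clean* images
only, optimized with L-BFGS (strong-Wolfe line search, at most 100
iterations) on mean cross-entropy plus an L2 penalty on the weights.
Attack efficacy is the accuracy drop — clean minus attacked accuracy, in
percentage points — measured on patches unseen by both the probe and the
attack optimization.

Cross-model transfer is summarized as a matrix indexed by (training encoder,
evaluated encoder); the diagonal holds internal attacks, off-diagonal
entries black-box transfer.  Feature-space structure is inspected via
CLS-vs-patch-token cosine heatmaps and 2-D UMAP/PCA projections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .attacks import Perturbation, apply_perturbation, cosine_similarity
from .data import ImagePatchSet
from .encoder import preprocess

__all__ = [
    "ProbeModel",
    "TransferReport",
    "HeatmapGrid",
    "encode_patchset",
    "train_linear_probe",
    "evaluate_probe",
    "accuracy_drop",
    "transfer_matrix",
    "attention_heatmap",
    "project_features",
    "render_perturbation",
]


@dataclass
class ProbeModel:
    """Multinomial logistic classifier over CLS features."""

    weights: np.ndarray      # (C, D)
    bias: np.ndarray         # (C,)
    l2_strength: float
    converged: bool
    n_iters: int

    def logits(self, features: np.ndarray) -> np.ndarray:
        return np.asarray(features) @ self.weights.T + self.bias

    def predict(self, features: np.ndarray) -> np.ndarray:
        # argmax with lowest-index tie-break (numpy argmax is first-match)
        return np.argmax(self.logits(features), axis=1)


def encode_patchset(encoder, patchset, chunk: int = 32) -> np.ndarray:
    """CLS features for every patch in the set (or a raw uint8 image array)."""
    images = patchset.images if isinstance(patchset, ImagePatchSet) else np.asarray(patchset)
    out = []
    for i in range(0, len(images), chunk):
        cls, _, _ = encoder.forward(preprocess(images[i : i + chunk], encoder.spec))
        out.append(cls)
    return np.concatenate(out, axis=0)


def _probe_objective(theta, x, y, c, d, l2):
    w = theta[: c * d].reshape(c, d)
    b = theta[c * d :]
    logits = x @ w.T + b
    z = logits - logits.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=1))
    n = len(y)
    ce = float((lse - z[np.arange(n), y]).mean())
    obj = ce + l2 * float((w * w).sum())
    prob = np.exp(z - lse[:, None])
    d_logits = prob
    d_logits[np.arange(n), y] -= 1.0
    d_logits /= n
    gw = d_logits.T @ x + 2.0 * l2 * w
    gb = d_logits.sum(axis=0)
    return obj, np.concatenate([gw.ravel(), gb])


def train_linear_probe(
    features: np.ndarray,
    labels: np.ndarray,
    l2_strength: float | None = None,
    max_iter: int = 100,
) -> ProbeModel:
    """Fit the probe by L-BFGS from zero initialization (deterministic).

    Objective: mean cross-entropy + l2_strength·‖W‖².  The default
    regularization scales with the sample count (1/n), so the penalty stays
    commensurate with the mean loss.
    """
    x = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    if not np.isfinite(x).all():
        raise ValueError("features contain non-finite values")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("probe training needs at least two classes")
    c = int(y.max()) + 1
    d = x.shape[1]
    if l2_strength is None:
        l2_strength = 1.0 / len(y)
    theta0 = np.zeros(c * d + c)
    res = minimize(
        _probe_objective, theta0, args=(x, y, c, d, l2_strength),
        method="L-BFGS-B", jac=True, options={"maxiter": max_iter},
    )
    return ProbeModel(
        weights=res.x[: c * d].reshape(c, d),
        bias=res.x[c * d :],
        l2_strength=float(l2_strength),
        converged=bool(res.success),
        n_iters=int(res.nit),
    )


def evaluate_probe(probe: ProbeModel, features: np.ndarray, labels: np.ndarray) -> float:
    """Classification accuracy in percent."""
    labels = np.asarray(labels)
    if len(labels) == 0:
        raise ValueError("cannot evaluate on an empty set")
    return 100.0 * float((probe.predict(features) == labels).mean())


def accuracy_drop(original: float, attacked: float) -> float:
    """Accuracy drop in percentage points: original − attacked."""
    return float(original) - float(attacked)


@dataclass
class TransferReport:
    """Original/attacked/drop accuracy matrices over (source, target) encoders."""

    original_acc: pd.DataFrame   # rows: training encoder, cols: evaluated encoder
    attacked_acc: pd.DataFrame
    drop: pd.DataFrame

    def __post_init__(self) -> None:
        if not np.allclose(self.drop.values, self.original_acc.values - self.attacked_acc.values):
            raise ValueError("drop must equal original_acc − attacked_acc")


def transfer_matrix(
    perturbations: dict[str, Perturbation],
    encoders: dict[str, object],
    test_set: ImagePatchSet,
    probes: dict[str, ProbeModel],
) -> TransferReport:
    """Evaluate each source perturbation against each target encoder.

    ``probes[name]`` must be pretrained on clean features of ``encoders[name]``
    over training patches disjoint from ``test_set``.  The (source, target)
    cell applies the source's perturbation (full image, no mask) to the test
    patches and probes them through the target encoder.
    """
    for name in encoders:
        if name not in probes:
            raise KeyError(f"missing pretrained probe for encoder {name!r}")
    sources = list(perturbations)
    targets = list(encoders)
    orig = {}
    for tgt in targets:
        feats = encode_patchset(encoders[tgt], test_set)
        orig[tgt] = evaluate_probe(probes[tgt], feats, test_set.labels)
    original = pd.DataFrame(
        {tgt: [orig[tgt]] * len(sources) for tgt in targets}, index=sources
    )
    attacked = pd.DataFrame(index=sources, columns=targets, dtype=float)
    for src in sources:
        attacked_set = apply_perturbation(test_set, perturbations[src])
        for tgt in targets:
            feats = encode_patchset(encoders[tgt], attacked_set)
            attacked.loc[src, tgt] = evaluate_probe(probes[tgt], feats, test_set.labels)
    drop = original - attacked
    return TransferReport(original_acc=original, attacked_acc=attacked, drop=drop)


@dataclass
class HeatmapGrid:
    """CLS-vs-patch-token cosine similarities on the token grid."""

    values: np.ndarray   # (G, G), each in [-1, 1]

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("heatmap must be a square grid")


def attention_heatmap(image: np.ndarray, encoder) -> HeatmapGrid:
    """Cosine similarity between the CLS token and every patch token.

    The grid is row-major over image tiles; zero-norm tokens map to 0 with
    a warning.
    """
    cls, tokens, _ = encoder.forward(preprocess(np.asarray(image)[None], encoder.spec))
    cls, tokens = cls[0], tokens[0]
    g = encoder.spec.grid_side
    vals = np.zeros(len(tokens))
    for i, tok in enumerate(tokens):
        if np.linalg.norm(tok) == 0.0 or np.linalg.norm(cls) == 0.0:
            warnings.warn(f"zero-norm token at index {i}; heatmap value set to 0")
            vals[i] = 0.0
        else:
            vals[i] = cosine_similarity(cls, tok)
    return HeatmapGrid(values=vals.reshape(g, g))


def project_features(
    features: np.ndarray, method: str = "pca", seed: int = 0, **kwargs
) -> np.ndarray:
    """Project features to 2-D by PCA (deterministic) or seeded UMAP.

    The PCA sign convention fixes each component so its largest-magnitude
    loading is positive, making repeated runs identical.
    """
    x = np.asarray(features, dtype=np.float64)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 samples to project")
    if method == "pca":
        from sklearn.decomposition import PCA

        pca = PCA(n_components=2, svd_solver="full")
        coords = pca.fit_transform(x)
        for j in range(2):
            load = pca.components_[j]
            if load[np.argmax(np.abs(load))] < 0:
                coords[:, j] = -coords[:, j]
        return coords
    if method == "umap":
        import umap

        reducer = umap.UMAP(n_components=2, random_state=seed, **kwargs)
        return np.asarray(reducer.fit_transform(x))
    raise ValueError(f"unknown projection method {method!r}")


def render_perturbation(p: Perturbation, n_bins: int = 81):
    """Visualize a perturbation on neutral gray and histogram its intensities.

    Returns ``(rgb, (counts, bin_edges))`` where ``rgb`` is
    clamp(128 + p·255, 0, 255) as uint8, and the histogram is over the
    channel-mean intensity map in 8-bit units with support within [−ε, +ε].
    """
    vis = np.clip(np.round(128.0 + p.values * 255.0), 0, 255).astype(np.uint8)
    mean_map = (p.values * 255.0).mean(axis=-1)
    eps = float(p.epsilon_8bit)
    counts, edges = np.histogram(mean_map, bins=n_bins, range=(-eps, eps))
    return vis, (counts, edges)
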