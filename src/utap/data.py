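"""Synthetic labeled patch datasets and on-disk artifact I/O.

The generator emulates multi-class H&E-like texture at desk scale: each class
has a characteristic background color plus scattered nucleus-like elliptical
blobs whose density, size and color are class-conditional.  The point is not
histological realism — it is a controlled testbed whose classes are linearly
separable in a frozen encoder's feature space, so that attack efficacy can be
read off a linear probe.

All images are 8-bit RGB, lossless on disk (PNG), indexed by a CSV manifest
with columns ``id, path, label``.  Perturbations are stored as 32-bit float
TIFF with a JSON sidecar recording the L∞ bound and provenance.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image
from scipy.ndimage import gaussian_filter

__all__ = [
    "ImagePatchSet",
    "SynthesisConfig",
    "generate_synthetic_patches",
    "read_patchset",
    "write_patchset",
    "save_perturbation",
    "load_perturbation",
    "ConfigurationError",
    "PatchIOError",
    "IntegrityError",
]


class ConfigurationError(ValueError):
    """Invalid synthesis or run configuration."""


class PatchIOError(IOError):
    """Manifest or image file error; the message names the offending row."""


class IntegrityError(IOError):
    """A loaded artifact contradicts its recorded metadata."""


# Default 9-class palette: pale-to-deep H&E-like backgrounds with dark
# nucleus-like blobs.  Backgrounds are pairwise well separated in RGB so that
# classes stay linearly separable under mild pixel noise.
_DEFAULT_BACKGROUNDS: tuple[tuple[int, int, int], ...] = (
    (244, 238, 244),  # adipose-like, mostly empty
    (225, 208, 228),
    (238, 192, 210),
    (210, 170, 205),
    (232, 222, 185),
    (188, 200, 225),
    (205, 230, 205),
    (235, 170, 170),
    (172, 172, 212),
)
_DEFAULT_BLOB_COLORS: tuple[tuple[int, int, int], ...] = (
    (120, 85, 150),
    (95, 70, 140),
    (110, 60, 120),
    (80, 55, 125),
    (130, 100, 90),
    (70, 80, 130),
    (85, 120, 95),
    (140, 75, 95),
    (65, 60, 110),
)
_DEFAULT_DENSITIES: tuple[tuple[float, float], ...] = (
    (3, 6), (8, 14), (16, 24), (28, 38), (44, 56), (62, 76), (84, 100), (110, 130), (140, 165),
)
_DEFAULT_RADII: tuple[tuple[float, float], ...] = (
    (6, 10), (5, 9), (5, 8), (4, 8), (4, 7), (4, 7), (3, 6), (3, 6), (3, 5),
)


@dataclass
class ImagePatchSet:
    """A labeled set of equally sized 8-bit RGB patches.

    ``meta`` carries optional per-image synthesis metadata (e.g. the number
    of rendered blobs); it is not part of the on-disk manifest contract.
    """

    images: np.ndarray              # (N, H, W, 3) uint8
    labels: np.ndarray              # (N,) int
    class_names: list[str]
    ids: list[str]
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.images.ndim != 4 or self.images.shape[-1] != 3:
            raise ConfigurationError(f"images must be (N, H, W, 3), got {self.images.shape}")
        if self.images.dtype != np.uint8:
            raise ConfigurationError("images must be 8-bit (uint8)")
        if len(self.labels) != len(self.images):
            raise ConfigurationError("labels length must equal number of images")
        if len(self.ids) != len(self.images):
            raise ConfigurationError("ids length must equal number of images")
        c = len(self.class_names)
        if len(self.labels) and (self.labels.min() < 0 or self.labels.max() >= c):
            raise ConfigurationError(f"labels must lie in [0, {c})")
        if len(set(self.ids)) != len(self.ids):
            raise ConfigurationError("ids must be unique")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def image_size(self) -> int:
        return self.images.shape[1]

    def subset(self, index) -> "ImagePatchSet":
        index = np.asarray(index)
        return ImagePatchSet(
            images=self.images[index],
            labels=self.labels[index],
            class_names=list(self.class_names),
            ids=[self.ids[i] for i in index],
            meta=None if self.meta is None else self.meta.iloc[index].reset_index(drop=True),
        )


@dataclass
class SynthesisConfig:
    """Parameters of the synthetic H&E-like patch generator.

    ``blob_density_range[c]`` is the (lo, hi) range of the Poisson mean blob
    count for class ``c``; ``blob_radius_range[c]`` the (lo, hi) blob radius
    in pixels.  ``None`` class-conditional fields fall back to the built-in
    nine-class palette (truncated/cycled to ``n_classes``).
    """

    n_classes: int = 9
    per_class: int = 100
    image_size: int = 224
    blob_density_range: list[tuple[float, float]] | None = None
    blob_radius_range: list[tuple[float, float]] | None = None
    background_color_per_class: list[tuple[int, int, int]] | None = None
    blob_color_per_class: list[tuple[int, int, int]] | None = None
    noise_sd: float = 4.0
    seed: int = 0
    patch_divisor: int = 14

    def __post_init__(self) -> None:
        if self.per_class < 1:
            raise ConfigurationError("per_class must be >= 1")
        if self.n_classes < 1:
            raise ConfigurationError("n_classes must be >= 1")
        if self.image_size % self.patch_divisor != 0:
            raise ConfigurationError(
                f"image_size {self.image_size} must be divisible by {self.patch_divisor}"
            )

        def _fill(given, defaults):
            if given is None:
                return [defaults[i % len(defaults)] for i in range(self.n_classes)]
            if len(given) != self.n_classes:
                raise ConfigurationError(
                    f"class-conditional parameter list has length {len(given)}, "
                    f"expected {self.n_classes}"
                )
            return list(given)

        self.blob_density_range = _fill(self.blob_density_range, _DEFAULT_DENSITIES)
        self.blob_radius_range = _fill(self.blob_radius_range, _DEFAULT_RADII)
        self.background_color_per_class = _fill(
            self.background_color_per_class, _DEFAULT_BACKGROUNDS
        )
        self.blob_color_per_class = _fill(self.blob_color_per_class, _DEFAULT_BLOB_COLORS)

    def digest(self) -> str:
        payload = json.dumps(
            {k: (list(map(list, v)) if isinstance(v, list) else v)
             for k, v in sorted(self.__dict__.items())},
            sort_keys=True, default=float,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _render_patch(rng: np.random.Generator, cfg: SynthesisConfig, cls: int) -> tuple[np.ndarray, int]:
    """Render one patch of class ``cls``; returns (uint8 image, blob count)."""
    s = cfg.image_size
    bg = np.array(cfg.background_color_per_class[cls], dtype=np.float32)
    blob_color = np.array(cfg.blob_color_per_class[cls], dtype=np.float32)
    dlo, dhi = cfg.blob_density_range[cls]
    rlo, rhi = cfg.blob_radius_range[cls]
    lam = rng.uniform(dlo, dhi)
    n_blobs = int(rng.poisson(lam))
    alpha = np.zeros((s, s), dtype=np.float32)
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float32)
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0, s, size=2)
        a = rng.uniform(rlo, rhi)
        b = rng.uniform(rlo, rhi)
        phi = rng.uniform(0, np.pi)
        # local window around the blob keeps rendering O(blob area)
        r = int(np.ceil(max(a, b))) + 3
        y0, y1 = max(0, int(cy) - r), min(s, int(cy) + r + 1)
        x0, x1 = max(0, int(cx) - r), min(s, int(cx) + r + 1)
        if y0 >= y1 or x0 >= x1:
            continue
        dy = yy[y0:y1, x0:x1] - cy
        dx = xx[y0:y1, x0:x1] - cx
        c, sn = np.cos(phi), np.sin(phi)
        u = (c * dx + sn * dy) / a
        v = (-sn * dx + c * dy) / b
        inside = (u * u + v * v) <= 1.0
        np.maximum(alpha[y0:y1, x0:x1], inside.astype(np.float32), out=alpha[y0:y1, x0:x1])
    alpha = gaussian_filter(alpha, sigma=1.0)
    np.clip(alpha, 0.0, 1.0, out=alpha)
    img = bg * (1.0 - alpha[..., None]) + blob_color * alpha[..., None]
    if cfg.noise_sd > 0:
        img = img + rng.normal(0.0, cfg.noise_sd, size=img.shape).astype(np.float32)
    return np.clip(np.round(img), 0, 255).astype(np.uint8), n_blobs


def generate_synthetic_patches(config: SynthesisConfig) -> ImagePatchSet:
    """Generate a shuffled, labeled synthetic patch set.

    Deterministic for a fixed ``config.seed`` (a single seeded generator
    drives blob placement, pixel noise and the final shuffle).  Patch ids
    encode the class of origin as ``c{label}-{running index}``.
    """
    rng = np.random.default_rng(config.seed)
    images, labels, ids, blob_counts = [], [], [], []
    for cls in range(config.n_classes):
        for i in range(config.per_class):
            img, n_blobs = _render_patch(rng, config, cls)
            images.append(img)
            labels.append(cls)
            ids.append(f"c{cls}-{i:04d}")
            blob_counts.append(n_blobs)
    order = rng.permutation(len(images))
    meta = pd.DataFrame(
        {"n_blobs": np.asarray(blob_counts)[order], "seed": config.seed}
    )
    return ImagePatchSet(
        images=np.stack(images)[order],
        labels=np.asarray(labels)[order],
        class_names=[f"class{c}" for c in range(config.n_classes)],
        ids=[ids[i] for i in order],
        meta=meta,
    )


# ---- patch set I/O ------------------------------------------------------


def write_patchset(patchset: ImagePatchSet, out_dir) -> Path:
    """Write PNG images plus a ``manifest.csv``; returns the manifest path."""
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for img, label, pid in zip(patchset.images, patchset.labels, patchset.ids):
        rel = f"images/{pid}.png"
        Image.fromarray(img).save(out_dir / rel)
        rows.append({"id": pid, "path": rel, "label": int(label),
                     "class_name": patchset.class_names[label]})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=["id", "path", "label", "class_name"]).to_csv(
        manifest, index=False
    )
    return manifest


def read_patchset(manifest_path) -> ImagePatchSet:
    """Read a patch set back from its CSV manifest.

    The manifest must have columns ``id, path, label`` (paths relative to the
    manifest's directory).  Pixel data round-trips exactly (PNG is lossless).
    """
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    for col in ("id", "path", "label"):
        if col not in df.columns:
            raise PatchIOError(f"manifest missing required column {col!r}")
    if len(df) == 0:
        warnings.warn("empty manifest: returning an empty patch set with 0 classes")
        return ImagePatchSet(
            images=np.zeros((0, 1, 1, 3), np.uint8), labels=np.zeros(0, int),
            class_names=[], ids=[],
        )
    if "class_name" in df.columns:
        n_classes = int(df["label"].max()) + 1
        class_names = [""] * n_classes
        for _, row in df.iterrows():
            class_names[int(row["label"])] = str(row["class_name"])
        class_names = [cn or f"class{i}" for i, cn in enumerate(class_names)]
    else:
        n_classes = int(df["label"].max()) + 1
        class_names = [f"class{i}" for i in range(n_classes)]
    base = manifest_path.parent
    images, labels, ids = [], [], []
    for i, row in df.iterrows():
        label = int(row["label"])
        if not (0 <= label < n_classes):
            raise PatchIOError(f"manifest row {i} (id={row['id']}): label {label} outside [0, {n_classes})")
        path = base / str(row["path"])
        if not path.exists():
            raise PatchIOError(f"manifest row {i} (id={row['id']}): missing file {path}")
        with Image.open(path) as im:
            if im.mode not in ("RGB", "L"):
                raise PatchIOError(
                    f"manifest row {i} (id={row['id']}): image mode {im.mode} is not 8-bit RGB"
                )
            arr = np.asarray(im.convert("RGB"))
        images.append(arr)
        labels.append(label)
        ids.append(str(row["id"]))
    shapes = {im.shape for im in images}
    if len(shapes) > 1:
        raise PatchIOError(f"patches have inconsistent dimensions: {sorted(shapes)}")
    return ImagePatchSet(
        images=np.stack(images), labels=np.asarray(labels),
        class_names=class_names, ids=ids,
    )


# ---- perturbation I/O ---------------------------------------------------


def save_perturbation(p, path) -> Path:
    """Save a perturbation as 32-bit float TIFF + JSON sidecar.

    The sidecar records the 8-bit L∞ bound, provenance (encoder names,
    config hash) and lets :func:`load_perturbation` verify integrity.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    values = np.asarray(p.values, dtype=np.float32)
    tifffile.imwrite(path, values, photometric="rgb")
    sidecar = {
        "epsilon_8bit": float(p.epsilon_8bit),
        "provenance": p.provenance,
        "shape": list(values.shape),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))
    return path


def load_perturbation(path, expected_epsilon: float | None = None):
    """Load a perturbation; verifies the recorded bound and optional context.

    Raises :class:`IntegrityError` if the array violates its recorded L∞
    bound (tampering) or if ``expected_epsilon`` disagrees with the metadata.
    """
    from .attacks import Perturbation  # local import avoids a module cycle

    path = Path(path)
    values = tifffile.imread(path).astype(np.float32)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise PatchIOError(f"missing JSON sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    eps = float(sidecar["epsilon_8bit"])
    if expected_epsilon is not None and expected_epsilon != eps:
        raise IntegrityError(
            f"perturbation was saved with epsilon={eps}, requested context epsilon={expected_epsilon}"
        )
    bound = np.float32(eps / 255.0)
    if np.abs(values).max(initial=0.0) > bound + 1e-7:
        raise IntegrityError(
            f"perturbation values exceed recorded bound ±{eps}/255 "
            f"(max |p| = {np.abs(values).max():.6g})"
        )
    return Perturbation(
        values=values, epsilon_8bit=eps, provenance=sidecar.get("provenance", {})
    )
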