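"""Synthetic multi-class segmentation phantoms.

The generator emulates the failure modes that make organ segmentation hard:
several foreground structures of very unequal pixel area, overlapping
intensity distributions between classes, Gaussian-blurred boundaries and
additive acquisition noise.  Every phantom is an elliptical-blob scene with
an integer label map, so ground truth is exact and all downstream modules
can be trained and evaluated offline.

Shapes are rotated super-ellipses painted in decreasing order of target
area, so the smallest class is painted last and never occluded — small
targets are always present, which the dynamic loss-weighting experiments
rely on.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter


class PlacementError(RuntimeError):
    """Raised when non-overlapping shapes cannot be placed within the retry budget."""


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one phantom family.

    ``target_fractions`` are intended per-class pixel fractions; realized
    fractions vary with shape discretization and are recorded on the output.
    ``intensity_overlap`` is the within-class intensity standard deviation:
    larger values make neighbouring class distributions overlap more.
    """

    height: int = 64
    width: int = 64
    num_fg_classes: int = 3
    target_fractions: tuple = (0.15, 0.06, 0.02)
    intensity_means: tuple = (0.2, 0.45, 0.65, 0.85)  # background first
    intensity_overlap: float = 0.08
    boundary_blur_sigma: float = 1.0
    noise_std: float = 0.03
    seed: int = 0

    def __post_init__(self):
        k = self.num_fg_classes
        if k < 1:
            raise ValueError("num_fg_classes must be >= 1")
        if len(self.target_fractions) != k:
            raise ValueError("target_fractions must have one entry per foreground class")
        if any(f <= 0 for f in self.target_fractions):
            raise ValueError("all target fractions must be > 0")
        if sum(self.target_fractions) >= 1:
            raise ValueError("sum of target fractions must be < 1")
        if len(self.intensity_means) != k + 1:
            raise ValueError("intensity_means needs background + one mean per class")
        if not 0 <= self.intensity_overlap <= 0.5:
            raise ValueError("intensity_overlap must lie in [0, 0.5]")
        if self.boundary_blur_sigma < 0 or self.noise_std < 0:
            raise ValueError("blur sigma and noise std must be >= 0")

    def replace(self, **kw) -> "PhantomSpec":
        return dataclasses.replace(self, **kw)


@dataclasses.dataclass
class LabeledImage:
    """One image with its integer label map (0 = background, 1..K = classes)."""

    image: np.ndarray        # H x W float in [0, 1]
    label_map: np.ndarray    # H x W integer in {0..K}
    class_fractions: np.ndarray  # length K+1, sums to 1

    @property
    def num_classes(self) -> int:
        return len(self.class_fractions) - 1


def class_pixel_fractions(label_map: np.ndarray, num_fg_classes: int) -> np.ndarray:
    """Pixel proportion of background and each of the K foreground classes."""
    labels = np.asarray(label_map)
    if labels.min() < 0 or labels.max() > num_fg_classes:
        raise ValueError(
            f"label values must lie in 0..{num_fg_classes}, "
            f"got range [{labels.min()}, {labels.max()}]"
        )
    counts = np.bincount(labels.ravel(), minlength=num_fg_classes + 1)
    return counts / labels.size


def _superellipse_mask(h, w, cy, cx, a, b, theta, power) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    return (np.abs(u / a) ** power + np.abs(v / b) ** power) <= 1.0


def generate_phantom(spec: PhantomSpec) -> LabeledImage:
    """Draw one phantom; deterministic given ``spec`` (including its seed)."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    k = spec.num_fg_classes
    label = np.zeros((h, w), dtype=np.uint8)

    # paint classes from largest to smallest target so small blobs survive
    order = np.argsort(spec.target_fractions)[::-1]
    max_tries = 60
    for cls_idx in order:
        target_area = spec.target_fractions[cls_idx] * h * w
        placed = False
        for _ in range(max_tries):
            aspect = rng.uniform(0.5, 2.0)
            a = np.sqrt(target_area * aspect / np.pi)
            b = a / aspect
            theta = rng.uniform(0, np.pi)
            power = rng.uniform(1.6, 3.0)
            cy = rng.uniform(a, h - a) if h > 2 * a else h / 2
            cx = rng.uniform(a, w - a) if w > 2 * a else w / 2
            mask = _superellipse_mask(h, w, cy, cx, a, b, theta, power)
            if mask.sum() == 0:
                continue
            overlap = (label[mask] != 0).mean()
            if overlap <= 0.05 or spec.target_fractions[cls_idx] > 0.5:
                label[mask] = cls_idx + 1
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place class {cls_idx + 1} "
                f"(target fraction {spec.target_fractions[cls_idx]}) "
                f"after {max_tries} attempts"
            )

    means = np.asarray(spec.intensity_means, dtype=np.float64)
    base = means[label]
    if spec.boundary_blur_sigma > 0:
        base = gaussian_filter(base, spec.boundary_blur_sigma, mode="nearest")
    image = base
    if spec.intensity_overlap > 0:
        image = image + rng.normal(0.0, spec.intensity_overlap, size=(h, w))
    if spec.noise_std > 0:
        image = image + rng.normal(0.0, spec.noise_std, size=(h, w))
    image = np.clip(image, 0.0, 1.0)

    fractions = class_pixel_fractions(label, k)
    return LabeledImage(image=image, label_map=label, class_fractions=fractions)


def _child_seed(base_seed: int, index: int) -> int:
    """Deterministic per-item seed, stable across runs and platforms."""
    digest = hashlib.sha256(f"{base_seed}:{index}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def generate_dataset(spec: PhantomSpec, n: int, out_dir) -> dict:
    """Write ``n`` phantom image/label pairs plus a JSON manifest.

    Images are stored as float NPZ, label maps as 8-bit PNG whose pixel
    values are the class indices.  Regeneration with the same spec produces
    byte-identical label files.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i in range(n):
        seed = _child_seed(spec.seed, i)
        sample = generate_phantom(spec.replace(seed=seed))
        img_path = out_dir / f"phantom_{i:04d}.npz"
        lbl_path = out_dir / f"phantom_{i:04d}_label.png"
        try:
            np.savez(img_path, image=sample.image.astype(np.float32))
            Image.fromarray(sample.label_map, mode="L").save(lbl_path)
        except OSError as err:
            raise OSError(f"failed writing phantom files under {out_dir}: {err}") from err
        entries.append({
            "path_image": img_path.name,
            "path_label": lbl_path.name,
            "seed": seed,
            "fractions": sample.class_fractions.tolist(),
        })
    manifest = {
        "num_fg_classes": spec.num_fg_classes,
        "height": spec.height,
        "width": spec.width,
        "base_seed": spec.seed,
        "entries": entries,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def load_manifest(data_dir) -> dict:
    data_dir = Path(data_dir)
    path = data_dir / "manifest.json"
    if not path.exists():
        raise FileNotFoundError(f"no manifest.json in {data_dir}")
    with open(path) as fh:
        return json.load(fh)


def load_sample(data_dir, entry: dict) -> LabeledImage:
    data_dir = Path(data_dir)
    image = np.load(data_dir / entry["path_image"])["image"].astype(np.float64)
    label = np.asarray(Image.open(data_dir / entry["path_label"]), dtype=np.uint8)
    return LabeledImage(
        image=image,
        label_map=label,
        class_fractions=np.asarray(entry["fractions"], dtype=np.float64),
    )


def load_dataset(data_dir) -> tuple:
    """Load all samples listed by the manifest; returns (samples, manifest)."""
    manifest = load_manifest(data_dir)
    samples = [load_sample(data_dir, e) for e in manifest["entries"]]
    return samples, manifest
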