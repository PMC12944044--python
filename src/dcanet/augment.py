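"""Training-time augmentation and preprocessing.

The augmentation menu follows the common albumentations-style protocol for
2-D medical segmentation: horizontal/vertical flips, Gaussian blur (kernel
1–3), Gaussian noise (variance 10–50 on the 0–255 intensity scale),
brightness ±0.2 / contrast ±0.3, and a combined shift (±0.2) / scale (±0.5)
/ rotation (±40°) warp.  Each transform fires independently with a given
probability; geometric transforms are applied identically to image and
label map (nearest-neighbour for labels), photometric ones to the image
only.  Images stay clipped to [0, 1] and the label value set never grows.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .phantoms import LabeledImage


def _affine_pair(image, label, shift, scale, angle_deg, rng_unused=None):
    """Rotate/scale about the image center, then shift; reflect-pad image,
    background-pad labels."""
    h, w = label.shape
    angle = np.deg2rad(angle_deg)
    c, s = np.cos(angle), np.sin(angle)
    # output->input mapping: x_in = R^T/scale (x_out - center - shift) + center
    lin = np.array([[c, -s], [s, c]]) / scale
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    offset = center + np.array([shift[0] * h, shift[1] * w])
    matrix = lin
    off = center - matrix @ offset
    img_out = np.empty_like(image)
    if image.ndim == 3:
        for ch in range(image.shape[2]):
            img_out[:, :, ch] = ndimage.affine_transform(
                image[:, :, ch], matrix, offset=off, order=1, mode="reflect")
    else:
        img_out = ndimage.affine_transform(image, matrix, offset=off, order=1,
                                           mode="reflect")
    lbl_out = ndimage.affine_transform(label, matrix, offset=off, order=0,
                                       mode="constant", cval=0,
                                       output=label.dtype)
    return img_out, lbl_out


def hflip(sample: LabeledImage) -> LabeledImage:
    """Horizontal flip of image and label map (an involution)."""
    return LabeledImage(image=np.ascontiguousarray(sample.image[:, ::-1]),
                        label_map=np.ascontiguousarray(sample.label_map[:, ::-1]),
                        class_fractions=sample.class_fractions.copy())


def augment(sample: LabeledImage, prob: float, rng: np.random.Generator) -> LabeledImage:
    """Randomly augmented copy of ``sample``; deterministic given ``rng``."""
    image = sample.image.copy()
    label = sample.label_map.copy()

    if rng.random() < prob:  # horizontal flip
        image = image[:, ::-1].copy()
        label = label[:, ::-1].copy()
    if rng.random() < prob:  # vertical flip
        image = image[::-1].copy()
        label = label[::-1].copy()
    if rng.random() < prob:  # gaussian blur, kernel size 1..3 (odd)
        ksize = int(rng.choice([1, 3]))
        if ksize > 1:
            sigma = 0.3 * ((ksize - 1) * 0.5 - 1) + 0.8
            image = ndimage.gaussian_filter(image, sigma)
    if rng.random() < prob:  # gaussian noise, variance 10..50 on 0-255 scale
        var = rng.uniform(10.0, 50.0)
        image = image + rng.normal(0.0, np.sqrt(var) / 255.0, size=image.shape)
    if rng.random() < prob:  # brightness ±0.2
        image = image + rng.uniform(-0.2, 0.2)
    if rng.random() < prob:  # contrast ±0.3 about the mid-gray level
        factor = 1.0 + rng.uniform(-0.3, 0.3)
        image = (image - 0.5) * factor + 0.5
    if rng.random() < prob:  # shift ±0.2, scale ±0.5, rotation ±40°
        shift = (rng.uniform(-0.2, 0.2), rng.uniform(-0.2, 0.2))
        scale = 1.0 + rng.uniform(-0.5, 0.5)
        angle = rng.uniform(-40.0, 40.0)
        image, label = _affine_pair(image, label, shift, scale, angle)

    image = np.clip(image, 0.0, 1.0)
    counts = np.bincount(label.ravel(), minlength=len(sample.class_fractions))
    return LabeledImage(image=image, label_map=label,
                        class_fractions=counts / label.size)


def compute_stats(samples) -> tuple:
    """Per-channel mean/std over a training split (for standardization)."""
    pixels = np.concatenate([np.asarray(s.image, dtype=np.float64).ravel()
                             for s in samples])
    mean, std = float(pixels.mean()), float(pixels.std())
    if std == 0:
        raise ValueError("training split has zero intensity variance")
    return mean, std


def _resize_image(image: np.ndarray, size: tuple) -> np.ndarray:
    h, w = image.shape[:2]
    if (h, w) == size:
        return image.astype(np.float64)
    from .autograd import resize_bilinear, Tensor

    arr = image[None, None] if image.ndim == 2 else image.transpose(2, 0, 1)[None]
    out = resize_bilinear(Tensor(arr), size[0], size[1]).data
    return out[0, 0] if image.ndim == 2 else out[0].transpose(1, 2, 0)


def _resize_label(label: np.ndarray, size: tuple) -> np.ndarray:
    h, w = label.shape
    if (h, w) == size:
        return label
    rows = (np.arange(size[0]) + 0.5) * h / size[0] - 0.5
    cols = (np.arange(size[1]) + 0.5) * w / size[1] - 0.5
    rows = np.clip(np.round(rows), 0, h - 1).astype(np.intp)
    cols = np.clip(np.round(cols), 0, w - 1).astype(np.intp)
    return label[np.ix_(rows, cols)]


def preprocess(sample: LabeledImage, size: tuple, stats: tuple) -> tuple:
    """Bilinear-resize and standardize; returns (image, label) arrays.

    ``stats`` is the (mean, std) pair computed once from the training split.
    """
    mean, std = stats
    if std == 0:
        raise ValueError("zero standard deviation in preprocessing stats")
    image = _resize_image(np.asarray(sample.image, dtype=np.float64), size)
    label = _resize_label(np.asarray(sample.label_map), size)
    return (image - mean) / std, label
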