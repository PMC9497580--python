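"""Image preparation: quantile clipping, unit scaling, resize/3-channel
replication, and per-channel standardization.

Raw radiograph-like intensities often contain a tiny cluster of saturated
"landmark" pixels far above the anatomical range; min-max scaling such an
image crushes the useful dynamic range. Clipping at a high empirical
quantile (default 0.9995) before scaling removes those outliers while
leaving ordinary pixels untouched. Images are then scaled to [0, 1],
resized (bilinear) to a square side, replicated to three identical channels
so channel-pretrained networks accept them, and standardized per channel.

The canonical order of the chain is clip -> scale -> resize -> standardize.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

logger = logging.getLogger(__name__)

__all__ = [
    "ProcessedImage", "IMAGENET_MEAN", "IMAGENET_SD",
    "clip_quantile", "scale_unit", "resize_and_stack", "standardize",
    "preprocess", "preprocess_batch",
]

IMAGENET_MEAN = (0.485, 0.456, 0.406)
IMAGENET_SD = (0.229, 0.224, 0.225)


@dataclass
class ProcessedImage:
    """3 x side x side image tensor plus the normalization constants applied.

    The three channels are identical before standardization; after
    :func:`standardize`, ``channel_means``/``channel_sds`` record the
    constants that were subtracted/divided.
    """

    values: np.ndarray
    channel_means: tuple[float, float, float] | None = None
    channel_sds: tuple[float, float, float] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[0] != 3:
            raise ValueError("ProcessedImage values must be (3, H, W)")


def _check_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if not np.isfinite(img).all():
        raise ValueError("image contains non-finite values")
    return img


def clip_quantile(img: np.ndarray, q: float = 0.9995) -> np.ndarray:
    """Clip intensities at the empirical ``q``-quantile.

    Values above the quantile (linear-interpolation convention) are set to
    it; everything below is unchanged. Idempotent.
    """
    if not 0.0 < q <= 1.0:
        raise ValueError(f"quantile q must lie in (0, 1], got {q}")
    img = _check_gray(img)
    thr = np.quantile(img, q)
    return np.minimum(img, thr)


def scale_unit(img: np.ndarray) -> np.ndarray:
    """Affinely map intensities to [0, 1]; a constant image maps to zeros."""
    img = _check_gray(img)
    lo, hi = img.min(), img.max()
    if hi == lo:
        logger.warning("scale_unit: constant image, returning all zeros")
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def resize_and_stack(img: np.ndarray, side: int = 224,
                     crop: float | None = None) -> ProcessedImage:
    """Bilinear resize to ``side`` x ``side`` and replicate to 3 channels.

    ``crop``, if given, first extracts the central ``crop`` fraction of each
    dimension (a stand-in for dedicated chest-region extraction).
    """
    img = _check_gray(img)
    if img.size == 0:
        raise ValueError("empty image")
    if crop is not None:
        if not 0.0 < crop <= 1.0:
            raise ValueError("crop fraction must lie in (0, 1]")
        h, w = img.shape
        ch, cw = max(1, round(h * crop)), max(1, round(w * crop))
        r0, c0 = (h - ch) // 2, (w - cw) // 2
        img = img[r0:r0 + ch, c0:c0 + cw]
    if img.shape != (side, side):
        img = _sk_resize(img, (side, side), order=1, mode="reflect",
                         anti_aliasing=None, preserve_range=True)
    return ProcessedImage(values=np.stack([img, img, img], axis=0))


def standardize(pimg: ProcessedImage,
                means: tuple[float, float, float] = IMAGENET_MEAN,
                sds: tuple[float, float, float] = IMAGENET_SD) -> ProcessedImage:
    """Per-channel (x - mean) / sd."""
    means = tuple(float(m) for m in means)
    sds = tuple(float(s) for s in sds)
    if any(s <= 0 for s in sds):
        raise ValueError("standard deviations must be positive")
    m = np.asarray(means)[:, None, None]
    s = np.asarray(sds)[:, None, None]
    return ProcessedImage(values=(pimg.values - m) / s,
                          channel_means=means, channel_sds=sds)


def preprocess(img: np.ndarray, *, clip_q: float = 0.9995, side: int = 224,
               crop: float | None = None,
               means: tuple[float, float, float] = IMAGENET_MEAN,
               sds: tuple[float, float, float] = IMAGENET_SD) -> ProcessedImage:
    """Full chain: clip -> unit scale -> resize/stack -> standardize."""
    x = clip_quantile(img, clip_q)
    x = scale_unit(x)
    p = resize_and_stack(x, side=side, crop=crop)
    return standardize(p, means=means, sds=sds)


def preprocess_batch(images, *, clip_q: float = 0.9995, side: int = 64,
                     crop: float | None = None,
                     intensity_range: tuple[float, float] | None = None,
                     means: tuple[float, float, float] = (0.5, 0.5, 0.5),
                     sds: tuple[float, float, float] = (0.25, 0.25, 0.25)) -> np.ndarray:
    """Preprocess a list of grayscale images into an (n, 3, side, side) array.

    Defaults are tuned for the synthetic fixture networks (side 64,
    mean 0.5 / sd 0.25); pass ImageNet constants for nets expecting them.

    ``intensity_range=(lo, hi)`` replaces the per-image min-max scaling with
    a fixed affine map (clipped to [0, 1]). Per-image scaling ties every
    background pixel's value to the image's brightest structure, a global
    label leak that lets a classifier shortcut around localization; a fixed
    range keeps label evidence strictly local, which the localization
    benchmarks require.
    """
    out = []
    for im in images:
        x = clip_quantile(im, clip_q)
        if intensity_range is None:
            x = scale_unit(x)
        else:
            lo, hi = intensity_range
            if hi <= lo:
                raise ValueError("intensity_range must satisfy hi > lo")
            x = np.clip((x - lo) / (hi - lo), 0.0, 1.0)
        p = resize_and_stack(x, side=side, crop=crop)
        out.append(standardize(p, means=means, sds=sds).values)
    return np.stack(out).astype(np.float32)
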