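"""Saliency and localization agreement.

Grad-CAM weights the final convolutional feature maps by the spatial mean of
the gradient of a chosen class output, sums, rectifies, upsamples to image
resolution and min-max normalizes, yielding a coarse map of where the
network looked. For a network whose head is global average pooling followed
by a dense layer, those gradients are constant over space and equal the
dense weights, so Grad-CAM coincides with the classical class activation
map (CAM) up to normalization — a property the test suite exploits as an
oracle.

Saliency maps can be averaged across models and across populations of
images (each map normalized first), thresholded at a quantile (default 0.8)
into a binary mask, boxed, and compared against an expert-drawn mask. The
agreement score is the intersection area divided by the expert area.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.measure import label as _cc_label, regionprops
from skimage.transform import resize as _sk_resize

logger = logging.getLogger(__name__)

__all__ = ["SaliencyMap", "BoundingBox", "grad_cam", "average_maps",
           "quantile_mask", "bounding_box", "agreement"]


@dataclass
class SaliencyMap:
    """2-D nonnegative relevance map; in [0, 1] once ``normalized``."""

    values: np.ndarray
    normalized: bool = True
    degenerate: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("saliency map must be 2-D")
        if not np.isfinite(self.values).all():
            raise ValueError("saliency map must be finite")


@dataclass
class BoundingBox:
    """Inclusive 0-based pixel bounds."""

    row_min: int
    row_max: int
    col_min: int
    col_max: int

    def __post_init__(self):
        if self.row_min > self.row_max or self.col_min > self.col_max:
            raise ValueError("box min exceeds max")


def _normalize(v: np.ndarray) -> tuple[np.ndarray, bool]:
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros_like(v), True
    return (v - lo) / (hi - lo), False


def grad_cam(model, image: np.ndarray, class_index: int,
             upsample_to: tuple[int, int] | None = None) -> SaliencyMap:
    """Gradient-weighted class activation map for one image.

    Channel weights are the spatial means of the gradient of the class
    logit w.r.t. the final conv maps; the weighted sum is rectified
    (ReLU), bilinearly upsampled to the image size (or ``upsample_to``)
    and min-max normalized. An all-zero rectified map is returned as
    zeros and flagged degenerate.
    """
    image = np.asarray(image)
    x = image[None] if image.ndim == 3 else image
    if x.ndim != 4 or x.shape[0] != 1:
        raise ValueError("grad_cam expects a single (C, H, W) image")
    maps = model.conv_maps(x)[0]                      # (C, h, w)
    grads = model.conv_grad(x, class_index)[0]        # (C, h, w)
    weights = grads.mean(axis=(1, 2))                 # alpha_c
    cam = np.maximum((weights[:, None, None] * maps).sum(axis=0), 0.0)
    shape = upsample_to or x.shape[2:]
    if cam.shape != tuple(shape):
        cam = _sk_resize(cam.astype(float), shape, order=1, mode="reflect",
                         anti_aliasing=False, preserve_range=True)
        cam = np.maximum(cam, 0.0)
    if cam.max() == 0.0:
        logger.warning("grad_cam: rectified map is all zero")
        return SaliencyMap(values=np.zeros(shape), normalized=False,
                           degenerate=True)
    norm, _ = _normalize(cam)
    return SaliencyMap(values=norm, normalized=True)


def average_maps(maps: list[SaliencyMap | np.ndarray]) -> SaliencyMap:
    """Pixelwise mean of maps (each min-max normalized first), renormalized.

    Used both across models for one image and across a population of
    images for one model. A constant mean is flagged degenerate.
    """
    if not maps:
        raise ValueError("no maps to average")
    arrays = [m.values if isinstance(m, SaliencyMap) else np.asarray(m, dtype=float)
              for m in maps]
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValueError("all maps must share a shape")
    normed = [_normalize(a)[0] for a in arrays]
    mean = np.mean(normed, axis=0)
    out, degenerate = _normalize(mean)
    if degenerate:
        logger.warning("average_maps: degenerate (constant) mean map")
    return SaliencyMap(values=out, normalized=True, degenerate=degenerate)


def quantile_mask(smap: SaliencyMap | np.ndarray, q: float = 0.8) -> np.ndarray:
    """Boolean mask of pixels strictly above the map's ``q``-quantile."""
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie in (0, 1)")
    v = smap.values if isinstance(smap, SaliencyMap) else np.asarray(smap, dtype=float)
    thr = np.quantile(v, q)
    mask = v > thr
    if not mask.any():
        logger.warning("quantile_mask: empty mask (constant map?)")
    return mask


def bounding_box(mask: np.ndarray, mode: str = "union"):
    """Tightest box over true pixels (``union``) or one box per 8-connected
    component (``components``). An empty mask yields None / an empty list."""
    mask = np.asarray(mask, dtype=bool)
    if mode == "union":
        if not mask.any():
            return None
        rows, cols = np.nonzero(mask)
        return BoundingBox(int(rows.min()), int(rows.max()),
                           int(cols.min()), int(cols.max()))
    if mode == "components":
        if not mask.any():
            return []
        lab = _cc_label(mask, connectivity=2)
        boxes = []
        for region in regionprops(lab):
            r0, c0, r1, c1 = region.bbox  # half-open
            boxes.append(BoundingBox(r0, r1 - 1, c0, c1 - 1))
        return boxes
    raise ValueError(f"unknown box mode {mode!r}")


def _box_to_mask(box: BoundingBox, shape: tuple[int, int]) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    m[box.row_min:box.row_max + 1, box.col_min:box.col_max + 1] = True
    return m


def agreement(pred_mask: np.ndarray, expert_mask: np.ndarray,
              use_box: bool = False) -> float | None:
    """Intersection area over expert area, in [0, 1].

    ``use_box=True`` replaces the predicted mask with its filled union
    bounding box before intersecting. An empty expert mask has no defined
    agreement and returns None with a warning. Monotone in the predicted
    mask: adding predicted pixels never lowers the score.
    """
    pred_mask = np.asarray(pred_mask, dtype=bool)
    expert_mask = np.asarray(expert_mask, dtype=bool)
    if pred_mask.shape != expert_mask.shape:
        raise ValueError("masks must share a shape")
    expert_area = int(expert_mask.sum())
    if expert_area == 0:
        logger.warning("agreement: empty expert mask, undefined")
        return None
    if use_box:
        box = bounding_box(pred_mask, mode="union")
        pred_mask = (np.zeros_like(pred_mask) if box is None
                     else _box_to_mask(box, pred_mask.shape))
    return float((pred_mask & expert_mask).sum() / expert_area)
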