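"""Synthetic inputs for the whole pipeline.

Real multi-label radiograph collections cannot ship with a test suite, so this
module fabricates every input the other modules need, with ground truth that
makes each downstream claim checkable:

* images whose labels are *caused* by geometric signatures (discs, bars,
  ring arcs) drawn at known locations, so localization can be verified
  against exact truth masks, plus optional saturated "landmark" pixel
  clusters that quantile clipping is expected to remove;
* classifier prediction matrices with controlled per-label skill and
  calibration (calibrated / overconfident / uninformative);
* embedding matrices with label-informative dimensions of known effect size;
* small trainable convolutional fixture networks (conv blocks -> GAP ->
  dense sigmoid head) standing in for large pretrained classifiers.

Every generator is deterministic under a fixed seed. The default label list
and prevalences mirror a small hospital radiograph cohort: seven findings
(normal, cardiac, lung, pneumothorax, pleura, bone, device) with prevalences
between 4% and 45%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from .fixture_net import FixtureCNN
from .types import EmbeddingMatrix

__all__ = [
    "Signature", "SyntheticImageSpec", "SyntheticPredictionSpec",
    "SyntheticEmbeddingSpec", "generate_images", "generate_predictions",
    "generate_embeddings", "build_fixture_cnn", "make_blob_task",
    "make_domain_shift_scenario", "child_seed", "DEFAULT_LABELS",
    "DEFAULT_PREVALENCE",
]

# Seven-finding cohort structure: label list and empirical prevalences.
DEFAULT_LABELS = ["normal", "cardiac", "lung", "pnx", "pleura", "bone", "device"]
DEFAULT_PREVALENCE = [0.2901, 0.0988, 0.4538, 0.0404, 0.1435, 0.1460, 0.1556]


def child_seed(seed: int, k: int) -> int:
    """Fan a global seed out to per-generator child seeds by fixed offsets."""
    return int((int(seed) * 1_000_003 + 10_007 * (k + 1)) % (2 ** 31))


@dataclass
class Signature:
    """Geometric label signature: a shape drawn somewhere inside ``region``.

    region is (row0, row1, col0, col1) in pixels (half-open); ``size`` is the
    disc/arc radius or bar half-thickness; ``lift`` the additive intensity.
    """

    shape: str = "disc"          # disc | bar | arc
    region: tuple[int, int, int, int] = (0, 0, 0, 0)
    size: int = 8
    lift: float = 250.0


@dataclass
class SyntheticImageSpec:
    height: int = 128
    width: int = 128
    n_images: int = 200
    label_names: list[str] = field(default_factory=lambda: list(DEFAULT_LABELS))
    prevalence: list[float] = field(default_factory=lambda: list(DEFAULT_PREVALENCE))
    signature_geometry: dict[str, Signature] | None = None
    background_level: float = 400.0
    noise_sd: float = 30.0
    landmark_prob: float = 0.10
    landmark_cluster_px: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.signature_geometry is None:
            self.signature_geometry = default_geometry(
                self.label_names, self.height, self.width)
        self.validate()

    def validate(self) -> None:
        if self.height < 8 or self.width < 8:
            raise ValueError("image side must be at least 8 pixels")
        if len(self.prevalence) != len(self.label_names):
            raise ValueError("prevalence list must match label_names")
        for p in self.prevalence:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence {p} outside [0, 1]")
        for name in self.label_names:
            sig = self.signature_geometry.get(name)
            if sig is None:
                raise ValueError(f"no signature geometry for label {name!r}")
            r0, r1, c0, c1 = sig.region
            if not (0 <= r0 < r1 <= self.height and 0 <= c0 < c1 <= self.width):
                raise ValueError(f"signature region for {name!r} exceeds image bounds")
            if r1 - r0 < 2 * sig.size or c1 - c0 < 2 * sig.size:
                raise ValueError(f"signature region for {name!r} too small for size {sig.size}")


def default_geometry(label_names: list[str], height: int, width: int) -> dict[str, Signature]:
    """Assign each label a disjoint cell of a 3x3 grid and a cycling shape."""
    shapes = ["disc", "bar", "arc"]
    cells = [(r, c) for r in range(3) for c in range(3)]
    if len(label_names) > len(cells):
        raise ValueError("default geometry supports at most 9 labels")
    geo = {}
    rh, cw = height // 3, width // 3
    size = max(3, min(rh, cw) // 4)
    for i, name in enumerate(label_names):
        r, c = cells[i]
        geo[name] = Signature(
            shape=shapes[i % 3],
            region=(r * rh, (r + 1) * rh, c * cw, (c + 1) * cw),
            size=size,
            lift=250.0,
        )
    return geo


def _draw_signature(sig: Signature, rng: np.random.Generator,
                    height: int, width: int) -> np.ndarray:
    r0, r1, c0, c1 = sig.region
    s = sig.size
    cy = int(rng.integers(r0 + s, r1 - s + 1))
    cx = int(rng.integers(c0 + s, c1 - s + 1))
    yy, xx = np.ogrid[:height, :width]
    if sig.shape == "disc":
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= s ** 2
    elif sig.shape == "bar":
        half_len = min(2 * s, (c1 - c0) // 2)
        mask = (np.abs(yy - cy) <= max(1, s // 2)) & (np.abs(xx - cx) <= half_len)
        # keep the bar inside its region
        region = np.zeros((height, width), dtype=bool)
        region[r0:r1, c0:c1] = True
        mask = mask & region
    elif sig.shape == "arc":
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        ring = (d2 <= s ** 2) & (d2 >= max(1, s - max(2, s // 3)) ** 2)
        theta = np.arctan2(yy - cy, xx - cx)
        t0 = rng.uniform(-np.pi, np.pi)
        span = np.pi  # half-circle arc
        dt = np.mod(theta - t0, 2 * np.pi)
        mask = ring & (dt <= span)
        region = np.zeros((height, width), dtype=bool)
        region[r0:r1, c0:c1] = True
        mask = mask & region
    else:
        raise ValueError(f"unknown signature shape {sig.shape!r}")
    return mask


def generate_images(spec: SyntheticImageSpec):
    """Generate images with label-linked signatures at known locations.

    Returns
    -------
    images : list of 2-D float arrays (nonnegative intensities)
    labels : (n_images, n_labels) int array; label i is positive iff its
        signature was drawn into the image
    truth_masks : list of dicts mapping each *positive* label name to the
        boolean mask of exactly its signature pixels
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    n_l = len(spec.label_names)
    labels = np.zeros((spec.n_images, n_l), dtype=np.int8)
    images, truth_masks = [], []
    for i in range(spec.n_images):
        img = spec.background_level + rng.normal(0.0, spec.noise_sd, size=(h, w))
        np.maximum(img, 0.0, out=img)
        masks: dict[str, np.ndarray] = {}
        draw = rng.random(n_l) < np.asarray(spec.prevalence)
        for j, name in enumerate(spec.label_names):
            if draw[j]:
                mask = _draw_signature(spec.signature_geometry[name], rng, h, w)
                img[mask] += spec.signature_geometry[name].lift
                masks[name] = mask
                labels[i, j] = 1
        if rng.random() < spec.landmark_prob:
            # saturated landmark cluster, well above the 99th pct of background
            value = 12.0 * np.quantile(img, 0.99)
            k = spec.landmark_cluster_px
            r = int(rng.integers(0, h))
            c = int(rng.integers(0, w - k + 1))
            img[r, c:c + k] = value
        images.append(img)
        truth_masks.append(masks)
    return images, labels, truth_masks


@dataclass
class SyntheticPredictionSpec:
    """Controls fabricated classifier score matrices.

    ``skill`` is the latent-score separation between positives and negatives
    (per classifier, scalar broadcast); calibration picks how latent scores
    become probabilities.
    """

    n_classifiers: int = 3
    skill: float | list[float] = 1.5
    calibration: str = "calibrated"   # calibrated | overconfident | uninformative
    temperature: float = 8.0          # sharpening for overconfident mode
    seed: int = 0

    def validate(self) -> None:
        if self.n_classifiers < 1:
            raise ValueError("need at least one classifier")
        if self.calibration not in ("calibrated", "overconfident", "uninformative"):
            raise ValueError(f"unknown calibration mode {self.calibration!r}")


def generate_predictions(spec: SyntheticPredictionSpec, labels: np.ndarray) -> np.ndarray:
    """Fabricate per-sample prediction matrices, shape (n, K, L), in [0, 1].

    Latent scores are unit-variance Gaussians shifted by ``skill`` for
    positives; calibrated mode converts them through the exact posterior for
    that two-Gaussian model, overconfident mode additionally sharpens the
    logits by ``temperature``, and uninformative mode ignores the labels and
    concentrates scores near 0.5.
    """
    spec.validate()
    labels = np.asarray(labels)
    if labels.ndim != 2 or not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be a binary (n, L) matrix")
    rng = np.random.default_rng(spec.seed)
    n, L = labels.shape
    K = spec.n_classifiers
    skills = np.broadcast_to(np.asarray(spec.skill, dtype=float), (K,))
    out = np.empty((n, K, L))
    prev = np.clip(labels.mean(axis=0), 0.05, 0.95)
    for k in range(K):
        s = skills[k]
        if spec.calibration == "uninformative":
            p = np.clip(0.5 + rng.normal(0.0, 0.02, size=(n, L)), 0.01, 0.99)
        else:
            z = rng.normal(0.0, 1.0, size=(n, L)) + s * labels
            lo = s * z - 0.5 * s ** 2 + logit(prev)[None, :]
            if spec.calibration == "overconfident":
                lo = spec.temperature * lo
            p = expit(lo)
        out[:, k, :] = p
    return out


@dataclass
class SyntheticEmbeddingSpec:
    """Controls fabricated embedding matrices with label-informative dims."""

    dim: int = 32
    dims_per_label: int = 4
    informative: dict[int, list[int]] | None = None  # label index -> dims
    effect_size: float = 2.0
    noise_sd: float = 1.0
    allow_overlap: bool = False
    seed: int = 0

    def informative_sets(self, n_labels: int) -> dict[int, list[int]]:
        if self.informative is not None:
            sets = {int(k): list(v) for k, v in self.informative.items()}
        else:
            m = self.dims_per_label
            sets = {j: list(range(j * m, (j + 1) * m)) for j in range(n_labels)}
        used: set[int] = set()
        for j, dims in sets.items():
            if not dims:
                raise ValueError(f"label {j} has no informative dimensions")
            if max(dims) >= self.dim or min(dims) < 0:
                raise ValueError(f"informative dims for label {j} outside [0, {self.dim})")
            if not self.allow_overlap and used & set(dims):
                raise ValueError("informative sets overlap; set allow_overlap=True to permit")
            used |= set(dims)
        return sets


def generate_embeddings(spec: SyntheticEmbeddingSpec, labels: np.ndarray) -> EmbeddingMatrix:
    """Gaussian embeddings; positives shifted by ``effect_size`` on their dims."""
    labels = np.asarray(labels)
    n, L = labels.shape
    sets = spec.informative_sets(L)
    rng = np.random.default_rng(spec.seed)
    values = rng.normal(0.0, spec.noise_sd, size=(n, spec.dim))
    for j, dims in sets.items():
        values[np.ix_(labels[:, j] == 1, dims)] += spec.effect_size
    return EmbeddingMatrix(values=values, sample_ids=[f"s{i}" for i in range(n)],
                           extractor_id="synthetic")


def build_fixture_cnn(n_labels: int, seed: int = 0, *, in_channels: int = 3,
                      widths: tuple[int, ...] = (8, 16)) -> FixtureCNN:
    """Small conv->GAP->dense network exposing probabilities, final conv maps,
    GAP embeddings, and gradients of any output w.r.t. the final conv maps."""
    return FixtureCNN(n_labels=n_labels, in_channels=in_channels,
                      widths=widths, seed=seed)


#: Fixed affine intensity window for feeding blob-task images to a network
#: (background ~400, signature ~650); see ``preprocessing.preprocess_batch``.
BLOB_INTENSITY_RANGE = (0.0, 700.0)


def make_blob_task(n: int = 400, side: int = 64, seed: int = 0,
                   prevalence: float = 0.5) -> tuple[list[np.ndarray], np.ndarray, list[dict]]:
    """Single-label localization benchmark: a bright disc in the upper-left
    quadrant (radius 8 px, centre jittered inside the quadrant) causes the
    positive label. Returns (images, labels (n,1), truth_masks).

    Feed images to a network via ``preprocess_batch(images, side=side,
    intensity_range=BLOB_INTENSITY_RANGE)``: the fixed window keeps label
    evidence local to the disc (per-image min-max scaling would leak blob
    presence into every background pixel through the image maximum)."""
    quad = side // 2
    sig = Signature(shape="disc", region=(2, quad, 2, quad), size=8, lift=250.0)
    spec = SyntheticImageSpec(
        height=side, width=side, n_images=n,
        label_names=["blob"], prevalence=[prevalence],
        signature_geometry={"blob": sig},
        noise_sd=30.0, landmark_prob=0.0, seed=seed,
    )
    return generate_images(spec)


def make_domain_shift_scenario(seed: int = 0, *, n: int = 600, n_labels: int = 3,
                               n_classifiers: int = 3, base_skill: float = 0.25,
                               effect_size: float = 2.0):
    """Domain-shift setup: base classifiers degraded on the target
    distribution (low skill) while embeddings stay informative.

    Returns dict with ``labels`` (n, L), ``predictions`` (n, K, L) and
    ``embeddings`` (:class:`EmbeddingMatrix`).
    """
    rng = np.random.default_rng(child_seed(seed, 0))
    labels = (rng.random((n, n_labels)) < 0.3).astype(np.int8)
    preds = generate_predictions(
        SyntheticPredictionSpec(n_classifiers=n_classifiers, skill=base_skill,
                                calibration="calibrated", seed=child_seed(seed, 1)),
        labels)
    emb = generate_embeddings(
        SyntheticEmbeddingSpec(dim=8 * n_labels, dims_per_label=4,
                               effect_size=effect_size, noise_sd=1.0,
                               seed=child_seed(seed, 2)),
        labels)
    return {"labels": labels, "predictions": preds, "embeddings": emb}
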