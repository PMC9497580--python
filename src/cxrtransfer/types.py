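"""Shared lightweight containers used across modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PredictionMatrix", "EmbeddingMatrix"]


@dataclass
class PredictionMatrix:
    """K classifiers x L labels of probabilities for one sample (or a batch).

    ``values`` may be (K, L) for a single sample or (n, K, L) for a batch;
    entries must lie in [0, 1].
    """

    values: np.ndarray
    classifier_ids: list[str] = field(default_factory=list)
    label_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim not in (2, 3):
            raise ValueError("values must be (K, L) or (n, K, L)")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ValueError("probabilities must lie in [0, 1]")

    @property
    def n_classifiers(self) -> int:
        return self.values.shape[-2]

    @property
    def n_labels(self) -> int:
        return self.values.shape[-1]


@dataclass
class EmbeddingMatrix:
    """n samples x d pooled convolutional features from one extractor."""

    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    extractor_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (n samples x d features)")
        if not np.isfinite(self.values).all():
            raise ValueError("embedding values must be finite")

    @property
    def dim(self) -> int:
        return self.values.shape[1]
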