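"""Combine per-classifier probabilities into ensemble scores.

Two combiners are provided for a K x L matrix of probabilities p_{k,i}
(classifier k, label i):

* simple average::

      y_i = (1/N) * sum_k p_{k,i}

* entropy-weighted average, which down-weights uncertain classifiers using
  the base-2 binary entropy H(p) = -p log2 p - (1-p) log2 (1-p)::

      y_i = sum_k (1 - H(p_{k,i})) * p_{k,i}

The entropy-weighted form is, as written, unnormalized: the weights need not
sum to one, so scores can exceed 1 (two fully confident classifiers at
p = 1 give y = 2). That is harmless when scores are only ranked (AUC), and
it is the default; a normalized variant dividing by sum_k (1 - H(p_{k,i}))
is available, falling back to the simple average for a label whose weights
sum to zero (all classifiers at p = 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import xlogy

from .types import PredictionMatrix

__all__ = ["EnsemblePrediction", "binary_entropy", "simple_average",
           "entropy_weighted_average"]


@dataclass
class EnsemblePrediction:
    """Ensemble scores per label; ``scores`` is (..., L)."""

    scores: np.ndarray
    method: str
    k_used: int


def binary_entropy(p) -> np.ndarray | float:
    """Base-2 binary entropy with the 0*log(0) = 0 convention.

    Accepts scalars or arrays in [0, 1]; H(0) = H(1) = 0, H(0.5) = 1.
    """
    arr = np.asarray(p, dtype=float)
    if arr.size and (np.nanmin(arr) < 0 or np.nanmax(arr) > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    h = -(xlogy(arr, arr) + xlogy(1.0 - arr, 1.0 - arr)) / np.log(2.0)
    return float(h) if np.isscalar(p) else h


def _values(P) -> np.ndarray:
    v = P.values if isinstance(P, PredictionMatrix) else np.asarray(P, dtype=float)
    if v.ndim < 2:
        raise ValueError("expected a (K, L) or (n, K, L) prediction matrix")
    if v.shape[-2] < 1 or v.size == 0:
        raise ValueError("need at least one classifier")
    if v.min() < 0 or v.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    return v


def simple_average(P) -> EnsemblePrediction:
    """Arithmetic mean over classifiers (axis K); scores stay in [0, 1]."""
    v = _values(P)
    return EnsemblePrediction(scores=v.mean(axis=-2), method="simple",
                              k_used=v.shape[-2])


def entropy_weighted_average(P, normalize: bool = False) -> EnsemblePrediction:
    """Confidence-weighted combination with weights 1 - H(p).

    ``normalize=False`` (default) returns the literal weighted sum, whose
    range is [0, K]; ``normalize=True`` divides by the summed weights,
    falling back to the simple average where all weights vanish.
    """
    v = _values(P)
    wts = 1.0 - binary_entropy(v)
    weighted = (wts * v).sum(axis=-2)
    if not normalize:
        return EnsemblePrediction(scores=weighted, method="entropy",
                                  k_used=v.shape[-2])
    denom = wts.sum(axis=-2)
    simple = v.mean(axis=-2)
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = np.where(denom > 0, weighted / np.where(denom > 0, denom, 1.0), simple)
    return EnsemblePrediction(scores=scores, method="entropy_normalized",
                              k_used=v.shape[-2])
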