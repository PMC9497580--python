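"""ROC curves and per-label / mean AUROC, the pipeline's sole metric.

AUC here is trapezoidal area under the ROC curve with the midrank tie
convention, which makes it identical to the Mann-Whitney concordance
probability: the chance a random positive scores above a random negative,
counting ties as one half. Labels with a single observed class have no
defined AUC and are reported as missing (and excluded from the mean).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

logger = logging.getLogger(__name__)

__all__ = ["LabelRoc", "RocResult", "roc_auc", "evaluate_multilabel", "mean_auc"]


@dataclass
class LabelRoc:
    """ROC curve and AUC for one label; ``auc`` is None when undefined."""

    auc: float | None
    fpr: np.ndarray
    tpr: np.ndarray
    n_pos: int
    n_neg: int


@dataclass
class RocResult:
    """Per-label ROC results plus their unweighted mean AUC."""

    per_label: dict[str, LabelRoc] = field(default_factory=dict)

    @property
    def aucs(self) -> dict[str, float | None]:
        return {k: v.auc for k, v in self.per_label.items()}

    @property
    def mean_auc(self) -> float:
        return mean_auc(self)


def roc_auc(scores, labels) -> LabelRoc:
    """AUC and ROC points for one label.

    Requires both classes present; otherwise the AUC is undefined and
    returned as None with a warning.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary")
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        logger.warning("roc_auc: single-class labels, AUC undefined")
        return LabelRoc(auc=None, fpr=np.array([0.0, 1.0]),
                        tpr=np.array([0.0, 1.0]), n_pos=n_pos, n_neg=n_neg)
    fpr, tpr, _ = roc_curve(labels, scores)
    return LabelRoc(auc=float(roc_auc_score(labels, scores)),
                    fpr=fpr, tpr=tpr, n_pos=n_pos, n_neg=n_neg)


def evaluate_multilabel(scores: np.ndarray, labels: np.ndarray,
                        label_names: list[str] | None = None) -> RocResult:
    """Per-label ROC/AUC for (n, L) score and binary label matrices."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 2:
        raise ValueError("scores and labels must both be (n, L)")
    names = label_names or [f"label_{j}" for j in range(scores.shape[1])]
    res = RocResult()
    for j, name in enumerate(names):
        res.per_label[name] = roc_auc(scores[:, j], labels[:, j])
    return res


def mean_auc(result: RocResult) -> float:
    """Unweighted mean over labels with a defined AUC."""
    vals = [r.auc for r in result.per_label.values() if r.auc is not None]
    if not vals:
        raise ValueError("no label has a defined AUC")
    return float(np.mean(vals))
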