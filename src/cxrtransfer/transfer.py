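"""The four transfer strategies: direct mapped inference, stacking,
embeddings + tree classifiers, and fine-tuning.

A source-trained classifier emits probabilities over *source* labels; the
target task has its own label set, with each target label corresponding to
one or more source labels (e.g. a "cardiac" target covering both an
enlarged-cardiomediastinum and a cardiomegaly source label). Direct mapped
inference takes, for each target label, the maximum source probability over
its source set. Stacking trains a random-forest metaclassifier on the mapped
outputs of all base classifiers. The embedding strategy trains tree models
(decision tree, random forest, extremely randomized trees) on the GAP
feature vectors extracted by each network, with exhaustive grid search under
stratified K-fold cross-validation. Fine-tuning replaces the dense head with
a fresh target-sized one and retrains briefly with a decaying learning rate.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .fixture_net import FixtureCNN, TrainHistory
from .types import EmbeddingMatrix, PredictionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "LabelMapping", "CHEXPERT_TO_TARGET", "map_predictions",
    "extract_embeddings", "TreeGridConfig", "TreeFit", "fit_tree_classifier",
    "StackingFit", "fit_stacking", "FineTuneConfig", "fine_tune",
    "stratified_split",
]

# Canonical source->target label correspondence for chest-radiograph tasks:
# each target finding collects the source findings it subsumes.
CHEXPERT_TO_TARGET: dict[str, list[str]] = {
    "pleura": ["pleural effusion", "pleural other"],
    "device": ["support devices"],
    "pnx": ["pneumothorax"],
    "cardiac": ["enlarged cardiomediastinum", "cardiomegaly"],
    "lung": ["lung opacity", "lung lesion", "consolidation", "pneumonia",
             "atelectasis", "edema"],
    "bone": ["fracture"],
    "normal": ["no finding"],
}


@dataclass
class LabelMapping:
    """Target label list plus, per target, the source-label indices it maps."""

    target_labels: list[str]
    source_sets: list[list[int]]
    n_source: int | None = None

    def __post_init__(self):
        if len(self.target_labels) != len(self.source_sets):
            raise ValueError("one source set required per target label")
        for name, s in zip(self.target_labels, self.source_sets):
            if len(s) == 0:
                raise ValueError(f"empty source set for target label {name!r}")
            if any(i < 0 for i in s):
                raise ValueError("negative source index")
            if self.n_source is not None and max(s) >= self.n_source:
                raise ValueError(f"source index out of range for {name!r}")

    @classmethod
    def from_names(cls, source_labels: list[str],
                   name_map: dict[str, list[str]]) -> "LabelMapping":
        idx = {n: i for i, n in enumerate(source_labels)}
        targets, sets = [], []
        for tgt, sources in name_map.items():
            targets.append(tgt)
            try:
                sets.append([idx[s] for s in sources])
            except KeyError as e:
                raise ValueError(f"unknown source label {e.args[0]!r}") from None
        return cls(target_labels=targets, source_sets=sets,
                   n_source=len(source_labels))


def map_predictions(source_preds, mapping: LabelMapping):
    """Map source-label probabilities to target labels by per-set maximum.

    Accepts a (K, L_s) or (n, K, L_s) array or a :class:`PredictionMatrix`;
    returns the same kind with L_t target columns. Raising any source
    probability never lowers a target score (the max is monotone).
    """
    is_pm = isinstance(source_preds, PredictionMatrix)
    v = source_preds.values if is_pm else np.asarray(source_preds, dtype=float)
    l_s = v.shape[-1]
    for name, s in zip(mapping.target_labels, mapping.source_sets):
        if max(s) >= l_s:
            raise ValueError(f"source index out of range for target {name!r}")
    out = np.stack([v[..., s].max(axis=-1) for s in mapping.source_sets], axis=-1)
    if is_pm:
        return PredictionMatrix(values=out,
                                classifier_ids=list(source_preds.classifier_ids),
                                label_names=list(mapping.target_labels))
    return out


def extract_embeddings(model, images: np.ndarray, *, extractor_id: str = "",
                       batch: int = 64) -> EmbeddingMatrix:
    """GAP embeddings: channel-wise spatial mean of the final conv maps."""
    if not hasattr(model, "conv_maps"):
        raise TypeError("model does not expose final convolutional maps")
    images = np.asarray(images)
    if images.ndim == 3:
        images = images[None]
    rows = [model.conv_maps(images[i:i + batch]).mean(axis=(2, 3))
            for i in range(0, images.shape[0], batch)]
    values = np.concatenate(rows, axis=0)
    return EmbeddingMatrix(values=values,
                           sample_ids=[f"s{i}" for i in range(values.shape[0])],
                           extractor_id=extractor_id)


# --------------------------------------------------------------------- trees

#: Exhaustive hyperparameter grids for the tree models.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "DT": {
        "max_depth": [1, 2, 3, 4, 5, 10, 20],
        "min_samples_leaf": [1, 2, 4],
        "min_samples_split": [2, 5, 10],
        "criterion": ["gini", "entropy"],
    },
    "RF": {
        "max_depth": [1, 2, 3, 4, 5, 10, 20],
        "min_samples_leaf": [1, 2, 4],
        "min_samples_split": [2, 5, 10],
        "criterion": ["gini", "entropy"],
        "n_estimators": [10, 20, 30, 50, 100, 200, 300],
    },
}
DEFAULT_GRIDS["XRT"] = dict(DEFAULT_GRIDS["RF"])

#: Tuned single configurations (used when no grid search is requested).
TUNED_PARAMS: dict[str, dict] = {
    "DT": {"max_depth": 10, "min_samples_leaf": 1, "min_samples_split": 2,
           "criterion": "gini"},
    "RF": {"max_depth": 10, "min_samples_leaf": 4, "min_samples_split": 10,
           "criterion": "gini", "n_estimators": 100},
    "XRT": {"max_depth": 10, "min_samples_leaf": 2, "min_samples_split": 2,
            "criterion": "entropy", "n_estimators": 200},
}


@dataclass
class TreeGridConfig:
    """Grid-search configuration for one tree-model kind (DT | RF | XRT)."""

    kind: str = "RF"
    grids: dict[str, list] = field(default_factory=dict)
    k_folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("DT", "RF", "XRT"):
            raise ValueError(f"unknown tree kind {self.kind!r}")
        if not self.grids:
            self.grids = {k: list(v) for k, v in DEFAULT_GRIDS[self.kind].items()}
        if any(len(v) == 0 for v in self.grids.values()):
            raise ValueError("every grid axis must be nonempty")
        if self.k_folds < 2:
            raise ValueError("k_folds must be at least 2")

    def cells(self) -> list[dict]:
        """Grid cells in fixed lexicographic order of parameter names and
        values, so selection (and tie-breaking) cannot depend on how the
        grid happened to be listed."""
        keys = sorted(self.grids)
        axes = [sorted(set(self.grids[k]), key=lambda v: (v is None, str(v)))
                for k in keys]
        return [dict(zip(keys, combo)) for combo in itertools.product(*axes)]


def _make_tree(kind: str, params: dict, seed: int):
    cls = {"DT": DecisionTreeClassifier, "RF": RandomForestClassifier,
           "XRT": ExtraTreesClassifier}[kind]
    return cls(random_state=seed, **params)


def _proba_pos(est, X: np.ndarray) -> np.ndarray:
    p = est.predict_proba(X)
    pos = list(est.classes_).index(1)
    return p[:, pos]


@dataclass
class TreeFit:
    """Fitted per-label tree models plus the grid-search record."""

    kind: str
    models: dict[str, object]
    best_params: dict
    cv_table: pd.DataFrame
    label_names: list[str]
    skipped_labels: list[str]

    def predict(self, emb) -> np.ndarray:
        """Positive-class scores, shape (n, L); NaN for skipped labels."""
        X = emb.values if isinstance(emb, EmbeddingMatrix) else np.asarray(emb)
        out = np.full((X.shape[0], len(self.label_names)), np.nan)
        for j, name in enumerate(self.label_names):
            if name in self.models:
                out[:, j] = _proba_pos(self.models[name], X)
        return out


def fit_tree_classifier(emb, labels: np.ndarray, cfg: TreeGridConfig,
                        label_names: list[str] | None = None) -> TreeFit:
    """Exhaustive grid search with stratified K-fold CV, then refit.

    Each cell is scored by mean AUC across folds, averaged across labels;
    the best cell (ties broken by the fixed lexicographic cell order) is
    refit on the full training data, one binary model per label. Labels
    with a single class are skipped with a warning.
    """
    X = emb.values if isinstance(emb, EmbeddingMatrix) else np.asarray(emb, dtype=float)
    y = np.asarray(labels)
    if y.ndim == 1:
        y = y[:, None]
    names = label_names or [f"label_{j}" for j in range(y.shape[1])]
    usable = []
    for j, name in enumerate(names):
        counts = np.bincount(y[:, j], minlength=2)
        if counts.min() >= 2:
            usable.append(j)
        else:
            logger.warning("label %r has a single class (or <2 minority "
                           "samples) in training data; skipped", name)
    if not usable:
        raise ValueError("no label has two classes in the training data")

    records = []
    for cell_idx, params in enumerate(cfg.cells()):
        label_scores = []
        for j in usable:
            yj = y[:, j]
            k = min(cfg.k_folds, int(np.bincount(yj, minlength=2).min()))
            if k < 2:
                continue
            skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=cfg.seed)
            fold_aucs = []
            for tr, va in skf.split(X, yj):
                if len(np.unique(yj[va])) < 2:
                    continue
                est = _make_tree(cfg.kind, params, cfg.seed)
                est.fit(X[tr], yj[tr])
                fold_aucs.append(roc_auc_score(yj[va], _proba_pos(est, X[va])))
            if fold_aucs:
                label_scores.append(np.mean(fold_aucs))
        records.append({**params, "mean_cv_auc": float(np.mean(label_scores)),
                        "_cell": cell_idx})
    cv_table = pd.DataFrame.from_records(records)
    best_row = cv_table.sort_values(["mean_cv_auc", "_cell"],
                                    ascending=[False, True]).iloc[0]
    best_params = cfg.cells()[int(best_row["_cell"])]

    models = {}
    for j in usable:
        est = _make_tree(cfg.kind, best_params, cfg.seed)
        est.fit(X, y[:, j])
        models[names[j]] = est
    return TreeFit(kind=cfg.kind, models=models, best_params=best_params,
                   cv_table=cv_table.drop(columns="_cell"), label_names=names,
                   skipped_labels=[n for i, n in enumerate(names) if i not in usable])


# ------------------------------------------------------------------ stacking

@dataclass
class StackingFit:
    """Random-forest metaclassifier over base-classifier outputs."""

    models: dict[str, object]
    label_names: list[str]
    per_label_features: bool
    skipped_labels: list[str]

    def _features(self, base_preds: np.ndarray, j: int) -> np.ndarray:
        if self.per_label_features:
            return base_preds[:, :, j]
        n = base_preds.shape[0]
        return base_preds.reshape(n, -1)

    def predict(self, base_preds: np.ndarray) -> np.ndarray:
        base_preds = np.asarray(base_preds)
        out = np.full((base_preds.shape[0], len(self.label_names)), np.nan)
        for j, name in enumerate(self.label_names):
            if name in self.models:
                out[:, j] = _proba_pos(self.models[name], self._features(base_preds, j))
        return out


def fit_stacking(base_preds: np.ndarray, labels: np.ndarray, *,
                 label_names: list[str] | None = None, seed: int = 0,
                 rf_params: dict | None = None,
                 per_label_features: bool = False) -> StackingFit:
    """Train one random-forest metaclassifier per target label.

    ``base_preds`` is (n, K, L_t): the mapped outputs of the K base
    classifiers. By default the feature vector for every label is the full
    flattened K*L_t matrix (cross-label signals help); ``per_label_features``
    restricts it to the K columns of the label being predicted. The forest
    uses the tuned RF configuration unless ``rf_params`` overrides it.
    """
    base_preds = np.asarray(base_preds, dtype=float)
    if base_preds.ndim != 3:
        raise ValueError("base_preds must be (n, K, L)")
    y = np.asarray(labels)
    names = label_names or [f"label_{j}" for j in range(y.shape[1])]
    params = dict(TUNED_PARAMS["RF"]) if rf_params is None else dict(rf_params)
    fit = StackingFit(models={}, label_names=names,
                      per_label_features=per_label_features, skipped_labels=[])
    for j, name in enumerate(names):
        if len(np.unique(y[:, j])) < 2:
            logger.warning("stacking: label %r single-class, skipped", name)
            fit.skipped_labels.append(name)
            continue
        est = RandomForestClassifier(random_state=seed, **params)
        est.fit(fit._features(base_preds, j), y[:, j])
        fit.models[name] = est
    return fit


# ---------------------------------------------------------------- fine-tune

@dataclass
class FineTuneConfig:
    """Short retraining protocol for a source-trained network.

    Five epochs with early stopping (patience 3) on validation mean AUC,
    binary cross-entropy loss, Adam, learning rate 1e-4 divided by ten
    after every epoch.
    """

    epochs: int = 5
    patience: int = 3
    lr0: float = 1e-4
    lr_decay: float = 0.1
    batch_size: int = 4
    head_init_sd: float = 1e-4
    split: tuple[float, float, float] = (0.7, 0.1, 0.2)
    seed: int = 0

    def __post_init__(self):
        self.split = tuple(self.split)
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


def fine_tune(model: FixtureCNN, train: tuple[np.ndarray, np.ndarray],
              val: tuple[np.ndarray, np.ndarray],
              cfg: FineTuneConfig) -> tuple[FixtureCNN, TrainHistory]:
    """Replace the dense head and retrain; returns the best-epoch model.

    The head is re-initialized at small random scale and sized to the
    target label count, with its bias set to the logit of each label's
    training prevalence (prior initialization): a short low-learning-rate
    run then spends its steps on the discriminative signal instead of on
    re-learning the class priors through the bias. The checkpoint with the
    best validation mean AUC is returned, with early stopping after
    ``cfg.patience`` epochs without improvement.
    """
    Xv, yv = val
    if len(np.asarray(Xv)) == 0:
        raise ValueError("fine_tune requires a nonempty validation set")
    X, y = train
    y = np.asarray(y)
    n_labels = 1 if y.ndim == 1 else y.shape[1]
    tuned = model.copy()
    tuned.replace_head(n_labels, seed=cfg.seed, init_sd=cfg.head_init_sd)
    prev = np.clip(y.reshape(len(y), n_labels).mean(axis=0), 1e-3, 1 - 1e-3)
    tuned.bd = np.log(prev / (1 - prev)).astype(tuned.bd.dtype)
    history = tuned.fit(np.asarray(X), y, epochs=cfg.epochs, lr=cfg.lr0,
                        lr_decay=cfg.lr_decay, batch_size=cfg.batch_size,
                        seed=cfg.seed, val=(np.asarray(Xv), np.asarray(yv)),
                        patience=cfg.patience)
    return tuned, history


# ------------------------------------------------------------------- splits

def stratified_split(labels: np.ndarray, fractions: tuple[float, ...],
                     seed: int = 0) -> tuple[np.ndarray, ...]:
    """Split sample indices by the given fractions, stratifying on the
    rarest positive label so scarce findings appear in every part."""
    labels = np.asarray(labels)
    if labels.ndim == 1:
        labels = labels[:, None]
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    pos = labels.sum(axis=0).astype(float)
    pos[pos == 0] = np.inf
    strat = labels[:, int(np.argmin(pos))] if np.isfinite(pos).any() \
        else np.zeros(labels.shape[0], dtype=int)
    rng = np.random.default_rng(seed)
    parts: list[list[int]] = [[] for _ in fractions]
    cum = np.cumsum(fractions)
    for value in np.unique(strat):
        idx = np.flatnonzero(strat == value)
        idx = idx[rng.permutation(len(idx))]
        bounds = np.round(cum * len(idx)).astype(int)
        start = 0
        for p, b in enumerate(bounds):
            parts[p].extend(idx[start:b])
            start = b
    return tuple(np.sort(np.asarray(p, dtype=int)) for p in parts)
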