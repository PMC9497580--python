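"""End-to-end experiment: synthesize data, run all four transfer strategies,
ensemble, evaluate, and emit a comparison report.

The synthetic experiment mirrors the structure of a two-dataset transfer
study. A "source" collection of images with fine-grained source labels is
used to pretrain K fixture networks. A separate "target" collection — drawn
with a shifted background level and noisier acquisition, emulating a change
of hospital/scanner — carries coarser target labels, each the union of one
or more source labels. The four strategies are then compared on the target
test split:

* ``baseline``    — direct mapped inference (max over each source set),
* ``stacking``    — random-forest metaclassifier on the mapped outputs,
* ``embeddings``  — tree models (DT/RF/XRT) on GAP embeddings per network,
* ``finetune``    — brief retraining of each network with a fresh head.

Per-classifier outputs are combined with simple and entropy-weighted
averaging; every AUC lands in one report table whose rows are
(strategy, model) and whose columns are the target labels plus their mean.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ensembles, synthetic, transfer
from .evaluation import evaluate_multilabel
from .preprocessing import preprocess_batch
from .synthetic import Signature, SyntheticImageSpec, child_seed
from .transfer import FineTuneConfig, LabelMapping, TreeGridConfig

__all__ = ["ExperimentConfig", "ComparisonReport", "run_experiment",
           "load_labels", "save_report"]

#: Source-label prevalences for the default synthetic study.
DEFAULT_SOURCE_LABELS = {
    "effusion": 0.20, "pleural_other": 0.10, "cardiomegaly": 0.15,
    "enlarged_cm": 0.10, "opacity": 0.40,
}
DEFAULT_TARGET_MAP = {
    "pleura": ["effusion", "pleural_other"],
    "cardiac": ["cardiomegaly", "enlarged_cm"],
    "lung": ["opacity"],
}
#: Desk-scale grid for the tree stage of the default pipeline run.
DEFAULT_PIPELINE_GRIDS = {
    "DT": {"max_depth": [3, 10], "min_samples_leaf": [1], "min_samples_split": [2],
           "criterion": ["gini"]},
    "RF": {"max_depth": [3, 10], "min_samples_leaf": [1], "min_samples_split": [2],
           "criterion": ["gini"], "n_estimators": [50]},
    "XRT": {"max_depth": [3, 10], "min_samples_leaf": [1], "min_samples_split": [2],
            "criterion": ["gini"], "n_estimators": [50]},
}


@dataclass
class ExperimentConfig:
    """Everything a full run needs; round-trips losslessly through YAML."""

    n_source_images: int = 240
    n_target_images: int = 240
    image_side: int = 64
    source_labels: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SOURCE_LABELS))
    target_map: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_TARGET_MAP.items()})
    n_classifiers: int = 3
    net_widths: list[list[int]] = field(
        default_factory=lambda: [[6, 12], [8, 16], [10, 20]])
    pretrain_epochs: int = 4
    pretrain_lr: float = 3e-3
    pretrain_batch: int = 16
    # acquisition shift of the target collection relative to the source
    target_background_shift: float = 60.0
    target_noise_scale: float = 1.4
    strategies: list[str] = field(
        default_factory=lambda: ["baseline", "stacking", "embeddings", "finetune"])
    tree_kinds: list[str] = field(default_factory=lambda: ["DT", "RF", "XRT"])
    tree_grids: dict[str, dict] = field(
        default_factory=lambda: {k: {a: list(v) for a, v in g.items()}
                                 for k, g in DEFAULT_PIPELINE_GRIDS.items()})
    tree_k_folds: int = 3
    ensemble_methods: list[str] = field(default_factory=lambda: ["simple", "entropy"])
    split: list[float] = field(default_factory=lambda: [0.7, 0.1, 0.2])
    finetune: FineTuneConfig = field(default_factory=FineTuneConfig)
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self):
        if not self.strategies:
            raise ValueError("at least one strategy must be requested")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if isinstance(self.finetune, dict):
            self.finetune = FineTuneConfig(**self.finetune)

    # ------------------------------------------------------------ serialization

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        js = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(js.encode()).hexdigest()[:16]


@dataclass
class ComparisonReport:
    """AUC grid (strategy x model x label) plus provenance and predictions."""

    table: pd.DataFrame
    predictions: dict[str, pd.DataFrame]
    provenance: dict

    def mean_auc(self, strategy: str, model: str) -> float:
        sel = self.table[(self.table.strategy == strategy) & (self.table.model == model)]
        if sel.empty:
            raise KeyError(f"no row for {strategy}/{model}")
        return float(sel["mean"].iloc[0])


def _image_spec(cfg: ExperimentConfig, *, background: float, noise: float,
                seed: int) -> SyntheticImageSpec:
    names = list(cfg.source_labels)
    geometry = synthetic.default_geometry(names, cfg.image_side, cfg.image_side)
    return SyntheticImageSpec(
        height=cfg.image_side, width=cfg.image_side,
        n_images=0,  # set by caller
        label_names=names, prevalence=[cfg.source_labels[n] for n in names],
        signature_geometry=geometry, background_level=background,
        noise_sd=noise, landmark_prob=0.10, seed=seed,
    )


def _ensemble_scores(preds_kl: np.ndarray, method: str) -> np.ndarray:
    if method == "simple":
        return ensembles.simple_average(preds_kl).scores
    if method == "entropy":
        return ensembles.entropy_weighted_average(preds_kl).scores
    if method == "entropy_normalized":
        return ensembles.entropy_weighted_average(preds_kl, normalize=True).scores
    raise ValueError(f"unknown ensemble method {method!r}")


def _auc_row(strategy: str, model: str, scores: np.ndarray, y: np.ndarray,
             names: list[str]) -> dict:
    res = evaluate_multilabel(scores, y, names)
    row = {"strategy": strategy, "model": model}
    row.update({k: v for k, v in res.aucs.items()})
    row["mean"] = res.mean_auc
    return row


def run_experiment(cfg: ExperimentConfig) -> ComparisonReport:
    """Run the configured strategies end to end on synthetic data.

    A failure inside one strategy is isolated: it is recorded in
    ``provenance['errors']`` and the remaining strategies still run.
    """
    t0 = time.perf_counter()
    timings: dict[str, float] = {}
    errors: dict[str, str] = {}
    target_names = list(cfg.target_map)

    # ---- data ---------------------------------------------------------
    src_spec = _image_spec(cfg, background=400.0, noise=30.0,
                           seed=child_seed(cfg.seed, 1))
    src_spec.n_images = cfg.n_source_images
    src_images, src_y, _ = synthetic.generate_images(src_spec)

    tgt_spec = _image_spec(
        cfg, background=400.0 + cfg.target_background_shift,
        noise=30.0 * cfg.target_noise_scale, seed=child_seed(cfg.seed, 2))
    tgt_spec.n_images = cfg.n_target_images
    tgt_images, tgt_src_y, _ = synthetic.generate_images(tgt_spec)

    mapping = LabelMapping.from_names(list(cfg.source_labels), cfg.target_map)
    tgt_y = np.stack([tgt_src_y[:, s].max(axis=1) for s in mapping.source_sets],
                     axis=1)

    # fixed intensity window: keeps label evidence local and preserves the
    # background shift of the target collection as a genuine domain shift
    window = (0.0, 800.0)
    Xs = preprocess_batch(src_images, side=cfg.image_side, intensity_range=window)
    Xt = preprocess_batch(tgt_images, side=cfg.image_side, intensity_range=window)
    tr, va, te = transfer.stratified_split(tgt_y, tuple(cfg.split),
                                           seed=child_seed(cfg.seed, 3))
    trva = np.sort(np.concatenate([tr, va]))
    timings["data"] = time.perf_counter() - t0

    # ---- pretrain the K base networks on the source task --------------
    t1 = time.perf_counter()
    nets = []
    for k in range(cfg.n_classifiers):
        widths = tuple(cfg.net_widths[k % len(cfg.net_widths)])
        net = synthetic.build_fixture_cnn(
            n_labels=src_y.shape[1], seed=child_seed(cfg.seed, 10 + k),
            widths=widths)
        net.fit(Xs, src_y, epochs=cfg.pretrain_epochs, lr=cfg.pretrain_lr,
                batch_size=cfg.pretrain_batch, seed=child_seed(cfg.seed, 20 + k))
        nets.append(net)
    timings["pretrain"] = time.perf_counter() - t1

    rows: list[dict] = []
    predictions: dict[str, pd.DataFrame] = {}
    ids_te = [f"img{i:04d}" for i in te]

    def record(tag: str, scores: np.ndarray) -> None:
        predictions[tag] = pd.DataFrame(scores, index=pd.Index(ids_te, name="image_id"),
                                        columns=target_names)

    # mapped base predictions, used by baseline and stacking
    base_all = np.stack([net.predict_proba(Xt) for net in nets], axis=1)  # (n,K,Ls)
    mapped_all = transfer.map_predictions(base_all, mapping)              # (n,K,Lt)

    if "baseline" in cfg.strategies:
        t1 = time.perf_counter()
        try:
            m_te = mapped_all[te]
            for k in range(cfg.n_classifiers):
                rows.append(_auc_row("baseline", f"net{k}", m_te[:, k, :],
                                     tgt_y[te], target_names))
            for method in cfg.ensemble_methods:
                scores = _ensemble_scores(m_te, method)
                rows.append(_auc_row("baseline", method, scores, tgt_y[te],
                                     target_names))
                record(f"baseline_{method}", scores)
        except Exception as e:  # noqa: BLE001 - stage isolation
            errors["baseline"] = repr(e)
        timings["baseline"] = time.perf_counter() - t1

    if "stacking" in cfg.strategies:
        t1 = time.perf_counter()
        try:
            fit = transfer.fit_stacking(mapped_all[trva], tgt_y[trva],
                                        label_names=target_names,
                                        seed=child_seed(cfg.seed, 30))
            scores = np.nan_to_num(fit.predict(mapped_all[te]), nan=0.5)
            rows.append(_auc_row("stacking", "rf_meta", scores, tgt_y[te],
                                 target_names))
            record("stacking", scores)
        except Exception as e:  # noqa: BLE001
            errors["stacking"] = repr(e)
        timings["stacking"] = time.perf_counter() - t1

    if "embeddings" in cfg.strategies:
        t1 = time.perf_counter()
        try:
            embs = [transfer.extract_embeddings(net, Xt, extractor_id=f"net{k}")
                    for k, net in enumerate(nets)]
            for kind in cfg.tree_kinds:
                tcfg = TreeGridConfig(kind=kind, grids=cfg.tree_grids[kind],
                                      k_folds=cfg.tree_k_folds,
                                      seed=child_seed(cfg.seed, 40))
                per_net = []
                for emb in embs:
                    fit = transfer.fit_tree_classifier(
                        emb.values[trva], tgt_y[trva], tcfg,
                        label_names=target_names)
                    per_net.append(np.nan_to_num(fit.predict(emb.values[te]),
                                                 nan=0.5))
                stackk = np.stack(per_net, axis=1)  # (n_te, K, Lt)
                for method in cfg.ensemble_methods:
                    scores = _ensemble_scores(stackk, method)
                    rows.append(_auc_row("embeddings", f"{kind}+{method}",
                                         scores, tgt_y[te], target_names))
                    record(f"embeddings_{kind}_{method}", scores)
        except Exception as e:  # noqa: BLE001
            errors["embeddings"] = repr(e)
        timings["embeddings"] = time.perf_counter() - t1

    if "finetune" in cfg.strategies:
        t1 = time.perf_counter()
        try:
            ft_cfg = cfg.finetune
            tuned = []
            for k, net in enumerate(nets):
                ft = dataclasses.replace(ft_cfg, seed=child_seed(cfg.seed, 50 + k))
                model, _ = transfer.fine_tune(net, (Xt[tr], tgt_y[tr]),
                                              (Xt[va], tgt_y[va]), ft)
                tuned.append(model)
            ft_all = np.stack([m.predict_proba(Xt) for m in tuned], axis=1)
            for k in range(len(tuned)):
                rows.append(_auc_row("finetune", f"net{k}", ft_all[te][:, k, :],
                                     tgt_y[te], target_names))
            for method in cfg.ensemble_methods:
                scores = _ensemble_scores(ft_all[te], method)
                rows.append(_auc_row("finetune", method, scores, tgt_y[te],
                                     target_names))
                record(f"finetune_{method}", scores)
            sfit = transfer.fit_stacking(ft_all[trva], tgt_y[trva],
                                         label_names=target_names,
                                         seed=child_seed(cfg.seed, 60))
            scores = np.nan_to_num(sfit.predict(ft_all[te]), nan=0.5)
            rows.append(_auc_row("finetune", "stacking", scores, tgt_y[te],
                                 target_names))
            record("finetune_stacking", scores)
        except Exception as e:  # noqa: BLE001
            errors["finetune"] = repr(e)
        timings["finetune"] = time.perf_counter() - t1

    table = pd.DataFrame(rows)
    provenance = {
        "config": cfg.to_dict(), "config_hash": cfg.config_hash(),
        "seed": cfg.seed, "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "errors": errors,
        "split_sizes": {"train": len(tr), "val": len(va), "test": len(te)},
    }
    report = ComparisonReport(table=table, predictions=predictions,
                              provenance=provenance)
    if cfg.outdir:
        save_report(report, cfg.outdir)
    return report


def load_labels(path) -> pd.DataFrame:
    """Read a multi-label matrix from CSV (UTF-8, header, image_id column)."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"label file {path} is empty") from None
    if "image_id" not in df.columns:
        raise ValueError(f"label file {path} has no 'image_id' column")
    return df.set_index("image_id")


def save_report(report: ComparisonReport, outdir) -> list[Path]:
    """Write report.csv, report.json and per-strategy prediction CSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    p = outdir / "report.csv"
    report.table.to_csv(p, index=False)
    written.append(p)
    p = outdir / "report.json"
    payload = {"table": report.table.to_dict(orient="records"),
               "provenance": report.provenance}
    p.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))
    written.append(p)
    for tag, df in report.predictions.items():
        p = outdir / f"preds_{tag}.csv"
        df.to_csv(p)
        written.append(p)
    return written
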