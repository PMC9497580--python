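"""Label mapping, embedding extraction, tree grids, stacking, fine-tuning."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from cxrtransfer import (FineTuneConfig, LabelMapping, SyntheticEmbeddingSpec,
                         SyntheticPredictionSpec, TreeGridConfig,
                         extract_embeddings, fine_tune, fit_stacking,
                         fit_tree_classifier, generate_embeddings,
                         generate_predictions, map_predictions,
                         stratified_split)
from cxrtransfer.transfer import CHEXPERT_TO_TARGET


CHEXPERT_LABELS = ["no finding", "enlarged cardiomediastinum", "cardiomegaly",
                   "lung opacity", "lung lesion", "edema", "consolidation",
                   "pneumonia", "atelectasis", "pneumothorax",
                   "pleural effusion", "pleural other", "fracture",
                   "support devices"]


class TestMapping:
    def test_cardiac_is_max_of_its_two_sources(self):
        m = LabelMapping.from_names(CHEXPERT_LABELS, CHEXPERT_TO_TARGET)
        preds = np.zeros((1, len(CHEXPERT_LABELS)))
        preds[0, CHEXPERT_LABELS.index("enlarged cardiomediastinum")] = 0.3
        preds[0, CHEXPERT_LABELS.index("cardiomegaly")] = 0.7
        out = map_predictions(preds, m)
        assert out[0, m.target_labels.index("cardiac")] == pytest.approx(0.7)

    def test_singleton_mapping_is_identity_on_that_column(self):
        m = LabelMapping.from_names(CHEXPERT_LABELS, CHEXPERT_TO_TARGET)
        preds = np.random.default_rng(0).random((4, len(CHEXPERT_LABELS)))
        out = map_predictions(preds, m)
        j = m.target_labels.index("bone")
        np.testing.assert_array_equal(
            out[:, j], preds[:, CHEXPERT_LABELS.index("fracture")])

    def test_max_over_three_sources(self):
        m = LabelMapping(target_labels=["lung"], source_sets=[[0, 1, 2]])
        out = map_predictions(np.array([[0.2, 0.7, 0.4]]), m)
        assert out[0, 0] == pytest.approx(0.7)

    def test_empty_source_set_rejected(self):
        with pytest.raises(ValueError, match="empty source set"):
            LabelMapping(target_labels=["x"], source_sets=[[]])

    @given(st.integers(0, 2), st.floats(0, 1))
    def test_monotone_raising_source_never_lowers_target(self, idx, newval):
        m = LabelMapping(target_labels=["t"], source_sets=[[0, 1, 2]])
        base = np.array([[0.2, 0.5, 0.3]])
        before = map_predictions(base, m)[0, 0]
        bumped = base.copy()
        bumped[0, idx] = max(base[0, idx], newval)
        assert map_predictions(bumped, m)[0, 0] >= before


class TestExtractEmbeddings:
    def test_matches_brute_force_spatial_mean(self, blob_net):
        net = blob_net["net"]
        X = blob_net["test_X"][:8]
        emb = extract_embeddings(net, X, extractor_id="net")
        oracle = np.stack([net.conv_maps(X[i:i + 1])[0].mean(axis=(1, 2))
                           for i in range(8)])
        np.testing.assert_allclose(emb.values, oracle, atol=1e-6)
        assert emb.dim == net.embed_dim

    def test_deterministic_given_fixed_weights(self, blob_net):
        net, X = blob_net["net"], blob_net["test_X"][:4]
        a = extract_embeddings(net, X).values
        b = extract_embeddings(net, X).values
        np.testing.assert_array_equal(a, b)

    def test_model_without_conv_maps_rejected(self):
        with pytest.raises(TypeError):
            extract_embeddings(object(), np.zeros((1, 3, 8, 8)))


@pytest.fixture()
def separable(rng):
    labels = (rng.random((300, 2)) < 0.4).astype(np.int8)
    emb = generate_embeddings(SyntheticEmbeddingSpec(
        dim=8, dims_per_label=2, effect_size=5.0, noise_sd=1.0, seed=1), labels)
    return emb, labels


class TestTreeClassifier:
    def test_grid_of_size_one_is_selected(self, separable):
        emb, labels = separable
        cfg = TreeGridConfig(kind="DT", grids={"max_depth": [3]}, k_folds=2)
        fit = fit_tree_classifier(emb, labels, cfg)
        assert fit.best_params == {"max_depth": 3}

    def test_cv_table_is_exhaustive_product(self, separable):
        emb, labels = separable
        cfg = TreeGridConfig(kind="DT",
                             grids={"max_depth": [2, 5], "criterion":
                                    ["gini", "entropy"],
                                    "min_samples_leaf": [1, 2, 4]},
                             k_folds=2)
        fit = fit_tree_classifier(emb, labels, cfg)
        assert len(fit.cv_table) == 2 * 2 * 3

    def test_strong_embeddings_reach_high_test_auc(self, rng):
        labels = (rng.random((400, 2)) < 0.4).astype(np.int8)
        emb = generate_embeddings(SyntheticEmbeddingSpec(
            dim=8, dims_per_label=2, effect_size=5.0, noise_sd=1.0, seed=2),
            labels)
        tr, te = stratified_split(labels, (0.7, 0.3), seed=0)
        cfg = TreeGridConfig(kind="RF", grids={"max_depth": [5],
                                               "n_estimators": [50]},
                             k_folds=3, seed=0)
        fit = fit_tree_classifier(emb.values[tr], labels[tr], cfg)
        scores = fit.predict(emb.values[te])
        aucs = [roc_auc_score(labels[te][:, j], scores[:, j]) for j in range(2)]
        assert min(aucs) >= 0.95

    def test_single_class_label_skipped_with_warning(self, separable, caplog):
        emb, labels = separable
        labels = labels.copy()
        labels[:, 1] = 0
        cfg = TreeGridConfig(kind="DT", grids={"max_depth": [2]}, k_folds=2)
        fit = fit_tree_classifier(emb, labels, cfg,
                                  label_names=["ok", "degenerate"])
        assert fit.skipped_labels == ["degenerate"]
        assert np.isnan(fit.predict(emb.values)[:, 1]).all()

    def test_reproducible_under_fixed_seed(self, separable):
        emb, labels = separable
        cfg = TreeGridConfig(kind="RF", grids={"max_depth": [3, 5],
                                               "n_estimators": [20]},
                             k_folds=2, seed=9)
        a = fit_tree_classifier(emb, labels, cfg).predict(emb.values)
        b = fit_tree_classifier(emb, labels, cfg).predict(emb.values)
        np.testing.assert_array_equal(a, b)

    def test_grid_order_invariance(self, separable):
        """Reversing the grid axes' listing yields the same selection."""
        emb, labels = separable
        g1 = {"max_depth": [2, 5, 10], "min_samples_leaf": [1, 4]}
        g2 = {"min_samples_leaf": [4, 1], "max_depth": [10, 5, 2]}
        f1 = fit_tree_classifier(emb, labels, TreeGridConfig(
            kind="DT", grids=g1, k_folds=2, seed=3))
        f2 = fit_tree_classifier(emb, labels, TreeGridConfig(
            kind="DT", grids=g2, k_folds=2, seed=3))
        assert f1.best_params == f2.best_params


class TestStacking:
    def test_perfect_bases_give_perfect_test_auc(self, rng):
        labels = (rng.random((300, 2)) < 0.4).astype(np.int8)
        base = np.repeat(labels[:, None, :].astype(float), 3, axis=1)
        tr, te = stratified_split(labels, (0.7, 0.3), seed=1)
        fit = fit_stacking(base[tr], labels[tr], seed=0)
        scores = fit.predict(base[te])
        for j in range(2):
            assert roc_auc_score(labels[te][:, j], scores[:, j]) == 1.0

    def test_uninformative_bases_give_chance_auc(self, rng):
        labels = (rng.random((600, 1)) < 0.5).astype(np.int8)
        base = generate_predictions(SyntheticPredictionSpec(
            n_classifiers=3, calibration="uninformative", seed=2), labels)
        tr, te = stratified_split(labels, (0.7, 0.3), seed=1)
        fit = fit_stacking(base[tr], labels[tr], seed=0)
        auc = roc_auc_score(labels[te][:, 0], fit.predict(base[te])[:, 0])
        assert abs(auc - 0.5) < 0.12

    def test_feature_dimension_is_k_times_l(self, rng):
        labels = (rng.random((100, 3)) < 0.5).astype(np.int8)
        base = rng.random((100, 4, 3))
        fit = fit_stacking(base, labels, seed=0,
                           rf_params={"n_estimators": 5})
        assert fit.models["label_0"].n_features_in_ == 4 * 3

    def test_per_label_feature_mode(self, rng):
        labels = (rng.random((100, 3)) < 0.5).astype(np.int8)
        base = rng.random((100, 4, 3))
        fit = fit_stacking(base, labels, seed=0, per_label_features=True,
                           rf_params={"n_estimators": 5})
        assert fit.models["label_0"].n_features_in_ == 4


class TestFineTune:
    def test_lr_schedule_decays_by_ten_each_epoch(self, blob_net):
        cfg = FineTuneConfig(epochs=3, patience=3, seed=0)
        X, y = blob_net["X"][:60], blob_net["y"][:60]
        _, hist = fine_tune(blob_net["net"], (X, y), (X[:20], y[:20]), cfg)
        np.testing.assert_allclose(hist.lr, [1e-4, 1e-5, 1e-6])

    def test_empty_validation_rejected(self, blob_net):
        cfg = FineTuneConfig()
        with pytest.raises(ValueError, match="validation"):
            fine_tune(blob_net["net"], (blob_net["X"], blob_net["y"]),
                      (blob_net["X"][:0], blob_net["y"][:0]), cfg)

    def test_blob_task_fine_tune_reaches_high_val_auc(self, blob_net):
        """Source-trained net, fresh head, short protocol: val AUC >= 0.9."""
        X, y = blob_net["test_X"], blob_net["test_y"]
        tr, va = np.arange(0, 140), np.arange(140, 200)
        tuned, hist = fine_tune(blob_net["net"], (X[tr], y[tr]),
                                (X[va], y[va]), FineTuneConfig(seed=1))
        assert max(hist.val_auc) >= 0.9
        assert tuned.n_labels == 1

    def test_head_replacement_sizes_outputs(self, blob_net):
        net = blob_net["net"].copy()
        net.replace_head(4, seed=0)
        p = net.predict_proba(blob_net["test_X"][:2])
        assert p.shape == (2, 4)


class TestStratifiedSplit:
    def test_fractions_and_coverage(self, rng):
        labels = (rng.random((200, 2)) < [0.5, 0.1]).astype(np.int8)
        tr, va, te = stratified_split(labels, (0.7, 0.1, 0.2), seed=0)
        assert len(tr) + len(va) + len(te) == 200
        assert len(np.intersect1d(tr, te)) == 0
        assert abs(len(tr) - 140) <= 2
        # rarest label present in every part
        for part in (tr, va, te):
            assert labels[part][:, 1].sum() > 0

    def test_deterministic(self, rng):
        labels = (rng.random((100, 1)) < 0.3).astype(np.int8)
        a = stratified_split(labels, (0.7, 0.3), seed=5)
        b = stratified_split(labels, (0.7, 0.3), seed=5)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)
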