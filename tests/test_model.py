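"""Stratified splitting, CNN training, feature extraction, and the XGB head."""

import numpy as np
import pytest

from conftest import make_window
from fallwatch.model import (
    CnnConfig,
    FallPipeline,
    SplitSpec,
    TrainConfig,
    XgbSearchSpace,
    build_cnn,
    extract_features,
    stratified_split,
    train_cnn,
    tune_and_train_xgb,
    windows_to_arrays,
)

L_SMALL = 40  # short windows keep these tests fast
SMALL_CNN = CnnConfig(filters_per_layer=8)


def separable_windows(rng, n_per_class=30, labels=("A", "B")):
    """Two classes distinguished by a strong low- vs high-frequency component."""
    out = []
    t = np.arange(L_SMALL)
    for ci, label in enumerate(labels):
        freq = 0.05 if ci == 0 else 0.25
        for i in range(n_per_class):
            base = 3.0 * np.sin(2 * np.pi * freq * t + rng.uniform(0, 6.28))
            samples = base[:, None] + 0.05 * rng.normal(size=(L_SMALL, 6))
            out.append(make_window(samples, label=label, rid=f"{label}{i}"))
    return out


class TestStratifiedSplit:
    def test_exact_fractions_single_class(self, rng):
        ws = [make_window(np.zeros((10, 6)), label="W") for _ in range(100)]
        tr, va, te = stratified_split(ws, SplitSpec(seed=0))
        assert (len(tr), len(va), len(te)) == (70, 15, 15)

    def test_per_class_proportions(self, rng):
        ws = [make_window(np.zeros((10, 6)), label=l) for l in ["A"] * 20 + ["B"] * 20]
        tr, va, te = stratified_split(ws, SplitSpec(seed=1))
        for split, size in [(tr, 14), (va, 3), (te, 3)]:
            labels = [w.label for w in split]
            assert labels.count("A") == size
            assert labels.count("B") == size

    def test_partition_disjoint_exhaustive(self, rng):
        ws = [make_window(np.zeros((10, 6)), label="A", rid=f"r{i}") for i in range(17)]
        tr, va, te = stratified_split(ws, SplitSpec(seed=2))
        ids = [w.source[0] for w in tr + va + te]
        assert sorted(ids) == sorted(w.source[0] for w in ws)
        assert len(set(ids)) == 17

    def test_deterministic_given_seed(self):
        ws = [make_window(np.zeros((10, 6)), label="A", rid=f"r{i}") for i in range(20)]
        a = stratified_split(ws, SplitSpec(seed=5))
        b = stratified_split(ws, SplitSpec(seed=5))
        for sa, sb in zip(a, b):
            assert [w.source for w in sa] == [w.source for w in sb]

    def test_small_class_named_in_error(self):
        ws = [make_window(np.zeros((10, 6)), label="LHF")] * 2
        with pytest.raises(ValueError, match="LHF"):
            stratified_split(ws, SplitSpec())

    def test_tiny_classes_get_all_three_splits(self):
        ws = [make_window(np.zeros((10, 6)), label="A", rid=f"r{i}") for i in range(4)]
        tr, va, te = stratified_split(ws, SplitSpec(seed=0))
        assert len(tr) >= 1 and len(va) >= 1 and len(te) >= 1


class TestTrainCnn:
    def test_separable_classes_reach_perfect_validation_uar(self, rng):
        ws = separable_windows(rng)
        tr, va, _ = stratified_split(ws, SplitSpec(seed=0))
        model = build_cnn(SMALL_CNN, L_SMALL, n_classes=2, seed=0)
        model, history = train_cnn(model, tr, va, TrainConfig(max_epochs=50, patience=50, seed=0),
                                   ("A", "B"))
        assert max(history) == pytest.approx(1.0)

    def test_patience_zero_trains_exactly_one_epoch(self, rng):
        ws = separable_windows(rng, n_per_class=6)
        model = build_cnn(SMALL_CNN, L_SMALL, n_classes=2, seed=0)
        _, history = train_cnn(model, ws, ws, TrainConfig(max_epochs=10, patience=0, seed=0),
                               ("A", "B"))
        assert len(history) == 1

    def test_history_bounded_by_max_epochs(self, rng):
        ws = separable_windows(rng, n_per_class=5)
        model = build_cnn(SMALL_CNN, L_SMALL, n_classes=2, seed=0)
        _, history = train_cnn(model, ws, ws, TrainConfig(max_epochs=3, patience=3, seed=0),
                               ("A", "B"))
        assert len(history) <= 3

    def test_returned_state_is_best_recorded(self, rng):
        """Early stopping restores the state whose validation UAR tops the history."""
        ws = separable_windows(rng, n_per_class=10)
        tr, va, _ = stratified_split(ws, SplitSpec(seed=1))
        model = build_cnn(SMALL_CNN, L_SMALL, n_classes=2, seed=1)
        model, history = train_cnn(model, tr, va, TrainConfig(max_epochs=15, patience=15, seed=1),
                                   ("A", "B"))
        x_val, y_val = windows_to_arrays(va, ("A", "B"))
        feats_logits = model.forward(x_val.astype(np.float32), train=False)
        pred = feats_logits.argmax(axis=1)
        recalls = [float((pred[y_val == c] == c).mean()) for c in np.unique(y_val)]
        assert np.mean(recalls) == pytest.approx(max(history))

    def test_empty_split_rejected(self, rng):
        model = build_cnn(SMALL_CNN, L_SMALL, n_classes=2)
        with pytest.raises(ValueError):
            train_cnn(model, [], [], TrainConfig(), ("A", "B"))


class TestExtractFeatures:
    def test_feature_columns_and_determinism(self, rng):
        model = build_cnn(SMALL_CNN, L_SMALL, n_classes=2, seed=0)
        w = make_window(rng.normal(size=(L_SMALL, 6)), label="A")
        feats = extract_features(model, [w, w, w])
        assert feats.shape[0] == 3
        assert np.array_equal(feats[0], feats[1])

    def test_empty_input_keeps_column_count(self):
        from fallwatch.model import feature_dim

        model = build_cnn(SMALL_CNN, L_SMALL, n_classes=2)
        feats = extract_features(model, [])
        assert feats.shape == (0, feature_dim(SMALL_CNN, L_SMALL))

    def test_length_mismatch_rejected(self, rng):
        model = build_cnn(SMALL_CNN, L_SMALL, n_classes=2)
        w = make_window(rng.normal(size=(L_SMALL + 4, 6)), label="A")
        with pytest.raises(ValueError):
            extract_features(model, [w])

    def test_features_independent_of_head(self, rng):
        """Swapping the softmax head never changes the extractor's outputs."""
        model = build_cnn(SMALL_CNN, L_SMALL, n_classes=2, seed=0)
        w = make_window(rng.normal(size=(L_SMALL, 6)), label="A")
        before = extract_features(model, [w])
        for p in model.head.params:
            p[...] = rng.normal(size=p.shape).astype(np.float32)
        after = extract_features(model, [w])
        assert np.array_equal(before, after)


class TestXgbHead:
    def _features(self, rng, n=40):
        x = rng.normal(size=(n, 8)).astype(np.float32)
        y = (x[:, 0] > 0).astype(np.int64)
        x[:, 1] = y * 5.0  # make the problem trivially separable
        return x, y

    def test_singleton_space_is_chosen(self, rng):
        x, y = self._features(rng)
        space = XgbSearchSpace(n_estimators=(50,), max_depth=(3,), learning_rate=(0.3,))
        _, params = tune_and_train_xgb(x, y, x, y, space, seed=0)
        assert params == {"n_estimators": 50, "max_depth": 3, "learning_rate": 0.3}

    def test_separable_features_perfect_validation(self, rng):
        x, y = self._features(rng)
        space = XgbSearchSpace(n_estimators=(50, 100), max_depth=(3,), learning_rate=(0.3,))
        clf, _ = tune_and_train_xgb(x, y, x, y, space, seed=0)
        assert (clf.predict(x) == y).all()

    def test_deterministic_choice(self, rng):
        x, y = self._features(rng)
        space = XgbSearchSpace(n_estimators=(20, 50), max_depth=(2, 3), learning_rate=(0.3,))
        _, p1 = tune_and_train_xgb(x, y, x, y, space, seed=4)
        _, p2 = tune_and_train_xgb(x, y, x, y, space, seed=4)
        assert p1 == p2

    def test_tie_breaks_toward_fewer_trees(self, rng):
        x, y = self._features(rng)
        space = XgbSearchSpace(n_estimators=(20, 200), max_depth=(2, 6), learning_rate=(0.3,))
        _, params = tune_and_train_xgb(x, y, x, y, space, seed=0)
        # trivially separable: every candidate scores 1.0, smallest wins
        assert params["n_estimators"] == 20 and params["max_depth"] == 2

    def test_degenerate_labels_rejected(self, rng):
        x = rng.normal(size=(10, 4)).astype(np.float32)
        y = np.zeros(10, dtype=np.int64)
        with pytest.raises(ValueError):
            tune_and_train_xgb(x, y, x, y, XgbSearchSpace(), seed=0)


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(7)
    ws = separable_windows(rng, n_per_class=20)
    model = build_cnn(SMALL_CNN, L_SMALL, n_classes=2, seed=0)
    model, _ = train_cnn(model, ws, ws, TrainConfig(max_epochs=20, patience=20, seed=0),
                         ("A", "B"))
    feats = extract_features(model, ws)
    _, y = windows_to_arrays(ws, ("A", "B"))
    space = XgbSearchSpace(n_estimators=(50,), max_depth=(3,), learning_rate=(0.3,))
    clf, params = tune_and_train_xgb(feats, y, feats, y, space, seed=0)
    pipe = FallPipeline(cnn=model, xgb=clf, class_order=("A", "B"),
                        cnn_cfg=SMALL_CNN, xgb_params=params)
    return pipe, ws


class TestPipeline:
    def test_training_labels_recovered(self, fitted):
        pipe, ws = fitted
        assert pipe.predict(ws) == [w.label for w in ws]

    def test_output_length_and_permutation_equivariance(self, fitted, rng):
        pipe, ws = fitted
        perm = rng.permutation(len(ws))
        pred = pipe.predict(ws)
        pred_perm = pipe.predict([ws[i] for i in perm])
        assert len(pred) == len(ws)
        assert pred_perm == [pred[i] for i in perm]

    def test_save_load_round_trip(self, fitted, tmp_path):
        pipe, ws = fitted
        pipe.save(tmp_path / "model")
        again = FallPipeline.load(tmp_path / "model")
        assert again.class_order == pipe.class_order
        assert again.predict(ws) == pipe.predict(ws)
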