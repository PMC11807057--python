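import numpy as np
import pandas as pd
import pytest

from cyanobench import (
    ClassifierConfig,
    ImageStack,
    LabeledMask,
    PhenotypeSpec,
    build_network,
    classify_cells,
    evaluate_classification,
    extract_patch,
    generate_phenotype_dataset,
    load_checkpoint,
    recolor_mask,
    save_checkpoint,
    train,
)


class TestNetworkConstruction:
    def test_forward_gives_normalized_probabilities(self):
        cfg = ClassifierConfig(n_channels=5, n_classes=4, seed=0)
        model = build_network(cfg)
        patch = np.random.default_rng(0).uniform(0, 255, (32, 32, 5))
        probs = model.predict_proba(patch)
        assert probs.shape == (1, 4)
        assert probs.min() >= 0
        assert abs(probs.sum() - 1.0) < 1e-6

    def test_initialization_deterministic_under_seed(self):
        cfg = ClassifierConfig(n_channels=2, n_classes=3, seed=123)
        a, b = build_network(cfg), build_network(cfg)
        for k, v in a.net.named_params().items():
            assert np.array_equal(v, b.net.named_params()[k])
        x = np.random.default_rng(1).normal(size=(3, 32, 32, 2))
        assert np.array_equal(a.predict_proba(x), b.predict_proba(x))

    def test_fully_connected_input_is_512_for_default_filters(self):
        # 32 -> 16 -> 8 -> 4 -> 2 spatial; 2*2*128 = 512
        cfg = ClassifierConfig(n_channels=2, n_classes=4)
        model = build_network(cfg)
        fc = model.net.layers[-1]
        assert fc.w.shape == (4, 512)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ClassifierConfig(patch_size=24)
        with pytest.raises(ValueError):
            ClassifierConfig(n_channels=7)
        with pytest.raises(ValueError):
            ClassifierConfig(conv_filters=(8, 8, 8))


class TestTraining:
    def test_zero_epochs_leaves_parameters_unchanged(self):
        cfg = ClassifierConfig(n_channels=2, n_classes=2, max_epochs=0, seed=0)
        model = build_network(cfg)
        before = {k: v.copy() for k, v in model.net.named_params().items()}
        X, y, *_ = generate_phenotype_dataset(
            4, [PhenotypeSpec("a", "none"), PhenotypeSpec("b", "diffuse")], seed=0
        )
        train(model, X, y)
        for k, v in model.net.named_params().items():
            assert np.array_equal(v, before[k])
        assert model.training_history == []

    def test_separable_two_class_set_is_learned(self):
        # unlabeled vs bright-focus cells are linearly separable in total
        # fluorescence; a short run should fit the training set
        specs = [PhenotypeSpec("dark", "none"),
                 PhenotypeSpec("bright", "focus", intensity_mean=200.0)]
        X, y, *_ = generate_phenotype_dataset(40, specs, seed=5)
        cfg = ClassifierConfig(n_channels=2, n_classes=2, max_epochs=25, seed=0)
        model = build_network(cfg, ("dark", "bright"))
        train(model, X, y)
        assert model.training_history[-1]["accuracy"] >= 0.95
        assert model.training_history[-1]["loss"] <= model.training_history[0]["loss"]

    def test_missing_class_warns(self):
        cfg = ClassifierConfig(n_channels=2, n_classes=3, max_epochs=1, seed=0)
        model = build_network(cfg)
        X = np.random.default_rng(0).normal(size=(8, 32, 32, 2)).astype(np.float32)
        y = np.zeros(8, dtype=int)
        with pytest.warns(UserWarning, match="absent"):
            train(model, X, y)

    def test_training_reproducible_under_seed(self):
        specs = [PhenotypeSpec("a", "none"), PhenotypeSpec("b", "diffuse")]
        X, y, *_ = generate_phenotype_dataset(10, specs, seed=2)
        cfg = ClassifierConfig(n_channels=2, n_classes=2, max_epochs=3, seed=7)
        h = []
        for _ in range(2):
            m = build_network(cfg, ("a", "b"))
            train(m, X, y)
            h.append(m.history_hash())
        assert h[0] == h[1]


class TestPatchExtraction:
    def _stack_mask(self, h=200, w=200):
        rng = np.random.default_rng(0)
        img = np.arange(h * w, dtype=float).reshape(h, w)
        stack = ImageStack((img, rng.uniform(size=(h, w))))
        px = np.zeros((h, w), dtype=np.int32)
        return stack, px

    def test_centered_object_window_arithmetic(self):
        stack, px = self._stack_mask()
        px[98:103, 98:103] = 9  # centroid exactly (100, 100)
        mask = LabeledMask(px)
        patch = extract_patch(stack, mask, 9)
        assert patch.shape == (32, 32, 2)
        # rows 84..115, cols 84..115 of the original image
        assert np.array_equal(patch[:, :, 0], stack.channels[0][84:116, 84:116])

    def test_corner_object_uses_reflection_padding(self):
        stack, px = self._stack_mask()
        px[0:2, 0:2] = 1
        patch = extract_patch(stack, LabeledMask(px), 1)
        assert patch.shape == (32, 32, 2)
        assert np.isfinite(patch).all()

    def test_constant_image_gives_constant_patch(self):
        img = np.full((64, 64), 3.5)
        stack = ImageStack((img,))
        px = np.zeros((64, 64), dtype=np.int32)
        px[30:34, 30:34] = 2
        patch = extract_patch(stack, LabeledMask(px), 2)
        assert (patch == 3.5).all()

    def test_missing_label_raises(self):
        stack, px = self._stack_mask()
        with pytest.raises(KeyError):
            extract_patch(stack, LabeledMask(px), 5)


@pytest.fixture(scope="module")
def model():
    cfg = ClassifierConfig(n_channels=2, n_classes=4, max_epochs=0, seed=0)
    return build_network(cfg)


class TestClassifyCells:

    def test_empty_mask_empty_table(self, model):
        stack = ImageStack((np.zeros((64, 64)), np.zeros((64, 64))))
        mask = LabeledMask(np.zeros((64, 64), dtype=np.int32))
        table = classify_cells(model, stack, mask)
        assert len(table) == 0
        assert "predicted_class" in table.columns

    def test_one_row_per_object_probs_sum_to_one(self, model):
        from cyanobench import generate_classified_frame

        stack, mask, _ = generate_classified_frame(15, 192, seed=3)
        table = classify_cells(model, stack, mask)
        assert len(table) == mask.n_objects
        prob_cols = [c for c in table.columns if c.startswith("prob_")]
        assert np.allclose(table[prob_cols].sum(axis=1), 1.0, atol=1e-6)
        assert (
            table[prob_cols].to_numpy().argmax(axis=1)
            == table["predicted_class"].to_numpy()
        ).all()

    def test_channel_mismatch_raises(self, model):
        stack = ImageStack((np.zeros((64, 64)),))
        mask = LabeledMask(np.zeros((64, 64), dtype=np.int32))
        with pytest.raises(ValueError, match="channels"):
            classify_cells(model, stack, mask)

    def test_label_permutation_permutes_rows_only(self, model):
        from cyanobench import generate_classified_frame

        stack, mask, _ = generate_classified_frame(10, 160, seed=9)
        table = classify_cells(model, stack, mask)
        shifted = LabeledMask(np.where(mask.pixels > 0, mask.pixels + 100, 0))
        table2 = classify_cells(model, stack, shifted)
        a = table.sort_values("label").reset_index(drop=True)
        b = table2.sort_values("label").reset_index(drop=True)
        assert np.array_equal(a["label"] + 100, b["label"])
        assert np.array_equal(
            a["predicted_class"].to_numpy(), b["predicted_class"].to_numpy()
        )


class TestRecolor:
    def _table(self, labels, classes, names=("a", "b", "c", "d")):
        return pd.DataFrame(
            {"frame": 0, "label": labels, "predicted_class": classes,
             "predicted_name": [names[c] for c in classes]}
        )

    def test_class_codes_are_index_plus_one(self):
        px = np.zeros((6, 6), dtype=np.int32)
        px[0:2, 0:2] = 4
        px[4:6, 4:6] = 9
        mask = LabeledMask(px)
        out = recolor_mask(mask, self._table([4, 9], [0, 3]))
        assert set(np.unique(out)) == {0, 1, 4}
        assert (out[px == 4] == 1).all() and (out[px == 9] == 4).all()

    def test_uniform_prediction_two_values(self):
        px = np.zeros((4, 4), dtype=np.int32)
        px[0, 0] = 1
        px[3, 3] = 2
        out = recolor_mask(LabeledMask(px), self._table([1, 2], [2, 2]))
        assert set(np.unique(out)) == {0, 3}

    def test_empty_mask_all_zero(self):
        out = recolor_mask(
            LabeledMask(np.zeros((4, 4), dtype=np.int32)), self._table([], [])
        )
        assert (out == 0).all()

    def test_missing_label_listed_in_error(self):
        px = np.zeros((4, 4), dtype=np.int32)
        px[0, 0] = 7
        with pytest.raises(KeyError, match="7"):
            recolor_mask(LabeledMask(px), self._table([1], [0]))


class TestEvaluation:
    def _tables(self, truth_classes, pred_classes):
        n = len(truth_classes)
        table = pd.DataFrame(
            {"frame": 0, "label": np.arange(1, n + 1),
             "predicted_class": pred_classes}
        )
        truth = pd.DataFrame(
            {"frame": 0, "label": np.arange(1, n + 1), "true_class": truth_classes}
        )
        return table, truth

    def test_perfect_predictions(self):
        t, u = self._tables([0, 1, 2, 3], [0, 1, 2, 3])
        s = evaluate_classification(t, u, ("a", "b", "c", "d"))
        assert np.array_equal(s.confusion, np.eye(4, dtype=int))
        assert s.accuracy == s.precision == s.recall == s.iou == 1.0

    def test_constant_predictor_uniform_truth(self):
        t, u = self._tables([0, 1, 2, 3] * 5, [0] * 20)
        s = evaluate_classification(t, u, ("a", "b", "c", "d"))
        assert s.accuracy == 0.25
        assert s.confusion[:, 0].sum() == 20

    def test_two_class_hand_computed_contingency(self):
        # 10 cells per class, 8 correct + 2 crossed each way
        truth = [0] * 10 + [1] * 10
        pred = [0] * 8 + [1] * 2 + [1] * 8 + [0] * 2
        t, u = self._tables(truth, pred)
        s = evaluate_classification(t, u, ("a", "b"))
        assert s.confusion.tolist() == [[8, 2], [2, 8]]
        assert s.precision == s.recall == 0.8
        assert s.iou == pytest.approx(16 / 24)
        # per-class Jaccard for either class is 8/12
        tp, fp, fn = 8, 2, 2
        assert tp / (tp + fp + fn) == pytest.approx(2 / 3)

    def test_row_sums_equal_truth_counts(self):
        rng = np.random.default_rng(0)
        truth = rng.integers(0, 3, 30)
        pred = rng.integers(0, 3, 30)
        t, u = self._tables(truth, pred)
        s = evaluate_classification(t, u, ("a", "b", "c"))
        assert s.confusion.sum(axis=1).tolist() == np.bincount(truth, minlength=3).tolist()

    def test_key_mismatch_lists_offenders(self):
        t, u = self._tables([0, 1], [0, 1])
        u2 = u.copy()
        u2["label"] = [1, 99]
        with pytest.raises(KeyError, match="99"):
            evaluate_classification(t, u2)


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tmp_path):
        specs = [PhenotypeSpec("a", "none"), PhenotypeSpec("b", "diffuse")]
        X, y, *_ = generate_phenotype_dataset(8, specs, seed=4)
        cfg = ClassifierConfig(n_channels=2, n_classes=2, max_epochs=2, seed=1)
        model = build_network(cfg, ("a", "b"))
        train(model, X, y)
        path = tmp_path / "model.ckpt"
        save_checkpoint(model, path)
        back = load_checkpoint(path)
        assert back.class_names == ("a", "b")
        assert back.config == model.config
        assert np.allclose(back.predict_proba(X), model.predict_proba(X))
        assert back.training_history == model.training_history
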