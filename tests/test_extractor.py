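"""The recurrent extractor: determinism, training contracts, feature extraction."""
import numpy as np
import pytest

from proptl.extractor import (
    ExtractorConfig,
    ExtractorError,
    TrainedExtractor,
    build_extractor,
    extract_features,
    fine_tune,
    pretrain,
)
from proptl.windows import EncodedBatch


def _weights(model):
    return [p.data.copy() for p in model.params()]


def _same(a, b):
    return all(np.array_equal(x, y) for x, y in zip(a, b))


class TestBuild:
    def test_same_seed_identical_weights(self, tiny_config):
        assert _same(_weights(build_extractor(tiny_config)),
                     _weights(build_extractor(tiny_config)))

    def test_different_seed_different_weights(self, tiny_config):
        from dataclasses import replace
        other = build_extractor(replace(tiny_config, seed=8))
        assert not _same(_weights(build_extractor(tiny_config)), _weights(other))

    def test_feature_and_output_shapes(self, tiny_config, rng):
        model = build_extractor(tiny_config)
        X = rng.integers(0, 21, size=(9, tiny_config.window_size))
        feats, logits = model.forward(X)
        assert feats.shape == (9, tiny_config.dense_units)
        assert logits.shape == (9, 1)
        proba = model.predict_proba(X)
        assert ((proba > 0) & (proba < 1)).all()

    def test_invalid_config_rejected(self):
        with pytest.raises(ExtractorError):
            ExtractorConfig(window_size=10).validate()
        with pytest.raises(ExtractorError):
            ExtractorConfig(dropout_rate=1.0).validate()


class TestPretrain:
    def test_zero_epochs_is_noop_on_weights(self, tiny_config, planted_batch):
        model = build_extractor(tiny_config)
        before = _weights(model)
        pretrain(model, planted_batch, epochs=0)
        assert _same(before, _weights(model))
        assert model.provenance == "pretrained-only"
        assert model.history["pretrain"] == []

    def test_loss_history_has_one_entry_per_epoch(self, tiny_config, planted_batch):
        model = pretrain(build_extractor(tiny_config), planted_batch)
        assert len(model.history["pretrain"]) == tiny_config.epochs

    def test_training_reduces_loss(self, tiny_config, planted_batch):
        model = pretrain(build_extractor(tiny_config), planted_batch, epochs=5)
        history = model.history["pretrain"]
        assert history[-1] <= history[0]

    def test_separable_motif_reaches_high_training_accuracy(self, planted_batch):
        """Planted deterministic motif: >=0.95 training accuracy within 10 epochs."""
        cfg = ExtractorConfig(window_size=11, embedding_dim=8, lstm_units=8,
                              gru_units=6, dense_units=16, dropout_rate=0.1,
                              epochs=10, batch_size=64, validation_fraction=0.0,
                              patience=0, seed=3)
        model = pretrain(build_extractor(cfg), planted_batch)
        acc = ((model.predict_proba(planted_batch.matrix) > 0.5)
               == planted_batch.labels).mean()
        assert acc >= 0.95

    def test_empty_batch_rejected(self, tiny_config):
        empty = EncodedBatch(np.zeros((0, 11), dtype=int), np.zeros(0, dtype=int))
        with pytest.raises(ExtractorError, match="empty"):
            pretrain(build_extractor(tiny_config), empty)


class TestFineTune:
    def test_requires_pretrained_model(self, tiny_config, planted_batch):
        with pytest.raises(ExtractorError, match="pretrained-only"):
            fine_tune(build_extractor(tiny_config), planted_batch)

    def test_cannot_fine_tune_twice(self, tiny_config, planted_batch):
        model = pretrain(build_extractor(tiny_config), planted_batch, epochs=1)
        fine_tune(model, planted_batch, epochs=1)
        with pytest.raises(ExtractorError, match="pretrained-only"):
            fine_tune(model, planted_batch, epochs=1)

    def test_continued_training_on_same_task_does_not_increase_loss(
        self, tiny_config, planted_batch
    ):
        model = pretrain(build_extractor(tiny_config), planted_batch, epochs=5)
        pre_loss = model.history["pretrain"][-1]
        fine_tune(model, planted_batch, epochs=5)
        assert model.history["finetune"][-1] <= pre_loss + 0.02

    def test_window_width_mismatch_rejected(self, tiny_config, planted_batch, rng):
        model = pretrain(build_extractor(tiny_config), planted_batch, epochs=0)
        wrong = EncodedBatch(rng.integers(0, 21, size=(8, 13)),
                             rng.integers(0, 2, size=8))
        with pytest.raises(ExtractorError, match="window size"):
            fine_tune(model, wrong)

    def test_architecture_unchanged_by_fine_tuning(self, tiny_config, planted_batch):
        model = pretrain(build_extractor(tiny_config), planted_batch, epochs=1)
        shapes_before = [p.data.shape for p in model.params()]
        fine_tune(model, planted_batch, epochs=1)
        assert [p.data.shape for p in model.params()] == shapes_before


class TestDropoutContract:
    def test_training_passes_differ_inference_passes_do_not(self, planted_batch):
        cfg = ExtractorConfig(window_size=11, embedding_dim=4, lstm_units=4,
                              gru_units=3, dense_units=8, dropout_rate=0.5,
                              epochs=1, seed=5)
        model = build_extractor(cfg)
        X = planted_batch.matrix[:16]
        rng = np.random.default_rng(0)
        _, train1 = model.forward(X, training=True, rng=rng)
        _, train2 = model.forward(X, training=True, rng=rng)
        assert not np.array_equal(train1.data, train2.data)
        _, inf1 = model.forward(X, training=False)
        _, inf2 = model.forward(X, training=False)
        assert np.array_equal(inf1.data, inf2.data)


class TestExtractFeatures:
    def test_shape_and_row_order(self, tiny_config, planted_batch):
        model = pretrain(build_extractor(tiny_config), planted_batch, epochs=1)
        feats = extract_features(model, planted_batch)
        assert feats.shape == (len(planted_batch), tiny_config.dense_units)
        assert np.isfinite(feats).all()

    def test_deterministic_and_rowwise(self, tiny_config, planted_batch):
        model = pretrain(build_extractor(tiny_config), planted_batch, epochs=1)
        sub = planted_batch.subset(np.array([0, 1, 0]))  # duplicated first window
        feats1 = extract_features(model, sub)
        feats2 = extract_features(model, sub)
        assert np.array_equal(feats1, feats2)
        assert np.array_equal(feats1[0], feats1[2])

    def test_untrained_model_warns(self, tiny_config, planted_batch):
        with pytest.warns(UserWarning, match="untrained"):
            extract_features(build_extractor(tiny_config), planted_batch.subset(np.arange(4)))


class TestReproducibilityAndPersistence:
    def test_full_pipeline_is_bitwise_reproducible(self, tiny_config, planted_batch):
        runs = []
        for _ in range(2):
            model = pretrain(build_extractor(tiny_config), planted_batch, epochs=2)
            fine_tune(model, planted_batch, epochs=1)
            runs.append(extract_features(model, planted_batch))
        assert np.array_equal(runs[0], runs[1])

    def test_save_load_round_trip(self, tiny_config, planted_batch, tmp_path):
        model = pretrain(build_extractor(tiny_config), planted_batch, epochs=1)
        path = tmp_path / "ckpt.npz"
        model.save(path)
        loaded = TrainedExtractor.load(path)
        assert loaded.provenance == "pretrained-only"
        assert np.array_equal(extract_features(model, planted_batch),
                              extract_features(loaded, planted_batch))
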