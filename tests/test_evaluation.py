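"""Metrics, ROC/AUC, pipeline cross-validation, and the window-size sweep."""
import numpy as np
import pytest
from sklearn.metrics import matthews_corrcoef

from proptl.evaluation import (
    ConfusionCounts,
    EvaluationError,
    PipelineSpec,
    confusion,
    kfold_cv,
    metrics,
    roc_auc,
    window_size_sweep,
)
from proptl.extractor import ExtractorConfig
from proptl.synthetic import MotifSpec, generate_proteome, plant_sites
from proptl.windows import encode, flank_from_size, segment_dataset


def _cheap_spec(window_size=11, epochs=3, **kwargs):
    cfg = ExtractorConfig(window_size=window_size, embedding_dim=6, lstm_units=6,
                          gru_units=4, dense_units=12, dropout_rate=0.1,
                          epochs=epochs, batch_size=128, validation_fraction=0.0,
                          patience=0, seed=2)
    return PipelineSpec(extractor_config=cfg, **kwargs)


class TestConfusion:
    def test_all_correct_positives(self):
        c = confusion([1] * 5, [1] * 5)
        assert (c.TP, c.TN, c.FP, c.FN) == (5, 0, 0, 0)

    def test_complement_prediction(self):
        truth = [1, 0, 1, 0]
        c = confusion(truth, [1 - t for t in truth])
        assert c.TP == 0 and c.TN == 0 and c.FP == 2 and c.FN == 2

    def test_matches_pairwise_counting_oracle(self, rng):
        truth = rng.integers(0, 2, 1000)
        pred = rng.integers(0, 2, 1000)
        c = confusion(truth, pred)
        brute = {"TP": 0, "TN": 0, "FP": 0, "FN": 0}
        for t, p in zip(truth, pred):
            brute[{(1, 1): "TP", (0, 0): "TN", (0, 1): "FP", (1, 0): "FN"}[(t, p)]] += 1
        assert (c.TP, c.TN, c.FP, c.FN) == tuple(brute[k] for k in ("TP", "TN", "FP", "FN"))
        assert c.n == 1000

    def test_length_mismatch(self):
        with pytest.raises(EvaluationError, match="mismatch"):
            confusion([1, 0], [1])


class TestMetrics:
    def test_perfect_prediction(self):
        r = metrics(ConfusionCounts(TP=50, TN=50, FP=0, FN=0))
        assert (r.SN, r.SP, r.ACC, r.MCC) == (1.0, 1.0, 1.0, 1.0)

    def test_mcc_equals_pearson_correlation(self, rng):
        for _ in range(300):
            n = int(rng.integers(10, 60))
            truth = rng.integers(0, 2, n)
            pred = rng.integers(0, 2, n)
            c = confusion(truth, pred)
            if len(set(truth)) < 2 or len(set(pred)) < 2:
                continue
            assert metrics(c).MCC == pytest.approx(np.corrcoef(truth, pred)[0, 1], abs=1e-12)
            assert metrics(c).MCC == pytest.approx(matthews_corrcoef(truth, pred), abs=1e-12)

    def test_mcc_symmetric_under_class_swap(self, rng):
        c = ConfusionCounts(TP=31, TN=18, FP=7, FN=11)
        swapped = ConfusionCounts(TP=c.TN, TN=c.TP, FP=c.FN, FN=c.FP)
        assert metrics(c).MCC == pytest.approx(metrics(swapped).MCC, abs=1e-15)

    def test_zero_denominator_flags_metric_as_zero(self):
        r = metrics(ConfusionCounts(TP=0, TN=4, FP=0, FN=0))
        assert r.SN == 0.0 and r.MCC == 0.0
        assert "SN" in r.flags and "MCC" in r.flags

    def test_all_zero_counts_rejected(self):
        with pytest.raises(EvaluationError):
            metrics(ConfusionCounts(0, 0, 0, 0))


class TestROC:
    def test_perfect_scores(self):
        truth = np.r_[np.ones(10), np.zeros(10)].astype(int)
        _, auc = roc_auc(truth.astype(float), truth)
        assert auc == 1.0

    def test_uninformative_scores_near_half(self, rng):
        truth = rng.integers(0, 2, 1000)
        scores = rng.normal(size=1000)
        _, auc = roc_auc(scores, truth)
        assert abs(auc - 0.5) < 0.06

    def test_equals_mann_whitney_pair_statistic(self, rng):
        truth = np.r_[np.ones(25), np.zeros(25)].astype(int)
        scores = rng.normal(size=50) + truth  # overlapping classes, some ties unlikely
        scores[::7] = np.round(scores[::7])  # force a few ties
        _, auc = roc_auc(scores, truth)
        pos, neg = scores[truth == 1], scores[truth == 0]
        pairs = sum((1.0 if p > q else 0.5 if p == q else 0.0) for p in pos for q in neg)
        assert auc == pytest.approx(pairs / (len(pos) * len(neg)), abs=1e-12)

    def test_curve_is_monotone(self, rng):
        truth = rng.integers(0, 2, 200)
        points, _ = roc_auc(rng.normal(size=200) + truth, truth)
        assert (np.diff(points[:, 0]) >= 0).all() and (np.diff(points[:, 1]) >= 0).all()

    def test_single_class_rejected(self):
        with pytest.raises(EvaluationError):
            roc_auc(np.ones(5), np.ones(5, dtype=int))


@pytest.fixture(scope="module")
def planted_windows():
    motif = MotifSpec(offsets=(-3, -1, 2, 4), residues=("W", "D", "F", "H"),
                      signal_strength=1.0)
    proteome = generate_proteome(120, seed=21)
    sites, proteome = plant_sites(proteome, motif, 150, 150, seed=21)
    return proteome, sites


class TestKFoldCV:
    def test_each_window_in_exactly_one_test_fold(self, planted_windows):
        proteome, sites = planted_windows
        windows = segment_dataset(proteome, sites, flank_from_size(11))
        result = kfold_cv(_cheap_spec(epochs=1), windows, k=3, seed=0)
        tested = np.concatenate([f.test_indices for f in result.folds])
        assert sorted(tested) == list(range(len(windows)))

    def test_no_fitting_stage_sees_held_out_windows(self, planted_windows):
        proteome, sites = planted_windows
        windows = segment_dataset(proteome, sites, flank_from_size(11))
        result = kfold_cv(_cheap_spec(epochs=1), windows, k=3, seed=0)
        for fold in result.folds:
            held_out = set(fold.test_indices.tolist())
            for stage in (fold.extractor_fit_indices, fold.scaler_fit_indices,
                          fold.svm_fit_indices):
                assert held_out.isdisjoint(stage.tolist())

    def test_planted_motif_yields_high_mean_mcc(self, planted_windows):
        proteome, sites = planted_windows
        windows = segment_dataset(proteome, sites, flank_from_size(11))
        cfg = ExtractorConfig(window_size=11, embedding_dim=8, lstm_units=8,
                              gru_units=6, dense_units=16, dropout_rate=0.1,
                              epochs=12, batch_size=128, learning_rate=3e-3,
                              validation_fraction=0.0, patience=0, seed=2)
        result = kfold_cv(PipelineSpec(extractor_config=cfg), windows, k=10, seed=0)
        assert result.mean.MCC >= 0.8

    def test_shuffled_labels_give_mcc_near_zero(self, planted_windows, rng):
        proteome, sites = planted_windows
        windows = segment_dataset(proteome, sites, flank_from_size(11))
        batch = encode(windows)
        batch.labels = rng.permutation(batch.labels)
        result = kfold_cv(_cheap_spec(epochs=2), batch, k=3, seed=0)
        assert abs(result.mean.MCC) <= 0.15

    def test_leave_one_out_runs_n_single_sample_folds(self, planted_windows):
        proteome, sites = planted_windows
        windows = segment_dataset(proteome, sites[:6] + sites[-6:], flank_from_size(11))
        result = kfold_cv(_cheap_spec(epochs=1), windows, k=12, seed=0)
        assert result.k == 12
        assert all(len(f.test_indices) == 1 for f in result.folds)

    def test_k_below_two_rejected(self, planted_windows):
        proteome, sites = planted_windows
        windows = segment_dataset(proteome, sites, flank_from_size(11))
        with pytest.raises(EvaluationError):
            kfold_cv(_cheap_spec(), windows, k=1, seed=0)


class TestWindowSizeSweep:
    def test_single_size_equals_plain_cv(self, planted_windows):
        proteome, sites = planted_windows

        def builder(size):
            return segment_dataset(proteome, sites, flank_from_size(size))

        spec = _cheap_spec(epochs=1)
        table, best = window_size_sweep([11], builder, spec, k=2, seed=5)
        assert len(table) == 1 and best == 11
        direct = kfold_cv(spec, builder(11), k=2, seed=5)
        assert table.loc[0, "MCC"] == pytest.approx(direct.mean.MCC)

    def test_even_size_rejected(self, planted_windows):
        proteome, sites = planted_windows
        with pytest.raises(Exception, match="odd"):
            window_size_sweep([10], lambda s: [], _cheap_spec(), k=2, seed=0)
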