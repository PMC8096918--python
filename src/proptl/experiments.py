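"""Canned simulation experiments at reduced scale.

These are the package's standard study conditions for validating the
transfer-learning premise on synthetic data: a source task of 1,000-2,000
positives per class, a target task of 300 training and 100 test positives
per class, six-constraint motifs at signal strength 0.45 (a mid-difficulty
regime comparable to real acylation data, where independent-test MCC sits
well below 1), and a compact extractor sized so a full trial runs in tens
of seconds on one CPU.  Pretraining and fine-tuning share one learning
rate, with convergence governed by early stopping, so the fine-tuned and
from-scratch arms get the same optimization budget on the target task.  Both the test suite and the results-reproduction
script call these entry points, so numbers quoted anywhere are produced by
exactly this code.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .evaluation import MetricsReport, confusion, metrics
from .extractor import ExtractorConfig, build_extractor, pretrain, extract_features
from .model import PropionylationTransferModel, TransferComparison, transfer_comparison
from .svm import predict_svm, train_svm
from .synthetic import (
    TransferPairSpec,
    generate_proteome,
    make_benchmark,
    make_transfer_pair,
    plant_sites,
    random_motif,
)
from .datasets import split_by_protein
from .windows import EncodedBatch, encode, flank_from_size, segment_dataset


def reduced_extractor_config(window_size: int = 21, seed: int = 0) -> ExtractorConfig:
    """The compact extractor used throughout the simulation experiments."""
    return ExtractorConfig(
        window_size=window_size, embedding_dim=8, lstm_units=12, gru_units=8,
        dense_units=16, dropout_rate=0.3, epochs=12, batch_size=256,
        learning_rate=1e-3, finetune_learning_rate=1e-3,
        validation_fraction=0.1, patience=3, seed=seed,
    )


def _encode_pair(spec: TransferPairSpec, window_size: int):
    source, target = make_transfer_pair(spec)
    n = flank_from_size(window_size)
    sb = encode(segment_dataset(source.proteins, source.sites, n))
    tr = encode(segment_dataset(target.proteins, target.train_sites, n))
    te = encode(segment_dataset(target.proteins, target.test_sites, n))
    return sb, tr, te


def transfer_trial(
    overlap: float,
    seed: int,
    signal_strength: float = 0.45,
    n_source_pos: int = 1500,
    n_target_pos: int = 300,
    n_target_test_pos: int = 100,
    window_size: int = 21,
) -> TransferComparison:
    """One pretrain+fine-tune vs from-scratch comparison on a fresh
    synthetic transfer pair with the given motif overlap."""
    spec = TransferPairSpec.with_overlap(
        overlap, seed=seed, signal_strength=signal_strength,
        n_source_pos=n_source_pos, n_target_pos=n_target_pos,
        n_target_test_pos=n_target_test_pos,
    )
    sb, tr, te = _encode_pair(spec, window_size)
    return transfer_comparison(sb, tr, te, reduced_extractor_config(window_size), seed=seed)


def single_task_mcc(
    signal_strength: float,
    seed: int,
    window_size: int = 21,
    n_train_pos: int = 200,
    n_test_pos: int = 70,
) -> float:
    """Independent-test MCC of a target-only pipeline at one signal strength
    (used to check that performance grows with the planted signal)."""
    rng = np.random.default_rng([seed, 5])
    motif = random_motif(rng, signal_strength=signal_strength)
    proteome = generate_proteome(160, seed=seed)
    split = split_by_protein(proteome, 0.8, seed=seed)
    train_prots = [p for p in proteome if p.id in split.train_protein_ids]
    test_prots = [p for p in proteome if p.id in split.test_protein_ids]
    train_sites, train_prots = plant_sites(train_prots, motif, n_train_pos,
                                           n_train_pos, seed=seed, partition="train")
    test_sites, test_prots = plant_sites(test_prots, motif, n_test_pos,
                                         n_test_pos, seed=seed + 1, partition="test")
    n = flank_from_size(window_size)
    train = encode(segment_dataset(train_prots, train_sites, n))
    test = encode(segment_dataset(test_prots, test_sites, n))
    cfg = replace(reduced_extractor_config(window_size, seed), epochs=6)
    model = build_extractor(cfg)
    pretrain(model, train)
    svm_model = train_svm(extract_features(model, train), train.labels)
    pred, _ = predict_svm(svm_model, extract_features(model, test))
    return metrics(confusion(test.labels, pred)).MCC


@dataclass(slots=True)
class BenchmarkTrial:
    """Results of a full run on the benchmark-scale synthetic dataset."""

    independent: MetricsReport
    train: MetricsReport
    cv_mean: MetricsReport | None
    null_independent: MetricsReport
    n_train_windows: int
    n_test_windows: int


def benchmark_trial(
    seed: int,
    window_size: int = 21,
    n_source_pos: int = 2000,
    cv_k: int = 10,
    run_cv: bool = True,
) -> BenchmarkTrial:
    """Run the whole pipeline on a dataset with the benchmark's bookkeeping
    (189 proteins, 304+304 train / 104+104 test sites, larger source task):
    pretrain, fine-tune, SVM, independent test, optional 10-fold CV, plus a
    shuffled-label null for reference."""
    source, target = make_benchmark(seed=seed, n_source_pos=n_source_pos)
    n = flank_from_size(window_size)
    sb = encode(segment_dataset(source.proteins, source.sites, n))
    tr = encode(segment_dataset(target.proteins, target.train_sites, n))
    te = encode(segment_dataset(target.proteins, target.test_sites, n))
    cfg = reduced_extractor_config(window_size, seed)
    model = PropionylationTransferModel(target_train=tr, source=sb, config=cfg, grid=None)
    results = model.fit()
    independent = results.evaluate(te)
    cv_mean = None
    if run_cv:
        cv_mean = results.crossval(k=cv_k, seed=seed).mean

    # shuffled-label null on the same features: what "no signal" looks like
    rng = np.random.default_rng([seed, 23])
    null_tr = EncodedBatch(tr.matrix, rng.permutation(tr.labels), tr.vocabulary)
    feats = results.features(null_tr)
    null_svm = train_svm(feats, null_tr.labels)
    pred, _ = predict_svm(null_svm, results.features(te))
    null_report = metrics(confusion(te.labels, pred))
    return BenchmarkTrial(
        independent=independent, train=results.train_report, cv_mean=cv_mean,
        null_independent=null_report, n_train_windows=len(tr), n_test_windows=len(te),
    )
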