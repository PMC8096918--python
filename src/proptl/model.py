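"""High-level modelling interface: fit the full transfer pipeline on data
and get back a results object with diagnostics and a summary table.

`PropionylationTransferModel` bundles the source (malonylation-like) and
target (propionylation-like) windows with the extractor configuration and
SVM search space; `fit()` runs pretrain -> fine-tune -> feature extraction
-> grid search -> final SVM and returns a `TransferResults` carrying the
trained extractor, the classifier, the grid table, and evaluation helpers.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .datasets import ProteinRecord, SiteAnnotation, read_fasta, read_site_table
from .evaluation import CVResult, MetricsReport, PipelineSpec, confusion, kfold_cv, metrics
from .extractor import (
    ExtractorConfig,
    TrainedExtractor,
    build_extractor,
    extract_features,
    fine_tune,
    pretrain,
)
from .svm import GridSearchResult, SVMGridSpec, SVMModel, grid_search, predict_svm, train_svm
from .windows import EncodedBatch, PeptideWindow, encode, flank_from_size, segment_dataset


class ModelError(ValueError):
    pass


@dataclass(slots=True)
class PropionylationTransferModel:
    """The transfer-learning site predictor, statsmodels-style.

    Parameters
    ----------
    target_train
        Encoded windows of the (small) target task used for fine-tuning
        and classifier training.
    source
        Encoded windows of the (large) source task used for pretraining;
        ``None`` trains the extractor on the target data alone.
    config
        Extractor hyperparameters; ``config.window_size`` must match the
        encoded window width.
    grid
        SVM search space; ``None`` skips the search and uses ``svm_params``.
    """

    target_train: EncodedBatch
    source: EncodedBatch | None = None
    config: ExtractorConfig = field(default_factory=ExtractorConfig)
    grid: SVMGridSpec | None = field(default_factory=SVMGridSpec)
    svm_params: tuple[float, str, str] = (1.0, "rbf", "scale")
    grid_k: int = 10

    @classmethod
    def from_files(
        cls,
        fasta: str | Path,
        site_table: str | Path,
        window_size: int = 29,
        source: EncodedBatch | None = None,
        config: ExtractorConfig | None = None,
        **kwargs,
    ) -> "PropionylationTransferModel":
        """Build from a FASTA + site-table pair, using the 'train' partition."""
        proteins = read_fasta(fasta)
        sites = read_site_table(site_table, proteins)
        train_sites = [s for s in sites if s.partition in ("train", "unassigned")]
        windows = segment_dataset(proteins, train_sites, flank_from_size(window_size))
        cfg = config or ExtractorConfig(window_size=window_size)
        return cls(target_train=encode(windows), source=source, config=cfg, **kwargs)

    def fit(self, seed: int | None = None, epochs: int | None = None) -> "TransferResults":
        """Run the full pipeline and return the fitted results."""
        cfg = self.config if seed is None else replace(self.config, seed=seed)
        if self.target_train.window_size != cfg.window_size:
            raise ModelError(
                f"encoded window width {self.target_train.window_size} does not "
                f"match config window_size {cfg.window_size}"
            )
        extractor = build_extractor(cfg)
        if self.source is not None:
            pretrain(extractor, self.source, epochs=epochs)
            fine_tune(extractor, self.target_train, epochs=epochs)
        else:
            pretrain(extractor, self.target_train, epochs=epochs)
        feats = extract_features(extractor, self.target_train)
        y = self.target_train.labels
        grid_result = None
        if self.grid is not None:
            from .svm import standardize
            scaled, _ = standardize(feats)
            grid_result = grid_search(scaled, y, self.grid, k=min(self.grid_k, len(y)),
                                      seed=cfg.seed)
            C, kernel, gamma = grid_result.best
        else:
            C, kernel, gamma = self.svm_params
        svm_model = train_svm(feats, y, C, kernel, gamma)
        pred, scores = predict_svm(svm_model, feats)
        train_report = metrics(confusion(y, pred), scores=scores, truth=y)
        return TransferResults(
            model=self, extractor=extractor, svm=svm_model,
            grid_result=grid_result, train_report=train_report, config=cfg,
        )


@dataclass(slots=True)
class TransferResults:
    """Fitted pipeline: extractor + SVM, with diagnostics."""

    model: PropionylationTransferModel
    extractor: TrainedExtractor
    svm: SVMModel
    grid_result: GridSearchResult | None
    train_report: MetricsReport
    config: ExtractorConfig

    def features(self, batch: EncodedBatch) -> np.ndarray:
        return extract_features(self.extractor, batch)

    def predict(self, batch: EncodedBatch) -> tuple[np.ndarray, np.ndarray]:
        """Predicted labels and signed decision scores for encoded windows."""
        return predict_svm(self.svm, self.features(batch))

    def evaluate(self, batch: EncodedBatch) -> MetricsReport:
        """SN/SP/ACC/MCC (+AUC) on an independent encoded test batch."""
        pred, scores = self.predict(batch)
        y = batch.labels
        both = len(np.unique(y)) == 2
        return metrics(confusion(y, pred), scores=scores if both else None,
                       truth=y if both else None)

    def crossval(self, k: int = 10, seed: int = 0) -> CVResult:
        """k-fold CV of the pipeline on the target training windows."""
        spec = PipelineSpec(
            extractor_config=self.config, source=self.model.source,
            svm_params=(self.svm.C, self.svm.kernel, self.svm.gamma),
        )
        return kfold_cv(spec, self.model.target_train, k=k, seed=seed)

    def summary(self) -> str:
        """A plain-text summary table of the fitted pipeline."""
        lines = [
            "Propionylation transfer-learning pipeline",
            "=" * 57,
            f"target training windows     {len(self.model.target_train):>8d}"
            f"   (window size {self.config.window_size})",
        ]
        if self.model.source is not None:
            lines.append(f"source pretraining windows  {len(self.model.source):>8d}")
        lines += [
            f"extractor provenance        {self.extractor.provenance:>8s}",
            f"feature dimensionality      {self.config.dense_units:>8d}",
            f"SVM hyperparameters         C={self.svm.C:g}, kernel={self.svm.kernel}, "
            f"gamma={self.svm.gamma}",
            "-" * 57,
            "training-set performance",
            f"  SN={self.train_report.SN:.4f}  SP={self.train_report.SP:.4f}  "
            f"ACC={self.train_report.ACC:.4f}  MCC={self.train_report.MCC:.4f}"
            + (f"  AUC={self.train_report.AUC:.4f}" if self.train_report.AUC is not None else ""),
        ]
        if self.grid_result is not None:
            lines.append("-" * 57)
            lines.append("top 5 grid combinations (mean CV accuracy)")
            head = self.grid_result.table.head(5)
            for _, r in head.iterrows():
                lines.append(
                    f"  C={r['C']:<7g} kernel={r['kernel']:<8s} gamma={r['gamma']:<6s} "
                    f"acc={r['mean_accuracy']:.4f}"
                )
        return "\n".join(lines)


@dataclass(frozen=True, slots=True)
class TransferComparison:
    """Test-set performance of fine-tuned vs from-scratch extractors."""

    finetuned: MetricsReport
    scratch: MetricsReport

    @property
    def mcc_gain(self) -> float:
        return self.finetuned.MCC - self.scratch.MCC


def transfer_comparison(
    source: EncodedBatch,
    target_train: EncodedBatch,
    target_test: EncodedBatch,
    config: ExtractorConfig,
    svm_params: tuple[float, str, str] = (1.0, "rbf", "scale"),
    seed: int = 0,
) -> TransferComparison:
    """Train the pipeline twice — pretrain+fine-tune vs target-only — and
    evaluate both on the same held-out target test windows."""
    cfg = replace(config, seed=seed)

    ft = build_extractor(cfg)
    pretrain(ft, source)
    fine_tune(ft, target_train)
    sc = build_extractor(cfg)
    pretrain(sc, target_train)

    reports = []
    for extractor in (ft, sc):
        train_feats = extract_features(extractor, target_train)
        svm_model = train_svm(train_feats, target_train.labels, *svm_params)
        pred, scores = predict_svm(svm_model, extract_features(extractor, target_test))
        y = target_test.labels
        reports.append(metrics(confusion(y, pred), scores=scores, truth=y))
    return TransferComparison(finetuned=reports[0], scratch=reports[1])


def dataset_windows(
    proteins: Sequence[ProteinRecord],
    sites: Sequence[SiteAnnotation],
    window_size: int,
) -> list[PeptideWindow]:
    """Convenience: segment at a full window size (2n+1)."""
    return segment_dataset(proteins, sites, flank_from_size(window_size))
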