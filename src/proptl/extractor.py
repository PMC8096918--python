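"""The recurrent feature extractor and its transfer-learning training loop.

Architecture (input to output): embedding -> bidirectional LSTM ->
bidirectional LSTM -> bidirectional GRU -> dropout -> flatten -> fully
connected -> single sigmoid output.  The network is first trained on the
data-rich source task (malonylation sites), then fine-tuned at a reduced
learning rate on the small target task (propionylation sites).  After
training, the fully connected layer's activations — the penultimate layer —
serve as learned sequence features for a downstream SVM.

Both recurrent stages return full sequences, so the flatten step sees one
vector per window position; dropout sits between the GRU and the flatten,
and is active only during training.
"""
from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .nn import autograd as ag
from .nn.autograd import Tensor, bce_with_logits
from .nn.layers import Adam, BiGRU, BiLSTM, Dense, Dropout, Embedding
from .windows import VOCAB_SIZE, EncodedBatch

logger = logging.getLogger(__name__)

PROVENANCES = ("untrained", "pretrained-only", "fine-tuned")


class ExtractorError(ValueError):
    """Raised for invalid extractor configuration or inputs."""


@dataclass(slots=True)
class ExtractorConfig:
    """Hyperparameters of the recurrent extractor.

    Defaults suit the small-data regime of PTM site prediction: a compact
    embedding, two sequence-returning biLSTM stages, one biGRU stage, the
    canonical 0.5 dropout, and Adam with early stopping on a held-out
    fraction of the training windows.  Fine-tuning reuses all weights at a
    ten-fold smaller learning rate.
    """

    window_size: int = 29
    vocab_size: int = VOCAB_SIZE
    embedding_dim: int = 32
    lstm_units: int = 64
    gru_units: int = 32
    dropout_rate: float = 0.5
    dense_units: int = 64
    learning_rate: float = 1e-3
    finetune_learning_rate: float = 1e-4
    epochs: int = 30
    batch_size: int = 64
    validation_fraction: float = 0.1
    patience: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.window_size < 1 or self.window_size % 2 == 0:
            raise ExtractorError(f"window_size must be odd and positive, got {self.window_size}")
        for name in ("embedding_dim", "lstm_units", "gru_units", "dense_units"):
            if getattr(self, name) < 1:
                raise ExtractorError(f"{name} must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ExtractorError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        if self.learning_rate <= 0 or self.finetune_learning_rate <= 0:
            raise ExtractorError("learning rates must be positive")
        if self.epochs < 0 or self.batch_size < 1:
            raise ExtractorError("epochs must be >= 0 and batch_size >= 1")
        if not 0.0 <= self.validation_fraction < 1.0:
            raise ExtractorError("validation_fraction must be in [0, 1)")


class TrainedExtractor:
    """The layer stack plus training history and provenance."""

    def __init__(self, config: ExtractorConfig):
        config.validate()
        self.config = config
        rng = np.random.default_rng([config.seed, 0])
        self.embedding = Embedding(config.vocab_size, config.embedding_dim, rng)
        self.lstm1 = BiLSTM(config.embedding_dim, config.lstm_units, rng)
        self.lstm2 = BiLSTM(2 * config.lstm_units, config.lstm_units, rng)
        self.gru = BiGRU(2 * config.lstm_units, config.gru_units, rng)
        self.dropout = Dropout(config.dropout_rate)
        flat_width = config.window_size * 2 * config.gru_units
        self.dense = Dense(flat_width, config.dense_units, rng)
        self.output = Dense(config.dense_units, 1, rng)
        self.provenance = "untrained"
        self.history: dict[str, list[float]] = {"pretrain": [], "finetune": []}

    # ------------------------------------------------------------------
    def params(self) -> list[Tensor]:
        return (
            self.embedding.params() + self.lstm1.params() + self.lstm2.params()
            + self.gru.params() + self.dense.params() + self.output.params()
        )

    def forward(
        self,
        matrix: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[Tensor, Tensor]:
        """Run the stack; returns (penultimate features, output logits)."""
        if matrix.ndim != 2 or matrix.shape[1] != self.config.window_size:
            raise ExtractorError(
                f"input width {matrix.shape[1] if matrix.ndim == 2 else '?'} "
                f"does not match window_size {self.config.window_size}"
            )
        if training and rng is None:
            raise ExtractorError("training-mode forward pass needs an rng for dropout")
        xs = [self.embedding(matrix[:, t]) for t in range(matrix.shape[1])]
        xs = self.lstm1(xs)
        xs = self.lstm2(xs)
        xs = self.gru(xs)
        xs = [self.dropout(x, training, rng) for x in xs]
        flat = ag.concat(xs, axis=1)
        features = ag.relu(self.dense(flat))
        logits = self.output(features)
        return features, logits

    def predict_proba(self, matrix: np.ndarray) -> np.ndarray:
        """Inference-mode positive-class probabilities, shape (batch,)."""
        _, logits = self.forward(matrix, training=False)
        return (0.5 * (np.tanh(0.5 * logits.data) + 1.0)).reshape(-1)

    def snapshot(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.params()]

    def restore(self, snapshot: list[np.ndarray]) -> None:
        for p, saved in zip(self.params(), snapshot):
            p.data = saved.copy()

    # -- persistence ----------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Save weights (npz) with a JSON sidecar for config and provenance."""
        path = Path(path)
        np.savez(path, **{f"p{i}": p.data for i, p in enumerate(self.params())})
        sidecar = {
            "config": asdict(self.config),
            "provenance": self.provenance,
            "history": self.history,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedExtractor":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        model = cls(ExtractorConfig(**sidecar["config"]))
        npz_path = path if path.suffix == ".npz" else path.with_suffix(".npz")
        with np.load(npz_path) as data:
            for i, p in enumerate(model.params()):
                p.data = data[f"p{i}"]
        model.provenance = sidecar["provenance"]
        model.history = sidecar["history"]
        return model


def build_extractor(config: ExtractorConfig) -> TrainedExtractor:
    """Build the layer stack with seed-deterministic initial weights."""
    return TrainedExtractor(config)


def _check_batch(model: TrainedExtractor, batch: EncodedBatch) -> None:
    if len(batch) == 0:
        raise ExtractorError("empty training batch")
    if batch.window_size != model.config.window_size:
        raise ExtractorError(
            f"batch window size {batch.window_size} does not match model "
            f"window_size {model.config.window_size}"
        )
    if not np.isin(batch.labels, (0, 1)).all():
        raise ExtractorError("labels must be binary")


def _fit(
    model: TrainedExtractor,
    batch: EncodedBatch,
    lr: float,
    epochs: int,
    rng: np.random.Generator,
    history_key: str,
    trainable: list[Tensor],
) -> None:
    """Mini-batch Adam on binary cross-entropy, with optional early stopping."""
    cfg = model.config
    n = len(batch)
    n_val = int(round(cfg.validation_fraction * n))
    use_val = n_val >= 1 and cfg.patience > 0 and (n - n_val) >= 1
    order = rng.permutation(n)
    if use_val:
        val_idx, train_idx = order[:n_val], order[n_val:]
    else:
        val_idx, train_idx = np.array([], dtype=int), order
    X, y = batch.matrix, batch.labels
    optimizer = Adam(trainable, lr=lr)
    best_val = np.inf
    best_weights: list[np.ndarray] | None = None
    strikes = 0
    history = model.history[history_key]
    for epoch in range(epochs):
        perm = rng.permutation(train_idx)
        losses = []
        for start in range(0, len(perm), cfg.batch_size):
            idx = perm[start: start + cfg.batch_size]
            _, logits = model.forward(X[idx], training=True, rng=rng)
            loss = bce_with_logits(logits, y[idx])
            if not np.isfinite(loss.data):
                raise ExtractorError(f"non-finite training loss at epoch {epoch}")
            loss.backward()
            optimizer.step()
            losses.append(float(loss.data) * len(idx))
        history.append(sum(losses) / len(perm))
        if use_val:
            _, val_logits = model.forward(X[val_idx], training=False)
            val_loss = float(bce_with_logits(val_logits, y[val_idx]).data)
            if val_loss < best_val - 1e-6:
                best_val, best_weights, strikes = val_loss, model.snapshot(), 0
            else:
                strikes += 1
                if strikes >= cfg.patience:
                    logger.info("early stop at epoch %d (val loss %.4f)", epoch, best_val)
                    break
    if use_val and best_weights is not None:
        model.restore(best_weights)
    if len(history) >= 2 and history[-1] > history[0]:
        warnings.warn(
            f"{history_key}: final epoch loss {history[-1]:.4f} above first "
            f"epoch loss {history[0]:.4f}; training may not have converged",
            stacklevel=3,
        )


def pretrain(
    model: TrainedExtractor, source: EncodedBatch, epochs: int | None = None
) -> TrainedExtractor:
    """Train the extractor from its initial weights on the source task."""
    _check_batch(model, source)
    cfg = model.config
    rng = np.random.default_rng([cfg.seed, 1])
    _fit(model, source, cfg.learning_rate, cfg.epochs if epochs is None else epochs,
         rng, "pretrain", model.params())
    model.provenance = "pretrained-only"
    return model


def fine_tune(
    model: TrainedExtractor,
    target: EncodedBatch,
    epochs: int | None = None,
    freeze_embedding: bool = False,
) -> TrainedExtractor:
    """Continue training on the target task at the fine-tuning learning rate.

    All layers stay trainable by default; ``freeze_embedding`` pins the
    embedding table.  The pretraining output head is reused (same binary
    task shape).
    """
    if model.provenance != "pretrained-only":
        raise ExtractorError(
            f"fine_tune expects a pretrained-only model, got provenance "
            f"{model.provenance!r}"
        )
    _check_batch(model, target)
    cfg = model.config
    rng = np.random.default_rng([cfg.seed, 2])
    trainable = model.params()
    if freeze_embedding:
        trainable = [p for p in trainable if p is not model.embedding.weights]
    _fit(model, target, cfg.finetune_learning_rate,
         cfg.epochs if epochs is None else epochs, rng, "finetune", trainable)
    model.provenance = "fine-tuned"
    return model


def extract_features(
    model: TrainedExtractor, batch: EncodedBatch, chunk_size: int = 512
) -> np.ndarray:
    """Penultimate-layer activations in inference mode, one row per window.

    Dropout is inactive, so repeated calls on the same batch are identical.
    """
    if model.provenance == "untrained":
        warnings.warn(
            "extracting features from an untrained extractor: the features "
            "are random projections", stacklevel=2,
        )
    if len(batch) == 0:
        return np.zeros((0, model.config.dense_units))
    rows = []
    for start in range(0, len(batch), chunk_size):
        feats, _ = model.forward(batch.matrix[start: start + chunk_size], training=False)
        rows.append(feats.data)
    out = np.concatenate(rows, axis=0)
    if not np.isfinite(out).all():
        raise ExtractorError("non-finite values in extracted features")
    return out
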