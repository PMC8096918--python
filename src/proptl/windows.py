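"""Lysine-centered peptide windows and their integer encoding.

A site at 1-based position ``p`` on a protein is represented by the window
of ``2n + 1`` residues centered on the lysine, with ``n`` flanking residues
on each side; positions hanging over either end of the protein are padded
with the character 'X' (which doubles as the encoding's pad symbol).
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .datasets import ProteinRecord, SiteAnnotation, _index_proteins

#: Fixed vocabulary: the 20 standard amino acids alphabetically, then 'X'.
VOCABULARY: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY") + ("X",)

VOCAB_SIZE = len(VOCABULARY)  # 21

_INDEX = {aa: i for i, aa in enumerate(VOCABULARY)}


class WindowError(ValueError):
    """Raised for invalid window geometry or encoding input."""


@dataclass(frozen=True, slots=True)
class PeptideWindow:
    """A fixed-length residue string centered on a candidate lysine."""

    protein_id: str
    position: int
    residues: str
    label: str

    def __post_init__(self) -> None:
        if len(self.residues) % 2 == 0:
            raise WindowError(f"window length must be odd, got {len(self.residues)}")
        n = len(self.residues) // 2
        if self.residues[n] != "K":
            raise WindowError(
                f"{self.protein_id}:{self.position}: center residue "
                f"{self.residues[n]!r} is not 'K'"
            )

    @property
    def flank(self) -> int:
        """The flank size n (window length = 2n + 1)."""
        return len(self.residues) // 2


@dataclass(slots=True)
class EncodedBatch:
    """Integer-encoded windows with aligned binary labels.

    ``matrix[i, j]`` is the vocabulary index of residue j of window i;
    ``labels[i]`` is 1 for positive, 0 for negative.
    """

    matrix: np.ndarray
    labels: np.ndarray
    vocabulary: tuple[str, ...] = VOCABULARY

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.matrix.ndim != 2:
            raise WindowError("matrix must be 2-D (windows x positions)")
        if self.matrix.shape[0] != self.labels.shape[0]:
            raise WindowError("matrix rows and labels must align")
        if self.matrix.size and self.matrix.max() >= len(self.vocabulary):
            raise WindowError("encoded index out of vocabulary range")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def window_size(self) -> int:
        return self.matrix.shape[1]

    def subset(self, indices) -> "EncodedBatch":
        return EncodedBatch(self.matrix[indices], self.labels[indices], self.vocabulary)


def flank_from_size(window_size: int) -> int:
    """Derive the flank n from a full window size 2n+1; even sizes error."""
    if window_size < 1 or window_size % 2 == 0:
        raise WindowError(f"window size must be a positive odd integer, got {window_size}")
    return window_size // 2


def extract_window(sequence: str, position: int, n: int) -> str:
    """Extract the 2n+1 residue window centered at a 1-based lysine position.

    Overhang beyond either end of the sequence is filled with 'X'.
    """
    if n < 0:
        raise WindowError(f"flank n must be non-negative, got {n}")
    if not 1 <= position <= len(sequence):
        raise WindowError(
            f"position {position} out of range 1..{len(sequence)}"
        )
    sequence = sequence.upper()
    if sequence[position - 1] != "K":
        raise WindowError(
            f"residue at position {position} is {sequence[position - 1]!r}, not 'K'"
        )
    start = position - 1 - n
    stop = position + n  # exclusive, 0-based
    left_pad = max(0, -start)
    right_pad = max(0, stop - len(sequence))
    core = sequence[max(0, start): min(len(sequence), stop)]
    return "X" * left_pad + core + "X" * right_pad


def segment_dataset(
    proteins: Sequence[ProteinRecord],
    sites: Sequence[SiteAnnotation],
    n: int,
) -> list[PeptideWindow]:
    """One window per site, order-preserving, labels carried through."""
    index = _index_proteins(proteins)
    windows: list[PeptideWindow] = []
    for s in sites:
        prot = index.get(s.protein_id)
        if prot is None:
            raise WindowError(f"site {s.protein_id}:{s.position}: unknown protein")
        try:
            residues = extract_window(prot.sequence, s.position, n)
        except WindowError as exc:
            raise WindowError(f"site {s.protein_id}:{s.position}: {exc}") from exc
        windows.append(PeptideWindow(s.protein_id, s.position, residues, s.label))
    return windows


def encode(
    windows: Sequence[PeptideWindow],
    vocabulary: Sequence[str] = VOCABULARY,
) -> EncodedBatch:
    """Integer-encode windows against an ordered vocabulary."""
    vocab = tuple(vocabulary)
    index = {aa: i for i, aa in enumerate(vocab)}
    if not windows:
        return EncodedBatch(np.zeros((0, 0), dtype=np.int64), np.zeros(0, dtype=np.int64), vocab)
    width = len(windows[0].residues)
    matrix = np.empty((len(windows), width), dtype=np.int64)
    labels = np.empty(len(windows), dtype=np.int64)
    for i, w in enumerate(windows):
        if len(w.residues) != width:
            raise WindowError("all windows in a batch must share one size")
        for j, aa in enumerate(w.residues):
            try:
                matrix[i, j] = index[aa]
            except KeyError:
                raise WindowError(
                    f"unknown symbol {aa!r} in window {w.protein_id}:{w.position}"
                ) from None
        labels[i] = 1 if w.label == "positive" else 0
    return EncodedBatch(matrix, labels, vocab)


def decode(batch: EncodedBatch) -> list[str]:
    """Invert :func:`encode`, returning the residue strings row by row."""
    vocab = batch.vocabulary
    return ["".join(vocab[j] for j in row) for row in batch.matrix]


def windows_to_tsv(windows: Iterable[PeptideWindow], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("protein_id\tposition\twindow\tlabel\n")
        for w in windows:
            handle.write(f"{w.protein_id}\t{w.position}\t{w.residues}\t{w.label}\n")


def windows_from_tsv(path: str | Path) -> list[PeptideWindow]:
    windows = []
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header != ["protein_id", "position", "window", "label"]:
            raise WindowError(f"{path}: unexpected header {header!r}")
        for line in handle:
            if not line.strip():
                continue
            pid, pos, residues, label = line.rstrip("\n").split("\t")
            windows.append(PeptideWindow(pid, int(pos), residues, label))
    return windows


def windows_to_fasta(windows: Iterable[PeptideWindow], path: str | Path) -> None:
    """Export windows as FASTA with ids ``proteinid_position_label``."""
    with open(path, "w") as handle:
        for w in windows:
            handle.write(f">{w.protein_id}_{w.position}_{w.label}\n{w.residues}\n")
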