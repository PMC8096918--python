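"""Protein sequences, lysine-site annotations, and dataset construction.

This module owns the data layer of the propionylation predictor: reading and
writing FASTA and site tables, validating every annotation against its
protein (a site must point at a lysine, 'K'), balanced negative sampling,
and the protein-level train/test split that makes site-level leakage across
partitions impossible by construction.
"""
from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 standard amino-acid one-letter codes, alphabetical.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Non-standard/ambiguity codes accepted on input; all are mapped to 'X'.
NONSTANDARD_AA = "BJOUZ"

SITE_TABLE_COLUMNS = ("protein_id", "position", "label", "modification", "partition")

LABELS = ("positive", "negative")
MODIFICATIONS = ("propionylation", "malonylation")
PARTITIONS = ("train", "test", "unassigned")


class DatasetError(ValueError):
    """Raised for malformed inputs or violated dataset invariants."""


@dataclass(frozen=True, slots=True)
class ProteinRecord:
    """One protein sequence with a stable identifier."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise DatasetError("protein id must be non-empty")
        if len(self.sequence) < 1:
            raise DatasetError(f"protein {self.id!r}: empty sequence")

    def lysine_positions(self) -> list[int]:
        """1-based positions of every 'K' residue."""
        return [i + 1 for i, aa in enumerate(self.sequence) if aa == "K"]


@dataclass(frozen=True, slots=True)
class SiteAnnotation:
    """A labeled lysine position on a protein (1-based, inclusive)."""

    protein_id: str
    position: int
    label: str
    modification: str = "propionylation"
    partition: str = "unassigned"

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise DatasetError(f"invalid label {self.label!r}")
        if self.modification not in MODIFICATIONS:
            raise DatasetError(f"invalid modification {self.modification!r}")
        if self.partition not in PARTITIONS:
            raise DatasetError(f"invalid partition {self.partition!r}")
        if self.position < 1:
            raise DatasetError(f"position must be >= 1, got {self.position}")


@dataclass(frozen=True, slots=True)
class DatasetSplit:
    """Disjoint protein-level train/test partition covering all proteins."""

    train_protein_ids: frozenset[str]
    test_protein_ids: frozenset[str]

    def __post_init__(self) -> None:
        overlap = self.train_protein_ids & self.test_protein_ids
        if overlap:
            raise DatasetError(f"proteins in both partitions: {sorted(overlap)[:5]}")

    def partition_of(self, protein_id: str) -> str:
        if protein_id in self.train_protein_ids:
            return "train"
        if protein_id in self.test_protein_ids:
            return "test"
        raise DatasetError(f"protein {protein_id!r} not covered by split")


def _clean_sequence(raw: str, record_id: str) -> str:
    seq = raw.upper().replace(" ", "")
    cleaned = []
    mapped = 0
    for aa in seq:
        if aa in NONSTANDARD_AA:
            cleaned.append("X")
            mapped += 1
        elif aa in STANDARD_AA or aa == "X" or aa == "*" or aa == "-":
            cleaned.append("X" if aa in "*-" else aa)
        else:
            raise DatasetError(f"protein {record_id!r}: invalid residue {aa!r}")
    if mapped:
        logger.warning(
            "protein %s: mapped %d non-standard residue(s) (%s) to 'X'",
            record_id, mapped, NONSTANDARD_AA,
        )
    return "".join(cleaned)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records from a FASTA file.

    The header token up to the first whitespace is the id; sequences are
    uppercased, line breaks removed, and non-standard residues (B, J, O, U,
    Z) mapped to 'X' with a warning.  Duplicate ids are an error.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    with open(path) as handle:
        first = handle.read(1)
        if first and first != ">":
            raise DatasetError(f"{path}: line 1: sequence data before any FASTA header")
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise DatasetError(f"{path}: duplicate protein id {entry.id!r}")
        seen.add(entry.id)
        records.append(ProteinRecord(entry.id, _clean_sequence(str(entry.seq), entry.id)))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records in standard FASTA (60-column wrapped)."""
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")


def _index_proteins(proteins: Sequence[ProteinRecord]) -> dict[str, ProteinRecord]:
    index: dict[str, ProteinRecord] = {}
    for p in proteins:
        if p.id in index:
            raise DatasetError(f"duplicate protein id {p.id!r}")
        index[p.id] = p
    return index


def validate_sites(
    sites: Iterable[SiteAnnotation], proteins: Sequence[ProteinRecord]
) -> None:
    """Check every annotation: known protein, position in range, residue 'K'.

    Raises :class:`DatasetError` listing every offending annotation.
    """
    index = _index_proteins(proteins)
    problems = []
    for s in sites:
        prot = index.get(s.protein_id)
        if prot is None:
            problems.append(f"{s.protein_id}:{s.position}: unknown protein id")
            continue
        if not 1 <= s.position <= len(prot.sequence):
            problems.append(
                f"{s.protein_id}:{s.position}: position out of range 1..{len(prot.sequence)}"
            )
            continue
        residue = prot.sequence[s.position - 1]
        if residue != "K":
            problems.append(
                f"{s.protein_id}:{s.position}: residue {residue!r} is not 'K'"
            )
    if problems:
        raise DatasetError("invalid site annotations:\n  " + "\n  ".join(problems))


def read_site_table(
    path: str | Path, proteins: Sequence[ProteinRecord]
) -> list[SiteAnnotation]:
    """Read a TSV site table and validate it against the given proteins.

    Expected columns: protein_id, position, label, modification, [partition]
    with a header row.  Positions are 1-based and must point at lysine.
    """
    path = Path(path)
    sites: list[SiteAnnotation] = []
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header[: len(SITE_TABLE_COLUMNS) - 1] != list(SITE_TABLE_COLUMNS[:-1]):
            raise DatasetError(
                f"{path}: bad header {header!r}; expected {SITE_TABLE_COLUMNS[:4]}"
                " with optional 'partition'"
            )
        has_partition = len(header) >= 5 and header[4] == "partition"
        for lineno, line in enumerate(handle, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            try:
                sites.append(
                    SiteAnnotation(
                        protein_id=fields[0],
                        position=int(fields[1]),
                        label=fields[2],
                        modification=fields[3],
                        partition=fields[4] if has_partition and len(fields) > 4 else "unassigned",
                    )
                )
            except (IndexError, ValueError) as exc:
                raise DatasetError(f"{path}: line {lineno}: {exc}") from exc
    validate_sites(sites, proteins)
    return sites


def write_site_table(sites: Iterable[SiteAnnotation], path: str | Path) -> None:
    """Write annotations as TSV with the standard header (round-trips)."""
    with open(path, "w") as handle:
        handle.write("\t".join(SITE_TABLE_COLUMNS) + "\n")
        for s in sites:
            handle.write(
                f"{s.protein_id}\t{s.position}\t{s.label}\t{s.modification}\t{s.partition}\n"
            )


def sample_negatives(
    proteins: Sequence[ProteinRecord],
    positives: Sequence[SiteAnnotation],
    ratio: float = 1.0,
    seed: int = 0,
    modification: str | None = None,
    partition: str | None = None,
) -> list[SiteAnnotation]:
    """Sample unmodified lysines as negatives, ``round(ratio * n_pos)`` of them.

    Candidates are all lysine positions in ``proteins`` that are not
    annotated positive, sampled uniformly without replacement across the
    whole collection.  Deterministic given ``seed``.
    """
    if ratio <= 0:
        raise DatasetError(f"ratio must be > 0, got {ratio}")
    if any(p.label != "positive" for p in positives):
        raise DatasetError("all input annotations must be positive")
    positive_keys = {(p.protein_id, p.position) for p in positives}
    candidates = [
        (prot.id, pos)
        for prot in proteins
        for pos in prot.lysine_positions()
        if (prot.id, pos) not in positive_keys
    ]
    n_needed = round(ratio * len(positives))
    if len(candidates) < n_needed:
        raise DatasetError(
            f"need {n_needed} negative lysines but only {len(candidates)} eligible "
            f"(deficit {n_needed - len(candidates)})"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(candidates), size=n_needed, replace=False)
    mod = modification or (positives[0].modification if positives else "propionylation")
    part = partition or (positives[0].partition if positives else "unassigned")
    return [
        SiteAnnotation(candidates[i][0], candidates[i][1], "negative", mod, part)
        for i in sorted(chosen)
    ]


def split_by_protein(
    proteins: Sequence[ProteinRecord], train_fraction: float = 0.8, seed: int = 0
) -> DatasetSplit:
    """Randomly assign whole proteins to train/test.

    The train count is ``train_fraction * N`` rounded half away from zero
    (4/5 of 189 -> 151).  Deterministic given ``seed``.
    """
    if not proteins:
        raise DatasetError("no proteins to split")
    if not 0 < train_fraction <= 1:
        raise DatasetError(f"train_fraction must be in (0, 1], got {train_fraction}")
    n = len(proteins)
    n_train = int(np.floor(train_fraction * n + 0.5))  # round half away from zero
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    ids = [proteins[i].id for i in order]
    return DatasetSplit(
        train_protein_ids=frozenset(ids[:n_train]),
        test_protein_ids=frozenset(ids[n_train:]),
    )


def assign_partitions(
    sites: Iterable[SiteAnnotation], split: DatasetSplit
) -> list[SiteAnnotation]:
    """Stamp each site with its protein's partition (sites inherit the split)."""
    return [replace(s, partition=split.partition_of(s.protein_id)) for s in sites]


def cdhit_reduce(
    proteins: Sequence[ProteinRecord],
    identity: float = 0.7,
    cdhit_binary: str = "cd-hit",
) -> list[ProteinRecord]:
    """Redundancy-reduce proteins with an external CD-HIT binary.

    Shells out to ``cd-hit -c <identity>`` and keeps one representative per
    cluster (the representative CD-HIT itself elects).  This is a thin hook
    around a user-installed binary; the clustering algorithm is not
    reimplemented here.  Raises :class:`DatasetError` if the binary is not
    on PATH.
    """
    if shutil.which(cdhit_binary) is None:
        raise DatasetError(
            f"CD-HIT binary {cdhit_binary!r} not found on PATH; install cd-hit "
            "or pass pre-deduplicated input"
        )
    word = 5 if identity >= 0.7 else 4
    with tempfile.TemporaryDirectory() as tmp:
        fasta_in = Path(tmp) / "in.fasta"
        fasta_out = Path(tmp) / "out.fasta"
        write_fasta(proteins, fasta_in)
        subprocess.run(
            [cdhit_binary, "-i", str(fasta_in), "-o", str(fasta_out),
             "-c", str(identity), "-n", str(word)],
            check=True, capture_output=True,
        )
        representatives = parse_clstr(fasta_out.with_suffix(".fasta.clstr"))
    index = _index_proteins(proteins)
    return [index[r] for r in representatives]


def parse_clstr(path: str | Path) -> list[str]:
    """Parse a CD-HIT ``.clstr`` file, returning one representative id per cluster."""
    reps: list[str] = []
    with open(path) as handle:
        for line in handle:
            if line.startswith(">"):
                continue
            # e.g. "0\t123aa, >P12345... *"  — '*' marks the representative
            if line.rstrip().endswith("*"):
                start = line.index(">") + 1
                reps.append(line[start:line.index("...")])
    return reps
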