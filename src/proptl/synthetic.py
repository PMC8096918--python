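"""Seeded synthetic benchmarks: random proteomes, planted sequence motifs,
and source/target task pairs with controllable motif overlap.

The generator emulates the structure of acylation-site datasets without any
downloads: proteins are i.i.d. uniform residue strings with a guaranteed
minimum lysine density; positive sites carry a planted flanking motif (a
set of (offset, residue) constraints applied with a given probability);
negatives are untouched lysines.  A transfer pair couples a large source
task and a small target task whose motifs share a controllable fraction of
constraints — the synthetic analogue of the sequence-level crosstalk
between malonylation and propionylation.

Uniform background residues are deliberate: realism of amino-acid
composition is irrelevant to the pipeline contracts under test, and a
uniform null makes "no signal" exact.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .datasets import (
    STANDARD_AA,
    DatasetSplit,
    ProteinRecord,
    SiteAnnotation,
    sample_negatives,
    split_by_protein,
    validate_sites,
    write_fasta,
    write_site_table,
)

AA = np.array(list(STANDARD_AA))


class SyntheticError(ValueError):
    """Raised for infeasible generator requests."""


@dataclass(frozen=True, slots=True)
class MotifSpec:
    """Flanking-sequence signal planted around positive lysines.

    Each (offset, residue) pair is a constraint: a positive site carries
    ``residue`` at ``offset`` (relative to the center lysine, offset 0
    forbidden) with probability ``signal_strength``; background positions
    stay uniform.
    """

    offsets: tuple[int, ...]
    residues: tuple[str, ...]
    signal_strength: float = 0.9

    def __post_init__(self) -> None:
        if len(self.offsets) != len(self.residues):
            raise SyntheticError("offsets and residues must align")
        if 0 in self.offsets:
            raise SyntheticError("offset 0 is the center lysine and cannot be constrained")
        if len(set(self.offsets)) != len(self.offsets):
            raise SyntheticError("offsets must be unique")
        if not 0.0 < self.signal_strength <= 1.0:
            raise SyntheticError("signal_strength must be in (0, 1]")
        bad = set(self.residues) - set(STANDARD_AA)
        if bad:
            raise SyntheticError(f"invalid motif residues {sorted(bad)}")

    @property
    def constraints(self) -> frozenset[tuple[int, str]]:
        return frozenset(zip(self.offsets, self.residues))


def random_motif(
    rng: np.random.Generator,
    n_constraints: int = 6,
    max_offset: int = 8,
    signal_strength: float = 0.9,
) -> MotifSpec:
    """Draw a motif with ``n_constraints`` distinct offsets within ±max_offset."""
    candidates = [o for o in range(-max_offset, max_offset + 1) if o != 0]
    offsets = rng.choice(candidates, size=n_constraints, replace=False)
    residues = rng.choice(AA, size=n_constraints)
    return MotifSpec(tuple(int(o) for o in offsets), tuple(residues), signal_strength)


@dataclass(frozen=True, slots=True)
class TransferPairSpec:
    """A source/target task pair with a controlled fraction of shared motif."""

    source_motif: MotifSpec
    target_motif: MotifSpec
    overlap: float
    n_source_pos: int = 2000
    n_target_pos: int = 300
    n_target_test_pos: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap <= 1.0:
            raise SyntheticError("overlap must be in [0, 1]")
        shared = self.source_motif.constraints & self.target_motif.constraints
        expected = round(self.overlap * len(self.source_motif.offsets))
        if len(shared) < expected:
            raise SyntheticError(
                f"motifs share {len(shared)} constraints but overlap={self.overlap} "
                f"requires {expected}"
            )

    @classmethod
    def with_overlap(
        cls,
        overlap: float,
        seed: int = 0,
        n_constraints: int = 6,
        signal_strength: float = 0.45,
        n_source_pos: int = 2000,
        n_target_pos: int = 300,
        n_target_test_pos: int = 100,
    ) -> "TransferPairSpec":
        """Construct a motif pair sharing ``round(overlap * n_constraints)``
        constraints; the remaining constraints are disjoint in both offset
        and residue preference."""
        rng = np.random.default_rng([seed, 91])
        n_shared = round(overlap * n_constraints)
        candidates = [o for o in range(-10, 11) if o != 0]
        # draw enough distinct offsets for shared + two disjoint remainders
        offsets = rng.choice(candidates, size=min(len(candidates), 2 * n_constraints - n_shared),
                             replace=False)
        shared = [(int(o), str(rng.choice(AA))) for o in offsets[:n_shared]]
        rest = offsets[n_shared:]
        n_rest = n_constraints - n_shared
        source_own = [(int(o), str(rng.choice(AA))) for o in rest[:n_rest]]
        target_own = [(int(o), str(rng.choice(AA))) for o in rest[n_rest: 2 * n_rest]]
        source = MotifSpec(
            tuple(o for o, _ in shared + source_own),
            tuple(r for _, r in shared + source_own),
            signal_strength,
        )
        target = MotifSpec(
            tuple(o for o, _ in shared + target_own),
            tuple(r for _, r in shared + target_own),
            signal_strength,
        )
        return cls(source, target, overlap, n_source_pos, n_target_pos,
                   n_target_test_pos, seed)


@dataclass(slots=True)
class SyntheticDataset:
    """A proteome plus validated site annotations, ready for segmentation."""

    proteins: list[ProteinRecord]
    sites: list[SiteAnnotation]
    motif: MotifSpec | None = None
    split: DatasetSplit | None = None

    @property
    def train_sites(self) -> list[SiteAnnotation]:
        return [s for s in self.sites if s.partition == "train"]

    @property
    def test_sites(self) -> list[SiteAnnotation]:
        return [s for s in self.sites if s.partition == "test"]

    def write(self, directory: str | Path, stem: str = "data") -> tuple[Path, Path]:
        """Emit standard FASTA + site TSV so synthetic and real data share code paths."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        fasta = directory / f"{stem}.fasta"
        table = directory / f"{stem}.sites.tsv"
        write_fasta(self.proteins, fasta)
        write_site_table(self.sites, table)
        return fasta, table


def generate_proteome(
    n_proteins: int,
    length_range: tuple[int, int] = (80, 200),
    seed: int = 0,
    min_lysine_fraction: float = 0.02,
    id_prefix: str = "syn",
) -> list[ProteinRecord]:
    """I.i.d. uniform-residue proteins with a guaranteed lysine density.

    Each protein of length L carries at least ``ceil(min_lysine_fraction*L)``
    lysines (extra lysines are planted uniformly when the draw falls short,
    which at the default 0.02 is rare enough to leave composition ~uniform).
    """
    lo, hi = length_range
    if lo < 3 or hi < lo:
        raise SyntheticError(f"invalid length range {length_range}")
    if not 0.0 <= min_lysine_fraction <= 0.5:
        raise SyntheticError("min_lysine_fraction must be in [0, 0.5]")
    rng = np.random.default_rng([seed, 7])
    proteins = []
    for i in range(n_proteins):
        length = int(rng.integers(lo, hi + 1))
        residues = rng.choice(AA, size=length)
        need = int(np.ceil(min_lysine_fraction * length))
        have = int(np.sum(residues == "K"))
        if have < need:
            non_k = np.flatnonzero(residues != "K")
            extra = rng.choice(non_k, size=need - have, replace=False)
            residues[extra] = "K"
        proteins.append(ProteinRecord(f"{id_prefix}{i:05d}", "".join(residues)))
    return proteins


def plant_sites(
    proteome: list[ProteinRecord],
    motif: MotifSpec,
    n_pos: int,
    n_neg: int,
    seed: int = 0,
    modification: str = "propionylation",
    partition: str = "unassigned",
) -> tuple[list[SiteAnnotation], list[ProteinRecord]]:
    """Choose lysine sites, rewrite positive flanks per the motif, label the rest.

    Sites are chosen greedily from a shuffled lysine pool so that no chosen
    site's motif footprint overwrites another chosen site's center — every
    annotation still points at a lysine after mutation.  Returns the
    annotations and the mutated proteome.
    """
    rng = np.random.default_rng([seed, 13])
    pool = [(p.id, pos) for p in proteome for pos in p.lysine_positions()]
    rng.shuffle(pool)
    lengths = {p.id: len(p.sequence) for p in proteome}
    chosen: list[tuple[str, int]] = []
    centers: set[tuple[str, int]] = set()
    footprints: set[tuple[str, int]] = set()
    total = n_pos + n_neg
    for pid, pos in pool:
        if len(chosen) == total:
            break
        foot = {(pid, pos + off) for off in motif.offsets
                if 1 <= pos + off <= lengths[pid]}
        if (pid, pos) in footprints or foot & centers:
            continue
        chosen.append((pid, pos))
        centers.add((pid, pos))
        footprints |= foot
    if len(chosen) < total:
        raise SyntheticError(
            f"proteome supports only {len(chosen)} non-colliding sites, "
            f"need {total}"
        )
    positives, negatives = chosen[:n_pos], chosen[n_pos:]
    sequences = {p.id: list(p.sequence) for p in proteome}
    for pid, pos in positives:
        seq = sequences[pid]
        for off, res in zip(motif.offsets, motif.residues):
            j = pos + off
            if 1 <= j <= len(seq) and (pid, j) not in centers:
                if rng.random() < motif.signal_strength:
                    seq[j - 1] = res
    mutated = [ProteinRecord(p.id, "".join(sequences[p.id])) for p in proteome]
    sites = [
        SiteAnnotation(pid, pos, "positive", modification, partition)
        for pid, pos in positives
    ] + [
        SiteAnnotation(pid, pos, "negative", modification, partition)
        for pid, pos in negatives
    ]
    validate_sites(sites, mutated)
    return sites, mutated


def _sized_proteome(n_sites: int, seed: int, id_prefix: str) -> list[ProteinRecord]:
    # ~7 usable lysines per protein at default density; 2x headroom
    n_proteins = max(4, int(np.ceil(n_sites / 3.5)))
    return generate_proteome(n_proteins, seed=seed, id_prefix=id_prefix)


def make_transfer_pair(spec: TransferPairSpec) -> tuple[SyntheticDataset, SyntheticDataset]:
    """Build the (large source, small target) dataset pair.

    The source is entirely training data (it only ever pretrains the
    extractor).  The target proteome is split 4/5 by protein into train and
    test, and sites are planted separately within each partition, so no
    target protein contributes windows to both partitions.
    """
    src_proteome = _sized_proteome(2 * spec.n_source_pos, spec.seed * 4 + 1, "src")
    src_sites, src_proteome = plant_sites(
        src_proteome, spec.source_motif, spec.n_source_pos, spec.n_source_pos,
        seed=spec.seed * 4 + 2, modification="malonylation", partition="train",
    )
    source = SyntheticDataset(src_proteome, src_sites, spec.source_motif)

    # the 1/5 test partition is the binding capacity constraint
    n_needed = max(2 * spec.n_target_pos / 0.8, 2 * spec.n_target_test_pos / 0.2)
    tgt_proteome = generate_proteome(
        max(10, int(np.ceil(n_needed / 3.2))), seed=spec.seed * 4 + 3, id_prefix="tgt",
    )
    split = split_by_protein(tgt_proteome, 0.8, seed=spec.seed * 4 + 3)
    train_prots = [p for p in tgt_proteome if p.id in split.train_protein_ids]
    test_prots = [p for p in tgt_proteome if p.id in split.test_protein_ids]
    train_sites, train_prots = plant_sites(
        train_prots, spec.target_motif, spec.n_target_pos, spec.n_target_pos,
        seed=spec.seed * 4 + 4, partition="train",
    )
    test_sites, test_prots = plant_sites(
        test_prots, spec.target_motif, spec.n_target_test_pos, spec.n_target_test_pos,
        seed=spec.seed * 4 + 5, partition="test",
    )
    target = SyntheticDataset(
        train_prots + test_prots, train_sites + test_sites, spec.target_motif, split,
    )
    return source, target


def make_benchmark(
    seed: int = 0,
    n_proteins: int = 189,
    train_fraction: float = 0.8,
    n_train_pos: int = 304,
    n_test_pos: int = 104,
    n_source_pos: int = 2000,
    motif: MotifSpec | None = None,
    source_motif: MotifSpec | None = None,
) -> tuple[SyntheticDataset, SyntheticDataset]:
    """A dataset emulating the shape of the real propionylation benchmark:
    189 proteins split 151/38 by protein, 304+304 train and 104+104 test
    sites at 1:1 balance, plus a larger malonylation-like source task whose
    motif shares most of the target's constraints.

    Positives are planted; negatives are drawn by the same uniform
    unmodified-lysine sampling used for real data, separately within the
    train and test pools so the counts match exactly.  Returns
    (source, target) datasets.
    """
    rng = np.random.default_rng([seed, 17])
    if motif is None or source_motif is None:
        pair = TransferPairSpec.with_overlap(0.7, seed=seed)
        motif = motif or pair.target_motif
        source_motif = source_motif or pair.source_motif
    # lengths sized so 151 proteins can host 304 positives + 304 negatives
    proteome = generate_proteome(
        n_proteins, length_range=(120, 260), seed=int(rng.integers(2**31)),
        id_prefix="bench",
    )
    split = split_by_protein(proteome, train_fraction, seed=int(rng.integers(2**31)))
    train_prots = [p for p in proteome if p.id in split.train_protein_ids]
    test_prots = [p for p in proteome if p.id in split.test_protein_ids]
    tr_pos, train_prots = plant_sites(
        train_prots, motif, n_train_pos, 0, seed=int(rng.integers(2**31)),
        partition="train",
    )
    te_pos, test_prots = plant_sites(
        test_prots, motif, n_test_pos, 0, seed=int(rng.integers(2**31)),
        partition="test",
    )
    tr_neg = sample_negatives(train_prots, tr_pos, 1.0, seed=int(rng.integers(2**31)))
    te_neg = sample_negatives(test_prots, te_pos, 1.0, seed=int(rng.integers(2**31)))
    proteins = train_prots + test_prots
    sites = tr_pos + tr_neg + te_pos + te_neg
    validate_sites(sites, proteins)
    target = SyntheticDataset(proteins, sites, motif, split)

    src_proteome = _sized_proteome(2 * n_source_pos, int(rng.integers(2**31)), "srcb")
    src_sites, src_proteome = plant_sites(
        src_proteome, source_motif, n_source_pos, n_source_pos,
        seed=int(rng.integers(2**31)), modification="malonylation", partition="train",
    )
    source = SyntheticDataset(src_proteome, src_sites, source_motif)
    return source, target
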