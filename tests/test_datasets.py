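"""Data layer: FASTA and site-table I/O, negative sampling, protein splits."""
import numpy as np
import pytest

from proptl.datasets import (
    DatasetError,
    ProteinRecord,
    SiteAnnotation,
    assign_partitions,
    read_fasta,
    read_site_table,
    sample_negatives,
    split_by_protein,
    validate_sites,
    write_fasta,
    write_site_table,
)


class TestFasta:
    def test_empty_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        assert read_fasta(path) == []

    def test_single_record(self, tmp_path):
        path = tmp_path / "one.fasta"
        path.write_text(">p1\nMKKA\n")
        assert read_fasta(path) == [ProteinRecord("p1", "MKKA")]

    def test_header_token_and_multiline_sequence(self, tmp_path):
        path = tmp_path / "multi.fasta"
        path.write_text(">sp|P1|NAME description here\nmkk\naLK\n")
        (record,) = read_fasta(path)
        assert record.id == "sp|P1|NAME"
        assert record.sequence == "MKKALK"

    def test_round_trip_random_records(self, tmp_path, rng):
        aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        records = [
            ProteinRecord(f"prot{i}", "".join(rng.choice(aas, size=rng.integers(5, 120))))
            for i in range(25)
        ]
        path = tmp_path / "rt.fasta"
        write_fasta(records, path)
        assert read_fasta(path) == records

    def test_sequence_before_header_is_parse_error(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text("MKKA\n>p1\nMKKA\n")
        with pytest.raises(DatasetError, match="line 1"):
            read_fasta(path)

    def test_duplicate_id_is_error(self, tmp_path):
        path = tmp_path / "dup.fasta"
        path.write_text(">p1\nMKKA\n>p1\nMKKA\n")
        with pytest.raises(DatasetError, match="duplicate"):
            read_fasta(path)

    def test_nonstandard_residues_mapped_to_x(self, tmp_path):
        path = tmp_path / "ns.fasta"
        path.write_text(">p1\nMKUBZK\n")
        (record,) = read_fasta(path)
        assert record.sequence == "MKXXXK"


class TestSiteTable:
    def test_valid_row_against_lysine(self, toy_proteins):
        validate_sites([SiteAnnotation("p1", 2, "positive")], toy_proteins)

    def test_non_lysine_residue_rejected_listing_row(self, toy_proteins):
        with pytest.raises(DatasetError, match="p1:1.*'M' is not 'K'"):
            validate_sites([SiteAnnotation("p1", 1, "positive")], toy_proteins)

    def test_unknown_protein_and_out_of_range(self, toy_proteins):
        with pytest.raises(DatasetError, match="unknown protein"):
            validate_sites([SiteAnnotation("nope", 2, "positive")], toy_proteins)
        with pytest.raises(DatasetError, match="out of range"):
            validate_sites([SiteAnnotation("p1", 99, "positive")], toy_proteins)

    def test_round_trip(self, tmp_path, toy_proteins, toy_sites):
        path = tmp_path / "sites.tsv"
        write_site_table(toy_sites, path)
        assert read_site_table(path, toy_proteins) == toy_sites

    def test_partition_column_optional(self, tmp_path, toy_proteins):
        path = tmp_path / "sites.tsv"
        path.write_text(
            "protein_id\tposition\tlabel\tmodification\n"
            "p1\t2\tpositive\tpropionylation\n"
        )
        (site,) = read_site_table(path, toy_proteins)
        assert site.partition == "unassigned"


class TestSampleNegatives:
    def test_count_matches_ratio(self, toy_proteins):
        positives = [SiteAnnotation("p1", 2, "positive")]
        negatives = sample_negatives(toy_proteins, positives, ratio=3.0, seed=0)
        assert len(negatives) == 3
        assert all(n.label == "negative" for n in negatives)
        validate_sites(negatives, toy_proteins)

    def test_never_reuses_positive_sites(self, toy_proteins):
        positives = [SiteAnnotation("p3", 4, "positive"), SiteAnnotation("p3", 8, "positive")]
        negatives = sample_negatives(toy_proteins, positives, ratio=4.0, seed=1)
        assert {(n.protein_id, n.position) for n in negatives}.isdisjoint(
            {(p.protein_id, p.position) for p in positives}
        )

    def test_deficit_reported(self, toy_proteins):
        positives = [SiteAnnotation("p1", 2, "positive")]
        with pytest.raises(DatasetError, match="deficit"):
            sample_negatives(toy_proteins, positives, ratio=100.0, seed=0)

    def test_protein_without_free_lysines_contributes_nothing(self):
        proteins = [ProteinRecord("a", "MKA"), ProteinRecord("b", "AKAKA")]
        positives = [SiteAnnotation("a", 2, "positive")]
        negatives = sample_negatives(proteins, positives, ratio=2.0, seed=0)
        assert all(n.protein_id == "b" for n in negatives)

    def test_seed_determinism_and_variation(self, rng):
        proteome = [
            ProteinRecord(f"p{i}", "".join(rng.choice(list("AKLM"), size=60)))
            for i in range(10)
        ]
        positives = [SiteAnnotation(proteome[0].id, proteome[0].lysine_positions()[0], "positive")]
        draws = [
            tuple((n.protein_id, n.position)
                  for n in sample_negatives(proteome, positives, ratio=10.0, seed=s))
            for s in range(20)
        ]
        assert draws[0] == tuple(
            (n.protein_id, n.position)
            for n in sample_negatives(proteome, positives, ratio=10.0, seed=0)
        )
        assert len(set(draws)) > 1  # different seeds give different samples


class TestSplitByProtein:
    def test_four_fifths_of_189_is_151(self):
        proteins = [ProteinRecord(f"p{i}", "KK") for i in range(189)]
        split = split_by_protein(proteins, 0.8, seed=0)
        assert len(split.train_protein_ids) == 151
        assert len(split.test_protein_ids) == 38

    def test_fraction_one_puts_everything_in_train(self, toy_proteins):
        split = split_by_protein(toy_proteins, 1.0, seed=0)
        assert len(split.train_protein_ids) == 3 and not split.test_protein_ids

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_partition_is_disjoint_and_covering(self, toy_proteins, seed):
        split = split_by_protein(toy_proteins, 0.5, seed=seed)
        ids = {p.id for p in toy_proteins}
        assert split.train_protein_ids | split.test_protein_ids == ids
        assert not split.train_protein_ids & split.test_protein_ids

    def test_invalid_fraction(self, toy_proteins):
        for bad in (0.0, 1.5, -0.3):
            with pytest.raises(DatasetError):
                split_by_protein(toy_proteins, bad, seed=0)

    def test_sites_inherit_protein_partition(self, toy_proteins, toy_sites):
        split = split_by_protein(toy_proteins, 0.5, seed=3)
        stamped = assign_partitions(toy_sites, split)
        for site in stamped:
            assert site.partition == split.partition_of(site.protein_id)
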