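import numpy as np
import pandas as pd
import pytest

from strainvar.core_io import (
    GeneLocus,
    PWM,
    SampleMeta,
    extract_promoters,
    read_annotations,
    read_expression_matrix,
    read_fasta,
    read_homolog_map,
    read_jaspar,
    read_loci,
    reverse_complement,
    write_expression_matrix,
    write_fasta,
    write_loci,
)


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestExpressionIO:
    def test_read_small_matrix(self, tmp_path):
        mat = _write(
            tmp_path, "x.tsv",
            "gene_id\ts1\ts2\ng1\t1.5\t2.5\ng2\t3.0\t4.0\ng3\t5.0\t6.0\n",
        )
        meta = _write(
            tmp_path, "m.tsv",
            "sample_id\tstrain\tahr_variant\tancestry_LE\ns1\tLE\t0\t1.0\ns2\tLE\t0\t1.0\n",
        )
        X = read_expression_matrix(mat, meta)
        assert X.values.shape == (3, 2)
        assert X.samples[0].strain == "LE"

    def test_duplicate_gene_errors_with_name(self, tmp_path):
        mat = _write(tmp_path, "x.tsv", "gene_id\ts1\ng1\t1\ng1\t2\n")
        meta = _write(tmp_path, "m.tsv", "sample_id\tstrain\ns1\tLE\n")
        with pytest.raises(ValueError, match="g1"):
            read_expression_matrix(mat, meta)

    def test_missing_sample_metadata_errors(self, tmp_path):
        mat = _write(tmp_path, "x.tsv", "gene_id\ts1\ts2\ng1\t1\t2\n")
        meta = _write(tmp_path, "m.tsv", "sample_id\tstrain\ns1\tLE\n")
        with pytest.raises(ValueError, match="s2"):
            read_expression_matrix(mat, meta)

    def test_non_numeric_cell_names_location(self, tmp_path):
        mat = _write(tmp_path, "x.tsv", "gene_id\ts1\ng1\t1.0\ng2\toops\n")
        meta = _write(tmp_path, "m.tsv", "sample_id\tstrain\ns1\tLE\n")
        with pytest.raises(ValueError, match="g2"):
            read_expression_matrix(mat, meta)

    def test_round_trip(self, tmp_path, small_world):
        X, _ = small_world
        write_expression_matrix(X, tmp_path / "x.tsv", tmp_path / "m.tsv")
        back = read_expression_matrix(tmp_path / "x.tsv", tmp_path / "m.tsv")
        assert np.allclose(back.values.to_numpy(), X.values.to_numpy(), atol=1e-12)
        assert [s.sample_id for s in back.samples] == [s.sample_id for s in X.samples]
        assert back.samples[3].ancestry == X.samples[3].ancestry


class TestTables:
    def test_loci_round_trip(self, tmp_path):
        loci = [GeneLocus("g1", "chr1", 10, 500, "+", 10),
                GeneLocus("g2", "chr2", 5, 60, "-", 60)]
        write_loci(loci, tmp_path / "loci.tsv")
        assert read_loci(tmp_path / "loci.tsv") == loci

    def test_loci_missing_column(self, tmp_path):
        (tmp_path / "bad.tsv").write_text("gene_id\tchromosome\ng1\tchr1\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_loci(tmp_path / "bad.tsv")

    def test_annotation_and_homolog_tables(self, tmp_path):
        (tmp_path / "ann.tsv").write_text("gene_id\tterm_id\ng1\tT1\ng2\tT1\n")
        ann = read_annotations(tmp_path / "ann.tsv")
        assert list(ann["term_id"]) == ["T1", "T1"]
        (tmp_path / "map.tsv").write_text("gene_a\tgene_b\nr1\tm1\n")
        assert read_homolog_map(tmp_path / "map.tsv").shape == (1, 2)

    def test_invalid_locus_rejected(self):
        with pytest.raises(ValueError, match="start"):
            GeneLocus("g", "chr1", 100, 50, "+", 75)


class TestSampleMeta:
    def test_ancestry_must_sum_to_one(self):
        with pytest.raises(ValueError, match="ancestry"):
            SampleMeta("s", "LnA", {"LE": 0.5, "HW": 0.4})

    def test_ahr_variant_binary(self):
        with pytest.raises(ValueError, match="ahr_variant"):
            SampleMeta("s", "HW", {"HW": 1.0}, ahr_variant=2)


JASPAR_PLAIN = """>MA0001 TEST1
4 19 0
16 0 20
0 1 0
0 0 0
>MA0002 TEST2
1 2
3 4
5 6
7 8
"""

JASPAR_BRACKET = """>MA0001 TEST1
A [ 4 19 0 ]
C [ 16 0 20 ]
G [ 0 1 0 ]
T [ 0 0 0 ]
>MA0002 TEST2
A [ 1 2 ]
C [ 3 4 ]
G [ 5 6 ]
T [ 7 8 ]
"""


class TestJaspar:
    def test_plain_dialect(self, tmp_path):
        motifs = read_jaspar(_write(tmp_path, "m.jaspar", JASPAR_PLAIN))
        assert [m.motif_id for m in motifs] == ["MA0001", "MA0002"]
        assert [m.length for m in motifs] == [3, 2]

    def test_dialects_equivalent(self, tmp_path):
        plain = read_jaspar(_write(tmp_path, "p.jaspar", JASPAR_PLAIN))
        bracket = read_jaspar(_write(tmp_path, "b.jaspar", JASPAR_BRACKET))
        for a, b in zip(plain, bracket):
            assert np.array_equal(a.counts, b.counts)

    def test_zero_column_rejected(self, tmp_path):
        bad = ">M1 X\n0 1\n0 1\n0 1\n0 1\n"
        with pytest.raises(ValueError, match="zero column"):
            read_jaspar(_write(tmp_path, "bad.jaspar", bad))

    def test_ragged_rows_rejected(self, tmp_path):
        bad = ">M1 X\n1 2 3\n1 2\n1 2 3\n1 2 3\n"
        with pytest.raises(ValueError, match="unequal"):
            read_jaspar(_write(tmp_path, "bad.jaspar", bad))

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            PWM("M1", "X", np.array([[1.0, -1.0], [1, 1], [1, 1], [1, 1]]))


class TestPromoters:
    def test_default_window_is_2001_bp(self):
        rng = np.random.default_rng(0)
        genome = {"chr1": "".join(rng.choice(list("ACGT"), 5000))}
        loci = [GeneLocus("g1", "chr1", 2000, 3000, "+", 2500)]
        seqs = extract_promoters(genome, loci, 1000, 1000)
        assert len(seqs["g1"]) == 2001

    def test_zero_window_is_tss_base(self):
        genome = {"chr1": "ACGTACGTAC"}
        loci = [GeneLocus("g1", "chr1", 1, 10, "+", 3)]
        assert extract_promoters(genome, loci, 0, 0)["g1"] == "G"

    def test_minus_strand_reverse_complement(self):
        genome = {"chr1": "AACCGGTTAG"}
        # plus-strand window around tss=5 (+/-2): positions 3..7 = CCGGT
        loci_plus = [GeneLocus("gp", "chr1", 1, 10, "+", 5)]
        loci_minus = [GeneLocus("gm", "chr1", 1, 10, "-", 5)]
        plus = extract_promoters(genome, loci_plus, 2, 2)["gp"]
        minus = extract_promoters(genome, loci_minus, 2, 2)["gm"]
        assert plus == "CCGGT"
        assert minus == reverse_complement(plus) == "ACCGG"

    def test_truncation_at_chromosome_end(self, caplog):
        genome = {"chr1": "ACGTACGTAC"}
        loci = [GeneLocus("g1", "chr1", 1, 10, "+", 2)]
        with caplog.at_level("WARNING"):
            seqs = extract_promoters(genome, loci, 5, 3)
        assert seqs["g1"] == "ACGTA"  # clipped at position 1
        assert "truncated" in caplog.text

    def test_unknown_chromosome(self):
        with pytest.raises(KeyError, match="chrX"):
            extract_promoters({"chr1": "ACGT"}, [GeneLocus("g", "chrX", 1, 2, "+", 1)], 0, 0)

    def test_negative_window_rejected(self):
        with pytest.raises(ValueError):
            extract_promoters({"chr1": "ACGT"}, [], -1, 0)

    def test_fasta_round_trip(self, tmp_path):
        seqs = {"a": "ACGT" * 30, "b": "TTGCA"}
        write_fasta(seqs, tmp_path / "s.fa")
        assert read_fasta(tmp_path / "s.fa") == seqs

    def test_extraction_from_fasta_file_matches_dict(self, tmp_path):
        rng = np.random.default_rng(3)
        genome = {"chr1": "".join(rng.choice(list("ACGT"), 400))}
        write_fasta(genome, tmp_path / "g.fa")
        loci = [GeneLocus("g1", "chr1", 100, 300, "+", 200),
                GeneLocus("g2", "chr1", 100, 300, "-", 250)]
        from_file = extract_promoters(tmp_path / "g.fa", loci, 50, 50)
        from_dict = extract_promoters(genome, loci, 50, 50)
        assert from_file == from_dict
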