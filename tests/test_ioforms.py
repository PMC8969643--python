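"""Format round trips, domain rejection, and the AGP/N-run conventions."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from spermlink import CellAlleleMatrix, FormatError
from spermlink import ioforms as io
from spermlink.scaffold import Component, ScaffoldGroup, ScaffoldPlan

from conftest import make_matrix


@pytest.fixture
def demo_matrix():
    return make_matrix(
        {(0, 0): 1, (0, 1): 2, (1, 0): 3, (2, 1): 1},
        n_markers=3,
        n_cells=2,
    )


class TestHetVcf:
    def test_roundtrip_preserves_markers_exactly(self, tmp_path, demo_matrix):
        path = tmp_path / "het.vcf"
        io.write_het_vcf(demo_matrix.markers, path, {"ctg1": 100})
        back = io.read_het_sites(path)
        pd.testing.assert_frame_equal(
            back, demo_matrix.markers.astype({"pos": back["pos"].dtype})
        )

    def test_indels_and_multiallelics_are_skipped(self, tmp_path):
        vcf = tmp_path / "mixed.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=ctg1,length=1000>\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "ctg1\t10\t.\tA\tC\t.\t.\t.\n"
            "ctg1\t20\t.\tG\tT\t.\t.\t.\n"
            "ctg1\t30\t.\tT\tA\t.\t.\t.\n"
            "ctg1\t40\t.\tTA\tT\t.\t.\t.\n"
            "ctg1\t50\t.\tA\tC,G\t.\t.\t.\n"
        )
        markers = io.read_het_sites(vcf)
        assert len(markers) == 3
        assert markers["pos"].tolist() == [10, 20, 30]

    def test_empty_body_gives_empty_marker_list(self, tmp_path):
        vcf = tmp_path / "empty.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        )
        assert len(io.read_het_sites(vcf)) == 0

    def test_malformed_vcf_raises_format_error(self, tmp_path):
        bad = tmp_path / "bad.vcf"
        bad.write_text("this is not a vcf\n")
        with pytest.raises(FormatError):
            io.read_het_sites(bad)


class TestAlleleMatrix:
    def test_mtx_roundtrip(self, tmp_path, demo_matrix):
        io.write_allele_matrix(demo_matrix, tmp_path / "m.mtx", tmp_path / "b.txt")
        back = io.read_allele_matrix(
            tmp_path / "m.mtx", tmp_path / "b.txt", demo_matrix.markers
        )
        assert back.barcodes == demo_matrix.barcodes
        assert (back.X != demo_matrix.X).nnz == 0

    def test_out_of_domain_value_rejected(self, tmp_path, demo_matrix):
        (tmp_path / "m.mtx").write_text(
            "%%MatrixMarket matrix coordinate integer general\n3 2 1\n1 1 4\n"
        )
        (tmp_path / "b.txt").write_text("c0\nc1\n")
        with pytest.raises(FormatError, match="values"):
            io.read_allele_matrix(
                tmp_path / "m.mtx", tmp_path / "b.txt", demo_matrix.markers
            )

    def test_explicit_zero_entries_are_missing(self, tmp_path, demo_matrix):
        (tmp_path / "m.mtx").write_text(
            "%%MatrixMarket matrix coordinate integer general\n3 2 2\n"
            "1 1 0\n2 2 2\n"
        )
        (tmp_path / "b.txt").write_text("c0\nc1\n")
        back = io.read_allele_matrix(
            tmp_path / "m.mtx", tmp_path / "b.txt", demo_matrix.markers
        )
        assert back.X.nnz == 1
        assert back.X[1, 1] == 2

    def test_dimension_mismatch_names_both_counts(self, tmp_path, demo_matrix):
        (tmp_path / "m.mtx").write_text(
            "%%MatrixMarket matrix coordinate integer general\n5 2 1\n1 1 1\n"
        )
        (tmp_path / "b.txt").write_text("c0\nc1\n")
        with pytest.raises(FormatError, match="5.*3|3.*5"):
            io.read_allele_matrix(
                tmp_path / "m.mtx", tmp_path / "b.txt", demo_matrix.markers
            )

    def test_duplicate_barcodes_rejected(self, demo_matrix):
        with pytest.raises(FormatError, match="duplicate"):
            CellAlleleMatrix(
                markers=demo_matrix.markers,
                barcodes=["c0", "c0"],
                X=demo_matrix.X,
            )


class TestCellVcf:
    def test_roundtrip_is_identity_on_sparse_content(self, tmp_path, demo_matrix):
        path = tmp_path / "cells.vcf"
        io.write_cell_vcf(demo_matrix, path, {"ctg1": 100})
        back = io.read_cell_vcf(path)
        assert back.barcodes == demo_matrix.barcodes
        assert (back.X != demo_matrix.X).nnz == 0

    def test_haploid_encoding_in_sample_fields(self, tmp_path, demo_matrix):
        path = tmp_path / "cells.vcf"
        io.write_cell_vcf(demo_matrix, path, {"ctg1": 100})
        lines = [
            l.split("\t") for l in path.read_text().splitlines()
            if not l.startswith("#")
        ]
        # marker 0: cell0 ref, cell1 alt; marker 1: cell0 both; marker 2 missing c0
        assert lines[0][9] == "0" and lines[0][10] == "1"
        assert lines[1][9] == "0/1"
        assert lines[2][9] in ("./.", ".")

    def test_empty_matrix_writes_header_only(self, tmp_path):
        empty = CellAlleleMatrix(
            markers=pd.DataFrame(columns=["contig", "pos", "ref", "alt"]),
            barcodes=["c0"],
            X=sparse.csr_matrix((0, 1), dtype=np.int8),
        )
        path = tmp_path / "empty.vcf"
        io.write_cell_vcf(empty, path)
        body = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert body == []


@pytest.fixture
def demo_plan():
    return ScaffoldPlan(
        groups=[
            ScaffoldGroup(
                name="lg1",
                components=[
                    Component(kind="contig", length=100, contig="a", orientation="+"),
                    Component(kind="gap", length=10_000),
                    Component(kind="contig", length=200, contig="b", orientation="-"),
                    Component(kind="gap", length=10_000),
                    Component(
                        kind="contig", length=500, contig="c", unoriented=True
                    ),
                ],
            )
        ],
        unplaced=[("d", 50)],
        gap_len=10_000,
    )


@pytest.fixture
def demo_seqs():
    rng = np.random.default_rng(0)
    bases = np.array(list("ACGT"))
    return {
        "a": "".join(rng.choice(bases, 100)),
        "b": "".join(rng.choice(bases, 200)),
        "c": "".join(rng.choice(bases, 500)),
        "d": "".join(rng.choice(bases, 50)),
    }


class TestAgpAndFasta:
    def test_scaffold_length_includes_gaps(self, tmp_path, demo_plan, demo_seqs):
        lengths = io.write_scaffold_fasta(demo_plan, demo_seqs, tmp_path / "s.fa")
        assert lengths["lg1"] == 100 + 10_000 + 200 + 10_000 + 500

    def test_unoriented_contig_becomes_n_run_plus_separate_record(
        self, tmp_path, demo_plan, demo_seqs
    ):
        path = tmp_path / "s.fa"
        lengths = io.write_scaffold_fasta(demo_plan, demo_seqs, path)
        seqs = io.read_fasta_sequences(path)
        assert seqs["lg1"].endswith("N" * 500)
        assert lengths["lg1_unoriented_c"] == 500
        assert seqs["lg1_unoriented_c"] == demo_seqs["c"]

    def test_minus_contig_is_reverse_complemented(self, tmp_path, demo_plan, demo_seqs):
        from Bio.Seq import Seq

        seqs = None
        io.write_scaffold_fasta(demo_plan, demo_seqs, tmp_path / "s.fa")
        seqs = io.read_fasta_sequences(tmp_path / "s.fa")
        segment = seqs["lg1"][10_100 : 10_300]
        assert segment == str(Seq(demo_seqs["b"]).reverse_complement())

    def test_missing_sequence_names_the_contig(self, tmp_path, demo_plan, demo_seqs):
        del demo_seqs["b"]
        with pytest.raises(FormatError, match="'b'"):
            io.write_scaffold_fasta(demo_plan, demo_seqs, tmp_path / "s.fa")

    def test_agp_is_valid_and_unoriented_contigs_are_gap_lines(
        self, tmp_path, demo_plan
    ):
        path = tmp_path / "s.agp"
        io.write_agp(demo_plan, path)
        assert io.validate_agp(path) == 5
        lines = [
            l.split("\t") for l in path.read_text().splitlines()
            if not l.startswith("#")
        ]
        kinds = [l[4] for l in lines]
        assert kinds == ["W", "N", "W", "N", "N"]
        assert lines[0][8] == "+" and lines[2][8] == "-"
        assert lines[4][6] == "contig"  # the unoriented contig's N-run

    def test_validator_rejects_non_contiguous_coordinates(self, tmp_path):
        path = tmp_path / "bad.agp"
        path.write_text(
            "##agp-version 2.1\n"
            "lg1\t1\t100\t1\tW\ta\t1\t100\t+\n"
            "lg1\t150\t200\t2\tW\tb\t1\t51\t+\n"
        )
        with pytest.raises(FormatError, match="contiguous"):
            io.validate_agp(path)


class TestMapTsv:
    def test_roundtrip(self, tmp_path):
        df = pd.DataFrame(
            {
                "group": ["lg1"],
                "contig": ["a"],
                "orientation": ["+"],
                "phys_start": [1],
                "phys_end": [100],
                "cM_start": [0.0],
                "cM_end": [1.5],
            }
        )
        io.write_map_tsv(df, tmp_path / "map.tsv")
        back = io.read_map_tsv(tmp_path / "map.tsv")
        pd.testing.assert_frame_equal(back, df)


class TestContigLengths:
    def test_from_fasta_and_tsv_agree(self, tmp_path):
        (tmp_path / "c.fa").write_text(">a\nACGT\n>b\nACGTACGT\n")
        (tmp_path / "c.tsv").write_text("contig\tlength\na\t4\nb\t8\n")
        assert io.read_contig_lengths(tmp_path / "c.fa") == {"a": 4, "b": 8}
        assert io.read_contig_lengths(tmp_path / "c.tsv") == {"a": 4, "b": 8}
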