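import numpy as np
import pytest

from bivalency.genome_io import (
    ParseError,
    ValidationError,
    make_tag_library,
    read_bedgraph,
    read_chrom_sizes,
    read_expression,
    read_gene_set,
    read_qpcr_plate,
    read_tags,
    read_tss,
    write_bedgraph,
    write_tags,
    write_tss,
)


class TestReadTss:
    @pytest.mark.parametrize(
        "row, gene, tss, strand",
        [
            ("chr1\t1000\t1500\tgeneA\t0\t+", "geneA", 1000, "+"),
            ("chr1\t1000\t1500\tgeneB\t0\t-", "geneB", 1499, "-"),
        ],
    )
    def test_strand_conventions(self, tmp_path, row, gene, tss, strand):
        """TSS is the interval start on + and the half-open end - 1 on -."""
        path = tmp_path / "tss.bed"
        path.write_text(row + "\n")
        (rec,) = read_tss(path)
        assert (rec.gene_id, rec.tss, rec.strand) == (gene, tss, strand)

    def test_duplicate_gene_id_rejected(self, tmp_path):
        path = tmp_path / "tss.bed"
        path.write_text("chr1\t100\t200\tgeneA\t0\t+\nchr2\t5\t9\tgeneA\t0\t+\n")
        with pytest.raises(ValidationError, match="geneA"):
            read_tss(path)

    def test_four_column_form_and_parse_error_names_line(self, tmp_path):
        path = tmp_path / "tss.txt"
        path.write_text("chr1\t5000\tgeneA\t-\n")
        (rec,) = read_tss(path)
        assert rec.tss == 5000 and rec.strand == "-"
        bad = tmp_path / "bad.bed"
        bad.write_text("chr1\t100\t200\tok\t0\t+\nchr1\tnotanumber\t9\tx\t0\t+\n")
        with pytest.raises(ParseError, match=":2:"):
            read_tss(bad)

    def test_round_trip(self, tmp_path):
        path = tmp_path / "tss.bed"
        path.write_text("chr1\t1000\t1500\ta\t0\t+\nchr1\t9000\t9100\tb\t0\t-\n")
        records = read_tss(path)
        out = tmp_path / "rt.bed"
        write_tss(records, out)
        back = read_tss(out)
        assert [(r.gene_id, r.chrom, r.tss, r.strand) for r in back] == [
            (r.gene_id, r.chrom, r.tss, r.strand) for r in records
        ]


class TestReadTags:
    def test_count_equals_records_and_five_prime_reduction(self, tmp_path):
        path = tmp_path / "tags.bed"
        path.write_text(
            "chr1\t100\t136\t.\t0\t+\n"
            "chr1\t100\t136\t.\t0\t-\n"
            "chr1\t500\t536\n"  # strandless defaults to +
        )
        lib = read_tags(path, "s1", "H3K4me3", "cond", {"chr1": 10_000})
        assert lib.total_tags == 3
        assert sorted(lib.tags["pos"]) == [100, 135, 500]

    def test_tag_beyond_chromosome_end_rejected(self, tmp_path):
        path = tmp_path / "tags.bed"
        # minus-strand read: its 5' tag position is end-1 = 135, past a
        # 120 bp chromosome even though the interval start is inside
        path.write_text("chr1\t100\t136\t.\t0\t-\n")
        with pytest.raises(ValidationError):
            read_tags(path, "s1", "H3", "c", {"chr1": 120})
        with pytest.raises(ValidationError, match="unknown chromosome"):
            read_tags(path, "s1", "H3", "c", {"chr2": 1000})

    def test_empty_file_gives_zero_tags(self, tmp_path, caplog):
        path = tmp_path / "tags.bed"
        path.write_text("")
        with caplog.at_level("WARNING"):
            lib = read_tags(path, "s1", "H3", "c", {"chr1": 100})
        assert lib.total_tags == 0
        assert any("empty" in r.message for r in caplog.records)

    def test_library_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        pos = rng.integers(0, 5000, size=200)
        lib = make_tag_library("s", "H3K27me3", "c", ["chr1"] * 200, pos)
        out = tmp_path / "tags.bed"
        write_tags(lib, out)
        back = read_tags(out, "s", "H3K27me3", "c", {"chr1": 5000})
        assert back.total_tags == lib.total_tags
        assert sorted(back.tags["pos"]) == sorted(lib.tags["pos"])

    def test_sam_reading_matches_bed_convention(self, tmp_path):
        sam = tmp_path / "tags.sam"
        sam.write_text(
            "@HD\tVN:1.6\tSO:unsorted\n"
            "@SQ\tSN:chr1\tLN:10000\n"
            "r1\t0\tchr1\t101\t60\t36M\t*\t0\t0\t" + "A" * 36 + "\t*\n"
            "r2\t16\tchr1\t101\t60\t36M\t*\t0\t0\t" + "A" * 36 + "\t*\n"
        )
        lib = read_tags(sam, "s", "H3", "c", {"chr1": 10_000}, fmt="sam")
        # SAM POS is 1-based: forward 5' = 100 (0-based), reverse 5' = 135
        assert sorted(lib.tags["pos"]) == [100, 135]


class TestBedgraph:
    def test_round_trip_single_interval(self, tmp_path):
        path = tmp_path / "x.bedgraph"
        write_bedgraph([("chr1", 0, 100, 1.5)], path)
        assert path.read_text() == "chr1\t0\t100\t1.5\n"
        assert read_bedgraph(path) == [("chr1", 0, 100, 1.5)]

    def test_empty_input_writes_empty_file(self, tmp_path):
        path = tmp_path / "x.bedgraph"
        write_bedgraph([], path)
        assert path.read_text() == ""

    @pytest.mark.parametrize(
        "intervals",
        [
            [("chr1", 100, 200, 1.0), ("chr1", 0, 50, 1.0)],  # unsorted
            [("chr1", 0, 100, 1.0), ("chr1", 50, 150, 1.0)],  # overlapping
        ],
    )
    def test_unsorted_or_overlapping_rejected(self, tmp_path, intervals):
        with pytest.raises(ValidationError):
            write_bedgraph(intervals, tmp_path / "x.bedgraph")


class TestTables:
    def test_chrom_sizes(self, tmp_path):
        path = tmp_path / "chrom.sizes"
        path.write_text("chr1\t1000\nchr2\t500\n")
        assert read_chrom_sizes(path) == {"chr1": 1000, "chr2": 500}
        bad = tmp_path / "bad.sizes"
        bad.write_text("chr1\t0\n")
        with pytest.raises(ValidationError):
            read_chrom_sizes(bad)

    def test_gene_set_validated_against_annotation(self, tmp_path):
        tss = tmp_path / "tss.bed"
        tss.write_text("chr1\t100\t200\tgeneA\t0\t+\n")
        annotation = read_tss(tss)
        gs_path = tmp_path / "testis_specific.csv"
        gs_path.write_text("gene_id\ngeneA\n")
        gs = read_gene_set(gs_path, annotation=annotation)
        assert gs.name == "testis_specific" and gs.members == {"geneA"}
        gs_path.write_text("gene_id\ngeneZ\n")
        with pytest.raises(ValidationError):
            read_gene_set(gs_path, annotation=annotation)

    def test_expression_requires_finite_values(self, tmp_path):
        path = tmp_path / "expr.csv"
        path.write_text("gene_id,condition,value\ng1,E10.5,5.0\n")
        assert len(read_expression(path)) == 1
        path.write_text("gene_id,condition,value\ng1,E10.5,inf\n")
        with pytest.raises(ValidationError):
            read_expression(path)

    def test_qpcr_plate_ct_range(self, tmp_path):
        path = tmp_path / "plate.csv"
        path.write_text(
            "target,antibody,replicate,ct_bound,ct_unbound\nSox9,H3K4me3,1,24.0,25.0\n"
        )
        assert len(read_qpcr_plate(path)) == 1
        path.write_text(
            "target,antibody,replicate,ct_bound,ct_unbound\nSox9,H3K4me3,1,50.0,25.0\n"
        )
        with pytest.raises(ValidationError):
            read_qpcr_plate(path)
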