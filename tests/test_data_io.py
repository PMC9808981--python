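import numpy as np
import pytest

from dpescan.data_io import (
    ParseError,
    count_reads_per_exon,
    read_count_matrix,
    read_exon_annotation,
    read_gmt,
    read_sample_sheet,
    write_count_matrix,
)
from dpescan.types import CountMatrix, ExonCatalog, ExonRecord

from conftest import write_sam


def gtf_line(chrom, start1, end1, exon_id=None, gene="G1", feature="exon"):
    attrs = f'gene_id "{gene}";'
    if exon_id:
        attrs += f' exon_id "{exon_id}";'
    return f"{chrom}\tsrc\t{feature}\t{start1}\t{end1}\t.\t+\t.\t{attrs}"


class TestAnnotation:
    def test_gtf_one_based_inclusive_becomes_zero_based_half_open(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(gtf_line("chr1", 100, 200, "e1") + "\n")
        cat = read_exon_annotation(p, "gtf")
        rec = cat.get("e1")
        assert (rec.start, rec.end) == (99, 200)

    def test_bed_used_as_is(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t99\t200\te1\n")
        cat = read_exon_annotation(p, "bed")
        rec = cat.get("e1")
        assert (rec.start, rec.end, rec.exon_id) == (99, 200, "e1")

    def test_duplicate_ids_get_ordinal_suffix(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(gtf_line("chr1", 1, 50, "E") + "\n" + gtf_line("chr1", 100, 150, "E") + "\n")
        cat = read_exon_annotation(p, "gtf")
        assert cat.exon_ids == ["E", "E_2"]

    def test_non_exon_features_skipped(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(gtf_line("chr1", 1, 50, "e1", feature="gene") + "\n"
                     + gtf_line("chr1", 1, 50, "e1") + "\n")
        assert len(read_exon_annotation(p, "gtf")) == 1

    @pytest.mark.parametrize("content,fmt", [
        ("chr1\tsrc\texon\tBAD\t200\t.\t+\t.\tgene_id \"G\";", "gtf"),
        ("chr1\tsrc\texon\t1\t200\t.\t+\t.\tfoo \"bar\";", "gtf"),  # no gene_id
        ("chr1\tonly-two-fields", "bed"),
        ("chr1\tX\t200\te1", "bed"),
    ])
    def test_malformed_line_names_line_number(self, tmp_path, content, fmt):
        p = tmp_path / f"bad.{fmt}"
        p.write_text(content + "\n")
        with pytest.raises(ParseError, match=":1"):
            read_exon_annotation(p, fmt)

    def test_gtf_to_bed_roundtrip_preserves_interval(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(gtf_line("chr3", 1234, 5678, "e9") + "\n")
        rec = read_exon_annotation(p, "gtf").get("e9")
        bed = tmp_path / "a.bed"
        bed.write_text(f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.exon_id}\n")
        back = read_exon_annotation(bed, "bed").get("e9")
        assert (back.chrom, back.start, back.end) == (rec.chrom, rec.start, rec.end)

    def test_interval_lookup_returns_exact_overlaps(self):
        cat = ExonCatalog([
            ExonRecord("a", "g", "chr1", 0, 100),
            ExonRecord("b", "g", "chr1", 100, 200),
            ExonRecord("c", "g", "chr2", 0, 100),
        ])
        assert cat.overlapping("chr1", 50, 150) == {"a", "b"}
        assert cat.overlapping("chr1", 100, 101) == {"b"}  # half-open: a ends at 100
        assert cat.overlapping("chr3", 0, 10) == set()


class TestSampleSheet:
    def test_basic_row(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("sample_id,group,sex\nS1,M,male\n")
        (s,) = read_sample_sheet(p)
        assert (s.sample_id, s.group, s.sex) == ("S1", "M", "male")

    def test_duplicate_sample_id_rejected(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("sample_id,group,sex\nS1,M,male\nS1,N,female\n")
        with pytest.raises(ParseError, match="S1"):
            read_sample_sheet(p)

    def test_unknown_group_names_row(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("sample_id,group,sex\nS1,M,male\nS2,X,male\n")
        with pytest.raises(ParseError, match="row 3"):
            read_sample_sheet(p)


class TestCountMatrix:
    def test_round_trip_identity(self, tmp_path):
        m = CountMatrix(np.array([[1, 2], [3, 4]]), ["e1", "e2"], ["s1", "s2"])
        p = tmp_path / "c.tsv"
        write_count_matrix(m, p)
        back = read_count_matrix(p)
        assert np.array_equal(back.counts, m.counts)
        assert back.exon_ids == m.exon_ids and back.sample_ids == m.sample_ids

    @pytest.mark.parametrize("cell", ["-1", "3.7"])
    def test_bad_cell_rejected_with_address(self, tmp_path, cell):
        p = tmp_path / "c.tsv"
        p.write_text(f"exon_id\ts1\ts2\ne1\t5\t{cell}\n")
        with pytest.raises(ParseError, match="s2"):
            read_count_matrix(p)


class TestGmt:
    def test_read_and_dedup(self, tmp_path):
        p = tmp_path / "a.gmt"
        p.write_text("SetA\tdesc\tG1\tG2\nSetB\tdesc\tG1\tG1\n")
        sets = read_gmt(p)
        assert sets[0].members == {"G1", "G2"}
        assert sets[1].members == {"G1"}

    def test_short_line_errors(self, tmp_path):
        p = tmp_path / "a.gmt"
        p.write_text("SetA\tdesc\n")
        with pytest.raises(ParseError, match=":1"):
            read_gmt(p)


class TestCounting:
    def catalog(self):
        return ExonCatalog([
            ExonRecord("e1", "g1", "chr1", 100, 200),
            ExonRecord("e2", "g1", "chr1", 300, 400),
        ])

    def test_read_inside_single_exon(self, tmp_path):
        sam = write_sam(tmp_path / "a.sam",
                        [{"qname": "r1", "chrom": "chr1", "pos": 120, "cigar": "50M"}],
                        {"chr1": 1000})
        counts, stats = count_reads_per_exon(sam, self.catalog())
        assert counts.tolist() == [1, 0] and stats["assigned"] == 1

    def test_read_spanning_two_exons_is_ambiguous(self, tmp_path):
        # spliced read touching both e1 and e2
        sam = write_sam(tmp_path / "a.sam",
                        [{"qname": "r1", "chrom": "chr1", "pos": 150, "cigar": "50M120N50M"}],
                        {"chr1": 1000})
        counts, stats = count_reads_per_exon(sam, self.catalog())
        assert counts.tolist() == [0, 0] and stats["ambiguous"] == 1

    def test_pair_counted_once_as_fragment(self, tmp_path):
        reads = [
            {"qname": "p1", "chrom": "chr1", "pos": 110, "cigar": "40M", "flag": 99,
             "rnext": "=", "pnext": 151, "tlen": 80},
            {"qname": "p1", "chrom": "chr1", "pos": 150, "cigar": "40M", "flag": 147,
             "rnext": "=", "pnext": 111, "tlen": -80},
        ]
        sam = write_sam(tmp_path / "a.sam", reads, {"chr1": 1000})
        counts, stats = count_reads_per_exon(sam, self.catalog())
        assert counts.tolist() == [1, 0] and stats["assigned"] == 1

    def test_low_mapq_and_flagged_reads_skipped(self, tmp_path):
        reads = [
            {"qname": "r1", "chrom": "chr1", "pos": 120, "cigar": "50M", "mapq": 5},
            {"qname": "r2", "chrom": "chr1", "pos": 120, "cigar": "50M", "flag": 1024},  # dup
            {"qname": "r3", "chrom": "chr1", "pos": 120, "cigar": "50M", "flag": 256},   # secondary
        ]
        sam = write_sam(tmp_path / "a.sam", reads, {"chr1": 1000})
        counts, _ = count_reads_per_exon(sam, self.catalog())
        assert counts.sum() == 0

    def test_counts_match_brute_force_oracle(self, tmp_path):
        rng = np.random.default_rng(7)
        records, pos = [], 0
        for i in range(10):
            pos += int(rng.integers(20, 120))
            end = pos + int(rng.integers(50, 200))
            records.append(ExonRecord(f"e{i}", "g", "chr1", pos, end))
            pos = end
        cat = ExonCatalog(records)
        reads = [
            {"qname": f"r{k}", "chrom": "chr1",
             "pos": int(rng.integers(0, pos)), "cigar": "100M"}
            for k in range(100)
        ]
        sam = write_sam(tmp_path / "r.sam", reads, {"chr1": pos + 200})
        counts, stats = count_reads_per_exon(sam, cat)
        oracle = {r.exon_id: 0 for r in records}
        n_amb = n_un = 0
        for r in reads:
            hits = [x.exon_id for x in records
                    if r["pos"] < x.end and r["pos"] + 100 > x.start]
            if len(hits) == 1:
                oracle[hits[0]] += 1
            elif hits:
                n_amb += 1
            else:
                n_un += 1
        assert counts.tolist() == [oracle[r.exon_id] for r in records]
        assert stats["ambiguous"] == n_amb and stats["unassigned"] == n_un
        # conservation: every eligible fragment lands in exactly one bucket
        assert stats["assigned"] + n_amb + n_un == len(reads)

    def test_unmapped_only_warns_and_returns_zero(self, tmp_path):
        sam = write_sam(tmp_path / "a.sam",
                        [{"qname": "r1", "chrom": "chr1", "pos": 120, "cigar": "50M",
                          "flag": 4}],
                        {"chr1": 1000})
        with pytest.warns(UserWarning, match="no mapped reads"):
            counts, _ = count_reads_per_exon(sam, self.catalog())
        assert counts.sum() == 0

    def test_non_union_mode_rejected(self, tmp_path):
        sam = write_sam(tmp_path / "a.sam", [], {"chr1": 1000})
        with pytest.raises(ValueError, match="union"):
            count_reads_per_exon(sam, self.catalog(), mode="intersection-strict")
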