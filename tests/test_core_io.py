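import numpy as np
import pandas as pd
import pytest

from dendtrans import core_io
from dendtrans.core_io import (CountMatrix, ORFRecord, ParseError, Thresholds,
                               TranscriptModel, read_annotation, read_counts,
                               select_longest_transcript)


def bed12_line(name, total, thick_start, thick_end, strand="+",
               blocks=None):
    if blocks is None:
        blocks = [(0, total)]
    sizes = ",".join(str(e - s) for s, e in blocks) + ","
    starts = ",".join(str(s) for s, e in blocks) + ","
    return "\t".join(map(str, ["chr1", 0, total, name, 0, strand,
                               thick_start, thick_end, 0, len(blocks),
                               sizes, starts]))


class TestTranscriptModel:
    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            TranscriptModel("g", "t", -1, 300, 100)

    def test_cds_not_multiple_of_three_warns(self):
        with pytest.warns(UserWarning):
            TranscriptModel("g", "t", 10, 301, 100)

    def test_seq_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            TranscriptModel("g", "t", 5, 300, 100, utr5_seq="ACGT")

    def test_gc_computed_from_seq(self):
        m = TranscriptModel("g", "t", 4, 300, 100, utr5_seq="GCGC")
        assert m.gc_frac == 1.0


class TestReadAnnotation:
    def test_noncoding_bed12_all_zero(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text(bed12_line("g1|t1", 500, 100, 100) + "\n")
        (m,) = read_annotation(p)
        assert (m.utr5_len, m.cds_len, m.utr3_len) == (0, 0, 0)
        assert not m.is_coding

    def test_plus_strand_regions(self, tmp_path):
        # 900 nt single exon, CDS genomic [300, 600) -> 300/300/300
        p = tmp_path / "a.bed"
        p.write_text(bed12_line("g1|t1", 900, 300, 600) + "\n")
        (m,) = read_annotation(p)
        assert (m.utr5_len, m.cds_len, m.utr3_len) == (300, 300, 300)

    def test_plus_strand_multiblock_matches_interval_arithmetic(self, tmp_path):
        # blocks [0,200)+[400,1100): 900 nt; CDS genomic [500,800)
        blocks = [(0, 200), (400, 1100)]
        p = tmp_path / "a.bed"
        p.write_text(bed12_line("g1|t1", 1100, 500, 800, blocks=blocks) + "\n")
        (m,) = read_annotation(p)
        # independent interval arithmetic: exonic bases before 500 = 200+100
        assert (m.utr5_len, m.cds_len, m.utr3_len) == (300, 300, 300)

    def test_minus_strand_swaps_utrs(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text(bed12_line("g1|t1", 900, 300, 660, strand="-") + "\n")
        (m,) = read_annotation(p)
        assert (m.utr5_len, m.cds_len, m.utr3_len) == (240, 360, 300)

    def test_region_sum_equals_exon_total(self, tmp_path):
        p = tmp_path / "a.bed"
        lines = [bed12_line(f"g{i}|t{i}", 300 + 60 * i, 60, 60 + 3 * (20 + i * 10))
                 for i in range(8)]
        p.write_text("\n".join(lines) + "\n")
        for m in read_annotation(p):
            assert m.utr5_len + m.cds_len + m.utr3_len == 300 + 60 * int(m.tx_id[1:])

    def test_malformed_line_reports_number(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text(bed12_line("g1|t1", 900, 300, 600) + "\nnot\ta\tbed\tline\n")
        with pytest.raises(ParseError, match="line 2"):
            read_annotation(p)

    def test_duplicate_tx_rejected(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("\n".join([bed12_line("g1|t1", 900, 300, 600)] * 2) + "\n")
        with pytest.raises(ParseError, match="duplicate"):
            read_annotation(p)

    def test_minimal_gtf(self, tmp_path):
        p = tmp_path / "a.gtf"
        attrs = 'gene_id "g1"; transcript_id "t1";'
        rows = [
            ["chr1", "x", "exon", "1", "900", ".", "+", ".", attrs],
            ["chr1", "x", "CDS", "301", "600", ".", "+", ".", attrs],
        ]
        p.write_text("\n".join("\t".join(r) for r in rows) + "\n")
        (m,) = read_annotation(p)
        assert (m.utr5_len, m.cds_len, m.utr3_len) == (300, 300, 300)

    def test_gtf_minus_strand(self, tmp_path):
        p = tmp_path / "a.gtf"
        attrs = 'gene_id "g1"; transcript_id "t1";'
        rows = [
            ["chr1", "x", "exon", "1", "900", ".", "-", ".", attrs],
            ["chr1", "x", "CDS", "301", "600", ".", "-", ".", attrs],
        ]
        p.write_text("\n".join("\t".join(r) for r in rows) + "\n")
        (m,) = read_annotation(p)
        assert (m.utr5_len, m.cds_len, m.utr3_len) == (300, 300, 300)


class TestSelectLongest:
    def test_single_transcript_identity(self):
        ms = [TranscriptModel("g1", "t1", 10, 300, 10)]
        assert select_longest_transcript(ms) == ms

    def test_max_length_retained(self):
        ms = [TranscriptModel("g1", "t1", 100, 600, 300),
              TranscriptModel("g1", "t2", 200, 600, 400)]
        assert [m.tx_id for m in select_longest_transcript(ms)] == ["t2"]

    def test_tie_break_lexicographic(self):
        ms = [TranscriptModel("g1", "tB", 100, 600, 300),
              TranscriptModel("g1", "tA", 100, 600, 300)]
        assert [m.tx_id for m in select_longest_transcript(ms)] == ["tA"]

    def test_output_size_equals_gene_count(self, strong_transcriptome):
        models, _, _ = strong_transcriptome
        out = select_longest_transcript(models)
        assert len(out) == len({m.gene_id for m in models})


class TestCountMatrix:
    def test_default_lib_sizes_are_column_sums(self):
        cm = CountMatrix(["a", "b"], ["s1", "s2"], np.array([[1, 2], [3, 4]]))
        assert np.array_equal(cm.lib_sizes, [4, 6])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            CountMatrix(["a"], ["s1"], np.array([[-1]]))

    def test_zero_library_warns(self):
        with pytest.warns(UserWarning):
            CountMatrix(["a", "b"], ["s1", "s2"], np.zeros((2, 2), dtype=int))

    def test_round_trip(self, tmp_path):
        cm = CountMatrix(["a", "b"], ["s1", "s2"], np.array([[1, 2], [3, 4]]))
        core_io.write_counts(cm, tmp_path / "c.tsv")
        back = read_counts(tmp_path / "c.tsv")
        assert back.feature_ids == cm.feature_ids
        assert back.sample_ids == cm.sample_ids
        assert np.array_equal(back.counts, cm.counts)
        assert np.array_equal(back.lib_sizes, cm.lib_sizes)

    def test_unknown_sample_column_named_in_error(self, tmp_path):
        pd.DataFrame({"feature_id": ["a"], "s1": [1], "rogue": [2]}).to_csv(
            tmp_path / "c.tsv", sep="\t", index=False)
        sheet = pd.DataFrame({"sample_id": ["s1"], "condition": ["rest"],
                              "bait": ["Pan"], "fraction": ["input"],
                              "biotin": ["plus"], "replicate": [1], "batch": ["b1"]})
        with pytest.raises(ParseError, match="rogue"):
            read_counts(tmp_path / "c.tsv", sheet)

    def test_non_integer_counts_rejected(self, tmp_path):
        pd.DataFrame({"feature_id": ["a"], "s1": [1.5]}).to_csv(
            tmp_path / "c.tsv", sep="\t", index=False)
        with pytest.raises(ParseError, match="non-integer"):
            read_counts(tmp_path / "c.tsv")


class TestThresholds:
    def test_defaults_match_printed_cutoffs(self):
        th = Thresholds()
        assert th.t_loc_single == 1 and th.t_loc_diff == 1.25
        assert th.z_cut == 1.96 and th.p_cds == 0.05
        assert th.basemean_min_cds == 1 and th.basemean_min_utr5 == 3
        assert th.orf_min_len_nt == 10 and th.orf_score == 0.7
        assert th.clip_pseudocount == 0.1 and th.clip_p == 0.2
        assert th.motif_min_score_frac == 0.95 and th.motif_fdr == 0.1
        assert th.ms_impute_width == 0.3 and th.ms_impute_downshift == 1.8
        assert th.guard_t_up == 2 and th.guard_t_down == -2
        assert th.psite_offset_nt == 12 and th.pca_top_n == 500

    def test_yaml_round_trip(self, tmp_path):
        th = Thresholds(z_cut=2.5, clip_p=0.1)
        th.to_yaml(tmp_path / "cfg.yaml")
        assert Thresholds.from_yaml(tmp_path / "cfg.yaml") == th

    def test_unknown_key_rejected(self, tmp_path):
        (tmp_path / "cfg.yaml").write_text("bogus: 1\n")
        with pytest.raises(ValueError, match="bogus"):
            Thresholds.from_yaml(tmp_path / "cfg.yaml")


class TestORFRecord:
    def test_end_before_start_rejected(self):
        with pytest.raises(ValueError):
            ORFRecord("t1", 10, 10, "ATG", "uORF", 0.9)

    def test_frame_violation_rejected(self):
        with pytest.raises(ValueError):
            ORFRecord("t1", 0, 10, "ATG", "uORF", 0.9)

    def test_round_trip(self, tmp_path):
        orfs = [ORFRecord("t1", 0, 12, "ATG", "uORF", 0.9),
                ORFRecord("t2", 3, 30, "CTG", "uORF", 0.5)]
        core_io.write_orfs(orfs, tmp_path / "o.tsv")
        assert core_io.read_orfs(tmp_path / "o.tsv") == orfs


class TestResultTable:
    def test_p_adj_below_p_rejected(self):
        df = pd.DataFrame({"feature_id": ["a"], "p": [0.5], "p_adj": [0.1]})
        with pytest.raises(ValueError):
            core_io.validate_result_table(df)

    def test_round_trip(self, tmp_path):
        df = pd.DataFrame({"feature_id": ["a", "b"], "log2fc": [1.5, -0.5],
                           "p": [0.01, 0.5], "p_adj": [0.02, 0.5]})
        core_io.write_result_table(df, tmp_path / "r.tsv")
        back = core_io.read_result_table(tmp_path / "r.tsv")
        pd.testing.assert_frame_equal(back, df)


class TestSampleSheet:
    def test_bad_level_rejected(self, tmp_path):
        sheet = pd.DataFrame({"sample_id": ["s1"], "condition": ["asleep"],
                              "bait": ["Pan"], "fraction": ["input"],
                              "biotin": ["plus"], "replicate": [1], "batch": ["b1"]})
        sheet.to_csv(tmp_path / "s.tsv", sep="\t", index=False)
        with pytest.raises(ParseError, match="condition"):
            core_io.read_sample_sheet(tmp_path / "s.tsv")

    def test_duplicate_sample_rejected(self, tmp_path):
        sheet = pd.DataFrame({"sample_id": ["s1", "s1"], "condition": ["rest"] * 2,
                              "bait": ["Pan"] * 2, "fraction": ["input"] * 2,
                              "biotin": ["plus"] * 2, "replicate": [1, 2],
                              "batch": ["b1", "b2"]})
        sheet.to_csv(tmp_path / "s.tsv", sep="\t", index=False)
        with pytest.raises(ParseError, match="duplicate"):
            core_io.read_sample_sheet(tmp_path / "s.tsv")
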