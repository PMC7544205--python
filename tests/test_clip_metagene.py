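"""Unit tests for annotation handling, conversion calling and metagene profiles."""

import numpy as np
import pandas as pd
import pytest

import rnptools as rt
from rnptools.clip_metagene import CrosslinkTrack

GTF_LINES = """\
chr1\tsrc\ttranscript\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1"; transcript_biotype "protein_coding";
chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1"; transcript_biotype "protein_coding";
chr1\tsrc\ttranscript\t1\t300\t.\t-\t.\tgene_id "g2"; transcript_id "t2"; transcript_biotype "protein_coding";
chr1\tsrc\texon\t1\t100\t.\t-\t.\tgene_id "g2"; transcript_id "t2"; transcript_biotype "protein_coding";
chr1\tsrc\texon\t201\t300\t.\t-\t.\tgene_id "g2"; transcript_id "t2"; transcript_biotype "protein_coding";
chr1\tsrc\ttranscript\t401\t500\t.\t+\t.\tgene_id "g3"; transcript_id "t3"; transcript_biotype "lincRNA";
chr1\tsrc\texon\t401\t500\t.\t+\t.\tgene_id "g3"; transcript_id "t3"; transcript_biotype "lincRNA";
"""


def track_from(rows) -> CrosslinkTrack:
    return CrosslinkTrack(pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "score"]))


def uniform_exonic_track(transcript, score=1.0) -> CrosslinkTrack:
    rows = [(transcript.chrom, p, transcript.strand, score)
            for s, e in transcript.exons for p in range(s, e)]
    return track_from(rows)


def mirror_annotation(ann, genome_len):
    flip = {"+": "-", "-": "+"}
    return rt.GenomeAnnotation([
        rt.Transcript(t.transcript_id, t.gene_id, t.chrom, flip[t.strand],
                      [(genome_len - e, genome_len - s) for s, e in t.exons],
                      t.biotype)
        for t in ann.transcripts])


def mirror_track(track, genome_len):
    df = track.records.copy()
    df["pos"] = genome_len - 1 - df["pos"]
    df["strand"] = df["strand"].map({"+": "-", "-": "+"})
    return CrosslinkTrack(df)


class TestLoadAnnotation:
    @pytest.fixture
    def gtf(self, tmp_path):
        path = tmp_path / "toy.gtf"
        path.write_text(GTF_LINES)
        return path

    def test_coordinate_convention(self, gtf):
        ann = rt.load_annotation(gtf)
        assert ann.by_id["t1"].exons == [(100, 200)]

    def test_minus_strand_first_exon_is_rightmost(self, gtf):
        ann = rt.load_annotation(gtf)
        t2 = ann.by_id["t2"]
        assert t2.exons_in_rank_order()[0] == (200, 300)
        assert t2.exon_category(1) == "first"
        assert t2.exon_category(2) == "last"

    def test_monoexonic_category(self, gtf):
        ann = rt.load_annotation(gtf)
        assert ann.by_id["t1"].exon_category(1) == "monoexonic"

    def test_biotype_filter(self, gtf):
        assert "t3" not in rt.load_annotation(gtf).by_id
        assert "t3" in rt.load_annotation(gtf, biotype_filter=None).by_id

    def test_transcript_without_exons_skipped(self, tmp_path, caplog):
        path = tmp_path / "bad.gtf"
        path.write_text(GTF_LINES + 'chr1\tsrc\ttranscript\t601\t700\t.\t+\t.\t'
                        'gene_id "g4"; transcript_id "t4";\n')
        with caplog.at_level("WARNING"):
            ann = rt.load_annotation(path)
        assert "t4" not in ann.by_id
        assert any("no exon records" in r.message for r in caplog.records)


class TestLoadTrackBed:
    def test_per_base_distribution(self, tmp_path):
        bed = tmp_path / "a.bed"
        bed.write_text("chr1\t10\t13\tpeak1\t3\t+\n")
        track = rt.load_track_bed(bed)
        assert len(track) == 3
        assert track.positions_in("chr1", "+", 10, 13)[1].tolist() == [3, 3, 3]

    def test_overlapping_intervals_sum(self, tmp_path):
        bed = tmp_path / "a.bed"
        bed.write_text("chr1\t10\t12\tp1\t1\t+\nchr1\t11\t13\tp2\t2\t+\n")
        track = rt.load_track_bed(bed)
        pos, score = track.positions_in("chr1", "+", 10, 13)
        assert dict(zip(pos.tolist(), score.tolist())) == {10: 1, 11: 3, 12: 2}

    def test_empty_file(self, tmp_path):
        bed = tmp_path / "a.bed"
        bed.write_text("")
        assert len(rt.load_track_bed(bed)) == 0

    def test_malformed_strand_errors_with_line_number(self, tmp_path):
        bed = tmp_path / "a.bed"
        bed.write_text("chr1\t10\t12\tp1\t1\t+\nchr1\t11\t13\tp2\t2\t*\n")
        with pytest.raises(ValueError, match=":2"):
            rt.load_track_bed(bed)


class TestCallConversions:
    def test_plus_strand_t_to_c(self, tmp_path):
        pileup = tmp_path / "p.txt"
        pileup.write_text("chr1\t100\tT\t5\t..CC.\tIIIII\n")
        track = rt.call_conversions(pileup)
        rec = track.records.iloc[0]
        assert (rec.chrom, rec.pos, rec.strand, rec.score) == ("chr1", 99, "+", 2.0)

    def test_minus_strand_a_to_g(self, tmp_path):
        pileup = tmp_path / "p.txt"
        pileup.write_text("chr1\t200\tA\t4\t,,gg\tIIII\n")
        rec = rt.call_conversions(pileup).records.iloc[0]
        assert (rec.chrom, rec.pos, rec.strand, rec.score) == ("chr1", 199, "-", 2.0)

    def test_non_t_a_reference_ignored(self, tmp_path):
        pileup = tmp_path / "p.txt"
        pileup.write_text("chr1\t300\tG\t3\tAAa\tIII\n")
        assert len(rt.call_conversions(pileup)) == 0

    def test_asymmetry(self, tmp_path):
        # uppercase G at ref A is a forward-read mismatch, not a conversion;
        # lowercase c at ref T likewise
        pileup = tmp_path / "p.txt"
        pileup.write_text("chr1\t10\tA\t3\t,,G\tIII\nchr1\t20\tT\t3\t..c\tIII\n")
        assert len(rt.call_conversions(pileup)) == 0

    def test_pileup_grammar_tokens_skipped(self, tmp_path):
        # read start ^I, read end $, insertion +2AT, deletion placeholder *
        pileup = tmp_path / "p.txt"
        pileup.write_text("chr1\t100\tT\t5\t^I.$,+2ATCC*\tIIIII\n")
        rec = rt.call_conversions(pileup).records.iloc[0]
        assert rec.score == 2.0

    def test_depth_mismatch_errors_with_line_number(self, tmp_path):
        pileup = tmp_path / "p.txt"
        pileup.write_text("chr1\t100\tT\t7\t..CC.\tIIIII\n")
        with pytest.raises(ValueError, match="line 1"):
            rt.call_conversions(pileup)

    def test_line_order_invariance(self, tmp_path):
        lines = ["chr1\t100\tT\t3\t.CC\tIII",
                 "chr1\t50\tT\t2\tC.\tII",
                 "chr2\t10\tA\t2\tgg\tII"]
        a, b = tmp_path / "a.txt", tmp_path / "b.txt"
        a.write_text("\n".join(lines) + "\n")
        b.write_text("\n".join(reversed(lines)) + "\n")
        pd.testing.assert_frame_equal(rt.call_conversions(a).records,
                                      rt.call_conversions(b).records)


class TestMetageneTranscriptProfile:
    def test_uniform_signal_is_flat(self, toy_annotation):
        tx = toy_annotation.by_id["txP"]
        ann = rt.GenomeAnnotation([tx])
        profile = rt.metagene_transcript_profile(
            uniform_exonic_track(tx), ann, n_bins=10)
        # mature length 950, uniform unit signal -> 95 per bin
        np.testing.assert_allclose(profile.values, 95.0)
        assert profile.total == pytest.approx(950.0)

    def test_unit_signal_at_tss_lands_in_bin_one(self, toy_annotation):
        for tid, tss in [("txP", 1000), ("txM", 6399)]:
            tx = toy_annotation.by_id[tid]
            ann = rt.GenomeAnnotation([tx])
            track = track_from([(tx.chrom, tss, tx.strand, 1.0)])
            profile = rt.metagene_transcript_profile(track, ann, n_bins=20)
            assert profile.values[0] > 0
            assert profile.values[1:].sum() == 0.0

    def test_intronic_signal_excluded(self, toy_annotation):
        tx = toy_annotation.by_id["txP"]
        ann = rt.GenomeAnnotation([tx])
        track = track_from([(tx.chrom, 1400, "+", 5.0)])  # intron
        profile = rt.metagene_transcript_profile(track, ann, n_bins=10)
        assert profile.total == 0.0

    def test_total_mass_equals_assigned_signal(self, toy_annotation):
        rng = np.random.default_rng(1)
        rows = [("chr1", int(p), s, float(sc)) for p, s, sc in zip(
            rng.integers(900, 8600, size=200),
            rng.choice(["+", "-"], size=200),
            rng.uniform(0.5, 3.0, size=200))]
        track = track_from(rows)
        profile = rt.metagene_transcript_profile(track, toy_annotation, 25)
        expected = sum(
            track.positions_in(t.chrom, t.strand, s, e)[1].sum()
            for t in toy_annotation.transcripts for s, e in t.exons)
        assert profile.values.sum() * profile.n_features == pytest.approx(expected)
        assert profile.total == pytest.approx(expected)

    def test_transcript_shorter_than_bins(self, toy_annotation):
        tx = toy_annotation.by_id["txMono"]
        ann = rt.GenomeAnnotation([tx])
        profile = rt.metagene_transcript_profile(
            uniform_exonic_track(tx), ann, n_bins=701)
        assert profile.total == pytest.approx(500.0)
        assert profile.values.sum() == pytest.approx(500.0)


class TestExonAnchoredProfile:
    def test_length_threshold_is_strict(self):
        ann = rt.GenomeAnnotation([
            rt.Transcript("short", "g1", "chr1", "+", [(0, 150)]),
            rt.Transcript("edge", "g2", "chr1", "+", [(1000, 1200)]),
            rt.Transcript("ok", "g3", "chr1", "+", [(2000, 2201)]),
        ])
        rows = [("chr1", p, "+", 1.0) for p in (75, 1100, 2100)]
        profile = rt.exon_anchored_profile(track_from(rows), ann, "monoexonic",
                                           min_exon_len=200, flank_bins=10)
        assert profile.n_features == 1  # only the 201 nt exon qualifies

    def test_duplicate_exons_average_to_single_profile(self):
        t1 = rt.Transcript("t1", "g1", "chr1", "+", [(0, 300)])
        t2 = rt.Transcript("t2", "g2", "chr1", "+", [(1000, 1300)])
        rows = [("chr1", 10, "+", 2.0), ("chr1", 150, "+", 1.0),
                ("chr1", 1010, "+", 2.0), ("chr1", 1150, "+", 1.0)]
        track = track_from(rows)
        single = rt.exon_anchored_profile(
            track, rt.GenomeAnnotation([t1]), "monoexonic", flank_bins=20)
        both = rt.exon_anchored_profile(
            track, rt.GenomeAnnotation([t1, t2]), "monoexonic", flank_bins=20)
        np.testing.assert_allclose(both.values, single.values)
        assert both.n_features == 2

    def test_empty_category_warns(self, toy_annotation, caplog):
        track = track_from([("chr1", 1005, "+", 1.0)])
        with caplog.at_level("WARNING"):
            profile = rt.exon_anchored_profile(track, toy_annotation,
                                               "internal", min_exon_len=500)
        assert profile.n_features == 0
        assert any("internal" in r.message for r in caplog.records)


class TestJunctionOffsetHistogram:
    def test_terminal_base_is_offset_one(self, toy_annotation):
        # internal exon of txP is [1500, 1750); its 3'-terminal base is 1749
        track = track_from([("chr1", 1749, "+", 4.0)])
        hist = rt.junction_offset_histogram(track, toy_annotation, max_offset=30)
        assert hist.loc[1] == 4.0
        assert hist.sum() == 4.0

    def test_minus_strand_offset_from_genomic_left_end(self, toy_annotation):
        # rank-1 exon of txM is [6000, 6400); position k bases from its
        # genomic left end is offset k in mature orientation
        k = 7
        track = track_from([("chr1", 6000 + k - 1, "-", 2.0)])
        hist = rt.junction_offset_histogram(track, toy_annotation, max_offset=30)
        assert hist.loc[k] == 2.0

    def test_strand_mirror_symmetry(self, toy_annotation):
        plus = track_from([("chr1", 2400 - 27, "+", 3.0)])  # skipped: last exon
        inner = track_from([("chr1", 1750 - 27, "+", 3.0)])
        hist = rt.junction_offset_histogram(inner, toy_annotation, 40)
        assert hist.loc[27] == 3.0
        assert rt.junction_offset_histogram(plus, toy_annotation, 40).sum() == 0

    def test_offsets_beyond_max_dropped(self, toy_annotation):
        track = track_from([("chr1", 1500, "+", 1.0)])  # offset 250
        hist = rt.junction_offset_histogram(track, toy_annotation, max_offset=50)
        assert hist.sum() == 0.0

    def test_requires_multiexonic(self):
        ann = rt.GenomeAnnotation(
            [rt.Transcript("t", "g", "chr1", "+", [(0, 100)])])
        with pytest.raises(ValueError, match="multiexonic"):
            rt.junction_offset_histogram(track_from([("chr1", 5, "+", 1.0)]),
                                         ann, 30)


class TestStrandMirrorInvariance:
    def test_all_profiles_bit_identical_under_reflection(self, toy_annotation):
        rng = np.random.default_rng(8)
        rows = []
        for t in toy_annotation.transcripts:
            for s, e in t.exons:
                picks = rng.integers(s, e, size=8)
                rows += [(t.chrom, int(p), t.strand, float(sc))
                         for p, sc in zip(picks, rng.uniform(0.5, 4, size=8))]
        track = track_from(rows)
        genome_len = 10000
        m_ann = mirror_annotation(toy_annotation, genome_len)
        m_track = mirror_track(track, genome_len)

        a = rt.metagene_transcript_profile(track, toy_annotation, 50)
        b = rt.metagene_transcript_profile(m_track, m_ann, 50)
        assert np.array_equal(a.values, b.values)

        for category in ("monoexonic", "first", "internal", "last"):
            a = rt.exon_anchored_profile(track, toy_annotation, category,
                                         min_exon_len=200, flank_bins=30)
            b = rt.exon_anchored_profile(m_track, m_ann, category,
                                         min_exon_len=200, flank_bins=30)
            assert np.array_equal(a.values, b.values)

        ha = rt.junction_offset_histogram(track, toy_annotation, 60)
        hb = rt.junction_offset_histogram(m_track, m_ann, 60)
        assert ha.equals(hb)
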