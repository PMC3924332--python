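"""Genome I/O, six-frame translation, ORF extraction and coordinate maps."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from famfinder.seqio import (
    STANDARD_CODE,
    GenomicSequence,
    extract_orfs,
    map_aa_to_genomic,
    read_annotation,
    read_genome,
    revcomp,
    six_frame_translate,
    translate_nt,
    write_fasta,
    write_gff3,
)
from famfinder.seqio import AnnotationModel

from oracles import split_orfs, translate_codons


class TestReadGenome:
    def test_round_trip_two_records(self, tmp_path):
        p = tmp_path / "g.fa"
        write_fasta([("chr1", "ACGTACGT"), ("chr2", "GGGTTT")], p)
        recs = read_genome(p)
        assert [(r.id, r.length) for r in recs] == [("chr1", 8), ("chr2", 6)]

    def test_lowercase_normalized(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">s\nacgt\n")
        assert read_genome(p)[0].residues == "ACGT"

    def test_ambiguity_maps_to_n_with_warning(self, tmp_path, caplog):
        p = tmp_path / "g.fa"
        p.write_text(">s\nACGR\n")
        with caplog.at_level("WARNING"):
            rec = read_genome(p)[0]
        assert rec.residues == "ACGN"
        assert any("replaced with N" in m for m in caplog.messages)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text("")
        with pytest.raises(ValueError):
            read_genome(p)

    def test_duplicate_ids_rejected(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">s\nACGT\n>s\nTTTT\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_genome(p)


class TestSixFrame:
    def test_forward_frame(self):
        t = six_frame_translate(GenomicSequence("s", "ATGGCCTAA"))
        assert t[0].aa == "MA*"

    def test_reverse_frame(self):
        t = six_frame_translate(GenomicSequence("s", "CAT"))
        minus1 = [x for x in t if x.frame == -1][0]
        assert minus1.aa == "M"

    def test_short_sequence_gives_six_empty(self):
        t = six_frame_translate(GenomicSequence("s", "AC"))
        assert len(t) == 6 and all(x.aa == "" for x in t)

    def test_n_codon_translates_to_x(self):
        t = six_frame_translate(GenomicSequence("s", "ATGNNN"))
        assert t[0].aa == "MX"

    def test_matches_codon_table_oracle(self):
        rng = np.random.default_rng(0)
        nt = "".join("ACGT"[i] for i in rng.integers(0, 4, 500))
        g = GenomicSequence("s", nt)
        for t in six_frame_translate(g):
            src = nt[t.rc_offset :] if t.frame > 0 else revcomp(nt)[t.rc_offset :]
            assert t.aa == translate_codons(src, STANDARD_CODE)

    def test_every_codon_covered_once_per_strand(self):
        # six-frame completeness: forward codon starts partition positions
        g = GenomicSequence("s", "ACGTACGTACGT")
        frames = six_frame_translate(g)
        fwd_starts = sorted(
            t.rc_offset + 3 * i
            for t in frames
            if t.frame > 0
            for i in range(len(t.aa))
        )
        assert fwd_starts == list(range(0, g.length - 2))


class TestOrfs:
    def test_min_length_boundary(self):
        g = GenomicSequence("s", "ATG" * 14 + "TAA")
        t = six_frame_translate(g)[0]
        assert extract_orfs(t, min_len=15) == []
        assert len(extract_orfs(t, min_len=14)) == 1

    def test_split_and_threshold(self):
        aa = "A" * 15 + "*" + "A" * 14
        t = six_frame_translate(
            GenomicSequence("s", "GCC" * 15 + "TAA" + "GCC" * 14)
        )[0]
        assert t.aa == aa
        orfs = extract_orfs(t, min_len=15)
        assert len(orfs) == 1 and orfs[0].aa == "A" * 15

    def test_x_does_not_break_orf(self):
        t = six_frame_translate(
            GenomicSequence("s", "GCC" * 8 + "NNN" + "GCC" * 8)
        )[0]
        orfs = extract_orfs(t, min_len=15)
        assert len(orfs) == 1 and "X" in orfs[0].aa

    def test_matches_split_oracle_bulk(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            n = int(rng.integers(1, 120))
            aa = "".join(rng.choice(list("ACDEF*"), n))
            nt = "".join(
                {"A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "*": "TAA"}[c]
                for c in aa
            )
            t = six_frame_translate(GenomicSequence("s", nt))[0]
            assert t.aa == aa
            got = [(o.aa_start, o.aa_end, o.aa) for o in extract_orfs(t, 5)]
            assert got == split_orfs(aa, 5)

    def test_idempotent_and_deterministic(self):
        t = six_frame_translate(GenomicSequence("s", "ATGAAATAAATGAAA" * 10))[0]
        a = extract_orfs(t, 3)
        b = extract_orfs(t, 3)
        assert a == b


class TestAaMapping:
    def test_plus_frame_identity(self):
        t = six_frame_translate(GenomicSequence("s", "ATGGCCTAA"))[0]
        assert map_aa_to_genomic(t, 0, 2) == (0, 6, "+")

    def test_minus_frame_geometry(self):
        t = [
            x
            for x in six_frame_translate(GenomicSequence("s", "ACGTACGTACGT"))
            if x.frame == -1
        ][0]
        assert map_aa_to_genomic(t, 0, 1) == (9, 12, "-")

    def test_out_of_range(self):
        t = six_frame_translate(GenomicSequence("s", "ATGGCCTAA"))[0]
        with pytest.raises(IndexError):
            map_aa_to_genomic(t, 0, 4)

    def test_round_trip_random(self):
        rng = np.random.default_rng(2)
        nt = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        g = GenomicSequence("s", nt)
        frames = six_frame_translate(g)
        for _ in range(200):
            t = frames[int(rng.integers(0, 6))]
            if len(t.aa) < 2:
                continue
            a0 = int(rng.integers(0, len(t.aa) - 1))
            a1 = int(rng.integers(a0 + 1, len(t.aa) + 1))
            gs, ge, strand = map_aa_to_genomic(t, a0, a1)
            assert ge - gs == 3 * (a1 - a0)
            piece = nt[gs:ge]
            if strand == "-":
                piece = revcomp(piece)
            assert translate_nt(piece) == t.aa[a0:a1]

    @given(st.integers(10, 80), st.integers(0, 5))
    def test_span_is_three_times_length(self, n, frame_i):
        nt = ("ACGT" * 30)[: 4 * n // 2]
        g = GenomicSequence("s", nt)
        t = six_frame_translate(g)[frame_i]
        if t.aa:
            gs, ge, _ = map_aa_to_genomic(t, 0, len(t.aa))
            assert ge - gs == 3 * len(t.aa)


class TestAnnotation:
    def _write(self, tmp_path, genome_nt, gff_body):
        gp = tmp_path / "g.fa"
        write_fasta([("chr1", genome_nt)], gp)
        ap = tmp_path / "a.gff3"
        ap.write_text("##gff-version 3\n" + gff_body)
        return gp, ap

    def test_single_exon_forward(self, tmp_path):
        nt = "AAA" + "ATGGCCGAATAA" + "CCC"
        gp, ap = self._write(
            tmp_path,
            nt,
            "chr1\t.\tgene\t4\t15\t.\t+\t.\tID=g1\n"
            "chr1\t.\tmRNA\t4\t15\t.\t+\t.\tID=m1;Parent=g1\n"
            "chr1\t.\tCDS\t4\t15\t.\t+\t0\tID=c1;Parent=m1\n",
        )
        models = read_annotation(ap, read_genome(gp))
        assert len(models) == 1
        assert models[0].protein == "MAE"
        assert models[0].translation_ok

    def test_two_exon_minus_strand(self, tmp_path):
        # spliced minus-strand CDS: revcomp(exon2 + exon1 in genome order)
        exon2 = revcomp("ATGGCC")  # transcription-first exon, higher coords
        exon1 = revcomp("GAATAA")
        nt = "AA" + exon1 + "GTTTAG" + exon2 + "CC"
        gp, ap = self._write(
            tmp_path,
            nt,
            "chr1\t.\tgene\t3\t20\t.\t-\t.\tID=g1\n"
            "chr1\t.\tmRNA\t3\t20\t.\t-\t.\tID=m1;Parent=g1\n"
            "chr1\t.\tCDS\t3\t8\t.\t-\t0\tID=c1;Parent=m1\n"
            "chr1\t.\tCDS\t15\t20\t.\t-\t0\tID=c2;Parent=m1\n",
        )
        models = read_annotation(ap, read_genome(gp))
        assert models[0].protein == "MAE"
        assert models[0].exons == [(14, 20), (2, 8)]  # transcription order

    def test_no_cds_features(self, tmp_path):
        gp, ap = self._write(
            tmp_path,
            "ACGTACGTACGT",
            "chr1\t.\tgene\t1\t12\t.\t+\t.\tID=g1\n"
            "chr1\t.\tmRNA\t1\t12\t.\t+\t.\tID=m1;Parent=g1\n",
        )
        assert read_annotation(ap, read_genome(gp)) == []

    def test_gff_round_trip(self, tmp_path):
        m = AnnotationModel(
            gene_id="m1",
            seq_id="chr1",
            strand="+",
            exons=[(3, 15)],
            protein="MAE",
        )
        gp = tmp_path / "g.fa"
        write_fasta([("chr1", "AAA" + "ATGGCCGAATAA" + "CCC")], gp)
        out = tmp_path / "out.gff3"
        write_gff3([m], out)
        back = read_annotation(out, read_genome(gp))
        assert back[0].exons == [(3, 15)]
        assert back[0].protein == "MAE"

    def test_aa_to_genomic_blocks_spans_junction(self):
        m = AnnotationModel(
            gene_id="g", seq_id="c", strand="+", exons=[(0, 9), (100, 112)]
        )
        # aa [2,5) covers CDS nt [6,15): 3 nt in exon1, 6 in exon2
        assert m.aa_to_genomic_blocks(2, 5) == [(6, 9), (100, 106)]


def test_family_alignment_reads_stockholm(tmp_path):
    from famfinder.hmm import FamilyAlignment

    p = tmp_path / "fam.sto"
    p.write_text(
        "# STOCKHOLM 1.0\n"
        "seq1  MKWV-C\n"
        "seq2  MKWVAC\n"
        "//\n"
    )
    fam = FamilyAlignment.read(p)
    assert fam.members == [("seq1", "MKWV-C"), ("seq2", "MKWVAC")]
    assert fam.columns == 6
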