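import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ectlnc.seqio import (
    AlphabetError,
    FastaFormatError,
    GenomicInterval,
    Gff3FormatError,
    TranscriptModel,
    read_fasta,
    read_gff3,
    reverse_complement,
    spliced_cdna,
    write_fasta,
    write_gff3,
)
from ectlnc.simulate import random_sequence

nt = st.text(alphabet="ACGTN", min_size=0, max_size=200)


class TestReverseComplement:
    @pytest.mark.parametrize(
        "seq,expected",
        [("AACG", "CGTT"), ("N", "N"), ("ACGT", "ACGT"), ("", "")],
    )
    def test_known_values(self, seq, expected):
        assert reverse_complement(seq) == expected

    @given(nt)
    @settings(max_examples=50, deadline=None)
    def test_involution_and_length(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq
        assert len(reverse_complement(seq)) == len(seq)

    def test_rejects_bad_alphabet(self):
        with pytest.raises(AlphabetError):
            reverse_complement("ACGU")


class TestFasta:
    def test_case_normalized_and_multi_record(self, tmp_path):
        p = tmp_path / "x.fa"
        p.write_text(">x\nacgt\n>b desc here\nCC\n")
        seqs = read_fasta(p)
        assert seqs == {"x": "ACGT", "b": "CC"}

    def test_non_acgtn_becomes_n(self, tmp_path):
        p = tmp_path / "x.fa"
        p.write_text(">x\nACRYGT\n")
        assert read_fasta(p)["x"] == "ACNNGT"

    def test_duplicate_id_rejected(self, tmp_path):
        p = tmp_path / "x.fa"
        p.write_text(">a\nAA\n>a\nCC\n")
        with pytest.raises(FastaFormatError, match="a"):
            read_fasta(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_fasta(tmp_path / "nope.fa")

    def test_round_trip_50_records(self, tmp_path, rng):
        original = {
            f"seq{i}": random_sequence(rng, int(rng.integers(1, 400)))
            for i in range(50)
        }
        path = tmp_path / "round.fa"
        write_fasta(original, path)
        assert read_fasta(path) == original


def _random_model(rng, tid="t1", chrom="chr1", strand="+"):
    n_exons = int(rng.integers(1, 5))
    pos = int(rng.integers(0, 50))
    exons = []
    for _ in range(n_exons):
        length = int(rng.integers(1, 120))
        exons.append(GenomicInterval(chrom, pos, pos + length, strand))
        pos += length + int(rng.integers(1, 80))
    locus = GenomicInterval(chrom, exons[0].start, exons[-1].end, strand)
    return TranscriptModel(tid, tid.split(".")[0], locus, exons, "lncRNA")


class TestGff3:
    def test_coordinate_convention(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t1\t300\t.\t+\t.\tID=g1\n"
            "chr1\tsrc\tmRNA\t1\t300\t.\t+\t.\tID=t1;Parent=g1\n"
            "chr1\tsrc\texon\t1\t4\t.\t+\t.\tID=e1;Parent=t1\n"
            "chr1\tsrc\texon\t201\t300\t.\t+\t.\tID=e2;Parent=t1\n"
        )
        (model,) = read_gff3(p)
        assert model.exons[0] == GenomicInterval("chr1", 0, 4, "+")
        assert len(model.exons[0]) == 4
        assert model.spliced_length == 104

    def test_spliced_length_two_exons(self, tmp_path):
        p = tmp_path / "b.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tmRNA\t1\t300\t.\t+\t.\tID=t1\n"
            "chr1\tsrc\texon\t1\t100\t.\t+\t.\tParent=t1\n"
            "chr1\tsrc\texon\t201\t300\t.\t+\t.\tParent=t1\n"
        )
        (model,) = read_gff3(p)
        assert model.spliced_length == 200

    def test_transcript_without_exons_gets_locus_exon(self, tmp_path):
        p = tmp_path / "c.gff3"
        p.write_text(
            "##gff-version 3\nchr1\tsrc\tlnc_RNA\t11\t60\t.\t-\t.\tID=t9\n"
        )
        (model,) = read_gff3(p)
        assert model.exons == [GenomicInterval("chr1", 10, 60, "-")]

    def test_exon_outside_transcript_rejected(self, tmp_path):
        p = tmp_path / "d.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tmRNA\t10\t50\t.\t+\t.\tID=t1\n"
            "chr1\tsrc\texon\t5\t40\t.\t+\t.\tParent=t1\n"
        )
        with pytest.raises(Gff3FormatError):
            read_gff3(p)

    def test_round_trip_preserves_intervals(self, tmp_path, rng):
        models = [_random_model(rng, tid=f"t{i}.1") for i in range(20)]
        path = tmp_path / "round.gff3"
        write_gff3(models, path)
        back = {m.transcript_id: m for m in read_gff3(path)}
        assert set(back) == {m.transcript_id for m in models}
        for m in models:
            assert back[m.transcript_id].locus == m.locus
            assert back[m.transcript_id].exons == m.exons


class TestSplicedCdna:
    def test_plus_strand_single_exon(self):
        genome = {"c": "ACGTT"}
        m = TranscriptModel(
            "t", "g", GenomicInterval("c", 0, 4, "+"), [GenomicInterval("c", 0, 4, "+")]
        )
        assert spliced_cdna(m, genome).seq == "ACGT"

    def test_minus_strand_reverse_complements(self):
        genome = {"c": "AACGT"}
        m = TranscriptModel(
            "t", "g", GenomicInterval("c", 0, 4, "-"), [GenomicInterval("c", 0, 4, "-")]
        )
        assert spliced_cdna(m, genome).seq == "CGTT"

    def test_out_of_bounds_exon(self):
        m = TranscriptModel(
            "t", "g", GenomicInterval("c", 0, 10, "+"), [GenomicInterval("c", 0, 10, "+")]
        )
        with pytest.raises(Exception):
            spliced_cdna(m, {"c": "ACGT"})

    def test_length_equals_exon_sum_both_strands(self, rng):
        genome = {"chr1": "".join(np.random.default_rng(1).choice(list("ACGT"), 2000))}
        for i in range(100):
            strand = "+" if i % 2 else "-"
            m = _random_model(rng, tid=f"t{i}", strand=strand)
            assert len(spliced_cdna(m, genome)) == m.spliced_length

    def test_cdna_to_genomic_round(self, rng):
        genome = {"chr1": random_sequence(rng, 2000)}
        m = _random_model(rng, tid="tx")
        positions = [m.cdna_to_genomic(i) for i in range(m.spliced_length)]
        # each genomic position lies in some exon, in order
        assert positions == sorted(positions)
        for p in positions:
            assert any(e.start <= p < e.end for e in m.exons)
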