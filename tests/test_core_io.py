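"""Core model invariants and format round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isoatlas import io as io_mod
from isoatlas.core import (
    Annotation,
    GenomeInterval,
    TranscriptModel,
    ValidationError,
    make_transcript,
)
from isoatlas.tracks import SignalTrack, merge_intervals


class TestGenomeInterval:
    def test_rejects_degenerate_intervals(self):
        with pytest.raises(ValidationError):
            GenomeInterval("chr1", 10, 10)
        with pytest.raises(ValidationError):
            GenomeInterval("chr1", -1, 5)
        with pytest.raises(ValidationError):
            GenomeInterval("", 0, 5)

    def test_overlap_length(self):
        a = GenomeInterval("chr1", 0, 10)
        assert a.overlap_length(GenomeInterval("chr1", 5, 20)) == 5
        assert a.overlap_length(GenomeInterval("chr2", 5, 20)) == 0


class TestTranscriptModel:
    def test_strand_aware_tss(self):
        plus = make_transcript("t1", "g", "chr1", "+", [(100, 200), (300, 400)])
        minus = make_transcript("t2", "g", "chr1", "-", [(100, 200), (300, 400)])
        assert plus.tss == 100 and plus.tes == 399
        assert minus.tss == 399 and minus.tes == 100

    def test_intron_chain(self):
        t = make_transcript("t", "g", "chr1", "+", [(0, 10), (20, 30), (45, 50)])
        assert t.intron_chain == ((10, 20), (30, 45))
        assert t.spliced_length == 25

    @pytest.mark.parametrize(
        "exons",
        [
            [(0, 10), (10, 20)],  # no gap
            [(0, 10), (5, 20)],  # overlap
            [],
        ],
    )
    def test_rejects_bad_exon_chains(self, exons):
        with pytest.raises(ValidationError):
            TranscriptModel(
                "t", "g", "chr1", "+",
                tuple(GenomeInterval("chr1", s, e, "+") for s, e in exons),
            )

    def test_rejects_unstranded(self):
        with pytest.raises(ValidationError):
            make_transcript("t", "g", "chr1", ".", [(0, 10)])


class TestGtf:
    def test_coordinate_conversion_is_identity_on_single_exon(self, tmp_path):
        # 1-based closed 10..100 -> 0-based half-open [9, 100)
        p = tmp_path / "one.gtf"
        p.write_text(
            'chr1\tx\texon\t10\t100\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
        )
        ann = io_mod.read_gtf(p)
        (t,) = list(ann)
        assert (t.exons[0].start, t.exons[0].end) == (9, 100)

    def test_out_of_order_exons_are_sorted(self, tmp_path):
        p = tmp_path / "two.gtf"
        p.write_text(
            'chr1\tx\texon\t301\t400\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
            'chr1\tx\texon\t10\t100\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
        )
        ann = io_mod.read_gtf(p)
        (t,) = list(ann)
        # line-by-line parse-and-sort oracle
        expected = sorted([(300, 400), (9, 100)])
        assert [(e.start, e.end) for e in t.exons] == expected

    def test_end_before_start_is_rejected(self, tmp_path):
        p = tmp_path / "bad.gtf"
        p.write_text(
            'chr1\tx\texon\t100\t10\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
        )
        with pytest.raises(ValidationError):
            io_mod.read_gtf(p)

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.gtf"
        p.write_text("chr1\tonly\tthree\n")
        with pytest.raises(io_mod.ParseError, match="bad.gtf:1"):
            io_mod.read_gtf(p)

    def test_mixed_strand_transcript_rejected(self, tmp_path):
        p = tmp_path / "mixed.gtf"
        p.write_text(
            'chr1\tx\texon\t10\t100\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
            'chr1\tx\texon\t200\t300\t.\t-\t.\tgene_id "g"; transcript_id "t";\n'
        )
        with pytest.raises(ValidationError):
            io_mod.read_gtf(p)

    def test_round_trip_on_synthetic_reference(self, dataset, tmp_path):
        """write(read(f)) re-read equals the first parse field by field."""
        p1 = tmp_path / "a.gtf"
        p2 = tmp_path / "b.gtf"
        io_mod.write_gtf(dataset.reference, p1)
        ann1 = io_mod.read_gtf(p1)
        io_mod.write_gtf(ann1, p2)
        ann2 = io_mod.read_gtf(p2)
        assert set(ann1.transcripts) == set(ann2.transcripts)
        for tid, t1 in ann1.transcripts.items():
            t2 = ann2.transcripts[tid]
            assert t1 == t2
        # and the writer is byte-deterministic
        assert p1.read_bytes() == p2.read_bytes()

    @given(start=st.integers(min_value=1, max_value=10**8),
           length=st.integers(min_value=0, max_value=10**6))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_coordinate_bijection(self, start, length):
        """GTF 1-based closed <-> internal 0-based half-open is exact."""
        end = start + length
        s_int, e_int = start - 1, end
        # inverse map restores the GTF coordinates exactly
        assert (s_int + 1, e_int) == (start, end)
        # half-open width equals the closed-interval base count
        assert e_int - s_int == end - start + 1


class TestSignalTrack:
    def test_direct_lookup_and_default(self):
        track = SignalTrack.from_runs([("chr1", 0, 10, 2.0)])
        assert track.value_at("chr1", 5) == 2.0
        assert track.value_at("chr1", 15) == 0.0
        assert track.value_at("chrX", 3) == 0.0

    def test_mean_with_partial_coverage(self):
        track = SignalTrack.from_runs([("chr1", 0, 10, 2.0), ("chr1", 10, 20, 4.0)])
        # brute-force per-base average over [5, 15)
        naive = np.mean([track.value_at("chr1", i) for i in range(5, 15)])
        assert track.mean("chr1", 5, 15) == pytest.approx(naive) == pytest.approx(3.0)

    def test_overlapping_runs_rejected(self):
        with pytest.raises(ValidationError):
            SignalTrack.from_runs([("chr1", 0, 10, 1.0), ("chr1", 5, 15, 2.0)])

    @given(
        runs=st.lists(
            st.tuples(
                st.integers(min_value=0, max_value=200),
                st.integers(min_value=1, max_value=30),
                st.floats(min_value=-5, max_value=5, allow_nan=False),
            ),
            min_size=1,
            max_size=8,
        ),
        q=st.tuples(
            st.integers(min_value=-10, max_value=250),
            st.integers(min_value=1, max_value=60),
        ),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_lookup_matches_naive_expansion(self, runs, q):
        """Run-length lookups agree with a per-base array expansion."""
        placed, cursor = [], 0
        for gap, length, value in runs:
            start = cursor + gap
            placed.append(("chr1", start, start + length, value))
            cursor = start + length
        track = SignalTrack.from_runs(placed)
        qs, qlen = q
        arr = track.values_array("chr1", qs, qs + qlen)
        naive = np.array([track.value_at("chr1", i) for i in range(qs, qs + qlen)])
        assert np.allclose(arr, naive)
        assert track.mean("chr1", qs, qs + qlen) == pytest.approx(float(naive.mean()))


class TestFasta:
    def test_fetch_plus_and_minus(self):
        genome = {"c": "ACGTAC"}
        iv = GenomeInterval("c", 1, 4)
        assert io_mod.fetch_sequence(genome, iv, "+") == "CGT"
        assert io_mod.fetch_sequence(genome, iv, "-") == "ACG"

    def test_fetch_bounds_and_unknown_chrom(self):
        genome = {"c": "ACGTAC"}
        with pytest.raises(IndexError):
            io_mod.fetch_sequence(genome, GenomeInterval("c", 4, 10), "+")
        with pytest.raises(KeyError):
            io_mod.fetch_sequence(genome, GenomeInterval("zz", 0, 2), "+")

    def test_faidx_view_matches_dict(self, tmp_path):
        seqs = {"chrA": "ACGTACGTAAACCCGGG", "chrB": "TTTTACGT"}
        path = tmp_path / "g.fa"
        io_mod.write_fasta(seqs, path, width=7)
        genome = io_mod.open_genome(path)
        iv = GenomeInterval("chrA", 3, 11)
        assert io_mod.fetch_sequence(genome, iv, "+") == seqs["chrA"][3:11]
        assert io_mod.fetch_sequence(genome, iv, "-") == io_mod.reverse_complement(
            seqs["chrA"][3:11]
        )

    def test_spliced_sequence_minus_strand(self):
        genome = {"c": "AAACGTTTGCAATT"}
        t = make_transcript("t", "g", "c", "-", [(0, 3), (6, 9)])
        # exon concatenation AAA + TTG, then reverse complement
        assert io_mod.spliced_sequence(genome, t) == io_mod.reverse_complement("AAATTG")


class TestMergeIntervals:
    def test_union(self):
        ivs = [
            GenomeInterval("c", 0, 10),
            GenomeInterval("c", 5, 15),
            GenomeInterval("c", 20, 30),
        ]
        merged = merge_intervals(ivs)
        assert [(m.start, m.end) for m in merged] == [(0, 15), (20, 30)]


class TestTabular:
    def test_expression_matrix_round_trip(self, dataset, tmp_path):
        p = tmp_path / "tpm.tsv"
        dataset.quant.tpm.to_tsv(p)
        back = io_mod.ExpressionMatrix.from_tsv(p, "TPM")
        assert np.allclose(back.values.to_numpy(), dataset.quant.tpm.values.to_numpy())

    def test_junction_table_round_trip(self, dataset, tmp_path):
        p = tmp_path / "j.tsv"
        dataset.quant.junctions.to_tsv(p)
        back = io_mod.JunctionSupportTable.from_tsv(p)
        assert back.counts == dataset.quant.junctions.counts

    def test_expression_matrix_validation(self):
        import pandas as pd

        with pytest.raises(ValidationError):
            io_mod.ExpressionMatrix(pd.DataFrame({"a": [1.0]}), "RPKM")
        with pytest.raises(ValidationError):
            io_mod.ExpressionMatrix(pd.DataFrame({"a": [-1.0]}), "TPM")
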