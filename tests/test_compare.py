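"""Classification, merging, stage dynamics and saturation."""

import numpy as np
import pytest

from oracles import oracle_code

from isoatlas.compare import (
    ReferenceIndex,
    classify_set,
    classify_transcript,
    merge_transcriptomes,
    saturation_curve,
    stage_dynamics,
)
from isoatlas.core import Annotation, make_transcript


def _ann(*transcripts):
    return Annotation.from_transcripts(transcripts)


REF = _ann(
    make_transcript("R1", "gA", "chr1", "+", [(100, 200), (300, 400), (500, 600)]),
    make_transcript("R2", "gA", "chr1", "+", [(100, 200), (500, 600)]),
    make_transcript("R3", "gB", "chr1", "-", [(2000, 2100), (2300, 2400)]),
    make_transcript("R4", "gC", "chr1", "+", [(5000, 5400)]),
)


class TestClassCodes:
    def test_identical_intron_chain_is_exact_regardless_of_ends(self):
        q = make_transcript("q", "x", "chr1", "+", [(150, 200), (300, 400), (500, 560)])
        rec = classify_transcript(q, REF)
        assert rec.code == "=" and rec.category == "exact_match"
        assert rec.best_ref == "R1"

    def test_contiguous_subchain_within_span_is_contained(self):
        q = make_transcript("q", "x", "chr1", "+", [(310, 400), (500, 590)])
        rec = classify_transcript(q, REF)
        assert rec.code == "c" and rec.category == "contained"

    def test_shared_plus_novel_junction_is_novel_isoform(self):
        # shares junction (200, 300) with R1 but carries a junction in no reference
        q = make_transcript("q", "x", "chr1", "+", [(100, 200), (300, 350), (450, 600)])
        rec = classify_transcript(q, REF)
        assert rec.code == "j" and rec.category == "novel_isoform"

    def test_no_reference_overlap_is_novel_gene(self):
        q = make_transcript("q", "x", "chr1", "+", [(9000, 9200)])
        rec = classify_transcript(q, REF)
        assert rec.code == "u" and rec.category == "novel_gene"
        assert rec.best_ref is None

    def test_unknown_chromosome_is_novel_gene(self):
        q = make_transcript("q", "x", "chrZ", "+", [(100, 200), (300, 400)])
        assert classify_transcript(q, REF).code == "u"

    def test_mono_exon_reciprocal_overlap_rule(self):
        hit = make_transcript("q", "x", "chr1", "+", [(5100, 5500)])
        assert classify_transcript(hit, REF).code == "="
        # < 50% of the query covered
        miss = make_transcript("q2", "x", "chr1", "+", [(5300, 6200)])
        assert classify_transcript(miss, REF).code != "="

    def test_exon_intron_readthrough_is_e(self):
        # mono-exon query over R1 exon 1 reading 50 bp into intron 1
        q = make_transcript("q", "x", "chr1", "+", [(150, 250)])
        rec = classify_transcript(q, REF)
        assert rec.code == "e" and rec.category == "novel_isoform"

    def test_antisense_and_intronic_are_other(self):
        anti = make_transcript("q", "x", "chr1", "-", [(120, 180)])
        rec = classify_transcript(anti, REF)
        assert rec.code == "other" and rec.sublabel == "antisense"
        intronic = make_transcript("q2", "x", "chr1", "+", [(220, 280)])
        rec2 = classify_transcript(intronic, REF)
        assert rec2.code == "other" and rec2.sublabel == "intronic"

    def test_set_labels(self):
        q = make_transcript("q", "x", "chr1", "+", [(310, 400), (500, 590)])
        assert classify_transcript(q, REF).set_label == "annotated"
        u = make_transcript("q2", "x", "chr1", "+", [(9000, 9200)])
        assert classify_transcript(u, REF).set_label == "novel"


def _random_reference(rng, n_genes=20):
    transcripts = []
    pos = 1000
    for g in range(n_genes):
        n_ex = int(rng.integers(2, 6))
        exons = []
        p = pos
        for i in range(n_ex):
            length = int(rng.integers(80, 250))
            exons.append((p, p + length))
            p += length + int(rng.integers(150, 500))
        strand = "+" if rng.random() < 0.5 else "-"
        transcripts.append(
            make_transcript(f"R{g}.1", f"g{g}", "chr1", strand, exons)
        )
        if rng.random() < 0.5 and n_ex >= 3:
            skip = int(rng.integers(1, n_ex - 1))
            transcripts.append(
                make_transcript(
                    f"R{g}.2", f"g{g}", "chr1", strand,
                    [e for i, e in enumerate(exons) if i != skip],
                )
            )
        pos = p + int(rng.integers(1000, 3000))
    return transcripts


def _random_queries(rng, refs, n=200):
    queries = []
    multi = [r for r in refs if r.n_exons > 1]
    for i in range(n):
        kind = rng.random()
        r = multi[int(rng.integers(len(multi)))]
        exons = [(e.start, e.end) for e in r.exons]
        if kind < 0.2:  # end-jittered copy
            d = int(rng.integers(0, 40))
            exons[0] = (max(0, exons[0][0] - d), exons[0][1])
            q = exons
            strand = r.strand
        elif kind < 0.35:  # interior subchain
            if len(exons) >= 3:
                q = exons[1:-1]
            else:
                q = exons
            strand = r.strand
        elif kind < 0.5:  # exon skip
            if len(exons) >= 3:
                skip = int(rng.integers(1, len(exons) - 1))
                q = [e for j, e in enumerate(exons) if j != skip]
            else:
                q = exons
            strand = r.strand
        elif kind < 0.6:  # antisense mono-exon
            q = [exons[0]]
            strand = "-" if r.strand == "+" else "+"
        elif kind < 0.7:  # intronic / readthrough mono-exon
            d, a = r.intron_chain[0]
            off = int(rng.integers(-60, 60))
            q = [(max(0, d + off), a - 5)]
            strand = r.strand
        else:  # random placement
            s = int(rng.integers(0, 60000))
            n_ex = int(rng.integers(1, 4))
            q = []
            p = s
            for _ in range(n_ex):
                length = int(rng.integers(80, 300))
                q.append((p, p + length))
                p += length + int(rng.integers(100, 400))
            strand = "+" if rng.random() < 0.5 else "-"
        queries.append(make_transcript(f"q{i}", f"qg{i}", "chr1", strand, q))
    return queries


class TestOracleEquivalence:
    def test_classifier_matches_bruteforce_oracle(self):
        """Fast indexed classification equals exhaustive rule checking on
        a 50-reference x 200-query random panel."""
        rng = np.random.default_rng(11)
        refs = _random_reference(rng)[:50]
        reference = _ann(*refs)
        queries = _random_queries(rng, refs, n=200)
        index = ReferenceIndex(reference)
        mismatches = []
        for q in queries:
            got = classify_transcript(q, reference, index).code
            want = oracle_code(q, refs)
            if got != want:
                mismatches.append((q.transcript_id, got, want))
        assert mismatches == []


class TestTruthRecovery:
    def test_planted_categories_recovered(self, dataset):
        """Planted exact/contained/novel-gene labels recover with zero
        errors, and planted 'other' is never called a novel isoform."""
        errors = []
        other_as_novel = []
        index = ReferenceIndex(dataset.reference)
        for stage, models in dataset.stage_sets.items():
            recs = classify_set(models, dataset.reference, index)
            for t in models:
                truth = dataset.labels.category[t.transcript_id]
                got = recs[t.transcript_id].category
                if truth in ("exact_match", "contained", "novel_gene") and got != truth:
                    errors.append((stage, t.transcript_id, truth, got))
                if truth == "other" and got == "novel_isoform":
                    other_as_novel.append(t.transcript_id)
        assert errors == []
        assert other_as_novel == []


class TestMerge:
    def test_same_chain_widest_ends_with_provenance(self):
        a = make_transcript("a", "g", "chr1", "+", [(100, 200), (300, 400)])
        b = make_transcript("b", "g", "chr1", "+", [(80, 200), (300, 450)])
        merged = merge_transcriptomes([("s1", [a]), ("s2", [b])])
        assert len(merged) == 1
        (t,) = merged.transcripts
        assert (t.start, t.end) == (80, 450)
        assert merged.provenance[t.transcript_id] == ["s1", "s2"]

    def test_disjoint_sets_sum(self):
        a = make_transcript("a", "g", "chr1", "+", [(100, 200), (300, 400)])
        b = make_transcript("b", "g", "chr1", "+", [(9000, 9100), (9300, 9400)])
        merged = merge_transcriptomes([("s1", [a]), ("s2", [b])])
        assert len(merged) == 2

    def test_mono_exon_union_span(self):
        a = make_transcript("a", "g", "chr1", "+", [(100, 300)])
        b = make_transcript("b", "g", "chr1", "+", [(250, 500)])
        c = make_transcript("c", "g", "chr1", "-", [(250, 500)])
        merged = merge_transcriptomes([("s1", [a, c]), ("s2", [b])])
        spans = sorted(
            (t.strand, t.start, t.end) for t in merged.transcripts
        )
        assert spans == [("+", 100, 500), ("-", 250, 500)]

    def test_idempotent(self, dataset):
        stage_sets = [(s, dataset.labels.stage_models(s)) for s in dataset.config.stages]
        m1 = merge_transcriptomes(stage_sets)
        m2 = merge_transcriptomes([("all", m1.transcripts)])
        k1 = sorted((t.chrom, t.strand, t.start, t.end, t.intron_chain) for t in m1.transcripts)
        k2 = sorted((t.chrom, t.strand, t.start, t.end, t.intron_chain) for t in m2.transcripts)
        assert k1 == k2


class TestStageDynamics:
    A = make_transcript("A", "g", "chr1", "+", [(100, 200), (300, 400)])
    B = make_transcript("B", "h", "chr1", "+", [(8000, 8100), (8300, 8400)])

    def test_identical_sets_fully_shared(self):
        d = stage_dynamics([self.A, self.B], [self.A, self.B])
        assert not d.gained and not d.lost
        assert d.gain_percent == 0.0 and d.loss_percent == 0.0

    def test_gain(self):
        d = stage_dynamics([self.A], [self.A, self.B])
        assert set(d.gained) == {"B"}
        assert d.gain_percent == pytest.approx(50.0)
        assert not d.lost

    def test_loss(self):
        d = stage_dynamics([self.A, self.B], [self.A])
        assert set(d.lost) == {"B"}
        assert d.loss_percent == pytest.approx(50.0)
        assert not d.gained

    def test_partition_invariant(self, dataset):
        stages = dataset.config.stages
        prev, curr = stages[2], stages[3]
        pm, cm = dataset.labels.stage_models(prev), dataset.labels.stage_models(curr)
        d = stage_dynamics(pm, cm, prev, curr)
        assert d.shared_current | d.gained == {t.transcript_id for t in cm}
        assert d.shared_previous | d.lost == {t.transcript_id for t in pm}


class TestSaturation:
    def test_two_disjoint_novel_sets_union(self):
        """Final-step count is the union size for both stage orders."""
        ref = _ann(
            make_transcript("R", "g", "chr1", "+", [(100, 200), (300, 400)])
        )
        novel_a = [
            make_transcript(f"a{i}", f"na{i}", "chr1", "+", [(10000 + 1000 * i, 10200 + 1000 * i)])
            for i in range(5)
        ]
        novel_b = [
            make_transcript(f"b{i}", f"nb{i}", "chr1", "+", [(50000 + 1000 * i, 50200 + 1000 * i)])
            for i in range(7)
        ]
        curve = saturation_curve([novel_a, novel_b], ref, reps=10, seed=3)
        assert curve.means[-1] == pytest.approx(12.0)
        assert curve.ci_low[-1] == curve.ci_high[-1] == 12.0

    def test_identical_stages_flat_after_first_step(self):
        ref = _ann(make_transcript("R", "g", "chr1", "+", [(100, 200), (300, 400)]))
        novel = [make_transcript("n", "ng", "chr1", "+", [(9000, 9300)])]
        curve = saturation_curve([novel, list(novel), list(novel)], ref, reps=5, seed=0)
        assert list(curve.means) == [1.0, 1.0, 1.0]

    def test_deterministic_under_seed(self, dataset):
        sets = [dataset.labels.stage_models(s) for s in dataset.config.stages[:4]]
        c1 = saturation_curve(sets, dataset.reference, reps=10, seed=5)
        c2 = saturation_curve(sets, dataset.reference, reps=10, seed=5)
        assert np.array_equal(c1.means, c2.means)
        assert np.array_equal(c1.ci_low, c2.ci_low)

    def test_reps_below_two_rejected(self):
        ref = _ann(make_transcript("R", "g", "chr1", "+", [(100, 200), (300, 400)]))
        with pytest.raises(ValueError):
            saturation_curve([[]], ref, reps=1)
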