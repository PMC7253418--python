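"""Junction motifs and validation, AS events, PSI, differential splicing."""

import numpy as np
import pytest
from scipy import stats

from oracles import brute_force_event_keys

from isoatlas.core import make_transcript
from isoatlas.io import ExpressionMatrix, JunctionSupportTable
from isoatlas.splicing import (
    canonical_fraction,
    compute_psi,
    diff_splice,
    enumerate_as_events,
    event_dynamics,
    extract_junctions,
    validate_junctions,
)

import pandas as pd


class TestJunctions:
    def test_plus_strand_canonical(self):
        #           0123456789...
        genome = {"c": "AAAAAGTCCCCAGAAAAA"}
        # exon [0,5), intron [5,13), exon [13,18): GT...AG
        t = make_transcript("t", "g", "c", "+", [(0, 5), (13, 18)])
        (j,) = extract_junctions(t, genome)
        assert j.motif == ("GT", "AG")
        assert j.canonical

    def test_minus_strand_reverse_complement(self):
        # genomic CT..AC reads GT..AG on the minus strand
        genome = {"c": "AAAAACTCCCCACAAAAA"}
        t = make_transcript("t", "g", "c", "-", [(0, 5), (13, 18)])
        (j,) = extract_junctions(t, genome)
        assert j.motif == ("GT", "AG")
        assert j.canonical

    def test_gc_ag_noncanonical(self):
        genome = {"c": "AAAAAGCCCCCAGAAAAA"}
        t = make_transcript("t", "g", "c", "+", [(0, 5), (13, 18)])
        (j,) = extract_junctions(t, genome)
        assert j.motif == ("GC", "AG")
        assert not j.canonical

    def test_planted_canonical_fraction_within_binomial_bounds(self, dataset):
        """Observed canonical share of distinct junctions lies in the
        99% binomial interval around the planted 97%."""
        juncs = []
        for s in dataset.config.stages:
            for t in dataset.labels.stage_models(s):
                if t.is_multi_exon:
                    juncs.extend(extract_junctions(t, dataset.genome))
        distinct = {j.key: j.canonical for j in juncs}
        n = len(distinct)
        share = canonical_fraction(juncs)
        lo = stats.binom.ppf(0.005, n, 0.97) / n
        hi = stats.binom.ppf(0.995, n, 0.97) / n
        assert lo <= share <= hi

    def test_extracted_motifs_match_planted_sites(self, dataset):
        labels = dataset.labels
        for s in dataset.config.stages:
            for t in labels.stage_models(s):
                if not t.is_multi_exon:
                    continue
                for j in extract_junctions(t, dataset.genome):
                    planted = labels.canonical_junctions.get(j.key)
                    if planted is not None:
                        assert j.canonical == planted


class TestValidation:
    def _junctions(self):
        genome = {"c": "AAAAAGTCCCCAGAAAAA" + "A" * 40}
        t = make_transcript("t", "g", "c", "+", [(0, 5), (13, 18)])
        return extract_junctions(t, genome)

    def test_one_sample_at_threshold_keeps(self):
        juncs = self._junctions()
        table = JunctionSupportTable({juncs[0].key: {"s1": 12, "s2": 0}})
        assert validate_junctions(juncs, table) == juncs

    def test_all_samples_below_threshold_drops(self):
        juncs = self._junctions()
        table = JunctionSupportTable({juncs[0].key: {"s1": 9, "s2": 9}})
        assert validate_junctions(juncs, table) == []

    def test_absent_junction_drops(self):
        juncs = self._junctions()
        table = JunctionSupportTable({})
        assert validate_junctions(juncs, table) == []

    def test_planted_unsupported_junctions_dropped(self, dataset):
        labels = dataset.labels
        juncs = []
        for s in dataset.config.stages:
            for t in labels.stage_models(s):
                if t.is_multi_exon:
                    juncs.extend(extract_junctions(t, dataset.genome))
        kept = {j.key for j in validate_junctions(juncs, dataset.quant.junctions)}
        dropped = {j.key for j in juncs} - kept
        assert dropped == labels.unsupported_junctions & {j.key for j in juncs}


# one hand-built gene per event type; each must yield exactly one event
FIXTURE_GENES = {
    "SE": [
        [(100, 200), (300, 400), (500, 600)],
        [(100, 200), (500, 600)],
    ],
    "A5": [
        [(100, 200), (500, 600)],
        [(100, 250), (500, 600)],
    ],
    "A3": [
        [(100, 200), (500, 600)],
        [(100, 200), (450, 600)],
    ],
    "RI": [
        [(100, 200), (300, 400)],
        [(100, 400)],
    ],
    "MX": [
        [(100, 200), (300, 400), (700, 800)],
        [(100, 200), (500, 600), (700, 800)],
    ],
    "AF": [
        [(100, 200), (500, 600)],
        [(250, 350), (500, 600)],
    ],
    "AL": [
        [(100, 200), (500, 600)],
        [(100, 200), (700, 800)],
    ],
}


def _fixture_gene(event_type, strand="+"):
    return [
        make_transcript(f"{event_type}.t{i + 1}", f"g{event_type}", "chr1", strand, exons)
        for i, exons in enumerate(FIXTURE_GENES[event_type])
    ]


class TestEventEnumeration:
    @pytest.mark.parametrize("event_type", sorted(FIXTURE_GENES))
    def test_exactly_one_event_per_fixture_gene(self, event_type):
        events = enumerate_as_events(_fixture_gene(event_type))
        assert [e.event_type for e in events] == [event_type]
        (ev,) = events
        assert ev.inclusion and ev.exclusion
        assert not (ev.inclusion & ev.exclusion)

    @pytest.mark.parametrize("event_type", sorted(FIXTURE_GENES))
    def test_matches_bruteforce_comparator(self, event_type):
        isoforms = _fixture_gene(event_type)
        got = {(e.event_type, e.coordinates) for e in enumerate_as_events(isoforms)}
        want = brute_force_event_keys(isoforms)
        assert got == want

    @pytest.mark.parametrize("event_type", ["SE", "A5", "A3", "RI", "MX", "AF", "AL"])
    def test_minus_strand_swaps_directional_types(self, event_type):
        swapped = {"A5": "A3", "A3": "A5", "AF": "AL", "AL": "AF"}
        events = enumerate_as_events(_fixture_gene(event_type, strand="-"))
        assert [e.event_type for e in events] == [
            swapped.get(event_type, event_type)
        ]

    def test_single_isoform_gene_has_no_events(self):
        t = make_transcript("t", "g", "chr1", "+", [(100, 200), (300, 400)])
        assert enumerate_as_events([t]) == []

    def test_mixed_gene_ids_rejected(self):
        a = make_transcript("a", "g1", "chr1", "+", [(100, 200), (300, 400)])
        b = make_transcript("b", "g2", "chr1", "+", [(100, 200), (300, 400)])
        with pytest.raises(ValueError):
            enumerate_as_events([a, b])

    def test_se_inclusion_exclusion_membership(self):
        events = enumerate_as_events(_fixture_gene("SE"))
        (ev,) = events
        assert ev.inclusion == {"SE.t1"}
        assert ev.exclusion == {"SE.t2"}

    def test_duplicate_events_reported_once(self):
        # three isoforms where two pairs witness the same skipped exon
        iso = _fixture_gene("SE")
        extra = make_transcript(
            "SE.t3", "gSE", "chr1", "+", [(100, 200), (300, 400), (500, 600), (700, 800)]
        )
        # t3 shares the inclusion path of t1 plus a downstream exon: the
        # (t3, t2) pair re-witnesses the same SE coordinates
        events = enumerate_as_events(iso + [extra])
        se = [e for e in events if e.event_type == "SE"]
        assert len(se) == 1
        assert se[0].inclusion == {"SE.t1", "SE.t3"}


class TestPsi:
    def _event(self):
        (ev,) = enumerate_as_events(_fixture_gene("SE"))
        return ev

    def _matrix(self, inc, exc):
        df = pd.DataFrame({"s1": [inc, exc]}, index=["SE.t1", "SE.t2"])
        return ExpressionMatrix(df, "TPM")

    def test_psi_arithmetic(self):
        assert compute_psi(self._event(), self._matrix(3.0, 1.0), "s1") == 0.75
        assert compute_psi(self._event(), self._matrix(2.0, 2.0), "s1") == 0.5

    def test_zero_denominator_is_undefined(self):
        assert compute_psi(self._event(), self._matrix(0.0, 0.0), "s1") is None

    def test_missing_isoform_row_rejected(self):
        df = pd.DataFrame({"s1": [1.0]}, index=["SE.t1"])
        with pytest.raises(KeyError):
            compute_psi(self._event(), ExpressionMatrix(df, "TPM"), "s1")

    def test_invariant_under_uniform_scaling(self):
        ev = self._event()
        p1 = compute_psi(ev, self._matrix(3.0, 1.0), "s1")
        p2 = compute_psi(ev, self._matrix(30.0, 10.0), "s1")
        assert p1 == pytest.approx(p2)


class TestDiffSplice:
    def test_identical_replicates_not_significant(self):
        res = diff_splice([0.5, 0.5, 0.5], [0.5, 0.5, 0.5], seed=0)
        assert res.delta_psi == 0.0
        assert res.direction == "none"

    def test_planted_up_shift_recovered(self):
        rng = np.random.default_rng(4)
        a = np.clip(rng.normal(0.1, 0.02, 5), 0, 1)
        b = np.clip(rng.normal(0.9, 0.02, 5), 0, 1)
        res = diff_splice(a, b, n_perm=500, seed=1)
        assert res.direction == "up"
        assert res.p_value < 0.05

    def test_down_classification(self):
        rng = np.random.default_rng(4)
        a = np.clip(rng.normal(0.8, 0.02, 5), 0, 1)
        b = np.clip(rng.normal(0.4, 0.02, 5), 0, 1)
        res = diff_splice(a, b, n_perm=500, seed=1)
        assert res.direction == "down" and res.delta_psi < 0

    def test_nan_psis_dropped(self):
        res = diff_splice([0.2, np.nan, 0.2], [0.8, 0.8, np.nan], n_perm=200, seed=0)
        assert res.delta_psi == pytest.approx(0.6)

    def test_all_undefined_rejected(self):
        with pytest.raises(ValueError):
            diff_splice([np.nan], [0.5], seed=0)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(9)
        a, b = rng.uniform(0, 1, 6), rng.uniform(0, 1, 6)
        r1 = diff_splice(a, b, n_perm=300, seed=7)
        r2 = diff_splice(a, b, n_perm=300, seed=7)
        assert r1 == r2


class TestEventDynamics:
    def test_identity(self):
        events = enumerate_as_events(_fixture_gene("SE"))
        d = event_dynamics(events, events)
        assert sum(d.gained.values()) == 0 and sum(d.lost.values()) == 0

    def test_gain_percent(self):
        se = enumerate_as_events(_fixture_gene("SE"))
        ri = enumerate_as_events(_fixture_gene("RI"))
        d = event_dynamics(se, se + ri)
        assert d.gained["RI"] == 1 and d.gain_percent["RI"] == 100.0
        assert d.gained["SE"] == 0

    def test_duplicates_collapse_before_differencing(self):
        se = enumerate_as_events(_fixture_gene("SE"))
        d = event_dynamics(se + se, se)
        assert sum(d.lost.values()) == 0
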