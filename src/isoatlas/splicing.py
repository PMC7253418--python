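"""Splice junctions, alternative-splicing events, PSI and differential splicing.

AS events are enumerated per gene from pairwise isoform comparison in
the local-event style: skipped exon (SE), alternative 5'/3' splice site
(A5/A3), retained intron (RI), mutually exclusive exons (MX) and
alternative first/last exon (AF/AL).  Every event records the inclusion
and exclusion isoform sets; PSI is the TPM share of the inclusion
isoforms.  Differential splicing between two conditions uses a
label-permutation test on replicate PSIs with the up/down rule
|dPSI| direction at p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .core import TranscriptModel, ValidationError
from .io import ExpressionMatrix, GenomeLike, JunctionSupportTable, fetch_sequence, reverse_complement
from .core import GenomeInterval

EVENT_TYPES = ("SE", "A5", "A3", "RI", "MX", "AF", "AL")
CANONICAL_MOTIF = ("GT", "AG")
MIN_SUPPORT_READS = 10
ALPHA = 0.05


@dataclass(frozen=True)
class JunctionRecord:
    chrom: str
    donor: int  # intron start, 0-based
    acceptor: int  # intron end, exclusive
    strand: str
    motif: Tuple[str, str]  # sense-strand (5' dinucleotide, 3' dinucleotide)
    canonical: bool

    @property
    def key(self) -> Tuple[str, int, int, str]:
        return (self.chrom, self.donor, self.acceptor, self.strand)


def extract_junctions(
    transcript: TranscriptModel, genome: GenomeLike
) -> List[JunctionRecord]:
    """One record per intron; motifs are read on the transcript's sense
    strand (minus-strand introns are reverse-complemented)."""
    records = []
    for d, a in transcript.intron_chain:
        left = fetch_sequence(
            genome, GenomeInterval(transcript.chrom, d, d + 2), strand="+"
        )
        right = fetch_sequence(
            genome, GenomeInterval(transcript.chrom, a - 2, a), strand="+"
        )
        if transcript.strand == "+":
            motif = (left, right)
        else:
            motif = (reverse_complement(right), reverse_complement(left))
        records.append(
            JunctionRecord(
                transcript.chrom,
                d,
                a,
                transcript.strand,
                motif,
                motif == CANONICAL_MOTIF,
            )
        )
    return records


def canonical_fraction(junctions: Iterable[JunctionRecord]) -> float:
    """Fraction of distinct junctions with the canonical GT..AG motif."""
    seen: Dict[Tuple[str, int, int, str], bool] = {}
    for j in junctions:
        seen[j.key] = j.canonical
    if not seen:
        raise ValueError("no junctions")
    return sum(seen.values()) / len(seen)


def validate_junctions(
    junctions: Sequence[JunctionRecord],
    support: JunctionSupportTable,
    min_reads: int = MIN_SUPPORT_READS,
) -> List[JunctionRecord]:
    """Keep junctions supported by >= min_reads short reads in >= 1 sample."""
    return [j for j in junctions if support.max_support(j.key) >= min_reads]


# ---------------------------------------------------------------------------
# AS event enumeration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ASEvent:
    event_id: str
    gene_id: str
    event_type: str
    chrom: str
    strand: str
    coordinates: Tuple[int, ...]
    inclusion: FrozenSet[str]
    exclusion: FrozenSet[str]

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValidationError(f"unknown AS event type {self.event_type}")
        if not self.inclusion or not self.exclusion:
            raise ValidationError("inclusion and exclusion sets must be non-empty")
        if self.inclusion & self.exclusion:
            raise ValidationError("inclusion and exclusion sets must be disjoint")

    @property
    def key(self) -> Tuple[str, str, str, Tuple[int, ...]]:
        """Identity for deduplication and stage dynamics."""
        return (self.event_type, self.chrom, self.strand, self.coordinates)


def _adjacent_intron_pairs(t: TranscriptModel):
    chain = t.intron_chain
    return [(chain[i], chain[i + 1]) for i in range(len(chain) - 1)]


def enumerate_as_events(gene_transcripts: Sequence[TranscriptModel]) -> List[ASEvent]:
    """Pairwise local-event enumeration within one gene.

    Duplicate events (same type and coordinates) are reported once, with
    inclusion/exclusion membership aggregated over all isoforms of the
    gene that carry the respective form.
    """
    if not gene_transcripts:
        raise ValueError("at least one transcript required")
    gene_ids = {t.gene_id for t in gene_transcripts}
    if len(gene_ids) != 1:
        raise ValueError(f"mixed gene_ids: {sorted(gene_ids)}")
    gene_id = gene_ids.pop()
    txs = list(gene_transcripts)
    chrom = txs[0].chrom
    strand = txs[0].strand

    # signature -> (type, coords, inclusion-form predicate, exclusion-form predicate)
    events: Dict[Tuple, ASEvent] = {}

    for t1, t2 in combinations(txs, 2):
        for ev in _pairwise_events(t1, t2, gene_id):
            events.setdefault(ev[0], ev[1])

    # Aggregate memberships across all isoforms.
    out: List[ASEvent] = []
    for key in sorted(events, key=lambda k: (k[0], k[3])):
        etype, _chrom, _strand, coords = key
        inc_pred, exc_pred = events[key]
        inclusion = frozenset(
            t.transcript_id for t in txs if inc_pred(t)
        )
        exclusion = frozenset(
            t.transcript_id for t in txs if exc_pred(t) and t.transcript_id not in inclusion
        )
        event_id = f"{gene_id};{etype}:{chrom}:{'-'.join(map(str, coords))}:{strand}"
        out.append(
            ASEvent(event_id, gene_id, etype, chrom, strand, coords, inclusion, exclusion)
        )
    return out


def _pairwise_events(t1: TranscriptModel, t2: TranscriptModel, gene_id: str):
    """Yield (key, (inclusion_predicate, exclusion_predicate)) tuples for
    every local event distinguishing the pair."""
    strand = t1.strand
    chrom = t1.chrom
    found = []

    def key_of(etype: str, coords: Tuple[int, ...]):
        return (etype, chrom, strand, coords)

    # --- SE: one isoform retains an exon spliced out by a single intron
    # in the other, with both flanking junctions shared.
    for inc, exc in ((t1, t2), (t2, t1)):
        exc_juncs = set(exc.intron_chain)
        for (d1, a1), (d2, a2) in _adjacent_intron_pairs(inc):
            if (d1, a2) in exc_juncs:
                coords = (d1, a1, d2, a2)
                found.append(
                    (
                        key_of("SE", coords),
                        (
                            _has_adjacent_introns((d1, a1), (d2, a2)),
                            _has_intron((d1, a2)),
                        ),
                    )
                )

    # --- A5/A3: introns sharing one boundary; the outer exon boundary on
    # the varying side must agree between the two isoforms.
    for i1, intron1 in enumerate(t1.intron_chain):
        for i2, intron2 in enumerate(t2.intron_chain):
            d1, a1 = intron1
            d2, a2 = intron2
            if d1 == d2 and a1 != a2:
                # acceptor varies (genomic right); downstream exons must share ends
                ex1 = t1.exons[i1 + 1]
                ex2 = t2.exons[i2 + 1]
                if ex1.end == ex2.end:
                    etype = "A3" if strand == "+" else "A5"
                    lo, hi = sorted((a1, a2))
                    coords = (d1, lo, hi, max(ex1.end, ex2.end))
                    short, long_ = ((d1, lo), (d1, hi))
                    # shorter intron keeps more exonic sequence -> inclusion
                    found.append(
                        (
                            key_of(etype, coords),
                            (_has_intron(short), _has_intron(long_)),
                        )
                    )
            elif a1 == a2 and d1 != d2:
                ex1 = t1.exons[i1]
                ex2 = t2.exons[i2]
                if ex1.start == ex2.start:
                    etype = "A5" if strand == "+" else "A3"
                    lo, hi = sorted((d1, d2))
                    coords = (min(ex1.start, ex2.start), lo, hi, a1)
                    short, long_ = ((hi, a1), (lo, a1))
                    found.append(
                        (
                            key_of(etype, coords),
                            (_has_intron(short), _has_intron(long_)),
                        )
                    )

    # --- RI: an intron of one isoform fully exonic in the other with
    # shared outer exon boundaries.
    for spliced, retained in ((t1, t2), (t2, t1)):
        retained_exons = {(ex.start, ex.end) for ex in retained.exons}
        for i, (d, a) in enumerate(spliced.intron_chain):
            left = spliced.exons[i]
            right = spliced.exons[i + 1]
            if (left.start, right.end) in retained_exons:
                coords = (left.start, d, a, right.end)
                found.append(
                    (
                        key_of("RI", coords),
                        (
                            _has_exon((left.start, right.end)),
                            _has_adjacent_exons((left.start, d), (a, right.end)),
                        ),
                    )
                )

    # --- MX: two internal exons each included exclusively, identical
    # outer flanking junction boundaries, non-overlapping alternatives.
    for ta, tb in ((t1, t2),):
        for (d1, x1), (y1, a1) in _adjacent_intron_pairs(ta):
            for (d2, x2), (y2, a2) in _adjacent_intron_pairs(tb):
                if d1 == d2 and a1 == a2 and (x1, y1) != (x2, y2):
                    # alternative exons [x, y) must not overlap
                    if y1 <= x2 or y2 <= x1:
                        exon_a, exon_b = sorted([(x1, y1), (x2, y2)])
                        # each isoform must exclude the partner's exon
                        if not _has_exon_region(ta, (x2, y2)) and not _has_exon_region(
                            tb, (x1, y1)
                        ):
                            coords = (d1, *exon_a, *exon_b, a1)
                            # inclusion = 5'-proximal alternative exon (strand-aware)
                            first, second = (
                                (exon_a, exon_b) if strand == "+" else (exon_b, exon_a)
                            )
                            found.append(
                                (
                                    key_of("MX", coords),
                                    (
                                        _has_adjacent_introns(
                                            (d1, first[0]), (first[1], a1)
                                        ),
                                        _has_adjacent_introns(
                                            (d1, second[0]), (second[1], a1)
                                        ),
                                    ),
                                )
                            )

    # --- AF/AL: distinct non-overlapping terminal exons spliced onto a
    # shared junction boundary.
    for left_sided in (True, False):
        ev = _terminal_event(t1, t2, left_sided)
        if ev is not None:
            (coords, form1, form2) = ev
            # genomically left terminal event is AF on + (alternative
            # first exon) and AL on -; right-sided is the mirror.
            if left_sided:
                etype = "AF" if strand == "+" else "AL"
            else:
                etype = "AL" if strand == "+" else "AF"
            # inclusion = distal form (5'-most first exon / 3'-most last exon)
            if left_sided:
                distal, proximal = (
                    (form1, form2) if form1[0] < form2[0] else (form2, form1)
                )
            else:
                distal, proximal = (
                    (form1, form2) if form1[1] > form2[1] else (form2, form1)
                )
            found.append(
                (
                    key_of(etype, coords),
                    (
                        _has_terminal_form(distal, left_sided),
                        _has_terminal_form(proximal, left_sided),
                    ),
                )
            )

    return found


def _terminal_event(t1: TranscriptModel, t2: TranscriptModel, left_sided: bool):
    """Detect an alternative terminal-exon event at the genomic left
    (first exon) or right (last exon) end of the pair."""
    if not (t1.is_multi_exon and t2.is_multi_exon):
        return None
    if left_sided:
        e1, e2 = t1.exons[0], t2.exons[0]
        j1, j2 = t1.intron_chain[0], t2.intron_chain[0]
        if j1[1] != j2[1] or j1[0] == j2[0]:
            return None
        # terminal exons must not overlap
        if not (e1.end <= e2.start or e2.end <= e1.start):
            return None
        a = j1[1]
        form1 = (e1.start, e1.end)  # with intron (e1.end, a)
        form2 = (e2.start, e2.end)
        lo, hi = sorted([form1, form2])
        coords = (lo[0], lo[1], hi[0], hi[1], a)
        return coords, form1, form2
    else:
        e1, e2 = t1.exons[-1], t2.exons[-1]
        j1, j2 = t1.intron_chain[-1], t2.intron_chain[-1]
        if j1[0] != j2[0] or j1[1] == j2[1]:
            return None
        if not (e1.end <= e2.start or e2.end <= e1.start):
            return None
        d = j1[0]
        form1 = (e1.start, e1.end)
        form2 = (e2.start, e2.end)
        lo, hi = sorted([form1, form2])
        coords = (d, lo[0], lo[1], hi[0], hi[1])
        return coords, form1, form2


# membership predicates -------------------------------------------------------

def _has_intron(intron: Tuple[int, int]):
    def pred(t: TranscriptModel) -> bool:
        return intron in set(t.intron_chain)

    return pred


def _has_adjacent_introns(i1: Tuple[int, int], i2: Tuple[int, int]):
    def pred(t: TranscriptModel) -> bool:
        chain = t.intron_chain
        for k in range(len(chain) - 1):
            if chain[k] == i1 and chain[k + 1] == i2:
                return True
        return False

    return pred


def _has_exon(exon: Tuple[int, int]):
    def pred(t: TranscriptModel) -> bool:
        return any((ex.start, ex.end) == exon for ex in t.exons)

    return pred


def _has_adjacent_exons(e1: Tuple[int, int], e2: Tuple[int, int]):
    def pred(t: TranscriptModel) -> bool:
        for a, b in zip(t.exons, t.exons[1:]):
            if (a.start, a.end) == e1 and (b.start, b.end) == e2:
                return True
        return False

    return pred


def _has_exon_region(t: TranscriptModel, exon: Tuple[int, int]) -> bool:
    return any(ex.start < exon[1] and exon[0] < ex.end for ex in t.exons)


def _has_terminal_form(form: Tuple[int, int], left_sided: bool):
    def pred(t: TranscriptModel) -> bool:
        if not t.is_multi_exon:
            return False
        ex = t.exons[0] if left_sided else t.exons[-1]
        return (ex.start, ex.end) == form

    return pred


def enumerate_all_events(
    transcripts: Sequence[TranscriptModel],
) -> Tuple[List[ASEvent], Set[str]]:
    """Events over an annotation: group by gene, enumerate, and flag AS
    genes (>= 1 event)."""
    by_gene: Dict[str, List[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    events: List[ASEvent] = []
    as_genes: Set[str] = set()
    for gene_id in sorted(by_gene):
        evs = enumerate_as_events(by_gene[gene_id])
        if evs:
            as_genes.add(gene_id)
            events.extend(evs)
    return events, as_genes


# ---------------------------------------------------------------------------
# PSI and differential splicing
# ---------------------------------------------------------------------------

def compute_psi(
    event: ASEvent, tpm: ExpressionMatrix, sample: str
) -> Optional[float]:
    """PSI = sum TPM(inclusion) / (sum TPM(inclusion) + sum TPM(exclusion));
    None when the denominator is zero."""
    for tid in event.inclusion | event.exclusion:
        if tid not in tpm.values.index:
            raise KeyError(f"isoform {tid} missing from the expression matrix")
    inc = float(tpm.values.loc[sorted(event.inclusion), sample].sum())
    exc = float(tpm.values.loc[sorted(event.exclusion), sample].sum())
    denom = inc + exc
    if denom == 0:
        return None
    return inc / denom


def psi_matrix(
    events: Sequence[ASEvent], tpm: ExpressionMatrix
) -> "np.ndarray":
    """Events x samples PSI matrix (NaN where undefined)."""
    import pandas as pd

    data = {}
    for ev in events:
        row = []
        for sample in tpm.samples:
            psi = compute_psi(ev, tpm, sample)
            row.append(np.nan if psi is None else psi)
        data[ev.event_id] = row
    return pd.DataFrame.from_dict(data, orient="index", columns=tpm.samples)


@dataclass(frozen=True)
class DiffSpliceResult:
    delta_psi: float
    p_value: float
    direction: str  # up | down | none


def diff_splice(
    psi_a: Sequence[float],
    psi_b: Sequence[float],
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = ALPHA,
    max_exact: int = 10,
) -> DiffSpliceResult:
    """Permutation test of mean PSI difference (condition B - A).

    Undefined (NaN) PSIs are dropped.  All label arrangements are
    enumerated when there are <= ``max_exact`` of them, otherwise the
    null is sampled by Monte Carlo (deterministic under the seed) with
    the add-one p-value estimate.  Direction is up/down when p < alpha.
    """
    a = np.asarray(psi_a, dtype=float)
    b = np.asarray(psi_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("all PSIs undefined in one condition")
    delta = float(b.mean() - a.mean())
    pooled = np.concatenate([a, b])
    n, m = a.size, b.size
    eps = 1e-12
    n_arrangements = comb(n + m, n)
    if n_arrangements <= max_exact:
        hits = 0
        for idx in combinations(range(n + m), n):
            mask = np.zeros(n + m, dtype=bool)
            mask[list(idx)] = True
            d = pooled[~mask].mean() - pooled[mask].mean()
            if abs(d) >= abs(delta) - eps:
                hits += 1
        p = hits / n_arrangements
    else:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(n + m)
            d = pooled[perm[n:]].mean() - pooled[perm[:n]].mean()
            if abs(d) >= abs(delta) - eps:
                hits += 1
        p = (hits + 1) / (n_perm + 1)
    if p < alpha and delta > 0:
        direction = "up"
    elif p < alpha and delta < 0:
        direction = "down"
    else:
        direction = "none"
    return DiffSpliceResult(delta, float(p), direction)


@dataclass
class EventDynamics:
    gained: Dict[str, int]
    lost: Dict[str, int]
    gain_percent: Dict[str, float]
    loss_percent: Dict[str, float]


def event_dynamics(
    events_prev: Sequence[ASEvent], events_curr: Sequence[ASEvent]
) -> EventDynamics:
    """Per-type gained/lost events between adjacent stages, keyed by
    (type, chrom, strand, coordinates); duplicates collapse first."""
    prev_keys = {e.key for e in events_prev}
    curr_keys = {e.key for e in events_curr}
    gained: Dict[str, int] = {t: 0 for t in EVENT_TYPES}
    lost: Dict[str, int] = {t: 0 for t in EVENT_TYPES}
    curr_totals: Dict[str, int] = {t: 0 for t in EVENT_TYPES}
    prev_totals: Dict[str, int] = {t: 0 for t in EVENT_TYPES}
    for k in curr_keys:
        curr_totals[k[0]] += 1
        if k not in prev_keys:
            gained[k[0]] += 1
    for k in prev_keys:
        prev_totals[k[0]] += 1
        if k not in curr_keys:
            lost[k[0]] += 1
    gain_pct = {
        t: (100.0 * gained[t] / curr_totals[t]) if curr_totals[t] else 0.0
        for t in EVENT_TYPES
    }
    loss_pct = {
        t: (100.0 * lost[t] / prev_totals[t]) if prev_totals[t] else 0.0
        for t in EVENT_TYPES
    }
    return EventDynamics(gained, lost, gain_pct, loss_pct)
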