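"""Exon-chain comparison against a reference annotation.

Each query transcript receives a single-character class code describing
how its exon-intron structure relates to its most closely matching
reference transcript:

* ``=``  exact match (identical intron chain; any end positions),
* ``c``  sequential subset of exons contained within a reference model,
* ``j``  shares >= 1 splice junction but carries a junction combination
         absent from the reference (potentially novel isoform),
* ``e``  overlaps a reference exon and reads >= 10 bp into the adjacent
         intron without matching the junction (potentially novel isoform),
* ``u``  no exonic overlap with the reference on either strand
         (potentially novel gene),
* ``other``  antisense, intronic or otherwise unclassifiable overlap.

Codes ``=`` and ``c`` form the "annotated" set, ``j``/``e``/``u`` the
"novel" set.  Rules are applied in the fixed priority
``= > c > j > e > other > u`` so multi-reference ambiguity resolves
deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from intervaltree import IntervalTree

from .core import Annotation, GenomeInterval, TranscriptModel, ValidationError

CODE_CATEGORY = {
    "=": "exact_match",
    "c": "contained",
    "j": "novel_isoform",
    "e": "novel_isoform",
    "u": "novel_gene",
    "other": "other",
}

ANNOTATED_CODES = frozenset({"=", "c"})
NOVEL_CODES = frozenset({"j", "e", "u"})

CATEGORIES = ("exact_match", "contained", "novel_isoform", "novel_gene", "other")

MONO_EXON_RECIPROCAL_OVERLAP = 0.5
INTRON_EXTENSION_BP = 10


@dataclass(frozen=True)
class ComparisonRecord:
    query_id: str
    code: str
    category: str
    best_ref: Optional[str] = None
    n_shared_junctions: int = 0
    sublabel: Optional[str] = None  # antisense / intronic / unclassified for "other"

    @property
    def set_label(self) -> str:
        if self.code in ANNOTATED_CODES:
            return "annotated"
        if self.code in NOVEL_CODES:
            return "novel"
        return "other"


class ReferenceIndex:
    """Prebuilt lookup structures over a reference annotation."""

    def __init__(self, reference: Annotation):
        self.reference = reference
        self.chain_map: Dict[Tuple[str, str, Tuple[Tuple[int, int], ...]], List[str]] = {}
        self.junction_map: Dict[Tuple[str, str, int, int], Set[str]] = {}
        self.exon_trees: Dict[Tuple[str, str], IntervalTree] = {}
        self.span_trees: Dict[Tuple[str, str], IntervalTree] = {}
        self.mono_exon: Dict[Tuple[str, str], List[TranscriptModel]] = {}
        for t in reference.sorted_transcripts():
            key = (t.chrom, t.strand)
            if t.is_multi_exon:
                self.chain_map.setdefault(t.chain_key(), []).append(t.transcript_id)
                for d, a in t.intron_chain:
                    self.junction_map.setdefault(
                        (t.chrom, t.strand, d, a), set()
                    ).add(t.transcript_id)
            else:
                self.mono_exon.setdefault(key, []).append(t)
            etree = self.exon_trees.setdefault(key, IntervalTree())
            for ex in t.exons:
                etree.addi(ex.start, ex.end, t.transcript_id)
            stree = self.span_trees.setdefault(key, IntervalTree())
            stree.addi(t.start, t.end, t.transcript_id)

    def exon_overlaps(self, t: TranscriptModel, strand: str) -> Set[str]:
        """Reference transcript ids with exonic overlap on the given strand."""
        tree = self.exon_trees.get((t.chrom, strand))
        if tree is None:
            return set()
        hits: Set[str] = set()
        for ex in t.exons:
            for iv in tree.overlap(ex.start, ex.end):
                hits.add(iv.data)
        return hits

    def span_overlaps(self, t: TranscriptModel, strand: str) -> Set[str]:
        tree = self.span_trees.get((t.chrom, strand))
        if tree is None:
            return set()
        return {iv.data for iv in tree.overlap(t.start, t.end)}


def _exonic_overlap_bp(a: TranscriptModel, b: TranscriptModel) -> int:
    total = 0
    for ea in a.exons:
        for eb in b.exons:
            total += ea.overlap_length(eb)
    return total


def _shared_junctions(query: TranscriptModel, ref: TranscriptModel) -> int:
    if query.chrom != ref.chrom or query.strand != ref.strand:
        return 0
    return len(set(query.intron_chain) & set(ref.intron_chain))


def _is_contiguous_subchain(
    sub: Sequence[Tuple[int, int]], full: Sequence[Tuple[int, int]]
) -> bool:
    n, m = len(sub), len(full)
    if n == 0 or n > m:
        return False
    for i in range(m - n + 1):
        if tuple(full[i : i + n]) == tuple(sub):
            return True
    return False


def _pick_best(
    query: TranscriptModel, candidates: Iterable[str], reference: Annotation
) -> Tuple[str, int]:
    """Tie-break: most shared junctions, then longest exonic overlap, then id."""
    best: Optional[Tuple[int, int, str]] = None
    for tid in candidates:
        ref = reference.transcripts[tid]
        shared = _shared_junctions(query, ref)
        ov = _exonic_overlap_bp(query, ref)
        key = (-shared, -ov, tid)
        if best is None or key < best:
            best = key
    assert best is not None
    return best[2], -best[0]


def classify_transcript(
    query: TranscriptModel,
    reference: Annotation,
    index: Optional[ReferenceIndex] = None,
) -> ComparisonRecord:
    """Assign the class code and five-way category for one query transcript."""
    if index is None:
        index = ReferenceIndex(reference)
    reference = index.reference

    same_strand_hits = index.exon_overlaps(query, query.strand)
    qjunc = set(query.intron_chain)

    # "=" -- identical intron chain (multi-exon) or >= 50% reciprocal
    # overlap with a mono-exon reference model.
    if query.is_multi_exon:
        exact_ids = index.chain_map.get(query.chain_key(), [])
        if exact_ids:
            best, shared = _pick_best(query, exact_ids, reference)
            return ComparisonRecord(
                query.transcript_id, "=", "exact_match", best, shared
            )
    else:
        qlen = query.spliced_length
        matches = []
        for ref in index.mono_exon.get((query.chrom, query.strand), []):
            ov = _exonic_overlap_bp(query, ref)
            if ov >= MONO_EXON_RECIPROCAL_OVERLAP * qlen and ov >= (
                MONO_EXON_RECIPROCAL_OVERLAP * ref.spliced_length
            ):
                matches.append(ref.transcript_id)
        if matches:
            best, shared = _pick_best(query, matches, reference)
            return ComparisonRecord(
                query.transcript_id, "=", "exact_match", best, shared
            )

    # "c" -- contiguous intron sub-chain within a reference span, or a
    # mono-exon query fully inside one reference exon.
    contained: List[str] = []
    for tid in same_strand_hits:
        ref = reference.transcripts[tid]
        if query.is_multi_exon:
            if (
                ref.is_multi_exon
                and len(query.intron_chain) < len(ref.intron_chain)
                and _is_contiguous_subchain(query.intron_chain, ref.intron_chain)
                and query.start >= ref.start
                and query.end <= ref.end
            ):
                contained.append(tid)
        else:
            ex = query.exons[0]
            for rex in ref.exons:
                if ex.start >= rex.start and ex.end <= rex.end:
                    contained.append(tid)
                    break
    if contained:
        best, shared = _pick_best(query, contained, reference)
        return ComparisonRecord(query.transcript_id, "c", "contained", best, shared)

    # "j" -- at least one shared junction, structure not matched above.
    if query.is_multi_exon:
        sharing: Set[str] = set()
        for d, a in qjunc:
            sharing |= index.junction_map.get((query.chrom, query.strand, d, a), set())
        if sharing:
            best, shared = _pick_best(query, sharing, reference)
            return ComparisonRecord(
                query.transcript_id, "j", "novel_isoform", best, shared
            )

    # "e" -- exonic overlap plus >= 10 bp extension into an adjacent
    # reference intron without matching the junction.
    e_candidates: List[str] = []
    for tid in same_strand_hits:
        ref = reference.transcripts[tid]
        if _extends_into_intron(query, ref):
            e_candidates.append(tid)
    if e_candidates:
        best, shared = _pick_best(query, e_candidates, reference)
        return ComparisonRecord(query.transcript_id, "e", "novel_isoform", best, shared)

    # "other" -- residual same-strand overlap, antisense, or intronic.
    if same_strand_hits:
        best, shared = _pick_best(query, same_strand_hits, reference)
        return ComparisonRecord(
            query.transcript_id, "other", "other", best, shared, sublabel="unclassified"
        )
    opposite = "-" if query.strand == "+" else "+"
    anti_hits = index.exon_overlaps(query, opposite)
    if anti_hits:
        best, shared = _pick_best(query, anti_hits, reference)
        return ComparisonRecord(
            query.transcript_id, "other", "other", best, shared, sublabel="antisense"
        )
    span_hits = index.span_overlaps(query, query.strand) | index.span_overlaps(
        query, opposite
    )
    if span_hits:
        best, shared = _pick_best(query, span_hits, reference)
        return ComparisonRecord(
            query.transcript_id, "other", "other", best, shared, sublabel="intronic"
        )

    return ComparisonRecord(query.transcript_id, "u", "novel_gene")


def _extends_into_intron(query: TranscriptModel, ref: TranscriptModel) -> bool:
    """True if a query exon overlaps a ref exon and reads >= 10 bp into an
    adjacent ref intron whose junction the query does not carry."""
    qjunc = set(query.intron_chain)
    for i, rex in enumerate(ref.exons):
        for qex in query.exons:
            if qex.overlap_length(rex) == 0:
                continue
            # upstream intron of rex (exists when i > 0)
            if i > 0:
                donor, acceptor = ref.intron_chain[i - 1]
                if qex.start <= acceptor - INTRON_EXTENSION_BP and (
                    (donor, acceptor) not in qjunc
                ):
                    return True
            if i < len(ref.exons) - 1:
                donor, acceptor = ref.intron_chain[i]
                if qex.end >= donor + INTRON_EXTENSION_BP and (
                    (donor, acceptor) not in qjunc
                ):
                    return True
    return False


def classify_set(
    queries: Iterable[TranscriptModel],
    reference: Annotation,
    index: Optional[ReferenceIndex] = None,
) -> Dict[str, ComparisonRecord]:
    if index is None:
        index = ReferenceIndex(reference)
    return {
        q.transcript_id: classify_transcript(q, reference, index) for q in queries
    }


# ---------------------------------------------------------------------------
# Cross-stage merging
# ---------------------------------------------------------------------------

@dataclass
class MergedTranscriptome:
    transcripts: List[TranscriptModel]
    provenance: Dict[str, List[str]]  # merged id -> contributing stage names
    sources: Dict[str, List[str]]  # merged id -> contributing transcript ids

    @property
    def annotation(self) -> Annotation:
        return Annotation.from_transcripts(self.transcripts)

    def __len__(self) -> int:
        return len(self.transcripts)


def merge_transcriptomes(
    stage_sets: Sequence[Tuple[str, Sequence[TranscriptModel]]],
) -> MergedTranscriptome:
    """Collapse transcripts across stages.

    Multi-exon models with identical (chrom, strand, intron chain) merge
    into one record spanning the extreme observed 5'/3' ends; mono-exon
    models merge transitively when same-strand overlapping, keeping the
    union span.  Gene ids are reassigned by same-strand exonic-overlap
    clustering (XLOC-style loci).
    """
    chains: Dict[
        Tuple[str, str, Tuple[Tuple[int, int], ...]],
        Dict[str, object],
    ] = {}
    monos: Dict[Tuple[str, str], List[Dict[str, object]]] = {}

    for stage, models in stage_sets:
        for t in models:
            if t.is_multi_exon:
                entry = chains.setdefault(
                    t.chain_key(),
                    {"start": t.start, "end": t.end, "stages": [], "ids": []},
                )
                entry["start"] = min(entry["start"], t.start)  # type: ignore[arg-type]
                entry["end"] = max(entry["end"], t.end)  # type: ignore[arg-type]
                entry["stages"].append(stage)  # type: ignore[union-attr]
                entry["ids"].append(t.transcript_id)  # type: ignore[union-attr]
            else:
                monos.setdefault((t.chrom, t.strand), []).append(
                    {
                        "start": t.start,
                        "end": t.end,
                        "stages": [stage],
                        "ids": [t.transcript_id],
                    }
                )

    records: List[Tuple[str, str, int, int, Tuple[Tuple[int, int], ...], List[str], List[str]]] = []
    for (chrom, strand, chain), entry in chains.items():
        records.append(
            (
                chrom,
                strand,
                int(entry["start"]),  # type: ignore[arg-type]
                int(entry["end"]),  # type: ignore[arg-type]
                chain,
                list(dict.fromkeys(entry["stages"])),  # type: ignore[arg-type]
                list(entry["ids"]),  # type: ignore[arg-type]
            )
        )
    for (chrom, strand), entries in monos.items():
        entries.sort(key=lambda e: (e["start"], e["end"]))
        cur = None
        for e in entries:
            if cur is not None and e["start"] <= cur["end"]:
                cur["end"] = max(cur["end"], e["end"])
                cur["stages"] += e["stages"]
                cur["ids"] += e["ids"]
            else:
                if cur is not None:
                    records.append(
                        (chrom, strand, cur["start"], cur["end"], (), list(dict.fromkeys(cur["stages"])), cur["ids"])
                    )
                cur = dict(e)
        if cur is not None:
            records.append(
                (chrom, strand, cur["start"], cur["end"], (), list(dict.fromkeys(cur["stages"])), cur["ids"])
            )

    records.sort(key=lambda r: (r[0], r[2], r[3], r[1], r[4]))

    # Locus clustering by same-strand exonic overlap -> merged gene ids.
    merged_models: List[TranscriptModel] = []
    provenance: Dict[str, List[str]] = {}
    sources: Dict[str, List[str]] = {}
    exon_lists: List[List[Tuple[int, int]]] = []
    for i, (chrom, strand, start, end, chain, stages, ids) in enumerate(records):
        if chain:
            bounds = [start] + [p for d_a in chain for p in d_a] + [end]
            exons = [(bounds[k], bounds[k + 1]) for k in range(0, len(bounds), 2)]
        else:
            exons = [(start, end)]
        exon_lists.append(exons)

    gene_of = _cluster_loci(records, exon_lists)
    for i, (chrom, strand, start, end, chain, stages, ids) in enumerate(records):
        tid = f"MT.{i + 1}"
        gid = f"XLOC_{gene_of[i] + 1:06d}"
        exons = tuple(
            GenomeInterval(chrom, s, e, strand) for s, e in exon_lists[i]
        )
        merged_models.append(TranscriptModel(tid, gid, chrom, strand, exons))
        provenance[tid] = stages
        sources[tid] = ids
    return MergedTranscriptome(merged_models, provenance, sources)


def _cluster_loci(records, exon_lists) -> List[int]:
    """Single-linkage clustering of records by same-strand exonic overlap."""
    parent = list(range(len(records)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    by_key: Dict[Tuple[str, str], List[int]] = {}
    for i, rec in enumerate(records):
        by_key.setdefault((rec[0], rec[1]), []).append(i)
    for idxs in by_key.values():
        tree = IntervalTree()
        for i in idxs:
            for s, e in exon_lists[i]:
                for hit in tree.overlap(s, e):
                    union(i, hit.data)
                tree.addi(s, e, i)
    roots = sorted({find(i) for i in range(len(records))})
    root_rank = {r: k for k, r in enumerate(roots)}
    return [root_rank[find(i)] for i in range(len(records))]


def category_summary(
    records: Iterable[ComparisonRecord],
) -> Dict[str, Dict[str, float]]:
    """Counts and percentages per five-way category."""
    counts = {c: 0 for c in CATEGORIES}
    total = 0
    for rec in records:
        counts[rec.category] += 1
        total += 1
    return {
        c: {
            "count": counts[c],
            "percent": (100.0 * counts[c] / total) if total else 0.0,
        }
        for c in CATEGORIES
    }


# ---------------------------------------------------------------------------
# Stage dynamics and saturation
# ---------------------------------------------------------------------------

@dataclass
class StageDynamics:
    previous_stage: str
    current_stage: str
    shared_current: FrozenSet[str]
    gained: FrozenSet[str]
    shared_previous: FrozenSet[str]
    lost: FrozenSet[str]

    @property
    def gain_percent(self) -> float:
        total = len(self.gained) + len(self.shared_current)
        return 100.0 * len(self.gained) / total if total else 0.0

    @property
    def loss_percent(self) -> float:
        total = len(self.lost) + len(self.shared_previous)
        return 100.0 * len(self.lost) / total if total else 0.0


def stage_dynamics(
    previous: Sequence[TranscriptModel],
    current: Sequence[TranscriptModel],
    previous_stage: str = "prev",
    current_stage: str = "curr",
) -> StageDynamics:
    """Gain/loss between adjacent stages.

    A current transcript is shared when its class code against the
    previous stage (used as the reference) is "=" or "c"; otherwise it
    is gained.  Loss is symmetric.
    """
    prev_ann = Annotation.from_transcripts(previous)
    curr_ann = Annotation.from_transcripts(current)
    gained, shared_curr = set(), set()
    if previous:
        recs = classify_set(current, prev_ann)
        for tid, rec in recs.items():
            (shared_curr if rec.code in ANNOTATED_CODES else gained).add(tid)
    else:
        gained = {t.transcript_id for t in current}
    lost, shared_prev = set(), set()
    if current:
        recs = classify_set(previous, curr_ann)
        for tid, rec in recs.items():
            (shared_prev if rec.code in ANNOTATED_CODES else lost).add(tid)
    else:
        lost = {t.transcript_id for t in previous}
    return StageDynamics(
        previous_stage,
        current_stage,
        frozenset(shared_curr),
        frozenset(gained),
        frozenset(shared_prev),
        frozenset(lost),
    )


@dataclass
class SaturationCurve:
    means: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    reps: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.means) < -1e-9):
            raise ValidationError("saturation means must be non-decreasing")


def _count_novel(
    merged: MergedTranscriptome, reference: Annotation, index: ReferenceIndex,
    cache: Dict[Tuple, bool],
) -> int:
    n = 0
    for t in merged.transcripts:
        key = (t.chrom, t.strand, t.start, t.end, t.intron_chain)
        novel = cache.get(key)
        if novel is None:
            rec = classify_transcript(t, reference, index)
            novel = rec.code in NOVEL_CODES
            cache[key] = novel
        n += int(novel)
    return n


def saturation_curve(
    stage_sets: Sequence[Sequence[TranscriptModel]],
    reference: Annotation,
    reps: int = 100,
    ci: float = 0.99,
    seed: int = 0,
    long_read_sets: Optional[Sequence[Sequence[TranscriptModel]]] = None,
) -> SaturationCurve:
    """Rarefaction of cumulative novel-transcript discovery.

    For each repetition the stage order is randomly permuted; stages are
    incrementally merged and the cumulative number of distinct novel
    transcripts (codes j/e/u against the reference) counted at each step.
    When long-read sets are supplied each stage is first merged with its
    long-read counterpart.  The band is the empirical percentile CI over
    repetitions.
    """
    if reps < 2:
        raise ValueError("reps must be >= 2 for a confidence interval")
    if not stage_sets:
        raise ValueError("at least one stage set is required")
    if long_read_sets is not None:
        if len(long_read_sets) != len(stage_sets):
            raise ValueError("long_read_sets must parallel stage_sets")
        combined = []
        for i, (short, longr) in enumerate(zip(stage_sets, long_read_sets)):
            merged = merge_transcriptomes(
                [(f"short{i}", list(short)), (f"long{i}", list(longr))]
            )
            combined.append(merged.transcripts)
        stage_sets = combined

    rng = np.random.default_rng(seed)
    index = ReferenceIndex(reference)
    cache: Dict[Tuple, bool] = {}
    n_steps = len(stage_sets)
    counts = np.zeros((reps, n_steps), dtype=np.int64)
    for r in range(reps):
        order = rng.permutation(n_steps)
        acc: List[Tuple[str, Sequence[TranscriptModel]]] = []
        for step, si in enumerate(order):
            acc.append((f"s{si}", list(stage_sets[si])))
            merged = merge_transcriptomes(acc)
            counts[r, step] = _count_novel(merged, reference, index, cache)
    means = counts.mean(axis=0)
    alpha = (1.0 - ci) / 2.0
    lo = np.percentile(counts, 100 * alpha, axis=0)
    hi = np.percentile(counts, 100 * (1 - alpha), axis=0)
    return SaturationCurve(means, lo, hi, reps)
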