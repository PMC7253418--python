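"""Conservation scoring of novel non-coding transcripts.

Each transcript is scored over its spliced (exon-concatenated) sequence
with two statistics: the fraction of bases whose phyloP score exceeds a
base cutoff, and the maximal mean phastCons over a 200-bp sliding
window.  Significance cutoffs are calibrated as the 95th percentile of
the same statistics over length-matched intergenic control regions (the
base cutoff is the 95th percentile of all control bases pooled).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, erf, sqrt
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import Annotation, GenomeInterval, TranscriptModel
from .tracks import SignalTrack, merge_intervals

DEFAULT_BASE_CUTOFF = 0.972
DEFAULT_FRACTION_CUTOFF = 0.2
DEFAULT_WINDOW_CUTOFF = 0.76
WINDOW_BP = 200
CALIBRATION_PERCENTILE = 95.0
MIN_CONTROLS = 20


@dataclass
class ControlRegionSet:
    regions: List[GenomeInterval]
    matched_to: List[str]
    seed: int


@dataclass(frozen=True)
class ConservationCutoffs:
    base_cutoff: float
    fraction_cutoff: float
    window_cutoff: float
    percentile: float = CALIBRATION_PERCENTILE

    @classmethod
    def study_defaults(cls) -> "ConservationCutoffs":
        return cls(DEFAULT_BASE_CUTOFF, DEFAULT_FRACTION_CUTOFF, DEFAULT_WINDOW_CUTOFF)


@dataclass(frozen=True)
class ConservationResult:
    transcript_id: str
    fraction_conserved: float
    max_window_mean: float
    phylop_significant: bool
    phastcons_significant: bool

    @property
    def both(self) -> bool:
        return self.phylop_significant and self.phastcons_significant

    @property
    def either(self) -> bool:
        return self.phylop_significant or self.phastcons_significant


def sample_control_regions(
    annotation: Annotation,
    transcripts: Sequence[TranscriptModel],
    genome_extent: Dict[str, int],
    seed: int = 0,
    max_tries: int = 10_000,
    min_regions: Optional[int] = None,
) -> ControlRegionSet:
    """One uniformly placed intergenic control per transcript, matching
    its spliced length exactly.

    Controls avoid every exon of ``annotation`` (either strand) but may
    overlap one another.  Deterministic under the seed.  When
    ``min_regions`` exceeds the transcript count, the transcript list is
    cycled so the control set stays large enough for a stable
    percentile calibration (extra controls remain length-matched).
    """
    rng = np.random.default_rng(seed)
    transcripts = list(transcripts)
    if min_regions is not None and transcripts:
        i = 0
        while len(transcripts) < min_regions:
            transcripts.append(transcripts[i % len(transcripts)])
            i += 1
    forbidden = merge_intervals(
        [ex for t in annotation for ex in t.exons]
    )
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for iv in forbidden:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    chroms = sorted(genome_extent)
    lengths = np.array([genome_extent[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()

    regions: List[GenomeInterval] = []
    matched: List[str] = []
    for t in transcripts:
        size = t.spliced_length
        placed = False
        for _ in range(max_tries):
            ci = int(rng.choice(len(chroms), p=probs))
            chrom = chroms[ci]
            limit = genome_extent[chrom] - size
            if limit <= 0:
                continue
            start = int(rng.integers(0, limit + 1))
            end = start + size
            if not _overlaps_any(by_chrom.get(chrom, []), start, end):
                regions.append(GenomeInterval(chrom, start, end))
                matched.append(t.transcript_id)
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place a {size}-bp intergenic control after "
                f"{max_tries} tries; intergenic space too small"
            )
    return ControlRegionSet(regions, matched, seed)


def _overlaps_any(sorted_ivs: List[Tuple[int, int]], start: int, end: int) -> bool:
    # linear scan; forbidden lists are small relative to retry counts
    for s, e in sorted_ivs:
        if s < end and start < e:
            return True
    return False


def conservation_stats(
    phylop: SignalTrack,
    phastcons: SignalTrack,
    chrom: str,
    exons: Sequence[Tuple[int, int]],
    base_cutoff: float = DEFAULT_BASE_CUTOFF,
    window: int = WINDOW_BP,
) -> Tuple[float, float]:
    """(fraction of bases with phyloP > cutoff, max 200-bp window mean
    phastCons) over the concatenated exon sequence.

    Regions shorter than the window use the whole-region mean.
    """
    if not exons:
        raise ValueError("empty region")
    pvals = np.concatenate(
        [phylop.values_array(chrom, s, e) for s, e in exons]
    )
    cvals = np.concatenate(
        [phastcons.values_array(chrom, s, e) for s, e in exons]
    )
    if pvals.size == 0:
        raise ValueError("region has zero length")
    fraction = float(np.mean(pvals > base_cutoff))
    if cvals.size <= window:
        max_window = float(cvals.mean())
    else:
        csum = np.concatenate([[0.0], np.cumsum(cvals)])
        window_means = (csum[window:] - csum[:-window]) / window
        max_window = float(window_means.max())
    return fraction, max_window


def transcript_conservation(
    phylop: SignalTrack,
    phastcons: SignalTrack,
    transcript: TranscriptModel,
    cutoffs: ConservationCutoffs,
    window: int = WINDOW_BP,
) -> ConservationResult:
    fraction, max_window = conservation_stats(
        phylop,
        phastcons,
        transcript.chrom,
        [(ex.start, ex.end) for ex in transcript.exons],
        base_cutoff=cutoffs.base_cutoff,
        window=window,
    )
    return ConservationResult(
        transcript.transcript_id,
        fraction,
        max_window,
        fraction > cutoffs.fraction_cutoff,
        max_window > cutoffs.window_cutoff,
    )


def calibrate_cutoffs(
    control_set: ControlRegionSet,
    phylop: SignalTrack,
    phastcons: SignalTrack,
    percentile: float = CALIBRATION_PERCENTILE,
    window: int = WINDOW_BP,
) -> ConservationCutoffs:
    """Derive the three cutoffs from control regions.

    Base cutoff: the stated percentile of all per-base phyloP values
    pooled over controls.  Fraction and window cutoffs: the same
    percentile of the per-control statistics computed with that base
    cutoff.  Percentiles use the linear-interpolation empirical quantile.
    """
    if len(control_set.regions) < MIN_CONTROLS:
        raise ValueError(
            f"need >= {MIN_CONTROLS} control regions, got {len(control_set.regions)}"
        )
    pooled = np.concatenate(
        [
            phylop.values_array(iv.chrom, iv.start, iv.end)
            for iv in control_set.regions
        ]
    )
    base_cutoff = float(np.percentile(pooled, percentile))
    fractions = []
    windows = []
    for iv in control_set.regions:
        f, w = conservation_stats(
            phylop,
            phastcons,
            iv.chrom,
            [(iv.start, iv.end)],
            base_cutoff=base_cutoff,
            window=window,
        )
        fractions.append(f)
        windows.append(w)
    return ConservationCutoffs(
        base_cutoff,
        float(np.percentile(fractions, percentile)),
        float(np.percentile(windows, percentile)),
        percentile,
    )


def rank_sum_test(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) p-value.

    Mid-ranks for ties.  Exact enumeration of all C(n+m, n) group
    assignments when n + m <= 16; otherwise the normal approximation
    with tie and continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    n, m = a.size, b.size
    if n < 1 or m < 1:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty_like(pooled)
    # mid-ranks
    sorted_vals = pooled[order]
    i = 0
    while i < pooled.size:
        j = i
        while j + 1 < pooled.size and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    u_obs = float(ranks[:n].sum() - n * (n + 1) / 2.0)

    if n + m <= 16:
        total = comb(n + m, n)
        le = ge = 0
        eps = 1e-9
        for idx in combinations(range(n + m), n):
            u = float(ranks[list(idx)].sum() - n * (n + 1) / 2.0)
            if u <= u_obs + eps:
                le += 1
            if u >= u_obs - eps:
                ge += 1
        p = 2.0 * min(le, ge) / total
        return min(1.0, p)

    mean_u = n * m / 2.0
    counts = _tie_counts(sorted_vals)
    nm = n + m
    tie_term = sum(t ** 3 - t for t in counts) / (nm * (nm - 1))
    var_u = n * m / 12.0 * (nm + 1 - tie_term)
    if var_u <= 0:
        return 1.0
    diff = u_obs - mean_u
    cc = 0.5 if diff != 0 else 0.0
    z = (abs(diff) - cc) / sqrt(var_u)
    p = 2.0 * 0.5 * (1.0 - erf(z / sqrt(2.0)))
    return min(1.0, max(0.0, p))


def _tie_counts(sorted_vals: np.ndarray) -> List[int]:
    counts = []
    i = 0
    while i < sorted_vals.size:
        j = i
        while j + 1 < sorted_vals.size and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        if j > i:
            counts.append(j - i + 1)
        i = j + 1
    return counts
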