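"""TSS categorization and validation by promoter chromatin and CAGE.

Novel-transcript TSSs fall into three groups: a potentially-novel-gene
transcript carries a novel-gene TSS; a potentially-novel-isoform
transcript whose TSS lies inside an annotated TSS interval (+-300 bp
around a same-strand reference TSS) carries a classic TSS; remaining
novel-isoform TSSs are novel TSSs.  Exact-match transcripts carry
annotated TSSs.  A TSS is high-confidence when a merged H3K4me3 peak
intersects its +-500 bp window, and CAGE-supported when a nonzero CAGE
interval does.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .compare import ComparisonRecord
from .core import Annotation, GenomeInterval, TranscriptModel
from .tracks import SignalTrack, merge_intervals

TSS_INTERVAL_HALFWIDTH = 300
PEAK_WINDOW_HALFWIDTH = 500
PROMOTER_SPAN = 4000
N_BINS = 161
BIN_WIDTH = 100
BIN_STEP = 50


@dataclass
class TssRecord:
    transcript_id: str
    position: int
    strand: str
    group: str  # classic | novel | novel_gene | annotated
    high_confidence: Optional[bool] = None
    cage_supported: Optional[bool] = None


class AnnotatedTssIndex:
    """Per-(chrom, strand) sorted reference TSS positions."""

    def __init__(self, annotation: Annotation, halfwidth: int = TSS_INTERVAL_HALFWIDTH):
        self.halfwidth = halfwidth
        self._pos: Dict[Tuple[str, str], List[int]] = {}
        for t in annotation:
            self._pos.setdefault((t.chrom, t.strand), []).append(t.tss)
        for v in self._pos.values():
            v.sort()

    def within_interval(self, chrom: str, strand: str, pos: int) -> bool:
        positions = self._pos.get((chrom, strand))
        if not positions:
            return False
        i = bisect_left(positions, pos)
        for j in (i - 1, i):
            if 0 <= j < len(positions) and abs(positions[j] - pos) <= self.halfwidth:
                return True
        return False


def categorize_tss(
    record: ComparisonRecord,
    transcript: TranscriptModel,
    annotation: Annotation,
    tss_index: Optional[AnnotatedTssIndex] = None,
    halfwidth: int = TSS_INTERVAL_HALFWIDTH,
) -> TssRecord:
    if tss_index is None:
        tss_index = AnnotatedTssIndex(annotation, halfwidth)
    category = record.category
    pos = transcript.tss
    if category == "novel_gene":
        group = "novel_gene"
    elif category == "novel_isoform":
        if tss_index.within_interval(transcript.chrom, transcript.strand, pos):
            group = "classic"
        else:
            group = "novel"
    elif category in ("exact_match", "contained"):
        group = "annotated"
    else:
        raise ValueError(
            f"transcript {transcript.transcript_id} has category "
            f"{category!r}; TSS groups are defined for classified "
            f"annotated/novel transcripts"
        )
    return TssRecord(transcript.transcript_id, pos, transcript.strand, group)


@dataclass
class PromoterProfile:
    transcript_id: str
    values: np.ndarray  # length 161, 5'->3' relative to the transcript

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_BINS,):
            raise ValueError(f"promoter profile must have {N_BINS} bins")


def promoter_profile(
    transcript_id: str,
    chrom: str,
    tss: int,
    strand: str,
    track: SignalTrack,
    n_bins: int = N_BINS,
    width: int = BIN_WIDTH,
    step: int = BIN_STEP,
) -> PromoterProfile:
    """Mean signal in 161 overlapping 100-bp bins (50-bp step) laid
    symmetrically across the +-4 kb promoter, oriented 5'->3'.

    Bin starts run from tss - (n_bins - 1) * step / 2 - width / 2 so the
    central bin is centered on the TSS; for minus-strand transcripts the
    bin order is reversed.  Out-of-chromosome bases take the track
    default.
    """
    first = tss - ((n_bins - 1) // 2) * step - width // 2
    values = np.array(
        [track.mean(chrom, first + i * step, first + i * step + width) for i in range(n_bins)]
    )
    if strand == "-":
        values = values[::-1]
    return PromoterProfile(transcript_id, values)


def high_confidence_tss(
    tss: int,
    chrom: str,
    merged_peaks: Sequence[GenomeInterval],
    halfwidth: int = PEAK_WINDOW_HALFWIDTH,
) -> bool:
    """True iff a merged peak intersects the closed +-500 bp TSS window."""
    lo, hi = tss - halfwidth, tss + halfwidth + 1  # closed window, half-open repr
    for peak in merged_peaks:
        if peak.chrom == chrom and peak.start < hi and lo < peak.end:
            return True
    return False


def merge_peaks(peak_sets: Sequence[Sequence[GenomeInterval]]) -> List[GenomeInterval]:
    """Interval union of peaks across stage files."""
    flat = [p for peaks in peak_sets for p in peaks]
    if not flat:
        return []
    return merge_intervals(flat)


def cage_support_intervals(
    cage_tracks: Sequence[SignalTrack],
) -> List[GenomeInterval]:
    """Union of bases with nonzero CAGE value in any sample."""
    ivs: List[GenomeInterval] = []
    for track in cage_tracks:
        for chrom in track.chroms():
            ivs.extend(track.nonzero_intervals(chrom))
    if not ivs:
        return []
    return merge_intervals(ivs)


def cage_supported(
    tss: int,
    chrom: str,
    support_intervals: Sequence[GenomeInterval],
    halfwidth: int = PEAK_WINDOW_HALFWIDTH,
) -> bool:
    lo, hi = tss - halfwidth, tss + halfwidth + 1
    for iv in support_intervals:
        if iv.chrom == chrom and iv.start < hi and lo < iv.end:
            return True
    return False
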