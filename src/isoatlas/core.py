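"""Core genomic data model.

All coordinates are 0-based half-open on the forward genomic strand;
GTF I/O converts to/from 1-based closed intervals at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple


class ValidationError(ValueError):
    """An object violates a structural invariant of the data model."""


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """Half-open genomic interval ``[start, end)``.

    strand is "+", "-" or "." (unstranded, e.g. peaks).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval chrom must be non-empty")
        if self.start < 0:
            raise ValidationError(f"interval start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"interval end must exceed start: [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomeInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomeInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class TranscriptModel:
    """Strand-aware exon chain; the unit of all structural comparison.

    Exons are sorted by start, pairwise disjoint with >= 1 bp gaps (the
    introns).  The intron chain -- ordered (donor_start, acceptor_end)
    genomic pairs -- defines structural identity for merging and for the
    exact-match class code.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: Tuple[GenomeInterval, ...]
    biotype: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"transcript {self.transcript_id}: strand must be + or -, "
                f"got {self.strand!r}"
            )
        if not self.exons:
            raise ValidationError(f"transcript {self.transcript_id}: no exons")
        exons = tuple(self.exons)
        object.__setattr__(self, "exons", exons)
        for ex in exons:
            if ex.chrom != self.chrom:
                raise ValidationError(
                    f"transcript {self.transcript_id}: exon on {ex.chrom}, "
                    f"transcript on {self.chrom}"
                )
        for a, b in zip(exons, exons[1:]):
            if b.start <= a.end:
                raise ValidationError(
                    f"transcript {self.transcript_id}: exons must be sorted "
                    f"and separated by >= 1 bp (got [{a.start},{a.end}) then "
                    f"[{b.start},{b.end}))"
                )

    # -- derived geometry ------------------------------------------------

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> GenomeInterval:
        return GenomeInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def is_multi_exon(self) -> bool:
        return len(self.exons) > 1

    @property
    def spliced_length(self) -> int:
        return sum(len(ex) for ex in self.exons)

    @property
    def intron_chain(self) -> Tuple[Tuple[int, int], ...]:
        """Ordered (intron start, intron end) pairs in genomic coordinates."""
        return tuple(
            (a.end, b.start) for a, b in zip(self.exons, self.exons[1:])
        )

    @property
    def introns(self) -> Tuple[GenomeInterval, ...]:
        return tuple(
            GenomeInterval(self.chrom, s, e, self.strand)
            for s, e in self.intron_chain
        )

    @property
    def tss(self) -> int:
        """Strand-aware 5' end, as a 0-based base position."""
        if self.strand == "+":
            return self.start
        return self.end - 1

    @property
    def tes(self) -> int:
        """Strand-aware 3' end, as a 0-based base position."""
        if self.strand == "+":
            return self.end - 1
        return self.start

    def chain_key(self) -> Tuple[str, str, Tuple[Tuple[int, int], ...]]:
        """Identity key for multi-exon merging: (chrom, strand, intron chain)."""
        return (self.chrom, self.strand, self.intron_chain)


def make_transcript(
    transcript_id: str,
    gene_id: str,
    chrom: str,
    strand: str,
    exons: Sequence[Tuple[int, int]],
    biotype: Optional[str] = None,
) -> TranscriptModel:
    """Convenience constructor from (start, end) pairs (0-based half-open)."""
    ivs = tuple(
        GenomeInterval(chrom, s, e, strand) for s, e in sorted(exons)
    )
    return TranscriptModel(transcript_id, gene_id, chrom, strand, ivs, biotype)


@dataclass
class Annotation:
    """A collection of transcripts grouped into genes."""

    transcripts: Dict[str, TranscriptModel] = field(default_factory=dict)
    genes: Dict[str, List[str]] = field(default_factory=dict)

    @classmethod
    def from_transcripts(cls, transcripts: Iterable[TranscriptModel]) -> "Annotation":
        ann = cls()
        for t in transcripts:
            ann.add(t)
        return ann

    def add(self, t: TranscriptModel) -> None:
        if t.transcript_id in self.transcripts:
            raise ValidationError(f"duplicate transcript_id {t.transcript_id}")
        self.transcripts[t.transcript_id] = t
        self.genes.setdefault(t.gene_id, []).append(t.transcript_id)

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self.transcripts.values())

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.transcripts

    def gene_transcripts(self, gene_id: str) -> List[TranscriptModel]:
        return [self.transcripts[tid] for tid in self.genes[gene_id]]

    def tss_index(self) -> Dict[str, int]:
        """transcript_id -> strand-aware TSS position."""
        return {tid: t.tss for tid, t in self.transcripts.items()}

    def sorted_transcripts(self) -> List[TranscriptModel]:
        """Deterministic order: (chrom, start, transcript_id)."""
        return sorted(
            self.transcripts.values(),
            key=lambda t: (t.chrom, t.start, t.transcript_id),
        )
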