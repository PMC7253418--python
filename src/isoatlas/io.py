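"""Readers/writers for GTF, bedGraph, BED, FASTA and the tabular inputs.

GTF coordinates are 1-based closed; everything internal is 0-based
half-open.  The conversion is the exact bijection
``start_internal = start_gtf - 1``, ``end_internal = end_gtf``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .core import (
    Annotation,
    GenomeInterval,
    TranscriptModel,
    ValidationError,
)
from .tracks import SignalTrack


class ParseError(ValueError):
    """A malformed input line; the message names the file and line number."""


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def read_gtf(path: Union[str, Path]) -> Annotation:
    """Parse exon features of a GTF file into an Annotation.

    Transcripts whose strand is not + or - are rejected (strand drives
    TSS, splice-motif and AS logic downstream).
    """
    path = Path(path)
    exons: Dict[str, List[GenomeInterval]] = {}
    meta: Dict[str, Tuple[str, str, str, Optional[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"{path.name}:{lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            try:
                start_1 = int(start_s)
                end_1 = int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path.name}:{lineno}: non-integer coordinate") from exc
            if end_1 < start_1:
                raise ValidationError(
                    f"{path.name}:{lineno}: end < start ({end_1} < {start_1})"
                )
            attr_map = dict(_ATTR_RE.findall(attrs))
            gene_id = attr_map.get("gene_id")
            transcript_id = attr_map.get("transcript_id")
            if not gene_id or not transcript_id:
                raise ParseError(
                    f"{path.name}:{lineno}: exon lacks gene_id/transcript_id"
                )
            if strand not in ("+", "-"):
                raise ValidationError(
                    f"{path.name}:{lineno}: transcript {transcript_id} is "
                    f"unstranded ({strand!r}); stranded models are required"
                )
            iv = GenomeInterval(chrom, start_1 - 1, end_1, strand)
            if transcript_id in meta:
                prev_chrom, prev_strand, prev_gene, _ = meta[transcript_id]
                if prev_chrom != chrom or prev_strand != strand:
                    raise ValidationError(
                        f"{path.name}:{lineno}: transcript {transcript_id} "
                        f"has exons on mixed chrom/strand"
                    )
            else:
                meta[transcript_id] = (
                    chrom,
                    strand,
                    gene_id,
                    attr_map.get("transcript_biotype"),
                )
            exons.setdefault(transcript_id, []).append(iv)

    transcripts = []
    for tid, ivs in exons.items():
        chrom, strand, gene_id, biotype = meta[tid]
        ivs.sort(key=lambda x: x.start)
        transcripts.append(
            TranscriptModel(tid, gene_id, chrom, strand, tuple(ivs), biotype)
        )
    transcripts.sort(key=lambda t: (t.chrom, t.start, t.transcript_id))
    return Annotation.from_transcripts(transcripts)


def write_gtf(annotation: Annotation, path: Union[str, Path]) -> None:
    """Emit exon features, 1-based closed, deterministic record order.

    Attributes are written in fixed order: gene_id, then transcript_id,
    then (if set) transcript_biotype.
    """
    with open(path, "w") as fh:
        for t in annotation.sorted_transcripts():
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            if t.biotype:
                attrs += f' transcript_biotype "{t.biotype}";'
            for ex in t.exons:
                fh.write(
                    "\t".join(
                        [
                            t.chrom,
                            "isoatlas",
                            "exon",
                            str(ex.start + 1),
                            str(ex.end),
                            ".",
                            t.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# bedGraph / BED
# ---------------------------------------------------------------------------

def read_signal_bedgraph(path: Union[str, Path], default: float = 0.0) -> SignalTrack:
    """Read a 4-column bedGraph (chrom, 0-based start, end, value)."""
    path = Path(path)
    runs: List[Tuple[str, int, int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ParseError(f"{path.name}:{lineno}: expected 4 columns")
            try:
                runs.append(
                    (fields[0], int(fields[1]), int(fields[2]), float(fields[3]))
                )
            except ValueError as exc:
                raise ParseError(
                    f"{path.name}:{lineno}: non-numeric bedGraph fields"
                ) from exc
    return SignalTrack.from_runs(runs, default=default)


def write_signal_bedgraph(track: SignalTrack, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for chrom, s, e, v in track.iter_runs():
            fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def read_bed(path: Union[str, Path]) -> List[GenomeInterval]:
    """Read BED3/BED6 intervals (0-based half-open)."""
    path = Path(path)
    out: List[GenomeInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ParseError(f"{path.name}:{lineno}: expected >= 3 columns")
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
            try:
                out.append(
                    GenomeInterval(fields[0], int(fields[1]), int(fields[2]), strand)
                )
            except ValueError as exc:
                raise ParseError(f"{path.name}:{lineno}: bad BED coordinates") from exc
    return out


def write_bed(intervals: Iterable[GenomeInterval], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

GenomeLike = Mapping[str, str]


def open_genome(path: Union[str, Path]) -> GenomeLike:
    """Open an indexed FASTA; returns a chrom -> sequence mapping view."""
    from pyfaidx import Fasta

    return _FaidxView(Fasta(str(path), sequence_always_upper=True))


class _FaidxView(Mapping):
    def __init__(self, fasta):
        self._fasta = fasta

    def __getitem__(self, chrom: str) -> str:
        return str(self._fasta[chrom])

    def __iter__(self):
        return iter(self._fasta.keys())

    def __len__(self):
        return len(self._fasta.keys())

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return str(self._fasta[chrom][start:end]).upper()

    def lengths(self) -> Dict[str, int]:
        return {name: len(rec) for name, rec in self._fasta.items()}


def fetch_sequence(
    genome: GenomeLike, interval: GenomeInterval, strand: Optional[str] = None
) -> str:
    """Extract an uppercase nucleotide substring; '-' reverse-complements."""
    strand = strand or interval.strand
    if interval.chrom not in genome:
        raise KeyError(f"chromosome {interval.chrom!r} not in genome")
    if hasattr(genome, "fetch"):
        length = genome.lengths()[interval.chrom]
        if interval.end > length:
            raise IndexError(
                f"interval [{interval.start},{interval.end}) exceeds "
                f"{interval.chrom} length {length}"
            )
        seq = genome.fetch(interval.chrom, interval.start, interval.end)
    else:
        chrom_seq = genome[interval.chrom]
        if interval.end > len(chrom_seq):
            raise IndexError(
                f"interval [{interval.start},{interval.end}) exceeds "
                f"{interval.chrom} length {len(chrom_seq)}"
            )
        seq = chrom_seq[interval.start : interval.end].upper()
    if strand == "-":
        return reverse_complement(seq)
    return seq


def spliced_sequence(genome: GenomeLike, transcript: TranscriptModel) -> str:
    """Sense-strand spliced (exon-concatenated) transcript sequence."""
    parts = [
        fetch_sequence(genome, ex, strand="+") for ex in transcript.exons
    ]
    seq = "".join(parts)
    if transcript.strand == "-":
        seq = reverse_complement(seq)
    return seq


def write_fasta(sequences: Mapping[str, str], path: Union[str, Path], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Expression matrices and junction-support tables
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Transcripts/genes x samples, non-negative TPM or FPKM values."""

    values: pd.DataFrame
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in ("TPM", "FPKM"):
            raise ValidationError(f"unit must be TPM or FPKM, got {self.unit!r}")
        if self.values.columns.duplicated().any():
            raise ValidationError("duplicate sample labels")
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("expression values must be >= 0")

    @property
    def samples(self) -> List[str]:
        return list(self.values.columns)

    def stage_of(self, sample: str) -> str:
        """Stage label of a 'stage_replicate' column name."""
        return sample.rsplit("_", 1)[0]

    def stage_means(self) -> pd.DataFrame:
        """Average replicate columns into one column per stage."""
        stages = [self.stage_of(c) for c in self.values.columns]
        return self.values.T.groupby(stages, sort=False).mean().T

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.values.to_csv(path, sep="\t", index_label="id")

    @classmethod
    def from_tsv(cls, path: Union[str, Path], unit: str) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, unit)


JunctionKey = Tuple[str, int, int, str]  # chrom, donor (intron start), acceptor (intron end), strand


@dataclass
class JunctionSupportTable:
    """(chrom, donor, acceptor, strand) -> per-sample short-read counts."""

    counts: Dict[JunctionKey, Dict[str, int]]

    def __post_init__(self) -> None:
        for (chrom, donor, acceptor, strand), per_sample in self.counts.items():
            if acceptor <= donor:
                raise ValidationError(
                    f"junction {chrom}:{donor}-{acceptor}: donor must precede acceptor"
                )
            for sample, n in per_sample.items():
                if n < 0:
                    raise ValidationError(
                        f"negative support count for {chrom}:{donor}-{acceptor} {sample}"
                    )

    def max_support(self, key: JunctionKey) -> int:
        per_sample = self.counts.get(key)
        if not per_sample:
            return 0
        return max(per_sample.values())

    def to_tsv(self, path: Union[str, Path]) -> None:
        samples = sorted({s for per in self.counts.values() for s in per})
        with open(path, "w") as fh:
            fh.write("chrom\tdonor\tacceptor\tstrand\t" + "\t".join(samples) + "\n")
            for key in sorted(self.counts):
                chrom, donor, acceptor, strand = key
                per = self.counts[key]
                row = [chrom, str(donor), str(acceptor), strand]
                row += [str(per.get(s, 0)) for s in samples]
                fh.write("\t".join(row) + "\n")

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "JunctionSupportTable":
        df = pd.read_csv(path, sep="\t")
        samples = [c for c in df.columns if c not in ("chrom", "donor", "acceptor", "strand")]
        cols = list(df.columns)
        si = {s: cols.index(s) for s in samples}
        counts: Dict[JunctionKey, Dict[str, int]] = {}
        for row in df.itertuples(index=False, name=None):
            key = (
                row[cols.index("chrom")],
                int(row[cols.index("donor")]),
                int(row[cols.index("acceptor")]),
                row[cols.index("strand")],
            )
            counts[key] = {s: int(row[si[s]]) for s in samples}
        return cls(counts)


def read_scores_tsv(path: Union[str, Path], value_col: str) -> Dict[str, float]:
    """Two-column TSV (transcript_id, <value_col>) -> dict."""
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["transcript_id"], df[value_col].astype(float)))
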