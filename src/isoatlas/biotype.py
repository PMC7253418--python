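"""Biotype assignment, ORF extraction, homology significance, expression tiers.

Novel transcripts are split by coding potential (score cutoff 0.44, the
CPAT mouse default): high-potential -> protein_coding; low-potential and
spliced length > 200 bp -> lncRNA; the rest -> else.  Annotated
transcripts map straight from their reference biotype.  Coding scores
are consumed, never computed here.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional

from Bio.Seq import Seq

from .core import TranscriptModel

CODING_SCORE_CUTOFF = 0.44
LNCRNA_MIN_LENGTH = 200
MIN_ORF_LENGTH = 300
LOG10_EVALUE_CUTOFF = -5.0

# Reference biotypes folded into the lncRNA class
_LNC_BIOTYPES = {
    "lncRNA",
    "lincRNA",
    "antisense",
    "processed_transcript",
    "sense_intronic",
    "sense_overlapping",
    "3prime_overlapping_ncRNA",
    "bidirectional_promoter_lncRNA",
}


@dataclass(frozen=True)
class BiotypeCall:
    transcript_id: str
    biotype_class: str  # protein_coding | lncRNA | else
    basis: str  # reference_biotype | coding_score
    coding_score: Optional[float] = None


def classify_biotype(
    transcript: TranscriptModel,
    category: str,
    coding_score: Optional[float] = None,
    cutoff: float = CODING_SCORE_CUTOFF,
    lnc_min_length: int = LNCRNA_MIN_LENGTH,
) -> BiotypeCall:
    """Three-way biotype split for one classified transcript.

    ``category`` is the five-way comparison category; annotated
    categories (exact_match/contained) use the reference biotype, novel
    categories require a coding score in [0, 1].
    """
    tid = transcript.transcript_id
    if category in ("exact_match", "contained"):
        biotype = transcript.biotype or "else"
        if biotype == "protein_coding":
            cls = "protein_coding"
        elif biotype in _LNC_BIOTYPES:
            cls = "lncRNA"
        else:
            cls = "else"
        return BiotypeCall(tid, cls, "reference_biotype")
    if coding_score is None:
        raise ValueError(f"novel transcript {tid} requires a coding score")
    if not (0.0 <= coding_score <= 1.0):
        raise ValueError(f"coding score must lie in [0, 1], got {coding_score}")
    if coding_score > cutoff:
        cls = "protein_coding"
    elif transcript.spliced_length > lnc_min_length:
        cls = "lncRNA"
    else:
        cls = "else"
    return BiotypeCall(tid, cls, "coding_score", coding_score)


@dataclass(frozen=True)
class OrfRecord:
    transcript_id: str
    frame: int  # 0, 1, 2
    start: int  # nt offset within the transcript, 0-based
    end: int  # exclusive; includes the stop codon when stop-terminated
    length: int
    peptide: str
    complete: bool  # stop-terminated


_STOPS = {"TAA", "TAG", "TGA"}
_VALID_SEQ = re.compile(r"^[ACGTN]*$")


def find_orfs(
    sequence: str,
    transcript_id: str = "",
    min_len: int = MIN_ORF_LENGTH,
    include_incomplete: bool = False,
) -> List[OrfRecord]:
    """ATG-initiated ORFs in the three forward frames of a sense-strand
    spliced sequence, length >= min_len, sorted by length descending.

    Stop-terminated ORFs include the stop codon in their length.  With
    ``include_incomplete`` ORFs running off the 3' end are also reported.
    """
    seq = sequence.upper()
    if not _VALID_SEQ.match(seq):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"sequence contains non-ACGTN characters: {bad}")
    orfs: List[OrfRecord] = []
    n = len(seq)
    for frame in range(3):
        start: Optional[int] = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if start is None:
                if codon == "ATG":
                    start = pos
            elif codon in _STOPS:
                end = pos + 3
                if end - start >= min_len:
                    pep = str(Seq(seq[start:pos]).translate())
                    orfs.append(
                        OrfRecord(transcript_id, frame, start, end, end - start, pep, True)
                    )
                start = None
        if include_incomplete and start is not None:
            end = n - ((n - frame) % 3)
            if end - start >= min_len:
                pep = str(Seq(seq[start:end]).translate())
                orfs.append(
                    OrfRecord(transcript_id, frame, start, end, end - start, pep, False)
                )
    orfs.sort(key=lambda o: (-o.length, o.start, o.frame))
    return orfs


@dataclass(frozen=True)
class HomologyCall:
    transcript_id: str
    blast_evalue: Optional[float]
    pfam_evalue: Optional[float]
    homology_class: str  # both | blast_only | pfam_only | none


def homology_significance(
    transcript_id: str,
    blast_evalue: Optional[float] = None,
    pfam_evalue: Optional[float] = None,
    log10_cutoff: float = LOG10_EVALUE_CUTOFF,
) -> HomologyCall:
    """Per-source significance: log10(e-value) strictly below -5."""

    def significant(e: Optional[float]) -> bool:
        if e is None:
            return False
        if e <= 0:
            raise ValueError(f"e-value must be > 0, got {e}")
        return math.log10(e) < log10_cutoff

    b = significant(blast_evalue)
    p = significant(pfam_evalue)
    cls = "both" if (b and p) else "blast_only" if b else "pfam_only" if p else "none"
    return HomologyCall(transcript_id, blast_evalue, pfam_evalue, cls)


def expression_tier(tpm: float) -> str:
    """not_detected (<= 1), expressed (1 < TPM <= 10), high (> 10)."""
    if tpm < 0:
        raise ValueError(f"TPM must be >= 0, got {tpm}")
    if tpm <= 1:
        return "not_detected"
    if tpm <= 10:
        return "expressed"
    return "high"


def tier_summary(tpms: Iterable[float]) -> Dict[str, int]:
    out = {"not_detected": 0, "expressed": 0, "high": 0}
    for v in tpms:
        out[expression_tier(v)] += 1
    return out
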