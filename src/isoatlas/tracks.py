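"""Run-length per-base signal tracks (H3K4me3, CAGE, phyloP, phastCons)."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

from .core import GenomeInterval, ValidationError


@dataclass
class SignalTrack:
    """Per-base numeric track stored as sorted, disjoint runs per chromosome.

    Bases not covered by any run score ``default`` (0 by default, matching
    the treatment of uncovered bases as zero when averaging over a fixed
    denominator).
    """

    default: float = 0.0
    # chrom -> (starts, ends, values) as parallel numpy arrays
    _runs: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )

    @classmethod
    def from_runs(
        cls,
        runs: Iterable[Tuple[str, int, int, float]],
        default: float = 0.0,
    ) -> "SignalTrack":
        by_chrom: Dict[str, List[Tuple[int, int, float]]] = {}
        for chrom, start, end, value in runs:
            if end <= start:
                raise ValidationError(f"run end must exceed start: {start}..{end}")
            by_chrom.setdefault(chrom, []).append((start, end, float(value)))
        track = cls(default=default)
        for chrom, rr in by_chrom.items():
            rr.sort()
            for (s1, e1, _), (s2, _, _) in zip(rr, rr[1:]):
                if s2 < e1:
                    raise ValidationError(
                        f"overlapping runs on {chrom}: [{s1},{e1}) and start {s2}"
                    )
            starts = np.array([r[0] for r in rr], dtype=np.int64)
            ends = np.array([r[1] for r in rr], dtype=np.int64)
            values = np.array([r[2] for r in rr], dtype=np.float64)
            track._runs[chrom] = (starts, ends, values)
        return track

    def chroms(self) -> List[str]:
        return sorted(self._runs)

    def runs(self, chrom: str) -> List[Tuple[int, int, float]]:
        if chrom not in self._runs:
            return []
        starts, ends, values = self._runs[chrom]
        return [(int(s), int(e), float(v)) for s, e, v in zip(starts, ends, values)]

    def iter_runs(self) -> Iterable[Tuple[str, int, int, float]]:
        for chrom in self.chroms():
            for s, e, v in self.runs(chrom):
                yield chrom, s, e, v

    def value_at(self, chrom: str, pos: int) -> float:
        if chrom not in self._runs:
            return self.default
        starts, ends, values = self._runs[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < ends[i]:
            return float(values[i])
        return self.default

    def values_array(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base values over [start, end); uncovered bases = default.

        start may be negative and end may exceed coverage; out-of-track
        bases take the default value.
        """
        if end <= start:
            raise ValidationError(f"empty query interval [{start}, {end})")
        out = np.full(end - start, self.default, dtype=np.float64)
        if chrom not in self._runs:
            return out
        starts, ends, values = self._runs[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        for i in range(lo, hi):
            s = max(int(starts[i]), start)
            e = min(int(ends[i]), end)
            if e > s:
                out[s - start : e - start] = values[i]
        return out

    def mean(self, chrom: str, start: int, end: int) -> float:
        """Mean per-base value over [start, end) with default-filled gaps."""
        if end <= start:
            raise ValidationError(f"empty query interval [{start}, {end})")
        if chrom not in self._runs:
            return self.default
        starts, ends, values = self._runs[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        total = 0.0
        covered = 0
        for i in range(lo, hi):
            s = max(int(starts[i]), start)
            e = min(int(ends[i]), end)
            if e > s:
                total += values[i] * (e - s)
                covered += e - s
        total += self.default * ((end - start) - covered)
        return total / (end - start)

    def nonzero_intervals(self, chrom: str) -> List[GenomeInterval]:
        """Maximal intervals where the track value is nonzero."""
        out: List[GenomeInterval] = []
        for s, e, v in self.runs(chrom):
            if v != 0.0:
                if out and out[-1].end == s:
                    out[-1] = GenomeInterval(chrom, out[-1].start, e)
                else:
                    out.append(GenomeInterval(chrom, s, e))
        return out


def merge_intervals(intervals: Sequence[GenomeInterval]) -> List[GenomeInterval]:
    """Union of (possibly overlapping) intervals, per chromosome, strand-blind."""
    by_chrom: Dict[str, List[GenomeInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: List[GenomeInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda x: (x.start, x.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                merged.append(GenomeInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        merged.append(GenomeInterval(chrom, cur_s, cur_e))
    return merged
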