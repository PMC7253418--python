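"""Independent brute-force oracles used to check the fast implementations.

These are deliberately written as plain nested loops over the documented
rules, with no shared code or indexes from the package internals.
"""

from itertools import combinations

STOPS = {"TAA", "TAG", "TGA"}


def _overlap(a, b):
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def _exons(t):
    return [(e.start, e.end) for e in t.exons]


def _exonic_overlap(q, r):
    return sum(_overlap(a, b) for a in _exons(q) for b in _exons(r))


def _is_contiguous_sub(sub, full):
    n, m = len(sub), len(full)
    return any(tuple(full[i : i + n]) == tuple(sub) for i in range(m - n + 1))


def oracle_code(q, refs):
    """Class code by exhaustive rule checking over every reference model."""
    same = [r for r in refs if r.chrom == q.chrom and r.strand == q.strand]
    opp = [r for r in refs if r.chrom == q.chrom and r.strand != q.strand]

    if len(q.exons) > 1:
        for r in same:
            if len(r.exons) > 1 and q.intron_chain == r.intron_chain:
                return "="
    else:
        qe = _exons(q)[0]
        for r in same:
            if len(r.exons) == 1:
                ov = _overlap(qe, _exons(r)[0])
                if ov >= 0.5 * (qe[1] - qe[0]) and ov >= 0.5 * (
                    r.exons[0].end - r.exons[0].start
                ):
                    return "="

    for r in same:
        if len(q.exons) > 1:
            if (
                len(r.exons) > 1
                and len(q.intron_chain) < len(r.intron_chain)
                and _is_contiguous_sub(q.intron_chain, r.intron_chain)
                and q.start >= r.start
                and q.end <= r.end
            ):
                return "c"
        else:
            qe = _exons(q)[0]
            if any(qe[0] >= e[0] and qe[1] <= e[1] for e in _exons(r)):
                return "c"

    if len(q.exons) > 1:
        ref_junctions = {j for r in same for j in r.intron_chain}
        if set(q.intron_chain) & ref_junctions:
            return "j"

    for r in same:
        if _exonic_overlap(q, r) == 0:
            continue
        for i, rex in enumerate(_exons(r)):
            for qex in _exons(q):
                if _overlap(qex, rex) == 0:
                    continue
                if i > 0:
                    d, a = r.intron_chain[i - 1]
                    if qex[0] <= a - 10 and (d, a) not in set(q.intron_chain):
                        return "e"
                if i < len(r.exons) - 1:
                    d, a = r.intron_chain[i]
                    if qex[1] >= d + 10 and (d, a) not in set(q.intron_chain):
                        return "e"

    if any(_exonic_overlap(q, r) > 0 for r in same):
        return "other"
    if any(_exonic_overlap(q, r) > 0 for r in opp):
        return "other"
    if any(
        q.start < r.end and r.start < q.end for r in same + opp
    ):
        return "other"
    return "u"


# ---------------------------------------------------------------------------
# AS events
# ---------------------------------------------------------------------------

def brute_force_event_keys(isoforms):
    """(type, coords) keys from direct pairwise definition checking."""
    keys = set()
    strand = isoforms[0].strand
    for t1, t2 in combinations(isoforms, 2):
        for a, b in ((t1, t2), (t2, t1)):
            keys |= _se(a, b)
            keys |= _ri(a, b)
            keys |= _a5a3(a, b, strand)
            keys |= _mx(a, b, strand)
            keys |= _af_al(a, b, strand)
    return keys


def _adjacent(t):
    ch = t.intron_chain
    return [(ch[i], ch[i + 1]) for i in range(len(ch) - 1)]


def _se(inc, exc):
    out = set()
    for (d1, a1), (d2, a2) in _adjacent(inc):
        if (d1, a2) in set(exc.intron_chain):
            out.add(("SE", (d1, a1, d2, a2)))
    return out


def _ri(spliced, retained):
    out = set()
    exset = {(e.start, e.end) for e in retained.exons}
    for i, (d, a) in enumerate(spliced.intron_chain):
        left, right = spliced.exons[i], spliced.exons[i + 1]
        if (left.start, right.end) in exset:
            out.add(("RI", (left.start, d, a, right.end)))
    return out


def _a5a3(t1, t2, strand):
    out = set()
    for i1, (d1, a1) in enumerate(t1.intron_chain):
        for i2, (d2, a2) in enumerate(t2.intron_chain):
            if d1 == d2 and a1 != a2:
                e1, e2 = t1.exons[i1 + 1], t2.exons[i2 + 1]
                if e1.end == e2.end:
                    typ = "A3" if strand == "+" else "A5"
                    lo, hi = sorted((a1, a2))
                    out.add((typ, (d1, lo, hi, e1.end)))
            if a1 == a2 and d1 != d2:
                e1, e2 = t1.exons[i1], t2.exons[i2]
                if e1.start == e2.start:
                    typ = "A5" if strand == "+" else "A3"
                    lo, hi = sorted((d1, d2))
                    out.add((typ, (e1.start, lo, hi, a1)))
    return out


def _mx(t1, t2, strand):
    out = set()
    for (d1, x1), (y1, a1) in _adjacent(t1):
        for (d2, x2), (y2, a2) in _adjacent(t2):
            if d1 == d2 and a1 == a2 and (x1, y1) != (x2, y2):
                if y1 <= x2 or y2 <= x1:
                    if not any(
                        e.start < y2 and x2 < e.end for e in t1.exons
                    ) and not any(e.start < y1 and x1 < e.end for e in t2.exons):
                        ea, eb = sorted([(x1, y1), (x2, y2)])
                        out.add(("MX", (d1, *ea, *eb, a1)))
    return out


def _af_al(t1, t2, strand):
    out = set()
    if len(t1.exons) > 1 and len(t2.exons) > 1:
        e1, e2 = t1.exons[0], t2.exons[0]
        j1, j2 = t1.intron_chain[0], t2.intron_chain[0]
        if j1[1] == j2[1] and j1[0] != j2[0]:
            if e1.end <= e2.start or e2.end <= e1.start:
                lo, hi = sorted([(e1.start, e1.end), (e2.start, e2.end)])
                typ = "AF" if strand == "+" else "AL"
                out.add((typ, (lo[0], lo[1], hi[0], hi[1], j1[1])))
        e1, e2 = t1.exons[-1], t2.exons[-1]
        j1, j2 = t1.intron_chain[-1], t2.intron_chain[-1]
        if j1[0] == j2[0] and j1[1] != j2[1]:
            if e1.end <= e2.start or e2.end <= e1.start:
                lo, hi = sorted([(e1.start, e1.end), (e2.start, e2.end)])
                typ = "AL" if strand == "+" else "AF"
                out.add((typ, (j1[0], lo[0], lo[1], hi[0], hi[1])))
    return out


# ---------------------------------------------------------------------------
# ORFs
# ---------------------------------------------------------------------------

def brute_force_orfs(seq, min_len=300):
    """(frame, start, end) of every maximal ATG-initiated, stop-terminated
    ORF: each ATG is tested; ORFs sharing a stop keep the earliest ATG."""
    seq = seq.upper()
    found = []
    for frame in range(3):
        stops_used = set()
        for start in range(frame, len(seq) - 2, 3):
            if seq[start : start + 3] != "ATG":
                continue
            for pos in range(start + 3, len(seq) - 2, 3):
                if seq[pos : pos + 3] in STOPS:
                    if pos not in stops_used and pos + 3 - start >= min_len:
                        found.append((frame, start, pos + 3))
                    stops_used.add(pos)
                    break
    return sorted(found)
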