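"""Synthetic multi-stage transcriptome with full ground truth.

The generator emulates, at desk scale, the inputs of a long-read
transcriptome-augmentation study of preimplantation development: a small
multi-chromosome genome carrying multi-isoform genes with realistic
GT..AG splice motifs; seven per-stage transcript sets containing planted
exact-match, contained, novel-isoform, novel-gene and "other"
(antisense/intronic) transcripts with configurable turnover between
consecutive stages; promoter H3K4me3 signal with bimodal bumps and
called peaks; CAGE support intervals; phyloP/phastCons tracks with a
planted conserved subset of non-coding transcripts; TPM/FPKM matrices
with planted ZGA transcripts, differential-splicing shifts and
splicing-factor/AS-count coupling; and a short-read junction-support
table.  Every planted label is recorded in :class:`TruthLabels` so each
downstream module can be scored against known truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .core import Annotation, GenomeInterval, TranscriptModel, make_transcript
from .io import ExpressionMatrix, JunctionSupportTable
from .splicing import enumerate_all_events
from .tracks import SignalTrack


class ConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study conditions for the synthetic dataset.

    Defaults mirror the emulated study design where it states one
    (seven stages sperm..blastocyst, two replicate batches per stage,
    ~97% canonical junctions) and otherwise hold desk-scale values
    chosen once for realism.
    """

    seed: int = 0
    n_chroms: int = 3
    chrom_length: int = 400_000
    n_genes: int = 90
    isoforms_per_gene: Tuple[int, int] = (1, 3)
    exons_per_gene: Tuple[int, int] = (4, 8)
    exon_length: Tuple[int, int] = (120, 320)
    intron_length: Tuple[int, int] = (300, 900)
    intergenic_gap: Tuple[int, int] = (2500, 6000)
    canonical_fraction: float = 0.97
    biotype_props: Tuple[float, float, float] = (0.7, 0.2, 0.1)  # pc, lnc, else
    stages: Tuple[str, ...] = ("sperm", "Oo", "1C", "2C", "4C", "8C", "BL")
    replicates: int = 2
    transcripts_per_stage: int = 100
    # exact, contained, novel_isoform, novel_gene, other
    category_props: Tuple[float, float, float, float, float] = (
        0.55,
        0.10,
        0.20,
        0.08,
        0.07,
    )
    share_fraction: float = 0.7
    n_novel_gene_loci: int = 24
    novel_tss_fraction: float = 0.5
    hc_tss_fraction: float = 0.6
    cage_fraction: float = 0.6
    conserved_fraction: float = 0.3
    coding_fraction_novel: float = 0.45
    n_zga: int = 12
    n_das_genes: int = 8
    das_delta_psi: float = 0.4
    psi_noise_sd: float = 0.03
    das_replicates: int = 5
    unsupported_junction_fraction: float = 0.1
    tpm_noise_sigma: float = 0.15
    splicing_factors: Tuple[Tuple[str, int], ...] = (
        ("Raly", -1),
        ("Phf5a", 1),
        ("Snrpd3", 1),
        ("Sf1", 1),
        ("Ddx20", -1),
        ("Srsf2", 1),
    )

    def __post_init__(self) -> None:
        if abs(sum(self.category_props) - 1.0) > 1e-9:
            raise ConfigError("category proportions must sum to 1")
        if abs(sum(self.biotype_props) - 1.0) > 1e-9:
            raise ConfigError("biotype proportions must sum to 1")
        if not (0.0 <= self.canonical_fraction <= 1.0):
            raise ConfigError("canonical_fraction must lie in [0, 1]")
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")


@dataclass
class DasTruth:
    gene_id: str
    inclusion_id: str
    exclusion_id: str
    event_key: Tuple[str, str, str, Tuple[int, ...]]  # type, chrom, strand, coords
    psi_by_stage: Dict[str, float]
    shift_transition: Tuple[str, str]
    delta_psi: float


@dataclass
class TruthLabels:
    """Planted ground truth for every emitted synthetic transcript."""

    templates: Dict[str, TranscriptModel] = field(default_factory=dict)
    category: Dict[str, str] = field(default_factory=dict)
    stage_members: Dict[str, List[str]] = field(default_factory=dict)
    tss_group: Dict[str, str] = field(default_factory=dict)
    coding_score: Dict[str, float] = field(default_factory=dict)
    high_confidence: Dict[str, bool] = field(default_factory=dict)
    cage: Dict[str, bool] = field(default_factory=dict)
    conserved: Dict[str, bool] = field(default_factory=dict)
    zga: Dict[str, bool] = field(default_factory=dict)
    das_truth: List[DasTruth] = field(default_factory=list)
    unsupported_junctions: Set[Tuple[str, int, int, str]] = field(default_factory=set)
    sf_signs: Dict[str, int] = field(default_factory=dict)
    gene_pool: Dict[str, str] = field(default_factory=dict)
    canonical_junctions: Dict[Tuple[str, int, int, str], bool] = field(
        default_factory=dict
    )
    novel_gene_catalog: List[str] = field(default_factory=list)

    def stage_models(self, stage: str) -> List[TranscriptModel]:
        return [self.templates[tid] for tid in self.stage_members[stage]]

    def novel_template_ids(self) -> List[str]:
        """All planted novel transcripts present in >= 1 stage."""
        used = {tid for members in self.stage_members.values() for tid in members}
        return sorted(
            tid
            for tid in used
            if self.category[tid] in ("novel_isoform", "novel_gene")
        )


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# Reference genome + annotation
# ---------------------------------------------------------------------------

def simulate_reference(
    config: SimConfig,
) -> Tuple[Dict[str, str], Annotation, TruthLabels]:
    """Generate the genome, the reference annotation and the hidden
    catalog of plantable novel-gene loci.  Deterministic under the seed."""
    rng = np.random.default_rng([config.seed, 0])
    labels = TruthLabels()

    pools = _assign_gene_pools(config)
    slots: List[Tuple[str, int]] = [("gene", i) for i in range(config.n_genes)]
    slots += [("novel", k) for k in range(config.n_novel_gene_loci)]
    rng.shuffle(slots)

    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    cursors = {c: int(rng.integers(2000, 4000)) for c in chrom_names}
    chrom_idx = 0

    gene_structures: Dict[str, dict] = {}
    novel_models: Dict[str, TranscriptModel] = {}
    genic_bp = 0

    for kind, idx in slots:
        if kind == "gene":
            gid = f"G{idx + 1:04d}"
            pool = pools[gid]
            n_ex = _exon_count_for_pool(pool, config, rng)
            span_len = _structure_span(n_ex, config, rng_peek=None)
        else:
            gid = f"NG{idx + 1:03d}"
            pool = "novel"
            n_ex = int(rng.integers(1, 4))
            span_len = None
        placed = False
        while chrom_idx < config.n_chroms:
            chrom = chrom_names[chrom_idx]
            gap = int(rng.integers(*config.intergenic_gap))
            start = cursors[chrom] + gap
            structure = _make_structure(rng, config, start, n_ex, kind, idx)
            end = structure["exons"][-1][1]
            if end + 2000 <= config.chrom_length:
                cursors[chrom] = end
                placed = True
                break
            chrom_idx += 1
        if not placed:
            raise ConfigError(
                "genome too small to place all gene and novel-gene loci; "
                "increase chrom_length or n_chroms"
            )
        strand = "+" if rng.random() < 0.5 else "-"
        structure["chrom"] = chrom
        structure["strand"] = strand
        genic_bp += structure["exons"][-1][1] - structure["exons"][0][0]
        if kind == "gene":
            gene_structures[gid] = structure
            labels.gene_pool[gid] = pool
        else:
            tid = f"{gid}.t1"
            model = make_transcript(
                tid, gid, chrom, strand, structure["exons"]
            )
            novel_models[tid] = model
            labels.novel_gene_catalog.append(tid)

    total_bp = config.n_chroms * config.chrom_length
    if (total_bp - genic_bp) / total_bp < 0.30:
        raise ConfigError("intergenic space below 30% of the genome")

    # isoform construction
    transcripts: List[TranscriptModel] = []
    biotype_cum = np.cumsum(config.biotype_props)
    biotype_names = ("protein_coding", "lncRNA", "else")
    for gid in sorted(gene_structures):
        st = gene_structures[gid]
        pool = labels.gene_pool[gid]
        u = rng.random()
        biotype = biotype_names[int(np.searchsorted(biotype_cum, u, side="right"))]
        isoforms = _make_isoforms(rng, config, gid, st, pool)
        for tid, exons in isoforms:
            transcripts.append(
                make_transcript(tid, gid, st["chrom"], st["strand"], exons, biotype)
            )
    annotation = Annotation.from_transcripts(transcripts)

    # splice-site motif assignment: one canonical draw per donor site
    junction_sites = _collect_junctions(
        list(annotation) + list(novel_models.values())
    )
    donor_canonical: Dict[Tuple[str, str, int], bool] = {}
    for chrom, d, a, strand in junction_sites:
        donor_pos = d if strand == "+" else a
        key = (chrom, strand, donor_pos)
        if key not in donor_canonical:
            donor_canonical[key] = bool(rng.random() < config.canonical_fraction)
        labels.canonical_junctions[(chrom, d, a, strand)] = donor_canonical[key]

    genome = _build_genome(
        rng, config, chrom_names, junction_sites, labels.canonical_junctions
    )

    # stash hidden novel-gene models as templates (emitted only when planted)
    for tid, model in novel_models.items():
        labels.templates[tid] = model
        labels.category[tid] = "novel_gene"
        labels.tss_group[tid] = "novel_gene"
    return genome, annotation, labels


def _assign_gene_pools(config: SimConfig) -> Dict[str, str]:
    n_sf = len(config.splicing_factors)
    n_das = config.n_das_genes
    counts = _category_counts(config)
    n_contained = counts["contained"] + 2
    n_novel_iso = counts["novel_isoform"] + 2
    n_exact_genes = config.n_genes - n_das - n_contained - n_novel_iso - n_sf
    if n_exact_genes < 10:
        raise ConfigError(
            "n_genes too small for the requested category mixture; "
            f"only {n_exact_genes} genes left for the exact-match pool"
        )
    pools: Dict[str, str] = {}
    order = (
        ["das"] * n_das
        + ["sf"] * n_sf
        + ["contained"] * n_contained
        + ["novel_iso"] * n_novel_iso
        + ["exact"] * n_exact_genes
    )
    for i, pool in enumerate(order):
        pools[f"G{i + 1:04d}"] = pool
    return pools


def _category_counts(config: SimConfig) -> Dict[str, int]:
    """Largest-remainder apportionment of per-stage category counts."""
    names = ("exact", "contained", "novel_isoform", "novel_gene", "other")
    n = config.transcripts_per_stage
    raw = [p * n for p in config.category_props]
    counts = [int(math.floor(x)) for x in raw]
    remainder = n - sum(counts)
    order = sorted(range(5), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:remainder]:
        counts[i] += 1
    return dict(zip(names, counts))


def _exon_count_for_pool(pool: str, config: SimConfig, rng) -> int:
    lo, hi = config.exons_per_gene
    if pool == "contained":
        lo = max(lo, 5)
    elif pool in ("novel_iso", "das"):
        lo = max(lo, 4)
    hi = max(hi, lo)
    return int(rng.integers(lo, hi + 1))


def _structure_span(n_ex: int, config: SimConfig, rng_peek) -> Optional[int]:
    return None  # spans are realized in _make_structure


def _make_structure(rng, config: SimConfig, start: int, n_ex: int, kind: str, idx: int) -> dict:
    if kind == "novel":
        # two deliberately short mono-exon loci feed the "else" biotype class
        if n_ex == 1:
            length = 160 if idx < 2 else int(rng.integers(250, 600))
            return {"exons": [(start, start + length)]}
        exon_lens = rng.integers(150, 400, size=n_ex)
    else:
        exon_lens = rng.integers(*config.exon_length, size=n_ex)
    intron_lens = rng.integers(*config.intron_length, size=max(0, n_ex - 1))
    exons = []
    pos = start
    for i in range(n_ex):
        exons.append((pos, pos + int(exon_lens[i])))
        pos += int(exon_lens[i])
        if i < n_ex - 1:
            pos += int(intron_lens[i])
    return {"exons": exons}


def _make_isoforms(
    rng, config: SimConfig, gid: str, structure: dict, pool: str
) -> List[Tuple[str, List[Tuple[int, int]]]]:
    """Reference isoforms for one gene.

    Pool constraints: contained/novel_iso/sf genes stay single-isoform
    (their planted derivatives must be unambiguous); das genes carry the
    full chain plus one internal-exon-skipping isoform; exact-pool genes
    carry 1-3 isoforms built by exon skipping, donor shifts or internal
    intron retention.
    """
    full = structure["exons"]
    n_ex = len(full)
    isoforms: List[List[Tuple[int, int]]] = [list(full)]
    if pool == "das":
        skip = int(rng.integers(1, n_ex - 1))
        isoforms.append([e for i, e in enumerate(full) if i != skip])
        structure["das_skip_exon"] = skip
    elif pool == "exact":
        lo, hi = config.isoforms_per_gene
        k = int(rng.integers(lo, hi + 1)) if n_ex >= 4 else 1
        used_ops: Set[Tuple[str, int]] = set()
        for _ in range(k - 1):
            variant = _make_variant(rng, config, full, used_ops)
            if variant is not None and variant not in isoforms:
                isoforms.append(variant)
    return [(f"{gid}.t{i + 1}", ex) for i, ex in enumerate(isoforms)]


def _make_variant(rng, config: SimConfig, full, used_ops):
    n_ex = len(full)
    for _ in range(10):
        op = rng.choice(["skip", "alt_donor", "retain"])
        if op == "skip" and n_ex >= 4:
            i = int(rng.integers(1, n_ex - 1))
            if ("skip", i) in used_ops:
                continue
            used_ops.add(("skip", i))
            return [e for j, e in enumerate(full) if j != i]
        if op == "alt_donor":
            j = int(rng.integers(0, n_ex - 1))
            if ("alt", j) in used_ops:
                continue
            intron_len = full[j + 1][0] - full[j][1]
            if intron_len < 260:
                continue
            delta = int(rng.integers(20, intron_len - 200))
            used_ops.add(("alt", j))
            variant = list(full)
            variant[j] = (full[j][0], full[j][1] + delta)
            return variant
        if op == "retain" and n_ex >= 4:
            j = int(rng.integers(1, n_ex - 2))  # internal intron only
            if ("retain", j) in used_ops:
                continue
            used_ops.add(("retain", j))
            variant = full[:j] + [(full[j][0], full[j + 1][1])] + full[j + 2 :]
            return variant
    return None


def _collect_junctions(models: Sequence[TranscriptModel]):
    sites = set()
    for t in models:
        for d, a in t.intron_chain:
            sites.add((t.chrom, d, a, t.strand))
    return sorted(sites)


_RC = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _build_genome(
    rng, config: SimConfig, chrom_names, junction_sites, canonical_by_junction
) -> Dict[str, str]:
    genome_arrays = {
        c: _BASES[rng.integers(0, 4, size=config.chrom_length)].copy()
        for c in chrom_names
    }
    for chrom, d, a, strand in junction_sites:
        canonical = canonical_by_junction[(chrom, d, a, strand)]
        donor = "GT" if canonical else "GC"
        acceptor = "AG"
        arr = genome_arrays[chrom]
        if strand == "+":
            arr[d : d + 2] = np.frombuffer(donor.encode(), dtype=np.uint8)
            arr[a - 2 : a] = np.frombuffer(acceptor.encode(), dtype=np.uint8)
        else:
            rc_donor = "".join(_RC[b] for b in reversed(donor))
            rc_acceptor = "".join(_RC[b] for b in reversed(acceptor))
            arr[a - 2 : a] = np.frombuffer(rc_donor.encode(), dtype=np.uint8)
            arr[d : d + 2] = np.frombuffer(rc_acceptor.encode(), dtype=np.uint8)
    return {c: arr.tobytes().decode("ascii") for c, arr in genome_arrays.items()}


# ---------------------------------------------------------------------------
# Stage transcriptomes
# ---------------------------------------------------------------------------

def simulate_stage_transcriptomes(
    reference: Annotation, labels: TruthLabels, config: SimConfig
) -> Dict[str, List[TranscriptModel]]:
    """Plant per-stage transcript sets with known five-way categories and
    configurable turnover between consecutive stages."""
    rng = np.random.default_rng([config.seed, 1])
    counts = _category_counts(config)
    by_pool: Dict[str, List[str]] = {}
    for gid, pool in labels.gene_pool.items():
        by_pool.setdefault(pool, []).append(gid)
    for pool in by_pool.values():
        pool.sort()

    # --- persistent templates -------------------------------------------
    persistent_exact: List[str] = []
    for gid in by_pool.get("das", []) + by_pool.get("sf", []):
        for t in reference.gene_transcripts(gid):
            persistent_exact.append(
                _add_template(labels, t, f"LR_{t.transcript_id}", "exact_match", "annotated")
            )
    exact_pool_transcripts = [
        t for gid in by_pool.get("exact", []) for t in reference.gene_transcripts(gid)
    ]
    zga_sources = list(
        rng.choice(
            [t.transcript_id for t in exact_pool_transcripts],
            size=min(config.n_zga, len(exact_pool_transcripts)),
            replace=False,
        )
    )
    for tid in zga_sources:
        t = reference.transcripts[tid]
        new_id = _add_template(labels, t, f"LR_{tid}", "exact_match", "annotated")
        labels.zga[new_id] = True
        persistent_exact.append(new_id)

    n_exact_turnover = counts["exact"] - len(persistent_exact)
    if n_exact_turnover < 0:
        raise ConfigError(
            "exact-category count too small for the persistent das/sf/zga templates"
        )
    turnover_exact_pool = [
        _add_template(labels, t, f"LR_{t.transcript_id}", "exact_match", "annotated", jitter=rng)
        for t in exact_pool_transcripts
        if t.transcript_id not in set(zga_sources)
    ]
    if len(turnover_exact_pool) < n_exact_turnover + 6:
        raise ConfigError("exact-pool too small for the requested turnover")

    contained_templates = [
        _make_contained(labels, reference, gid)
        for gid in by_pool.get("contained", [])
    ][: counts["contained"]]
    novel_iso_templates = _make_novel_isoforms(
        labels, reference, by_pool.get("novel_iso", []), config, rng
    )[: counts["novel_isoform"]]
    other_templates = _make_others(
        labels, reference, by_pool.get("exact", []), counts["other"], rng
    )
    novel_gene_pool = list(labels.novel_gene_catalog)
    if counts["novel_gene"] > len(novel_gene_pool):
        raise ConfigError("requested novel genes exceed the catalog of hidden loci")
    if len(contained_templates) < counts["contained"]:
        raise ConfigError("contained pool too small")
    if len(novel_iso_templates) < counts["novel_isoform"]:
        raise ConfigError("novel-isoform pool too small")

    persistent = (
        persistent_exact + contained_templates + novel_iso_templates + other_templates
    )

    # --- per-stage turnover ---------------------------------------------
    stage_sets: Dict[str, List[TranscriptModel]] = {}
    prev_exact: List[str] = []
    prev_novel: List[str] = []
    for si, stage in enumerate(config.stages):
        if si == 0:
            cur_exact = list(
                rng.choice(turnover_exact_pool, size=n_exact_turnover, replace=False)
            )
            cur_novel = list(
                rng.choice(novel_gene_pool, size=counts["novel_gene"], replace=False)
            )
        else:
            cur_exact = _turnover(
                rng, prev_exact, turnover_exact_pool, config.share_fraction
            )
            cur_novel = _turnover(
                rng, prev_novel, novel_gene_pool, config.share_fraction
            )
        member_ids = persistent + cur_exact + cur_novel
        labels.stage_members[stage] = sorted(member_ids)
        stage_sets[stage] = labels.stage_models(stage)
        prev_exact, prev_novel = cur_exact, cur_novel

    # planted coding scores for novel transcripts (consumed, not computed)
    for tid in labels.novel_template_ids():
        if rng.random() < config.coding_fraction_novel:
            labels.coding_score[tid] = float(rng.uniform(0.55, 0.95))
        else:
            labels.coding_score[tid] = float(rng.uniform(0.02, 0.40))

    # das event truth: the SE event between the full and skip isoforms
    for gid in by_pool.get("das", []):
        txs = reference.gene_transcripts(gid)
        full = max(txs, key=lambda t: t.n_exons)
        skip = min(txs, key=lambda t: t.n_exons)
        inc_id = f"LR_{full.transcript_id}"
        exc_id = f"LR_{skip.transcript_id}"
        chain_f = full.intron_chain
        chain_s = set(skip.intron_chain)
        coords = None
        for (d1, a1), (d2, a2) in zip(chain_f, chain_f[1:]):
            if (d1, a2) in chain_s:
                coords = (d1, a1, d2, a2)
                break
        assert coords is not None
        psi0 = float(rng.uniform(0.25, 0.45))
        ti = int(rng.integers(1, len(config.stages) - 1))
        transition = (config.stages[ti], config.stages[ti + 1])
        sign = 1 if rng.random() < 0.5 else -1
        psi_shifted = psi0 + sign * config.das_delta_psi
        if not (0.05 <= psi_shifted <= 0.95):
            sign = -sign
            psi_shifted = psi0 + sign * config.das_delta_psi
        psi_by_stage = {
            s: (psi0 if k <= ti else psi_shifted)
            for k, s in enumerate(config.stages)
        }
        labels.das_truth.append(
            DasTruth(
                gid,
                inc_id,
                exc_id,
                ("SE", full.chrom, full.strand, coords),
                psi_by_stage,
                transition,
                sign * config.das_delta_psi,
            )
        )
    return stage_sets


def _add_template(
    labels: TruthLabels,
    ref_transcript: TranscriptModel,
    new_id: str,
    category: str,
    tss_group: str,
    jitter=None,
) -> str:
    if new_id in labels.templates:
        return new_id
    exons = [(e.start, e.end) for e in ref_transcript.exons]
    if jitter is not None and len(exons) > 1:
        # small terminal-end wobble; intron chain (hence class code) unchanged
        d5 = int(jitter.integers(-30, 31))
        d3 = int(jitter.integers(-30, 31))
        s, e = exons[0]
        exons[0] = (max(0, min(s + d5, e - 50)), e)
        s, e = exons[-1]
        exons[-1] = (s, max(s + 50, e + d3))
    model = make_transcript(
        new_id, ref_transcript.gene_id, ref_transcript.chrom,
        ref_transcript.strand, exons,
    )
    labels.templates[new_id] = model
    labels.category[new_id] = category
    labels.tss_group[new_id] = tss_group
    return new_id


def _make_contained(labels: TruthLabels, reference: Annotation, gid: str) -> str:
    t = reference.gene_transcripts(gid)[0]
    inner = [(e.start, e.end) for e in t.exons[1:-1]]
    new_id = f"LR_{gid}.cont"
    model = make_transcript(new_id, gid, t.chrom, t.strand, inner)
    labels.templates[new_id] = model
    labels.category[new_id] = "contained"
    labels.tss_group[new_id] = "annotated"
    return new_id


def _make_novel_isoforms(
    labels: TruthLabels,
    reference: Annotation,
    gene_ids: Sequence[str],
    config: SimConfig,
    rng,
) -> List[str]:
    """One skip-variant per single-isoform gene; a configured fraction
    additionally get a >300 bp 5'-extended first exon (novel TSS)."""
    out = []
    for gi, gid in enumerate(gene_ids):
        t = reference.gene_transcripts(gid)[0]
        exons = [(e.start, e.end) for e in t.exons]
        skip = int(rng.integers(1, len(exons) - 1))
        variant = [e for i, e in enumerate(exons) if i != skip]
        novel_tss = rng.random() < config.novel_tss_fraction
        if novel_tss:
            delta = int(rng.integers(400, 801))
            if t.strand == "+":
                s, e = variant[0]
                variant[0] = (max(0, s - delta), e)
            else:
                s, e = variant[-1]
                variant[-1] = (s, e + delta)
        new_id = f"LR_{gid}.niso"
        model = make_transcript(new_id, gid, t.chrom, t.strand, variant)
        labels.templates[new_id] = model
        labels.category[new_id] = "novel_isoform"
        labels.tss_group[new_id] = "novel" if novel_tss else "classic"
        out.append(new_id)
    return out


def _make_others(
    labels: TruthLabels,
    reference: Annotation,
    exact_gene_ids: Sequence[str],
    n_other: int,
    rng,
) -> List[str]:
    """Mono-exon antisense (over an exon) and intronic (inside an
    internal intron) planted transcripts.

    Intronic placements use only introns intact in every isoform of the
    host gene, so the planted model cannot touch a sibling isoform's
    retained or extended exon.
    """
    out: List[str] = []
    hosts = list(exact_gene_ids)
    rng.shuffle(hosts)
    want_antisense = True
    for gid in hosts:
        if len(out) >= n_other:
            break
        txs = reference.gene_transcripts(gid)
        t = txs[0]
        k = len(out)
        new_id = f"LR_OTH{k + 1:03d}"
        if want_antisense:
            ex = t.exons[1]
            strand = "-" if t.strand == "+" else "+"
            model = make_transcript(
                new_id, f"OTH{k + 1:03d}", t.chrom, strand, [(ex.start, ex.end)]
            )
            want_antisense = False
        else:
            safe = _safe_intron(txs)
            if safe is None:
                continue
            d, a = safe
            model = make_transcript(
                new_id, f"OTH{k + 1:03d}", t.chrom, t.strand, [(d + 30, a - 30)]
            )
            want_antisense = True
        labels.templates[new_id] = model
        labels.category[new_id] = "other"
        labels.tss_group[new_id] = "other"
        out.append(new_id)
    if len(out) < n_other:
        raise ConfigError("not enough host genes for the 'other' category")
    return out


def _safe_intron(gene_isoforms: Sequence[TranscriptModel]):
    """An intron of the first isoform untouched by any sibling's exons,
    with room for a >= 60 bp mono-exon insert."""
    t = gene_isoforms[0]
    for d, a in t.intron_chain:
        if a - d < 150:
            continue
        clear = True
        for iso in gene_isoforms:
            for ex in iso.exons:
                if ex.start < a - 30 and d + 30 < ex.end:
                    clear = False
                    break
            if not clear:
                break
        if clear:
            return d, a
    return None


def _turnover(rng, prev: List[str], pool: List[str], share: float) -> List[str]:
    n = len(prev)
    n_keep = int(round(share * n))
    keep = list(rng.choice(prev, size=n_keep, replace=False)) if n_keep else []
    candidates = [x for x in pool if x not in set(prev)]
    n_new = n - n_keep
    new = list(rng.choice(candidates, size=n_new, replace=False)) if n_new else []
    return keep + new


# ---------------------------------------------------------------------------
# Tracks
# ---------------------------------------------------------------------------

@dataclass
class SimulatedTracks:
    h3k4me3: SignalTrack
    peaks_by_stage: Dict[str, List[GenomeInterval]]
    cage: List[SignalTrack]
    phylop: SignalTrack
    phastcons: SignalTrack


def simulate_tracks(
    reference: Annotation,
    labels: TruthLabels,
    config: SimConfig,
    genome_extent: Mapping[str, int],
) -> SimulatedTracks:
    """Build chromatin, CAGE and conservation tracks around the planted
    truth.  Assigns the high-confidence-TSS, CAGE and conserved flags."""
    rng = np.random.default_rng([config.seed, 2])

    # truth set for promoter validation: novel TSSs of novel isoforms
    # plus all novel-gene TSSs (planted loci)
    used = {tid for m in labels.stage_members.values() for tid in m}
    validation_set = sorted(
        tid
        for tid in used
        if labels.tss_group.get(tid) in ("novel", "novel_gene")
    )
    for tid in validation_set:
        labels.high_confidence[tid] = bool(rng.random() < config.hc_tss_fraction)
        labels.cage[tid] = bool(rng.random() < config.cage_fraction)

    # conserved flags over emitted novel non-coding transcripts
    noncoding = [
        tid
        for tid in labels.novel_template_ids()
        if labels.coding_score[tid] <= 0.44
    ]
    for tid in noncoding:
        labels.conserved[tid] = bool(rng.random() < config.conserved_fraction)

    bin_size = 50
    h3k = {
        c: np.zeros(genome_extent[c] // bin_size + 1) for c in genome_extent
    }

    def add_bump(chrom: str, tss: int, amp: float) -> None:
        arr = h3k[chrom]
        center = tss // bin_size
        for off in range(-24, 25):
            i = center + off
            if 0 <= i < arr.size:
                x = off * bin_size
                arr[i] += amp * (
                    math.exp(-((x + 400) ** 2) / (2 * 150.0 ** 2))
                    + math.exp(-((x - 400) ** 2) / (2 * 150.0 ** 2))
                )

    # annotated promoters get signal (no peaks)
    for gid in sorted(reference.genes):
        t = reference.gene_transcripts(gid)[0]
        add_bump(t.chrom, t.tss, float(rng.uniform(3, 10)))

    peak_stages = ("2C", "4C", "8C")
    peaks_by_stage: Dict[str, List[GenomeInterval]] = {s: [] for s in peak_stages}
    cage_runs: List[List[Tuple[str, int, int, float]]] = [[], []]
    for k, tid in enumerate(validation_set):
        t = labels.templates[tid]
        if labels.high_confidence[tid]:
            add_bump(t.chrom, t.tss, float(rng.uniform(8, 16)))
            stage = peak_stages[k % 3]
            peaks_by_stage[stage].append(
                GenomeInterval(t.chrom, max(0, t.tss - 300), t.tss + 300)
            )
        if labels.cage[tid]:
            sample = k % 2
            cage_runs[sample].append(
                (t.chrom, max(0, t.tss - 100), t.tss + 100, float(rng.uniform(1, 5)))
            )

    h3k_runs = []
    for chrom in sorted(h3k):
        arr = np.round(h3k[chrom], 4)
        for i in np.flatnonzero(arr > 1e-3):
            h3k_runs.append(
                (chrom, int(i) * bin_size, (int(i) + 1) * bin_size, float(arr[i]))
            )
    h3k_track = SignalTrack.from_runs(h3k_runs)
    cage_tracks = [SignalTrack.from_runs(runs) for runs in cage_runs]

    phylop, phastcons = _conservation_tracks(rng, labels, genome_extent, noncoding)
    return SimulatedTracks(h3k_track, peaks_by_stage, cage_tracks, phylop, phastcons)


def _conservation_tracks(rng, labels: TruthLabels, genome_extent, noncoding):
    tile = 100
    pvals = {}
    cvals = {}
    for chrom, length in genome_extent.items():
        n_tiles = length // tile + 1
        pvals[chrom] = np.repeat(rng.normal(0.0, 0.6, size=n_tiles), tile)[:length]
        cvals[chrom] = np.repeat(rng.uniform(0.0, 0.5, size=n_tiles), tile)[:length]
    for tid in noncoding:
        t = labels.templates[tid]
        conserved = labels.conserved.get(tid, False)
        for ex in t.exons:
            n = len(ex)
            n_chunks = n // tile + 1
            if conserved:
                pv = np.repeat(rng.normal(2.5, 0.4, size=n_chunks), tile)[:n]
                cv = np.repeat(rng.uniform(0.85, 0.98, size=n_chunks), tile)[:n]
            else:
                # transcribed but non-conserved: at or below background
                pv = np.repeat(rng.normal(-0.3, 0.5, size=n_chunks), tile)[:n]
                cv = np.repeat(rng.uniform(0.0, 0.35, size=n_chunks), tile)[:n]
            pvals[t.chrom][ex.start : ex.end] = pv
            cvals[t.chrom][ex.start : ex.end] = cv
    return (
        _array_to_track(pvals),
        _array_to_track(cvals),
    )


def _array_to_track(arrays: Dict[str, np.ndarray]) -> SignalTrack:
    runs = []
    for chrom in sorted(arrays):
        arr = np.round(arrays[chrom], 4)
        change = np.flatnonzero(np.diff(arr)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [arr.size]])
        for s, e in zip(starts, ends):
            v = float(arr[s])
            if v != 0.0:
                runs.append((chrom, int(s), int(e), v))
    return SignalTrack.from_runs(runs)


# ---------------------------------------------------------------------------
# Quantification
# ---------------------------------------------------------------------------

@dataclass
class SimulatedQuant:
    tpm: ExpressionMatrix
    gene_fpkm: ExpressionMatrix
    junctions: JunctionSupportTable
    as_counts_by_stage: Dict[str, int]


def simulate_quantification(
    reference: Annotation,
    labels: TruthLabels,
    config: SimConfig,
    stage_sets: Dict[str, List[TranscriptModel]],
) -> SimulatedQuant:
    """TPM/FPKM matrices, junction-support table, ZGA and coupling truth."""
    rng = np.random.default_rng([config.seed, 3])
    stages = list(config.stages)
    samples = [f"{s}_{r + 1}" for s in stages for r in range(config.replicates)]
    template_ids = sorted(labels.templates)
    used = {tid for m in labels.stage_members.values() for tid in m}
    template_ids = [tid for tid in template_ids if tid in used]

    das_rows = {
        tid
        for d in labels.das_truth
        for tid in (d.inclusion_id, d.exclusion_id)
    }
    zga_rows = {tid for tid, f in labels.zga.items() if f}
    for tid in template_ids:
        labels.zga.setdefault(tid, False)

    values = np.zeros((len(template_ids), len(samples)))
    row_of = {tid: i for i, tid in enumerate(template_ids)}
    sigma = config.tpm_noise_sigma

    for tid in template_ids:
        if tid in das_rows or tid in zga_rows:
            continue
        base = float(rng.lognormal(math.log(8), 0.8))
        for si, stage in enumerate(stages):
            present = tid in labels.stage_members[stage]
            stage_mean = base * float(rng.lognormal(0, 0.4)) if present else float(
                rng.uniform(0.0, 0.4)
            )
            for r in range(config.replicates):
                col = si * config.replicates + r
                values[row_of[tid], col] = stage_mean * float(rng.lognormal(0, sigma))
        # keep non-planted rows out of the ZGA set: a row passing the
        # oocyte-silence clause by chance is nudged into oocyte expression
        row = values[row_of[tid]]
        oo = _stage_mean(row, stages, config.replicates, "Oo")
        c1 = _stage_mean(row, stages, config.replicates, "1C")
        c2 = _stage_mean(row, stages, config.replicates, "2C")
        if oo <= 1.0 and c1 > 1.0 and c2 > 1.0 and c2 > 2 * c1:
            _set_stage(values, row_of[tid], stages, config.replicates, "Oo", 2.0, rng, sigma)

    for tid in zga_rows:
        i = row_of[tid]
        oo = float(rng.uniform(0.05, 0.6))
        c1 = float(rng.uniform(3.0, 6.0))
        c2 = c1 * float(rng.uniform(2.6, 4.0))
        late = c2 * float(rng.uniform(0.5, 1.5))
        for si, stage in enumerate(stages):
            mean = {"Oo": oo, "1C": c1, "2C": c2}.get(stage, late if stage in ("4C", "8C", "BL") else 0.2)
            for r in range(config.replicates):
                values[i, si * config.replicates + r] = mean * float(
                    rng.lognormal(0, 0.05)
                )
        # enforce the planted rule against residual noise
        _enforce_zga(values, i, stages, config.replicates)

    for das in labels.das_truth:
        for si, stage in enumerate(stages):
            total = float(rng.uniform(20, 40))
            psi_target = das.psi_by_stage[stage]
            for r in range(config.replicates):
                psi = float(
                    np.clip(rng.normal(psi_target, config.psi_noise_sd), 0.01, 0.99)
                )
                col = si * config.replicates + r
                values[row_of[das.inclusion_id], col] = psi * total
                values[row_of[das.exclusion_id], col] = (1 - psi) * total

    tpm = ExpressionMatrix(
        pd.DataFrame(values, index=template_ids, columns=samples), "TPM"
    )

    # per-stage AS-event totals drive the splicing-factor coupling
    as_counts = {
        stage: len(enumerate_all_events(models)[0])
        for stage, models in stage_sets.items()
    }
    corr_stages = [s for s in stages if s != "sperm"]
    count_vec = np.array([as_counts[s] for s in corr_stages], dtype=float)
    z = (count_vec - count_vec.mean()) / (count_vec.std() or 1.0)

    gene_ids = sorted(
        set(reference.genes)
        | {labels.templates[tid].gene_id for tid in template_ids}
    )
    gene_values = np.zeros((len(gene_ids), len(samples)))
    gene_row = {g: i for i, g in enumerate(gene_ids)}
    for tid in template_ids:
        g = labels.templates[tid].gene_id
        if g in gene_row:
            gene_values[gene_row[g]] += values[row_of[tid]]

    sf_gene_ids = [
        gid for gid, pool in sorted(labels.gene_pool.items()) if pool == "sf"
    ]
    for (name, sign), gid in zip(config.splicing_factors, sf_gene_ids):
        labels.sf_signs[name] = sign
        i = gene_row[gid]
        for si, stage in enumerate(stages):
            if stage in corr_stages:
                mean = max(0.1, 20.0 + sign * 6.0 * z[corr_stages.index(stage)])
            else:
                mean = 5.0
            for r in range(config.replicates):
                gene_values[i, si * config.replicates + r] = mean * float(
                    rng.lognormal(0, 0.02)
                )
    # expose factor names as row aliases: rows renamed gene->factor
    rename = dict(zip(sf_gene_ids, [n for n, _ in config.splicing_factors]))
    gene_index = [rename.get(g, g) for g in gene_ids]
    gene_fpkm = ExpressionMatrix(
        pd.DataFrame(gene_values, index=gene_index, columns=samples), "FPKM"
    )

    junction_table = _make_junction_table(rng, labels, config, samples, used)
    return SimulatedQuant(tpm, gene_fpkm, junction_table, as_counts)


def _stage_mean(row, stages, reps, stage) -> float:
    si = stages.index(stage)
    return float(row[si * reps : (si + 1) * reps].mean())


def _set_stage(values, i, stages, reps, stage, mean, rng, sigma) -> None:
    si = stages.index(stage)
    for r in range(reps):
        values[i, si * reps + r] = mean * float(rng.lognormal(0, sigma))


def _enforce_zga(values, i, stages, reps) -> None:
    def mean_of(stage):
        si = stages.index(stage)
        return values[i, si * reps : (si + 1) * reps].mean()

    si_oo = stages.index("Oo")
    if mean_of("Oo") > 1.0:
        values[i, si_oo * reps : (si_oo + 1) * reps] *= 0.8 / mean_of("Oo")
    si_c1 = stages.index("1C")
    if mean_of("1C") <= 1.0:
        values[i, si_c1 * reps : (si_c1 + 1) * reps] *= 3.0 / max(mean_of("1C"), 1e-6)
    si_c2 = stages.index("2C")
    if mean_of("2C") <= 2 * mean_of("1C") or mean_of("2C") <= 1.0:
        values[i, si_c2 * reps : (si_c2 + 1) * reps] *= (
            2.5 * mean_of("1C") / max(mean_of("2C"), 1e-6)
        )


def _make_junction_table(rng, labels: TruthLabels, config, samples, used):
    junctions = set()
    das_keys = set()
    for tid in used:
        t = labels.templates[tid]
        for d, a in t.intron_chain:
            junctions.add((t.chrom, d, a, t.strand))
    for das in labels.das_truth:
        for tid in (das.inclusion_id, das.exclusion_id):
            t = labels.templates[tid]
            for d, a in t.intron_chain:
                das_keys.add((t.chrom, d, a, t.strand))
    counts = {}
    for key in sorted(junctions):
        unsupported = key not in das_keys and (
            rng.random() < config.unsupported_junction_fraction
        )
        if unsupported:
            labels.unsupported_junctions.add(key)
            counts[key] = {s: int(rng.integers(0, 10)) for s in samples}
        else:
            per = {s: int(rng.poisson(40)) for s in samples}
            if max(per.values()) < 10:
                per[samples[0]] = 15
            counts[key] = per
    return JunctionSupportTable(counts)


# ---------------------------------------------------------------------------
# DAS replicate PSIs (higher replication than the expression matrix)
# ---------------------------------------------------------------------------

def simulate_das_psi(
    labels: TruthLabels, config: SimConfig
) -> Dict[str, Dict[str, np.ndarray]]:
    """Replicate PSI draws per planted event per stage.

    Differential-splicing testing needs more replication than the
    two-batch expression matrix provides; this emits
    ``das_replicates`` noisy PSI replicates around each planted
    trajectory, keyed by inclusion-isoform id then stage.
    """
    rng = np.random.default_rng([config.seed, 4])
    out: Dict[str, Dict[str, np.ndarray]] = {}
    for das in labels.das_truth:
        per_stage = {}
        for stage in config.stages:
            psi = das.psi_by_stage[stage]
            per_stage[stage] = np.clip(
                rng.normal(psi, config.psi_noise_sd, size=config.das_replicates),
                0.01,
                0.99,
            )
        out[das.inclusion_id] = per_stage
    return out


# ---------------------------------------------------------------------------
# One-call bundle + file emission
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    config: SimConfig
    genome: Dict[str, str]
    reference: Annotation
    labels: TruthLabels
    stage_sets: Dict[str, List[TranscriptModel]]
    tracks: SimulatedTracks
    quant: SimulatedQuant

    @property
    def genome_extent(self) -> Dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}


def simulate_all(config: Optional[SimConfig] = None) -> SimulatedDataset:
    config = config or SimConfig()
    genome, reference, labels = simulate_reference(config)
    stage_sets = simulate_stage_transcriptomes(reference, labels, config)
    extent = {c: len(s) for c, s in genome.items()}
    tracks = simulate_tracks(reference, labels, config, extent)
    quant = simulate_quantification(reference, labels, config, stage_sets)
    return SimulatedDataset(config, genome, reference, labels, stage_sets, tracks, quant)


def write_dataset(data: SimulatedDataset, outdir: Path) -> None:
    """Emit the dataset as the standard text formats."""
    from . import io as io_mod

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io_mod.write_fasta(data.genome, outdir / "genome.fa")
    io_mod.write_gtf(data.reference, outdir / "reference.gtf")
    for stage, models in data.stage_sets.items():
        io_mod.write_gtf(
            Annotation.from_transcripts(models), outdir / f"stage_{stage}.gtf"
        )
    io_mod.write_signal_bedgraph(data.tracks.h3k4me3, outdir / "h3k4me3.bedgraph")
    for stage, peaks in data.tracks.peaks_by_stage.items():
        io_mod.write_bed(peaks, outdir / f"peaks_{stage}.bed")
    for i, cage in enumerate(data.tracks.cage):
        io_mod.write_signal_bedgraph(cage, outdir / f"cage_{i + 1}.bedgraph")
    io_mod.write_signal_bedgraph(data.tracks.phylop, outdir / "phylop.bedgraph")
    io_mod.write_signal_bedgraph(data.tracks.phastcons, outdir / "phastcons.bedgraph")
    data.quant.tpm.to_tsv(outdir / "tpm.tsv")
    data.quant.gene_fpkm.to_tsv(outdir / "fpkm.tsv")
    data.quant.junctions.to_tsv(outdir / "junctions.tsv")
    _write_truth(data.labels, outdir / "truth.tsv")
    scores = pd.DataFrame(
        sorted(data.labels.coding_score.items()),
        columns=["transcript_id", "coding_score"],
    )
    scores.to_csv(outdir / "scores.tsv", sep="\t", index=False)


def _write_truth(labels: TruthLabels, path: Path) -> None:
    rows = []
    for tid in sorted(labels.templates):
        rows.append(
            {
                "transcript_id": tid,
                "category": labels.category.get(tid, ""),
                "tss_group": labels.tss_group.get(tid, ""),
                "high_confidence": labels.high_confidence.get(tid, ""),
                "cage": labels.cage.get(tid, ""),
                "conserved": labels.conserved.get(tid, ""),
                "zga": labels.zga.get(tid, ""),
                "coding_score": labels.coding_score.get(tid, ""),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
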