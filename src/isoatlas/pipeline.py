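"""End-to-end orchestration: classify -> merge -> biotype -> conservation
-> TSS validation -> splicing -> dynamics -> ZGA, from one config.

The pipeline consumes the standard text formats (GTF, FASTA, bedGraph,
BED, TSV), writes the augmented annotation (reference plus novel
isoforms and novel genes) and a structured JSON report whose counts
cross-foot with the per-record tables it also emits.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import io as io_mod
from .biotype import classify_biotype, tier_summary
from .compare import (
    ANNOTATED_CODES,
    ComparisonRecord,
    MergedTranscriptome,
    ReferenceIndex,
    category_summary,
    classify_set,
    merge_transcriptomes,
    stage_dynamics,
)
from .conservation import (
    ConservationCutoffs,
    calibrate_cutoffs,
    conservation_stats,
    rank_sum_test,
    sample_control_regions,
    transcript_conservation,
)
from .core import Annotation, TranscriptModel
from .expression import call_zga, sf_as_correlation, stage_zscore
from .splicing import (
    canonical_fraction,
    compute_psi,
    diff_splice,
    enumerate_all_events,
    event_dynamics,
    extract_junctions,
    psi_matrix,
    validate_junctions,
)
from .tss import (
    AnnotatedTssIndex,
    cage_support_intervals,
    cage_supported,
    categorize_tss,
    high_confidence_tss,
    merge_peaks,
    promoter_profile,
)


@dataclass
class PipelineConfig:
    """Flat, self-documenting run configuration; every threshold the
    analysis uses appears explicitly with its default."""

    reference_gtf: str = "reference.gtf"
    genome_fasta: str = "genome.fa"
    stage_gtfs: Dict[str, str] = field(default_factory=dict)  # stage -> path
    stage_order: Tuple[str, ...] = ("sperm", "Oo", "1C", "2C", "4C", "8C", "BL")
    tpm_tsv: str = "tpm.tsv"
    fpkm_tsv: str = "fpkm.tsv"
    junctions_tsv: str = "junctions.tsv"
    scores_tsv: str = "scores.tsv"
    h3k4me3_bedgraph: str = "h3k4me3.bedgraph"
    peak_beds: Tuple[str, ...] = ()
    cage_bedgraphs: Tuple[str, ...] = ()
    phylop_bedgraph: str = "phylop.bedgraph"
    phastcons_bedgraph: str = "phastcons.bedgraph"
    outdir: str = "isoatlas_out"
    seed: int = 0
    coding_cutoff: float = 0.44
    lncrna_min_length: int = 200
    min_orf_length: int = 300
    tss_interval_halfwidth: int = 300
    peak_window_halfwidth: int = 500
    min_junction_reads: int = 10
    calibrate_conservation: bool = True
    conservation_percentile: float = 95.0
    das_alpha: float = 0.05
    das_permutations: int = 1000
    zga_threshold: float = 1.0
    splicing_factors: Tuple[str, ...] = (
        "Raly",
        "Phf5a",
        "Snrpd3",
        "Sf1",
        "Ddx20",
        "Srsf2",
    )

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in raw:
                value = raw[f.name]
                if isinstance(value, list):
                    value = tuple(value)
                kwargs[f.name] = value
        return cls(**kwargs)

    def resolve(self, base: Path) -> "PipelineConfig":
        def r(p: str) -> str:
            return str((base / p) if not Path(p).is_absolute() else Path(p))

        return dataclasses.replace(
            self,
            reference_gtf=r(self.reference_gtf),
            genome_fasta=r(self.genome_fasta),
            stage_gtfs={s: r(p) for s, p in self.stage_gtfs.items()},
            tpm_tsv=r(self.tpm_tsv),
            fpkm_tsv=r(self.fpkm_tsv),
            junctions_tsv=r(self.junctions_tsv),
            scores_tsv=r(self.scores_tsv),
            h3k4me3_bedgraph=r(self.h3k4me3_bedgraph),
            peak_beds=tuple(r(p) for p in self.peak_beds),
            cage_bedgraphs=tuple(r(p) for p in self.cage_bedgraphs),
            phylop_bedgraph=r(self.phylop_bedgraph),
            phastcons_bedgraph=r(self.phastcons_bedgraph),
        )

    @classmethod
    def for_simulated_dir(cls, directory: Path, **overrides) -> "PipelineConfig":
        """Configuration matching the file layout of the simulate command."""
        directory = Path(directory)
        stages = overrides.pop(
            "stage_order", ("sperm", "Oo", "1C", "2C", "4C", "8C", "BL")
        )
        cfg = cls(
            stage_gtfs={s: f"stage_{s}.gtf" for s in stages},
            stage_order=tuple(stages),
            peak_beds=("peaks_2C.bed", "peaks_4C.bed", "peaks_8C.bed"),
            cage_bedgraphs=("cage_1.bedgraph", "cage_2.bedgraph"),
            **overrides,
        )
        return cfg.resolve(directory)


@dataclass
class AnalysisReport:
    """Aggregated result tables; every count cross-foots with the
    per-record tables written next to it."""

    per_stage_categories: Dict[str, Dict[str, Dict[str, float]]]
    merged_categories: Dict[str, Dict[str, float]]
    merged_count: int
    biotype_counts: Dict[str, Dict[str, int]]  # annotated/novel -> class -> n
    expression_tiers: Dict[str, Dict[str, int]]
    conservation: Dict[str, object]
    tss_summary: Dict[str, object]
    splicing_summary: Dict[str, object]
    transcript_dynamics: List[Dict[str, object]]
    event_dynamics: List[Dict[str, object]]
    das_river: List[Dict[str, object]]
    zga: Dict[str, object]
    sf_correlations: Dict[str, Optional[float]]
    thresholds: Dict[str, object]

    def to_json(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=_jsonify)


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialize {type(obj)}")


def run_pipeline(config: PipelineConfig) -> AnalysisReport:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "pipeline.log"
    log_lines: List[str] = [f"seed={config.seed}"]

    def log(stage: str, **kv) -> None:
        log_lines.append(stage + " " + " ".join(f"{k}={v}" for k, v in kv.items()))

    # ---- inputs --------------------------------------------------------
    reference = io_mod.read_gtf(config.reference_gtf)
    genome = _load_genome(config.genome_fasta)
    stage_models = {
        s: list(io_mod.read_gtf(config.stage_gtfs[s]))
        for s in config.stage_order
    }
    tpm = io_mod.ExpressionMatrix.from_tsv(config.tpm_tsv, "TPM")
    fpkm = io_mod.ExpressionMatrix.from_tsv(config.fpkm_tsv, "FPKM")
    junction_support = io_mod.JunctionSupportTable.from_tsv(config.junctions_tsv)
    coding_scores = io_mod.read_scores_tsv(config.scores_tsv, "coding_score")
    log("inputs", reference=len(reference), stages=len(stage_models))

    # ---- classification ------------------------------------------------
    ref_index = ReferenceIndex(reference)
    per_stage_records = {
        s: classify_set(models, reference, ref_index)
        for s, models in stage_models.items()
    }
    per_stage_categories = {
        s: category_summary(recs.values()) for s, recs in per_stage_records.items()
    }

    merged = merge_transcriptomes(
        [(s, stage_models[s]) for s in config.stage_order]
    )
    merged_records = classify_set(merged.transcripts, reference, ref_index)
    merged_categories = category_summary(merged_records.values())
    _write_comparison_tsv(merged_records, outdir / "comparison.tsv")
    log("classify", merged=len(merged))

    # map each merged transcript to an expression row (sum of its
    # distinct source transcripts present in the matrix)
    merged_tpm = _merged_expression(merged, tpm)

    # ---- biotype and expression tiers ---------------------------------
    biotype_counts = {"annotated": {}, "novel": {}}
    biotype_rows = []
    novel_noncoding: List[TranscriptModel] = []
    for t in merged.transcripts:
        rec = merged_records[t.transcript_id]
        if rec.code in ANNOTATED_CODES:
            ref_bio = reference.transcripts[rec.best_ref].biotype
            call = classify_biotype(
                dataclasses.replace(t, biotype=ref_bio), rec.category
            )
            group = "annotated"
        elif rec.set_label == "novel":
            score = _novel_score(t, merged, coding_scores)
            call = classify_biotype(
                t,
                rec.category,
                coding_score=score,
                cutoff=config.coding_cutoff,
                lnc_min_length=config.lncrna_min_length,
            )
            group = "novel"
            if call.biotype_class in ("lncRNA", "else"):
                novel_noncoding.append(t)
        else:
            continue
        biotype_counts[group][call.biotype_class] = (
            biotype_counts[group].get(call.biotype_class, 0) + 1
        )
        biotype_rows.append(
            {
                "transcript_id": t.transcript_id,
                "set": group,
                "class": call.biotype_class,
                "basis": call.basis,
            }
        )
    pd.DataFrame(biotype_rows).to_csv(outdir / "biotype.tsv", sep="\t", index=False)

    tiers = {"annotated": [], "novel": []}
    merged_stage_means = merged_tpm.stage_means()
    for t in merged.transcripts:
        rec = merged_records[t.transcript_id]
        group = (
            "annotated"
            if rec.code in ANNOTATED_CODES
            else "novel" if rec.set_label == "novel" else None
        )
        if group is None:
            continue
        if t.transcript_id in merged_stage_means.index:
            tiers[group].append(float(merged_stage_means.loc[t.transcript_id].max()))
    expression_tiers = {g: tier_summary(v) for g, v in tiers.items()}
    log("biotype", annotated=sum(biotype_counts["annotated"].values()),
        novel=sum(biotype_counts["novel"].values()))

    # ---- conservation --------------------------------------------------
    phylop = io_mod.read_signal_bedgraph(config.phylop_bedgraph)
    phastcons = io_mod.read_signal_bedgraph(config.phastcons_bedgraph)
    conservation_report = _conservation_stage(
        config, reference, merged, merged_records, novel_noncoding,
        phylop, phastcons, genome, outdir,
    )
    log("conservation", n_noncoding=len(novel_noncoding))

    # ---- TSS validation ------------------------------------------------
    tss_report = _tss_stage(
        config, reference, merged, merged_records, outdir
    )
    log("tss", **{k: v for k, v in tss_report.items() if isinstance(v, int)})

    # ---- splicing ------------------------------------------------------
    splicing_report, merged_events, per_stage_events = _splicing_stage(
        config, merged, stage_models, genome, junction_support, outdir
    )
    log("splicing", merged_events=len(merged_events))

    # ---- dynamics ------------------------------------------------------
    transcript_dyn = []
    for prev, curr in zip(config.stage_order, config.stage_order[1:]):
        d = stage_dynamics(stage_models[prev], stage_models[curr], prev, curr)
        transcript_dyn.append(
            {
                "transition": f"{prev}->{curr}",
                "gained": len(d.gained),
                "lost": len(d.lost),
                "gain_percent": round(d.gain_percent, 2),
                "loss_percent": round(d.loss_percent, 2),
            }
        )
    event_dyn = []
    for prev, curr in zip(config.stage_order, config.stage_order[1:]):
        ed = event_dynamics(per_stage_events[prev], per_stage_events[curr])
        event_dyn.append(
            {
                "transition": f"{prev}->{curr}",
                "gained": ed.gained,
                "lost": ed.lost,
                "gain_percent": {k: round(v, 2) for k, v in ed.gain_percent.items()},
                "loss_percent": {k: round(v, 2) for k, v in ed.loss_percent.items()},
            }
        )

    # ---- differential splicing (river table) ---------------------------
    das_river = _das_stage(config, merged_events, merged_tpm, outdir)

    # ---- ZGA and splicing factors --------------------------------------
    zga_calls = call_zga(tpm, threshold=config.zga_threshold)
    zga_transcripts = sorted(c.feature_id for c in zga_calls if c.is_zga)
    zga_gene_calls = call_zga(fpkm, threshold=config.zga_threshold)
    zga_genes = sorted(c.feature_id for c in zga_gene_calls if c.is_zga)
    pd.DataFrame(
        [dataclasses.asdict(c) for c in zga_calls if c.is_zga]
    ).to_csv(outdir / "zga.tsv", sep="\t", index=False)

    stage_fpkm = _stage_matrix(fpkm)
    corr_stages = [s for s in config.stage_order if s != "sperm"]
    sf_rows = [f for f in config.splicing_factors if f in stage_fpkm.index]
    as_counts = {s: len(per_stage_events[s]) for s in corr_stages}
    sf_corr = (
        sf_as_correlation(stage_fpkm.loc[sf_rows, corr_stages], as_counts)
        if sf_rows
        else {}
    )

    # row-wise z-scores of novel-transcript expression (stage-specificity)
    novel_ids = [
        t.transcript_id
        for t in merged.transcripts
        if merged_records[t.transcript_id].set_label == "novel"
        and t.transcript_id in merged_stage_means.index
    ]
    if novel_ids:
        z = stage_zscore(merged_stage_means.loc[novel_ids])
        z.to_csv(outdir / "novel_zscores.tsv", sep="\t")

    # ---- augmented annotation ------------------------------------------
    augmented = Annotation.from_transcripts(
        list(reference)
        + [
            t
            for t in merged.transcripts
            if merged_records[t.transcript_id].set_label == "novel"
        ]
    )
    io_mod.write_gtf(augmented, outdir / "augmented.gtf")
    log("augment", reference=len(reference), augmented=len(augmented))

    report = AnalysisReport(
        per_stage_categories=per_stage_categories,
        merged_categories=merged_categories,
        merged_count=len(merged),
        biotype_counts=biotype_counts,
        expression_tiers=expression_tiers,
        conservation=conservation_report,
        tss_summary=tss_report,
        splicing_summary=splicing_report,
        transcript_dynamics=transcript_dyn,
        event_dynamics=event_dyn,
        das_river=das_river,
        zga={
            "transcripts": zga_transcripts,
            "n_transcripts": len(zga_transcripts),
            "genes": zga_genes,
            "n_genes": len(zga_genes),
        },
        sf_correlations=sf_corr,
        thresholds={
            "coding_cutoff": config.coding_cutoff,
            "lncrna_min_length": config.lncrna_min_length,
            "min_orf_length": config.min_orf_length,
            "tss_interval_halfwidth": config.tss_interval_halfwidth,
            "peak_window_halfwidth": config.peak_window_halfwidth,
            "min_junction_reads": config.min_junction_reads,
            "das_alpha": config.das_alpha,
            "zga_threshold": config.zga_threshold,
            "seed": config.seed,
        },
    )
    report.to_json(outdir / "report.json")
    log_path.write_text("\n".join(log_lines) + "\n")
    return report


# ---------------------------------------------------------------------------
# stage helpers
# ---------------------------------------------------------------------------

def _load_genome(path: str) -> Mapping[str, str]:
    return io_mod.open_genome(path)


def _write_comparison_tsv(records: Dict[str, ComparisonRecord], path: Path) -> None:
    rows = [
        {
            "query_id": r.query_id,
            "code": r.code,
            "category": r.category,
            "best_ref": r.best_ref or "",
            "n_shared_junctions": r.n_shared_junctions,
        }
        for r in records.values()
    ]
    pd.DataFrame(rows).sort_values("query_id").to_csv(path, sep="\t", index=False)


def _merged_expression(
    merged: MergedTranscriptome, tpm: io_mod.ExpressionMatrix
) -> io_mod.ExpressionMatrix:
    """Expression matrix reindexed on merged transcript ids.

    Each merged transcript's value is the sum over its distinct source
    transcripts present in the input matrix; merged transcripts with no
    quantified source are absent.
    """
    rows = {}
    for t in merged.transcripts:
        sources = [
            s
            for s in dict.fromkeys(merged.sources[t.transcript_id])
            if s in tpm.values.index
        ]
        if sources:
            rows[t.transcript_id] = tpm.values.loc[sources].sum(axis=0)
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.columns = tpm.values.columns
    return io_mod.ExpressionMatrix(df, tpm.unit)


def _stage_matrix(mat: io_mod.ExpressionMatrix) -> pd.DataFrame:
    return mat.stage_means()


def _novel_score(
    t: TranscriptModel, merged: MergedTranscriptome, scores: Dict[str, float]
) -> float:
    for src in dict.fromkeys(merged.sources[t.transcript_id]):
        if src in scores:
            return scores[src]
    raise KeyError(
        f"no coding score for novel transcript {t.transcript_id} "
        f"(sources {sorted(set(merged.sources[t.transcript_id]))})"
    )


def _conservation_stage(
    config, reference, merged, merged_records, novel_noncoding,
    phylop, phastcons, genome, outdir,
):
    if not novel_noncoding:
        return {"n_noncoding": 0}
    augmented = Annotation.from_transcripts(
        list(reference)
        + [
            t
            for t in merged.transcripts
            if merged_records[t.transcript_id].set_label == "novel"
        ]
    )
    extent = {c: len(genome[c]) for c in genome}
    controls = sample_control_regions(
        augmented, novel_noncoding, extent, seed=config.seed, min_regions=20
    )
    if config.calibrate_conservation:
        cutoffs = calibrate_cutoffs(
            controls, phylop, phastcons, percentile=config.conservation_percentile
        )
    else:
        cutoffs = ConservationCutoffs.study_defaults()
    results = [
        transcript_conservation(phylop, phastcons, t, cutoffs)
        for t in novel_noncoding
    ]
    control_results = []
    for iv in controls.regions:
        f, w = conservation_stats(
            phylop, phastcons, iv.chrom, [(iv.start, iv.end)],
            base_cutoff=cutoffs.base_cutoff,
        )
        control_results.append((f, w))
    rows = [
        {
            "transcript_id": r.transcript_id,
            "fraction_conserved": round(r.fraction_conserved, 4),
            "max_window_phastcons": round(r.max_window_mean, 4),
            "phylop_significant": r.phylop_significant,
            "phastcons_significant": r.phastcons_significant,
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(outdir / "conservation.tsv", sep="\t", index=False)
    transcript_fracs = [r.fraction_conserved for r in results]
    control_fracs = [f for f, _ in control_results]
    p = rank_sum_test(transcript_fracs, control_fracs) if len(control_fracs) > 1 else None
    n_sig = sum(1 for r in results if r.either)
    return {
        "n_noncoding": len(results),
        "n_conserved": n_sig,
        "percent_conserved": round(100.0 * n_sig / len(results), 2),
        "cutoffs": dataclasses.asdict(cutoffs),
        "control_flag_rate_phylop": round(
            float(np.mean([f > cutoffs.fraction_cutoff for f, _ in control_results])), 4
        ),
        "control_flag_rate_phastcons": round(
            float(np.mean([w > cutoffs.window_cutoff for _, w in control_results])), 4
        ),
        "ranksum_p_vs_controls": p,
    }


def _tss_stage(config, reference, merged, merged_records, outdir):
    tss_index = AnnotatedTssIndex(reference, config.tss_interval_halfwidth)
    peaks = merge_peaks([io_mod.read_bed(p) for p in config.peak_beds])
    cage_tracks = [io_mod.read_signal_bedgraph(p) for p in config.cage_bedgraphs]
    support = cage_support_intervals(cage_tracks)
    h3k = io_mod.read_signal_bedgraph(config.h3k4me3_bedgraph)

    rows = []
    group_counts: Dict[str, int] = {}
    hc_counts = {"novel": 0, "novel_gene": 0}
    hc_totals = {"novel": 0, "novel_gene": 0}
    cage_counts = {"novel": 0, "novel_gene": 0}
    profiles = {}
    for t in merged.transcripts:
        rec = merged_records[t.transcript_id]
        if rec.category == "other":
            continue
        trec = categorize_tss(rec, t, reference, tss_index, config.tss_interval_halfwidth)
        trec.high_confidence = high_confidence_tss(
            trec.position, t.chrom, peaks, config.peak_window_halfwidth
        )
        trec.cage_supported = cage_supported(
            trec.position, t.chrom, support, config.peak_window_halfwidth
        )
        group_counts[trec.group] = group_counts.get(trec.group, 0) + 1
        if trec.group in hc_totals:
            hc_totals[trec.group] += 1
            hc_counts[trec.group] += int(trec.high_confidence)
            cage_counts[trec.group] += int(trec.cage_supported)
            profiles[t.transcript_id] = promoter_profile(
                t.transcript_id, t.chrom, trec.position, t.strand, h3k
            )
        rows.append(
            {
                "transcript_id": t.transcript_id,
                "tss": trec.position,
                "strand": trec.strand,
                "group": trec.group,
                "high_confidence": trec.high_confidence,
                "cage_supported": trec.cage_supported,
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "tss.tsv", sep="\t", index=False)
    if profiles:
        prof_df = pd.DataFrame(
            {tid: p.values for tid, p in profiles.items()}
        ).T
        prof_df.columns = [f"bin_{i + 1}" for i in range(prof_df.shape[1])]
        prof_df.to_csv(outdir / "promoter_profiles.tsv", sep="\t", index_label="transcript_id")
    return {
        "group_counts": group_counts,
        "high_confidence": {
            g: {"count": hc_counts[g], "total": hc_totals[g],
                "percent": round(100.0 * hc_counts[g] / hc_totals[g], 2) if hc_totals[g] else 0.0}
            for g in hc_totals
        },
        "cage_supported": {
            g: {"count": cage_counts[g], "total": hc_totals[g]}
            for g in hc_totals
        },
    }


def _splicing_stage(config, merged, stage_models, genome, junction_support, outdir):
    merged_junctions = []
    for t in merged.transcripts:
        if t.is_multi_exon:
            merged_junctions.extend(extract_junctions(t, genome))
    canon = canonical_fraction(merged_junctions) if merged_junctions else float("nan")
    validated = validate_junctions(
        merged_junctions, junction_support, config.min_junction_reads
    )
    distinct = {j.key for j in merged_junctions}
    distinct_validated = {j.key for j in validated}

    # events on the merged annotation restricted to junction-validated isoforms
    validated_models = [
        t
        for t in merged.transcripts
        if not t.is_multi_exon
        or all(
            (t.chrom, d, a, t.strand) in distinct_validated
            for d, a in t.intron_chain
        )
    ]
    merged_events, merged_as_genes = enumerate_all_events(validated_models)
    per_stage_events = {
        s: enumerate_all_events(models)[0] for s, models in stage_models.items()
    }
    event_rows = [
        {
            "event_id": e.event_id,
            "gene_id": e.gene_id,
            "type": e.event_type,
            "coordinates": "-".join(map(str, e.coordinates)),
            "inclusion": ",".join(sorted(e.inclusion)),
            "exclusion": ",".join(sorted(e.exclusion)),
        }
        for e in merged_events
    ]
    pd.DataFrame(event_rows).to_csv(outdir / "events.ioe.tsv", sep="\t", index=False)
    type_counts: Dict[str, int] = {}
    for e in merged_events:
        type_counts[e.event_type] = type_counts.get(e.event_type, 0) + 1
    multi_iso_genes = {
        g for g, tids in _genes_of(validated_models).items() if len(tids) > 1
    }
    report = {
        "n_junctions": len(distinct),
        "canonical_percent": round(100.0 * canon, 2),
        "n_validated_junctions": len(distinct_validated),
        "validated_percent": round(100.0 * len(distinct_validated) / len(distinct), 2)
        if distinct
        else 0.0,
        "n_events_merged": len(merged_events),
        "events_by_type": type_counts,
        "n_as_genes": len(merged_as_genes),
        "n_multi_isoform_genes": len(multi_iso_genes),
        "events_per_stage": {s: len(v) for s, v in per_stage_events.items()},
    }
    return report, merged_events, per_stage_events


def _genes_of(models: Sequence[TranscriptModel]) -> Dict[str, List[str]]:
    out: Dict[str, List[str]] = {}
    for t in models:
        out.setdefault(t.gene_id, []).append(t.transcript_id)
    return out


def _das_stage(config, merged_events, merged_tpm, outdir):
    """Differential splicing between consecutive stages (oocyte onward),
    classed up/down/none per transition."""
    quantified = set(merged_tpm.values.index)
    usable = [
        e
        for e in merged_events
        if (e.inclusion | e.exclusion) <= quantified
    ]
    psi = psi_matrix(usable, merged_tpm) if usable else None
    river = []
    if psi is None or psi.empty:
        return river
    stages = [s for s in config.stage_order if s != "sperm"]
    sample_stage = {c: c.rsplit("_", 1)[0] for c in psi.columns}
    for prev, curr in zip(stages, stages[1:]):
        cols_a = [c for c in psi.columns if sample_stage[c] == prev]
        cols_b = [c for c in psi.columns if sample_stage[c] == curr]
        classes = {"up": 0, "down": 0, "none": 0}
        for event_id, row in psi.iterrows():
            a = row[cols_a].to_numpy(dtype=float)
            b = row[cols_b].to_numpy(dtype=float)
            if np.all(np.isnan(a)) or np.all(np.isnan(b)):
                continue
            res = diff_splice(
                a, b, n_perm=config.das_permutations,
                seed=config.seed, alpha=config.das_alpha,
            )
            classes[res.direction] += 1
        river.append({"transition": f"{prev}->{curr}", **classes})
    pd.DataFrame(river).to_csv(outdir / "das_river.tsv", sep="\t", index=False)
    return river
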