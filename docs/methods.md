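# Methods

This note documents the models, rules and numerical conventions behind
`isoatlas`, the design choices made where a convention was genuinely
open, and what the synthetic benchmark does and does not demonstrate.

## Coordinates and data model

All internal coordinates are 0-based half-open; GTF I/O converts at the
boundary with the exact bijection `start_internal = start_gtf - 1`,
`end_internal = end_gtf`.  A transcript is a strand-aware chain of
sorted, disjoint exons separated by ≥ 1 bp introns; its *intron chain*
(the ordered donor/acceptor pairs) is the unit of structural identity.
The TSS is the strand-aware 5′ end of the transcript span.  Unstranded
transcripts are rejected at parse time, because strand drives TSS
assignment, splice-motif reading and AS typing; filtering them is
applied globally.  Signal tracks (H3K4me3, CAGE, phyloP, phastCons) are
stored as sorted disjoint runs; uncovered bases score the track default
(0), matching the convention of averaging over a fixed denominator with
uncovered bases as zero.

## Transcript classification

Class codes are assigned by the first matching rule in the fixed
priority `=` > `c` > `j` > `e` > other > `u`, so multi-reference
ambiguity resolves deterministically:

* `=` — identical intron chain with a reference transcript, regardless
  of terminal-end positions.  Mono-exon queries match `=` at ≥ 50%
  reciprocal overlap with a mono-exon reference; the convention for
  mono-exon equality is tool-defined in the field, and 50% reciprocal
  overlap is the common choice.
* `c` — the query's intron chain is a *contiguous* proper sub-chain of a
  reference chain with the query span inside the reference span; a
  mono-exon query fully inside one reference exon is also contained.
* `j` — shares ≥ 1 splice junction with a same-strand reference
  transcript but was not matched above (covers both novel junctions and
  novel combinations of known junctions).
* `e` — overlaps a reference exon and reads ≥ 10 bp into an adjacent
  reference intron without carrying that junction (single-exon
  read-through semantics).
* other — residual same-strand overlap (unclassified), antisense-only
  exonic overlap, or location inside a reference span without exonic
  overlap (intronic).
* `u` — no exonic overlap on either strand: a potentially novel gene.

The best reference is chosen by most shared junctions, then longest
exonic overlap, then lexicographic id.  `=`/`c` form the annotated set
and `j`/`e`/`u` the novel set; gain/loss between consecutive stages
re-classifies each stage against the other and calls a transcript
shared iff its code is `=` or `c`.

Merging collapses multi-exon models with identical (chrom, strand,
intron chain) into one record with the extreme observed ends; mono-exon
models merge transitively by same-strand overlap into their union span.
Merged loci (gene ids) are connected components under same-strand
exonic overlap.  The saturation analysis permutes the stage order,
merges incrementally and counts cumulative novel transcripts; the band
is the empirical percentile interval over repetitions (99% by default)
because no analytic CI form is canonical for rarefaction counts.

## Biotype, ORFs and homology

Coding-potential scores are consumed, not computed: the classification
rule, not the scoring model, is the subject here.  Novel transcripts
are protein-coding at score > 0.44 (the published mouse default of the
standard coding-potential tool), lncRNA at score ≤ 0.44 with spliced
length > 200 bp, else otherwise.  "Transcript length" is taken as
spliced (exon-concatenated) length, which is what coding-potential
tools score.  ORF extraction scans the three forward frames of the
sense-strand spliced sequence for ATG-initiated, stop-terminated ORFs of
≥ 300 bp, reporting the longest ORF per stop codon (the first ATG since
the previous in-frame stop); 3′-incomplete ORFs are off by default
behind a flag, since whether they were counted upstream is unstated.
Reverse frames are not scanned — transcripts are sense-stranded by
construction.  Homology significance is per source (protein database
vs domain database) at log10(e-value) < −5, strictly.

Expression tiers: not detected at TPM ≤ 1, expressed at 1 < TPM ≤ 10,
high at TPM > 10.

## Conservation

Conservation is computed over the spliced exonic sequence, since the
transcript is the unit of the analysis; control regions are unspliced
intergenic intervals of exactly matching total length, one per
transcript, sampled uniformly with rejection against every exon of the
annotation supplied.  The pipeline passes the reference *augmented with
the novel transcripts under test*, so that candidate loci cannot
contaminate the "intergenic" background.  When fewer than 20
transcripts are scored the transcript list is cycled so the control set
reaches the 20-region floor needed for a stable 95th percentile; extra
controls remain length-matched.

Calibration: the phyloP base cutoff is the 95th percentile of all
control bases pooled (pooling rather than per-region maxima; the
granularity is otherwise unstated, and pooling is documented here as
the choice).  The fraction and window cutoffs are then the 95th
percentiles of the per-control statistics computed with that base
cutoff.  Percentiles use the linear-interpolation empirical quantile so
tests can be exact.  Regions shorter than the 200-bp window use the
whole-region mean.  Study-scale defaults (0.972 base, 0.2 fraction,
0.76 window) are available when calibration is disabled.

The rank-sum comparison of transcript versus control scores is a
two-sided Mann–Whitney U with mid-ranks: exact enumeration of all
C(n+m, n) assignments when n + m ≤ 16, otherwise the normal
approximation with tie and continuity correction.  The exact two-sided
p is min(1, 2·min(P(U ≤ u), P(U ≥ u))).

## TSS validation

Annotated TSS intervals are ±300 bp around each reference transcript's
TSS (per transcript, not per gene; same strand required).  Promoter
metaprofiles cover ±4 kb with 161 bins of width 100 bp at 50-bp steps;
since 159 bins of that geometry fit strictly inside ±4 kb, the 161 bins
are laid from TSS − 4050 so the central bin is centered on the TSS (a
documented geometry convention, configurable).  Minus-strand profiles
are reversed so bins read 5′→3′.  High confidence requires a merged
H3K4me3 peak (union across the three cleavage-stage peak sets)
intersecting the closed ±500 bp TSS window; CAGE support requires a
base with nonzero CAGE signal in any sample within the same window.  No
rescue rule is applied for novel isoforms whose peaks overlap classic
TSSs, as none is defined.

## Alternative splicing

Events are enumerated per gene from pairwise isoform comparison in the
local-event style: SE (an exon spliced out by a single intron with both
flanking junctions shared), A5/A3 (one intron boundary shared, the
other alternative, with the outer exon boundary on the varying side
shared; 5′/3′ assigned strand-aware), RI (an intron fully exonic in
another isoform with shared outer exon boundaries), MX (two mutually
exclusive exons between identical flanking boundaries), AF/AL
(non-overlapping terminal exons spliced onto a shared junction
boundary).  Event identity is (type, chrom, strand, coordinate tuple);
duplicates collapse, and membership is aggregated over all isoforms of
the gene carrying each form.  Inclusion-form conventions, where not
forced by the definition, are fixed as: retained intron = inclusion
(RI); shorter intron = inclusion (A5/A3); strand-aware 5′-proximal
alternative exon = inclusion (MX); distal terminal exon = inclusion
(AF/AL).  These labels are deterministic bookkeeping; ΔPSI direction
classes are defined relative to them.

PSI is ΣTPM(inclusion)/(ΣTPM(inclusion)+ΣTPM(exclusion)), undefined at
zero denominator and propagated as missing.  Differential splicing uses
a label-permutation test on replicate PSIs (difference of means,
two-sided): all arrangements are enumerated when there are ≤ 10 of
them, otherwise Monte-Carlo sampling with the add-one estimate,
deterministic under the seed.  This is a deliberate simplification of
the expression-conditioned empirical null used by the standard PSI
tool: the threshold rule (up/down at p < 0.05 by ΔPSI sign) is what the
analysis depends on, and a permutation null is the defensible stand-in.
With only two replicates per condition the exact permutation p cannot
fall below 1/3, so the pipeline's river table is conservative at the
default two-batch design; differential-splicing benchmarks therefore
use five replicate PSI draws per condition (`das_replicates`), and the
methods of record for DAS power are the dedicated replicate-PSI
simulations.

Junction validation keeps junctions with ≥ 10 supporting short reads in
≥ 1 sample; merged-catalog events are enumerated on isoforms whose
junctions all pass (mono-exon isoforms pass vacuously).

## Expression dynamics

ZGA: oocyte ≤ 1, 1-cell > 1, 2-cell > 1, 2-cell > 2 × 1-cell, evaluated
on arithmetic replicate means per stage ("expressed" is read as > 1,
symmetric with the stated ≤ 1 silence rule; replicate handling is
otherwise unstated).  Splicing-factor coupling is plain Pearson
correlation of per-stage expression against per-stage AS event totals
over the six stages from oocyte to blastocyst.  Row z-scores use the
population standard deviation with constant rows mapped to zero.  The
quantification-change statistic δ is not defined upstream; it is
implemented as the pseudocounted fold change max(a+1, b+1)/min(a+1, b+1)
by default, with an absolute-difference variant behind a flag, and a
transcript is flagged at δ > 5 in ≥ 1 stage.

## The synthetic benchmark

The generator emulates the *inputs* of the study at desk scale — the
default is 3 chromosomes × 400 kb, 90 multi-isoform genes, 24 hidden
novel-gene loci, 7 stages × 100 transcripts with the five-way category
mixture (55/10/20/8/7%), 70% of turnover-eligible transcripts shared
between consecutive stages, two replicate batches per stage, and 97%
canonical junctions — sizes chosen once so the full pipeline and its
tests complete in seconds while every planted class keeps double-digit
membership.  Key constructions:

* **Splice motifs.** Donor sites carry GT with probability equal to the
  canonical fraction (GC otherwise) and acceptors carry AG, written
  strand-aware into the genome.  Junctions sharing a donor site share
  its motif, so the junction-level canonical share has slightly wider
  spread than an independent binomial.
* **Categories by construction.** Planted contained/novel-isoform
  transcripts derive from dedicated single-isoform genes (interior
  sub-chain; internal-exon skip with an optional > 300 bp 5′ extension
  for novel-TSS planting), so their codes are unambiguous.  "Other"
  transcripts are mono-exon antisense or intronic models, with intronic
  placements restricted to introns intact in every sibling isoform.
* **Promoters.** High-confidence TSSs get a bimodal H3K4me3 bump
  (Gaussian peaks ±400 bp, σ = 150 bp) and a ±300 bp peak assigned to
  one of the three cleavage-stage peak files; annotated promoters get
  signal but no peaks, so the planted high-confidence set is decisive.
  TSSs in the validation truth set are spaced > 1.6 kb apart so no peak
  can validate a foreign TSS.
* **Conservation.** Tracks are 100-bp tiles: background phyloP ~
  N(0, 0.6) and phastCons ~ U(0, 0.5); planted conserved exons are
  elevated (phyloP ~ N(2.5, 0.4), phastCons ~ U(0.85, 0.98)) and
  planted non-conserved transcribed exons sit at or slightly below
  background, keeping the planted classes separable at the default
  effect size.  Conserved flags are assigned only to emitted
  transcripts, so unused hidden loci stay background.
* **Expression.** TPM noise is log-normal and multiplicative (strictly
  positive, heavy-tailed, like real expression data; no noise model is
  stated upstream).  Planted ZGA rows satisfy the rule with margin and
  are re-checked after noise; non-planted rows that satisfy it by
  chance are nudged into oocyte expression, so recovery is exact by
  construction.  Planted differential events realize their PSI
  trajectory exactly per replicate (inclusion = ψT, exclusion =
  (1−ψ)T), with ψ noise at σ = 0.03.
* **Coupling.** Splicing-factor gene expression is linear in the
  z-scored per-stage AS event totals with the configured sign.

What passing these tests shows: the rules, statistics and bookkeeping
are implemented correctly and recover planted structure through the
complete file-format round trip.  What it does not show: robustness to
alignment artifacts, degraded 5′ ends, mono-exonic noise, expression
quantification error correlated with transcript structure, or genome
repeat content — none of which the generator emulates, and all of which
affect real long-read catalogs.  Headline counts from the emulated
study (tens of thousands of transcripts, thousands of events) derive
from deposited sequencing data and upstream assembly tools that are out
of scope here; the synthetic dataset reproduces the *procedures*, not
those magnitudes.

## Reproducibility and problem sizes

Every stochastic step takes an explicit seed and is deterministic under
it (per-step generators are derived from the dataset seed with fixed
stream indices).  The test suite and `scripts/acceptance.py` run the
default study conditions; the heavier calibration checks use 2,000
(type-I error) and 200 (power) simulated events at 5 replicates and 500
permutations, and saturation uses 30 repetitions — sizes at which the
Monte-Carlo error is comfortably inside the asserted bounds.
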