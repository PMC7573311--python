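# Methods

This note documents the models, algorithms, numerical choices and
limitations of `homeoquant`. Coordinates are 0-based half-open internally;
GFF3 I/O converts to 1-based inclusive.

## Synthetic data model

The generator (`simulate`) emulates the data-generating process the
analysis assumes, with every output a pure function of
(`SimulationConfig`, seed). Seeds expand through `numpy`'s `SeedSequence`,
so stages draw from independent, reproducible streams.

**Genomes.** Chromosomes are i.i.d. uniform A/C/G/T (no GC or composition
bias — deliberately out of scope). Genes are placed left to right with
random intergenic gaps, 2–6 exons of 150–500 bp separated by 60–300 bp
introns, random strand. Requesting more genes than fit raises a sizing
error naming the deficit.

**Parental divergence.** Each parent differs from the base by SNPs at
`snp_rate` per base (default 0.0075, giving ~1.5 % divergence *between*
the two parents) and optionally short indels (length 1–5, insertions and
deletions equally likely, default rate 0). SNP counts are
Binomial(length, rate) per chromosome; exonic and intergenic positions are
equally eligible. Indels are kept ≥ 3 bp away from every splice boundary
so annotation lift-over across splice sites stays exact; this is a
simulation convenience, not a property of real genomes. The emitted
variant set reconstructs the parent from the base byte-for-byte
(round-trip invariant), and the parent carries lifted annotations plus a
coordinate map to the base.

**Expression.** Expected fragment counts per homeolog per time point are
`depth` (fragments per expressed kilobase per subgenome copy, default 50)
× transcript kilobases × a class profile × copy number. Three gene
classes: *constant* (flat), *induced* (2^(fc·t/t_max), a monotone ramp in
log2 space reaching `induced_log2fc`, default 3 → 8-fold), *oscillating*
(2^(a·sin(2π(t−φ)/24 h)), phase φ uniform per gene, default amplitude 1 →
4-fold peak-to-trough). Default class fractions 0.6/0.2/0.2. Both
homeologs of a pair share the class and phase, so before noise the R:A
expectation ratio equals the dosage ratio (default 1:2) at every time
point. Baseline expression is uniform across genes; real libraries span
orders of magnitude, which matters only for statistics tied to absolute
FPKM (see the VEH benchmark below).

**Reads.** Per-homeolog fragment counts are Poisson (a gamma-Poisson
dispersion knob exists, default off — the design has no biological
replicates, so the simpler noise model matches what the analysis can see).
Fragment lengths are Normal(250, 30) clipped to [read length, transcript
length]; placement is uniform on the spliced transcript; mate 1 reads the
5' end forward, mate 2 the 3' end reverse-complemented; per-base errors
are i.i.d. substitutions at `error_rate` (default 0.001). Qualities are
constant "I" (optionally "#" at error sites). Transcripts shorter than the
read length are skipped with a warning. The truth tables record every
fragment's subgenome and gene, the expected-count matrix, and the gene
class labels.

What passing tests on these data do *not* show: robustness to indel-rich
or structurally rearranged genomes, sequencing-quality artefacts, library
biases, intron retention/alternative splicing, or mapping ambiguity from
paralogous gene families (synthetic genes are unrelated random sequences).

## Read mapping

`readmap` is a minimal spliced-transcript mapper sufficient for
low-divergence reads: exact k-mer seeds (k = 21, stride k plus the read
tail, both orientations) over the transcript set, ungapped full-read
Hamming extension, minimal-mismatch placement with `max_mismatches` = 8.
Ties on distinct genomic placements set a multimapped flag and resolve to
the leftmost coordinate for reproducibility. Hits are projected to genomic
blocks through the exon structure, and SAM I/O (NM tag = mismatch count)
lets any external spliced aligner substitute for it on real data. Gapped
alignment and base-quality-aware scoring are non-goals; the paired-mate
trimming surrogate is a plain minimum-length filter, since synthetic
qualities carry no information.

## Pseudo-genome assembly

`call_variants` accepts pileups (or alignment streams, or SAM) and emits
one SNP per locus where the majority alternative base is carried by
≥ `min_alt_fraction` (default 0.8, inclusive) of covering reads *and* by
at least `min_alt_depth` (default 5) reads. The depth threshold counts
reads carrying the alternative, not total depth — the stricter and, we
judge, intended reading; both thresholds are parameters. Only primary
alignments contribute, and no base-quality filter is applied. Ties between
alternative bases resolve alphabetically (deterministic).

`substitute` applies variants left-to-right; overlapping variants resolve
first-position-wins with the conflict logged and counted. Annotations and
the coordinate map are shifted through indels (positions inside a replaced
interval clamp onto the replacement); output length equals input length
plus the net indel balance. The coordinate map composes across rounds, so
any assembled position traces back to the base reference.

`iterate_assembly` runs map → call → substitute → re-annotate for
`n_iterations` (default 9) rounds, by default substituting only variants
overlapping annotated exons (the coding-region mode; a whole-genome switch
exists — RNA-seq pileups barely reach introns either way). Once a round
calls zero variants the genome is at a fixed point and iteration stops
early, padding the per-round counts with zeros. Because the caller's
pileup comes from ungapped alignments, iterated assembly recovers SNPs
only; indel-aware substitution remains available for variant sets produced
elsewhere.

Recovery is limited by coverage at transcript ends: a SNP within ~100 bp
of a transcript end sees fewer overlapping reads, and below 5 alternative
reads it is (correctly) not called. The recovery study therefore uses
pooled reads at 60× exonic coverage — the analogue of pooling a full
nine-sample time course before assembly, which is how the assembly stage
is meant to be fed — rather than a single shallow sample.

## Origin classification

The classifier is a deterministic mismatch-count comparison (summed over
mates; when a mate is unmapped on one genome, only mates mapped on both
are compared). A genome must win by ≥ `tie_margin` (default 1) mismatches;
otherwise *unclassified*. Fragments mapped on only one genome take that
origin — single-genome mappability is itself diagnostic — and are flagged
for audit. This replaces probabilistic read-sorting models: downstream
formulas consume only the three-way label, and with error-free reads a
wrong call would require fewer mismatches on the wrong genome, which
divergence alone cannot produce (misclassification is exactly 0 in that
regime; with sequencing errors it grows smoothly from 0). The diploid
evaluation reports wrong/(right+wrong) with unclassified and discarded
fractions separately; real-data rates depend on true divergence and error
profiles, which no synthetic setting claims to reproduce.

## Quantification

Fractional counting follows the overlap rule: each fragment distributes
weight 1 equally over the gene models its genomic blocks intersect on the
counting genome (A-origin on A, R-origin on R; unclassified on the
majority subgenome R by default, falling back to A when unmapped there —
configurable). Intergenic fragments contribute nothing.

Allocation and FPKM are exactly the formulas in the README. Two
conventions worth recording:

- Sample totals Aˢ, Rˢ are computed **post-allocation** (Σa′, Σr′), so
  Σ_h FPKM·L = 10⁹ identically and the unclassified mass is treated
  consistently; a pre-allocation option exists.
- When p is undefined (a+r = 0 with u > 0) the unclassified mass splits
  0.5/0.5 and the homeolog is flagged — conservative, biasing neither
  subgenome.

The ratio distribution histograms p over homeologs in 0.02-wide bins
anchored at 0; exact 0 and 1 (single-subgenome expression) are counted
separately as edge masses, and the mode is the midpoint of the
highest-mass interior bin (ties → lower bin). Note the midpoint
convention: values exactly at 0.5 fall in [0.50, 0.52), whose midpoint is
0.51. Between-time-point agreement is summarised by Pearson correlation
over homeologs with defined ratios at both points (NaN for degenerate
constant vectors; ≥ 3 pairs required).

## Time-course statistics

Expression gating is strict (FPKM > 1.0 at ≥ 1 time point); all statistics
use log₁₀(FPKM+1). PCA is SVD of the column-centered sample × homeolog
matrix — no unit-variance scaling — with each component's sign fixed by
making its largest-magnitude loading positive, so results reproduce
exactly. VEH calls use the sample standard deviation (ddof = 1; the
population convention is a parameter) and strict thresholds mean > 1.0,
CV > 0.20; both statistics are order-free in time. Zero-mean series have
no defined CV and are flagged, never called.

The VEH benchmark (`workflows.veh_benchmark`) draws Poisson counts around
50 expected fragments for constant and 8-fold-induced genes and computes
FPKM against a fixed library total chosen to put the constant baseline at
FPKM 12 — the benchmarked genes stand for a small slice of a large stable
transcriptome, so induction does not move the normalisation. The baseline
matters because CV on the log scale shrinks as absolute expression grows:
an 8-fold ramp at baseline FPKM ≈ 12 has CV ≈ 0.23, comfortably above the
0.20 threshold, while the same ramp at FPKM ≈ 100 would not be called.
The benchmark therefore characterises the detector in the regime the
thresholds were designed for.

## Enrichment

Depths are longest-path distances from a root (root = 1), computed by
topological order; cycles raise an error. The redundancy filter keeps
categories with 10–500 members at depth ≥ 3. The "below the third level"
reading is genuinely ambiguous; we interpret it as *more specific than*
the top two levels (depth ≥ 3), with the opposite reading (depth ≤ 3)
selectable. The universe is the expressed set of the relevant sample
group, not the whole genome, since VEH sets are drawn from expressed
homeologs. p-values are upper-tail hypergeometric P(X ≥ k); BH adjustment
runs across the retained categories of one sample set at a time;
enrichment means q < 0.1. Synthetic category DAGs (random levels, 1–2
parents per node, log-uniform member sizes, members sampled independently
per category) make FDR behaviour testable without real ontology files —
they reproduce the size/depth structure the filters consume, not the
nestedness of real ontologies, which the test statistics do not use.

## Pipeline

One global seed expands deterministically into per-stage, per-sample
seeds; every stage reads inputs from and writes artifacts to the output
directory, so downstream stages rerun in isolation bit-identically. The
manifest records parameters and SHA-256 hashes of all artifacts. Default
time points are the nine-sample design 0, 2, 4, 8, 12, 24, 48, 72, 96 h.

## Problem sizes in tests and studies

The packaged studies choose sizes that make their statistics stable:
the dosage-ratio study uses 700 homeolog pairs at ~400 expected fragments
per pair (above the ≥ 500 pairs / ≥ 200 fragments floor at which the
0.02-wide mode bin becomes a reliable estimator of the peak); the recovery
study uses 200 genes over 500 kb at 60× pooled exonic coverage; unit
fixtures use a 50-gene, 150 kb design. All are generated at test time;
nothing is stored.

## Known limitations

- Ungapped transcript-space mapping cannot discover indels; real-data
  users should supply SAM from a spliced aligner for indel-bearing taxa.
- Overlapping gene models are supported in counting but not generated by
  the simulator, so the 1/k split is exercised mainly by constructed
  cases.
- No TPM/DESeq-style normalisation, no differential tests between species
  or time points, no circadian period estimation — the analysis reports
  ratios, CV calls and correlations only.
- The probabilistic origin-classification literature (null-distribution
  significance machinery) is intentionally not reimplemented.
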