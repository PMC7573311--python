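"""Iterative pseudo-genome construction for a progenitor subgenome.

A progenitor's RNA-seq reads are mapped onto a related base reference, SNPs
are called from the pileup (a locus is accepted when at least 80% of the
covering reads carry the alternative base and at least five reads carry it),
the alternative bases are substituted into the reference, and the gene
annotations are lifted through the substitutions. Repeating the
map-call-substitute cycle (nine times by default) lets reads that initially
failed to map because of clustered divergence find a home on the improving
sequence, so the assembled pseudo-genome converges toward the progenitor.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

from .genome import (CoordinateMap, GeneModel, ReferenceGenome, Variant,
                     VariantSet, revcomp)
from .readmap import (DEFAULT_MAX_MISMATCHES, DEFAULT_SEED_K, TranscriptIndex,
                      _COMP)

logger = logging.getLogger(__name__)

DEFAULT_MIN_ALT_FRACTION = 0.8
DEFAULT_MIN_ALT_DEPTH = 5
DEFAULT_ITERATIONS = 9


# ---------------------------------------------------------------------------
# Pileup and variant calling
# ---------------------------------------------------------------------------

@dataclass
class AlignedBases:
    """Per-base placement of one aligned read: genome-frame positions and
    the read's bases expressed on the genome's forward strand."""

    chrom: str
    positions: np.ndarray  # int positions, genome frame
    bases: np.ndarray      # uint8 forward-strand base codes
    primary: bool = True


class Pileup:
    """Per-position coverage plus alternative-base tallies on one genome."""

    def __init__(self, genome: ReferenceGenome) -> None:
        self.genome = genome
        self._ref = {
            c: np.frombuffer(s.encode(), dtype=np.uint8)
            for c, s in genome.chromosomes.items()
        }
        self.coverage = {
            c: np.zeros(len(s), dtype=np.int32)
            for c, s in genome.chromosomes.items()
        }
        self.alt: dict[tuple[str, int], dict[str, int]] = {}

    def add_base(self, chrom: str, pos: int, base: str) -> None:
        """Record one covering read base (test/constructed-pileup entry)."""
        if chrom not in self.coverage:
            raise ValueError(f"alignment references unknown chromosome {chrom}")
        self.coverage[chrom][pos] += 1
        if base.encode()[0] != self._ref[chrom][pos]:
            d = self.alt.setdefault((chrom, pos), {})
            d[base] = d.get(base, 0) + 1

    def add_aligned(self, aln: AlignedBases) -> None:
        if not aln.primary:
            return
        if aln.chrom not in self.coverage:
            raise ValueError(
                f"alignment references unknown chromosome {aln.chrom}")
        np.add.at(self.coverage[aln.chrom], aln.positions, 1)
        ref = self._ref[aln.chrom][aln.positions]
        for i in np.nonzero(aln.bases != ref)[0]:
            key = (aln.chrom, int(aln.positions[i]))
            b = chr(aln.bases[i])
            d = self.alt.setdefault(key, {})
            d[b] = d.get(b, 0) + 1


def call_variants(alignments: Pileup | Iterable[AlignedBases],
                  reference: ReferenceGenome,
                  min_alt_fraction: float = DEFAULT_MIN_ALT_FRACTION,
                  min_alt_depth: int = DEFAULT_MIN_ALT_DEPTH) -> VariantSet:
    """SNPs from a pileup: loci where the (majority) alternative base is
    carried by >= ``min_alt_fraction`` of covering reads and by at least
    ``min_alt_depth`` reads.

    Both thresholds are inclusive; the depth threshold counts reads carrying
    the alternative base, not total depth. Only primary alignments
    contribute. Ties between alternative bases resolve alphabetically.
    """
    if isinstance(alignments, Pileup):
        pileup = alignments
    else:
        pileup = Pileup(reference)
        for aln in alignments:
            pileup.add_aligned(aln)
    out: list[Variant] = []
    for (chrom, pos), counts in sorted(pileup.alt.items()):
        # deterministic majority: highest count, then alphabetical
        best = max(counts.values())
        alt = min(b for b, n in counts.items() if n == best)
        alt_n = counts[alt]
        total = int(pileup.coverage[chrom][pos])
        if alt_n < min_alt_depth:
            continue
        if alt_n / total < min_alt_fraction:
            continue
        ref_base = reference.chromosomes[chrom][pos]
        out.append(Variant(chrom, pos, ref_base, alt, alt_n, total))
    return VariantSet(out)


def pileup_from_sam(path, reference: ReferenceGenome) -> Pileup:
    """Build a pileup from an external SAM file (primary alignments only)."""
    import pysam

    pileup = Pileup(reference)
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped or a.is_secondary or a.is_supplementary:
                continue
            if a.reference_name not in reference.chromosomes:
                raise ValueError(
                    f"alignment references unknown chromosome {a.reference_name}")
            pairs = a.get_aligned_pairs(matches_only=True)
            if not pairs:
                continue
            qpos, gpos = zip(*pairs)
            seq = a.query_sequence
            bases = np.frombuffer(
                "".join(seq[q] for q in qpos).encode(), dtype=np.uint8)
            pileup.add_aligned(AlignedBases(
                a.reference_name, np.asarray(gpos, dtype=np.int64), bases))
    return pileup


# ---------------------------------------------------------------------------
# Substitution with annotation lift-over
# ---------------------------------------------------------------------------

@dataclass
class SubstitutionReport:
    applied: list[Variant]
    conflicts: int

    @property
    def net_length_change(self) -> int:
        return sum(v.length_change for v in self.applied)


class _Lifter:
    """Old-frame -> new-frame position map over one chromosome's applied
    variants (positions inside a replaced interval clamp into it)."""

    def __init__(self) -> None:
        self.pos: list[int] = []      # variant ref start, old frame
        self.ref_end: list[int] = []  # variant ref end, old frame
        self.alt_len: list[int] = []
        self.shift_before: list[int] = []
        self._shift = 0

    def add(self, v: Variant) -> None:
        self.pos.append(v.pos)
        self.ref_end.append(v.pos + len(v.ref))
        self.alt_len.append(len(v.alt))
        self.shift_before.append(self._shift)
        self._shift += v.length_change

    def lift(self, old: int) -> int:
        i = bisect.bisect_right(self.pos, old) - 1
        if i < 0:
            return old
        if old >= self.ref_end[i]:
            return old + self.shift_before[i] + \
                (self.alt_len[i] - (self.ref_end[i] - self.pos[i]))
        # inside the replaced interval: clamp onto the alt allele
        return self.pos[i] + self.shift_before[i] + \
            min(old - self.pos[i], self.alt_len[i])


def substitute(reference: ReferenceGenome, variants: VariantSet
               ) -> tuple[ReferenceGenome, SubstitutionReport]:
    """Apply variants left-to-right, lifting annotations and coordinates.

    Overlapping variants resolve first-position-wins; conflicts are logged
    and counted in the report. The output genome's coordinate map leads all
    the way back to the base reference (composed through the input genome's
    own map), and its length equals the input length plus the net indel
    balance of the applied variants.
    """
    variants.validate_against(reference)
    by_chrom: dict[str, list[Variant]] = {}
    for v in variants:
        by_chrom.setdefault(v.chrom, []).append(v)

    new_chroms: dict[str, str] = {}
    lifters: dict[str, _Lifter] = {}
    applied: list[Variant] = []
    conflicts = 0
    new_map = CoordinateMap.identity(reference.chromosomes)
    for chrom, seq in reference.chromosomes.items():
        vs = by_chrom.get(chrom, [])
        lifter = _Lifter()
        parts: list[str] = []
        cursor = 0
        starts = [0]
        deltas = [0]
        shift = 0
        for v in vs:
            if v.pos < cursor:
                conflicts += 1
                logger.warning("overlapping variant skipped at %s:%d", chrom, v.pos)
                continue
            parts.append(seq[cursor : v.pos])
            parts.append(v.alt)
            lifter.add(v)
            applied.append(v)
            cursor = v.pos + len(v.ref)
            if v.length_change != 0:
                shift += v.length_change
                starts.append(v.pos + lifter.shift_before[-1] + len(v.alt))
                deltas.append(-shift)
        parts.append(seq[cursor:])
        new_chroms[chrom] = "".join(parts)
        lifters[chrom] = lifter
        new_map.starts[chrom] = starts
        new_map.deltas[chrom] = deltas

    new_genes: list[GeneModel] = []
    for g in reference.genes:
        lifter = lifters[g.chrom]
        exons = []
        for s, e in g.exons:
            ns, ne = lifter.lift(s), lifter.lift(e)
            if ne <= ns:
                logger.warning("exon of %s collapsed by a deletion; dropped",
                               g.gene_id)
                continue
            exons.append((ns, ne))
        if exons:
            new_genes.append(GeneModel(g.gene_id, g.chrom, g.strand,
                                       tuple(exons)))

    if reference.coordinate_map is not None:
        new_map = new_map.compose(reference.coordinate_map)
    out = ReferenceGenome(new_chroms, new_genes, new_map)
    out.validate()
    return out, SubstitutionReport(applied, conflicts)


# ---------------------------------------------------------------------------
# Exonic masks and filters
# ---------------------------------------------------------------------------

def exon_mask(genome: ReferenceGenome) -> dict[str, np.ndarray]:
    masks = {c: np.zeros(len(s), dtype=bool)
             for c, s in genome.chromosomes.items()}
    for g in genome.genes:
        for s, e in g.exons:
            masks[g.chrom][s:e] = True
    return masks


def filter_exonic(variants: VariantSet, genome: ReferenceGenome) -> VariantSet:
    """Keep variants whose reference span overlaps an exon."""
    masks = exon_mask(genome)
    return VariantSet(
        v for v in variants
        if masks[v.chrom][v.pos : v.pos + len(v.ref)].any()
    )


# ---------------------------------------------------------------------------
# Iterative assembly
# ---------------------------------------------------------------------------

def _transcript_mapper(k: int, max_mismatches: int
                       ) -> Callable[[ReferenceGenome, Sequence], Iterable[AlignedBases]]:
    def mapper(genome: ReferenceGenome, reads) -> Iterable[AlignedBases]:
        index = TranscriptIndex(genome, k=k)
        for fid, s1, s2 in reads:
            for s in (s1, s2):
                hit = index.map_sequence(s, max_mismatches)
                if hit is None:
                    continue
                gpos = index.genome_positions(hit, len(s))
                q = s if hit.orient == "F" else revcomp(s)
                qarr = np.frombuffer(q.encode(), dtype=np.uint8)
                if index.strands[hit.ti] == "-":
                    qarr = _COMP[qarr]  # transcript frame -> genome forward
                yield AlignedBases(index.chroms[hit.ti], gpos, qarr)
    return mapper


def iterate_assembly(reads: Sequence[tuple[str, str, str]],
                     base: ReferenceGenome,
                     n_iterations: int = DEFAULT_ITERATIONS,
                     mapper: Callable | None = None,
                     min_alt_fraction: float = DEFAULT_MIN_ALT_FRACTION,
                     min_alt_depth: int = DEFAULT_MIN_ALT_DEPTH,
                     exonic_only: bool = True,
                     snp_only: bool = False,
                     k: int = DEFAULT_SEED_K,
                     max_mismatches: int = DEFAULT_MAX_MISMATCHES
                     ) -> tuple[ReferenceGenome, list[int]]:
    """Run the map -> call -> substitute -> re-annotate cycle.

    ``mapper(genome, reads)`` must yield :class:`AlignedBases`; by default
    the built-in transcript-index mapper is used. ``exonic_only`` restricts
    substitution to variants overlapping annotated exons (the coding-region
    mode); set it False to substitute anywhere. Iteration stops early at the
    fixed point (no variants called), padding the per-iteration counts with
    zeros.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if mapper is None:
        mapper = _transcript_mapper(k, max_mismatches)
    genome = base
    counts: list[int] = []
    for it in range(n_iterations):
        variants = call_variants(mapper(genome, reads), genome,
                                 min_alt_fraction, min_alt_depth)
        if exonic_only:
            variants = filter_exonic(variants, genome)
        if snp_only:
            variants = variants.snps
        counts.append(len(variants))
        logger.info("assembly iteration %d: %d variants", it + 1, len(variants))
        if len(variants) == 0:
            break
        genome, _ = substitute(genome, variants)
    counts += [0] * (n_iterations - len(counts))
    return genome, counts


def snp_recovery(assembled: ReferenceGenome, true_variants: VariantSet,
                 base: ReferenceGenome, exonic_only: bool = True) -> float:
    """Fraction of true SNPs whose alternative base made it into the
    assembled sequence (positions compared in the base frame; valid for
    SNP-only divergence where coordinates are preserved)."""
    masks = exon_mask(base) if exonic_only else None
    snps = [v for v in true_variants.snps
            if masks is None or masks[v.chrom][v.pos]]
    if not snps:
        raise ValueError("no true SNPs to score")
    hit = sum(
        1 for v in snps if assembled.chromosomes[v.chrom][v.pos] == v.alt
    )
    return hit / len(snps)
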