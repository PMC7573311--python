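"""Synthetic data generation with known ground truth.

Emulates the data-generating process the downstream analysis assumes: a base
reference genome with exonic gene models; two progenitor genomes (labelled A
and R) diverged from it by SNPs and optionally short indels; a triploid
transcriptome expressing every homeolog pair in proportion to subgenome
dosage (one A copy, two R copies in the study design); nine-time-point
expression profiles mixing constant, monotonically induced and 24 h
oscillating gene classes; and paired-end 100 bp reads with configurable
per-base error. Every output is a pure function of the configuration and its
seed, and every simulated fragment's subgenome of origin is recorded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import GeneModel, ReferenceGenome, Variant, VariantSet, revcomp

logger = logging.getLogger(__name__)

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

GENE_CLASSES = ("constant", "induced", "oscillating")

#: Hours after the start of treatment at which samples are taken.
DEFAULT_TIME_POINTS = (0.0, 2.0, 4.0, 8.0, 12.0, 24.0, 48.0, 72.0, 96.0)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the triploid design: subgenome dosage A:R = 1:2, nine
    sampling times over 96 h, 100 bp paired-end reads. ``depth`` is the
    expected number of sequenced fragments per expressed kilobase per
    subgenome copy at the baseline expression level.
    """

    genome_length: int = 500_000
    n_chromosomes: int = 2
    n_genes: int = 200
    exons_per_gene: tuple[int, int] = (2, 6)
    exon_length: tuple[int, int] = (150, 500)
    intron_length: tuple[int, int] = (60, 300)
    snp_rate: float = 0.0075
    indel_rate: float = 0.0
    dosage: tuple[int, int] = (1, 2)
    time_points_h: tuple[float, ...] = DEFAULT_TIME_POINTS
    read_length: int = 100
    fragment_length_mean: float = 250.0
    fragment_length_sd: float = 30.0
    error_rate: float = 0.001
    depth: float = 50.0
    gene_class_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"constant": 0.6, "induced": 0.2,
                                 "oscillating": 0.2})
    induced_log2fc: float = 3.0
    oscillation_log2_amplitude: float = 1.0
    oscillation_period_h: float = 24.0
    dispersion: float = 0.0
    mark_error_quals: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.dosage) < 0 or sum(self.dosage) == 0:
            raise ValueError("dosage components must be >= 0 and not both 0")
        for name in ("snp_rate", "indel_rate", "error_rate"):
            r = getattr(self, name)
            if not (0.0 <= r <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {r}")
        tp = tuple(self.time_points_h)
        if any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError("time points must be strictly increasing")
        fr = dict(self.gene_class_fractions)
        if set(fr) - set(GENE_CLASSES):
            raise ValueError(f"unknown gene classes: {set(fr) - set(GENE_CLASSES)}")
        if abs(sum(fr.values()) - 1.0) > 1e-9:
            raise ValueError("gene_class_fractions must sum to 1")
        if min(fr.values(), default=0.0) < 0:
            raise ValueError("gene_class_fractions must be non-negative")

    def rng(self, *tags: int) -> np.random.Generator:
        """Deterministic per-stage generator derived from the global seed."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, *tags]))


@dataclass
class GroundTruth:
    """Everything the simulator knows that the pipeline must rediscover."""

    true_variants: dict[str, VariantSet]
    true_origin: dict[str, str]
    true_gene: dict[str, str]
    true_expression: pd.DataFrame
    veh_truth: dict[str, str]

    def validate(self) -> None:
        if set(self.true_origin) != set(self.true_gene):
            raise ValueError("origin and gene truth cover different fragments")
        if (self.true_expression.values < 0).any():
            raise ValueError("negative expected expression")


# ---------------------------------------------------------------------------
# Base genome
# ---------------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(BASES, size=length).tobytes().decode()


def generate_base_genome(config: SimulationConfig) -> ReferenceGenome:
    """Random base genome with non-overlapping exonic gene models.

    Genes are laid out left to right on each chromosome with random
    intergenic gaps, alternating over both strands at random. Raises a
    sizing error naming the shortfall if ``n_genes`` genes cannot be placed.
    """
    rng = config.rng(1)
    chroms = {
        f"chr{i + 1}": _random_sequence(rng, config.genome_length)
        for i in range(config.n_chromosomes)
    }
    genes: list[GeneModel] = []
    if config.n_genes:
        per_chrom = np.full(config.n_chromosomes, config.n_genes // config.n_chromosomes)
        per_chrom[: config.n_genes % config.n_chromosomes] += 1
        gid = 0
        for ci, name in enumerate(chroms):
            cursor = 0
            placed = 0
            while placed < per_chrom[ci]:
                gap = int(rng.integers(50, 500))
                n_ex = int(rng.integers(config.exons_per_gene[0],
                                        config.exons_per_gene[1] + 1))
                ex_lens = rng.integers(config.exon_length[0],
                                       config.exon_length[1] + 1, size=n_ex)
                in_lens = rng.integers(config.intron_length[0],
                                       config.intron_length[1] + 1,
                                       size=max(0, n_ex - 1))
                span = int(ex_lens.sum() + in_lens.sum())
                start = cursor + gap
                if start + span > config.genome_length:
                    missing = config.n_genes - len(genes)
                    raise ValueError(
                        f"genome too small: could not place {missing} of "
                        f"{config.n_genes} genes ({config.genome_length} bp "
                        f"per chromosome)"
                    )
                exons = []
                pos = start
                for j in range(n_ex):
                    exons.append((pos, pos + int(ex_lens[j])))
                    pos += int(ex_lens[j])
                    if j < n_ex - 1:
                        pos += int(in_lens[j])
                strand = "+" if rng.random() < 0.5 else "-"
                genes.append(GeneModel(f"g{gid:05d}", name, strand, tuple(exons)))
                gid += 1
                placed += 1
                cursor = start + span
    genome = ReferenceGenome(chroms, genes)
    genome.validate()
    return genome


# ---------------------------------------------------------------------------
# Parental divergence
# ---------------------------------------------------------------------------

def _exon_edge_forbidden(genes: Sequence[GeneModel], chrom: str,
                         margin: int = 3) -> list[tuple[int, int]]:
    """Windows around splice boundaries where indels are not placed."""
    zones = []
    for g in genes:
        if g.chrom != chrom:
            continue
        for s, e in g.exons:
            zones.append((s - margin, s + margin))
            zones.append((e - margin, e + margin))
    return sorted(zones)


def _in_zones(pos_lo: int, pos_hi: int, zones: list[tuple[int, int]]) -> bool:
    import bisect
    i = bisect.bisect_left(zones, (pos_hi, pos_hi)) if zones else 0
    for j in range(max(0, i - 2), min(len(zones), i + 2)):
        lo, hi = zones[j]
        if pos_lo < hi and lo < pos_hi:
            return True
    return False


def diverge_genome(base: ReferenceGenome, snp_rate: float, indel_rate: float,
                   seed: int | np.random.Generator) -> tuple[ReferenceGenome, VariantSet]:
    """Derive one parental genome from the base by random SNPs and indels.

    SNP count per chromosome is Binomial(length, ``snp_rate``); indels
    (length 1-5, insertions and deletions equally likely) are kept away from
    the first/last 3 bases of every exon so annotation lift-over across
    splice sites stays exact. Returns the diverged genome (with lifted gene
    models and coordinate map) and the variant set relative to the base;
    re-applying the variants to the base reproduces the parent exactly.
    """
    from .pseudogenome import substitute  # deferred: avoids module cycle

    if not (0.0 <= snp_rate <= 1.0 and 0.0 <= indel_rate <= 1.0):
        raise ValueError("rates must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)
    variants: list[Variant] = []
    for chrom, seq in base.chromosomes.items():
        length = len(seq)
        n_snp = rng.binomial(length, snp_rate) if snp_rate > 0 else 0
        snp_pos = set()
        if n_snp:
            snp_pos = set(map(int, rng.choice(length, size=n_snp, replace=False)))
            for p in sorted(snp_pos):
                ref = seq[p]
                alt = ref
                while alt == ref:
                    alt = "ACGT"[rng.integers(4)]
                variants.append(Variant(chrom, p, ref, alt))
        n_indel = rng.binomial(length, indel_rate) if indel_rate > 0 else 0
        if n_indel:
            zones = _exon_edge_forbidden(base.genes, chrom)
            used: set[int] = set()
            for _ in range(n_indel):
                for _attempt in range(50):
                    p = int(rng.integers(0, length - 10))
                    ilen = int(rng.integers(1, 6))
                    span = range(p, p + ilen + 1)
                    if any(q in used or q in snp_pos for q in span):
                        continue
                    if _in_zones(p, p + ilen + 1, zones):
                        continue
                    break
                else:
                    continue
                used.update(span)
                if rng.random() < 0.5 and p + 1 + ilen <= length:  # deletion
                    variants.append(Variant(chrom, p, seq[p : p + 1 + ilen], seq[p]))
                else:  # insertion
                    ins = "".join("ACGT"[rng.integers(4)] for _ in range(ilen))
                    variants.append(Variant(chrom, p, seq[p], seq[p] + ins))
    vset = VariantSet(variants)
    parent, report = substitute(base, vset)
    if report.conflicts:
        raise RuntimeError("simulated variants should never conflict")
    return parent, vset


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

@dataclass
class ExpressionTruth:
    """Expected fragment counts per homeolog per time point, plus the gene
    class labels the variability analysis should recover."""

    expected: pd.DataFrame  # rows "gene|A" / "gene|R", columns = hours
    gene_class: dict[str, str]


def _class_profile(cls: str, times: np.ndarray, config: SimulationConfig,
                   phase: float) -> np.ndarray:
    if cls == "constant":
        return np.ones_like(times)
    if cls == "induced":
        # monotone ramp in log2 space peaking at the last time point:
        # max/min expected count ratio is exactly 2**induced_log2fc
        return 2.0 ** (config.induced_log2fc * times / times[-1])
    if cls == "oscillating":
        w = 2.0 * np.pi / config.oscillation_period_h
        return 2.0 ** (config.oscillation_log2_amplitude
                       * np.sin(w * (times - phase)))
    raise ValueError(f"unknown gene class {cls!r}")


def simulate_expression(genome: ReferenceGenome,
                        config: SimulationConfig) -> ExpressionTruth:
    """Expected fragment counts for every homeolog at every time point.

    Baseline expectation for one subgenome copy is ``depth`` fragments per
    transcript kilobase; the A and R rows of a pair share the gene's class
    profile and differ only by the configured copy numbers, so before noise
    the R:A expectation ratio equals the dosage ratio at every time point.
    """
    rng = config.rng(2)
    times = np.asarray(config.time_points_h, dtype=float)
    classes = list(config.gene_class_fractions)
    probs = np.array([config.gene_class_fractions[c] for c in classes])
    rows, data = [], []
    gene_class: dict[str, str] = {}
    for g in genome.genes:
        cls = classes[int(rng.choice(len(classes), p=probs))]
        phase = float(rng.uniform(0.0, config.oscillation_period_h))
        gene_class[g.gene_id] = cls
        profile = _class_profile(cls, times, config, phase)
        base_mu = config.depth * (g.length / 1000.0)
        for label, copies in zip(("A", "R"), config.dosage):
            rows.append(f"{g.gene_id}|{label}")
            data.append(copies * base_mu * profile)
    expected = pd.DataFrame(
        np.array(data) if data else np.empty((0, len(times))),
        index=rows, columns=times,
    )
    return ExpressionTruth(expected, gene_class)


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

@dataclass
class SimFragment:
    """One paired-end fragment with its hidden origin."""

    frag_id: str
    seq1: str
    seq2: str
    qual1: str
    qual2: str
    origin: str  # subgenome label
    gene: str


def _inject_errors(seq: str, rng: np.random.Generator, rate: float,
                   mark: bool) -> tuple[str, str]:
    qual = "I" * len(seq)
    if rate <= 0.0:
        return seq, qual
    mask = rng.random(len(seq)) < rate
    if not mask.any():
        return seq, qual
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    qarr = np.frombuffer(qual.encode(), dtype=np.uint8).copy()
    for i in np.nonzero(mask)[0]:
        old = arr[i]
        new = old
        while new == old:
            new = BASES[rng.integers(4)]
        arr[i] = new
        if mark:
            qarr[i] = ord("#")
    return arr.tobytes().decode(), qarr.tobytes().decode()


def simulate_fragments(parents: Mapping[str, ReferenceGenome],
                       expected: pd.Series, config: SimulationConfig,
                       rng: np.random.Generator,
                       id_prefix: str = "frag") -> list[SimFragment]:
    """Draw sequenced fragments for one sample.

    ``expected`` is indexed by homeolog id ``gene|label``; the per-homeolog
    fragment count is Poisson around the expectation (gamma-Poisson when the
    dispersion knob is on). Fragments are placed uniformly on the spliced
    transcript of the homeolog's own parental genome; mate 1 reads the
    fragment's 5' end forward, mate 2 the 3' end on the opposite strand.
    Homeologs whose transcript is shorter than the read length are skipped
    with a warning.
    """
    fragments: list[SimFragment] = []
    transcripts: dict[str, str] = {}
    rl = config.read_length
    serial = 0
    for hid in expected.index:
        mu = float(expected.loc[hid])
        gene, label = hid.rsplit("|", 1)
        if mu <= 0.0:
            continue
        if hid not in transcripts:
            transcripts[hid] = parents[label].transcript(gene)
        tseq = transcripts[hid]
        if len(tseq) < rl:
            logger.warning("transcript %s (%d bp) shorter than read length; "
                           "skipped", hid, len(tseq))
            continue
        if config.dispersion > 0.0:
            lam = rng.gamma(1.0 / config.dispersion, config.dispersion * mu)
            n = int(rng.poisson(lam))
        else:
            n = int(rng.poisson(mu))
        if n == 0:
            continue
        tlen = len(tseq)
        flens = np.clip(
            np.rint(rng.normal(config.fragment_length_mean,
                               config.fragment_length_sd, size=n)).astype(int),
            rl, tlen,
        )
        starts = (rng.random(n) * (tlen - flens + 1)).astype(int)
        for flen, start in zip(flens, starts):
            frag = tseq[start : start + flen]
            r1 = frag[:rl]
            r2 = revcomp(frag[-rl:])
            r1, q1 = _inject_errors(r1, rng, config.error_rate,
                                    config.mark_error_quals)
            r2, q2 = _inject_errors(r2, rng, config.error_rate,
                                    config.mark_error_quals)
            fragments.append(SimFragment(f"{id_prefix}{serial:07d}",
                                         r1, r2, q1, q2, label, gene))
            serial += 1
    return fragments


def write_fastq(fragments: Iterable[SimFragment], path_r1: str | Path,
                path_r2: str | Path) -> None:
    """Write a fragment list as a phred+33 FASTQ pair."""
    with open(path_r1, "w") as f1, open(path_r2, "w") as f2:
        for fr in fragments:
            f1.write(f"@{fr.frag_id}/1\n{fr.seq1}\n+\n{fr.qual1}\n")
            f2.write(f"@{fr.frag_id}/2\n{fr.seq2}\n+\n{fr.qual2}\n")


def read_fastq_pair(path_r1: str | Path, path_r2: str | Path
                    ) -> list[tuple[str, str, str]]:
    """Load a FASTQ pair as ``(fragment_id, seq1, seq2)`` tuples."""
    import pysam

    out = []
    with pysam.FastxFile(str(path_r1)) as f1, \
            pysam.FastxFile(str(path_r2)) as f2:
        for e1, e2 in zip(f1, f2):
            fid = e1.name.rsplit("/", 1)[0]
            out.append((fid, e1.sequence, e2.sequence))
    return out


def simulate_sample_reads(parents: Mapping[str, ReferenceGenome],
                          expression: ExpressionTruth,
                          config: SimulationConfig, time_point: float,
                          sample_tag: int,
                          id_prefix: str | None = None) -> list[SimFragment]:
    """Fragments for one (sample, time point), deterministically seeded."""
    rng = config.rng(3, sample_tag, int(time_point * 1000))
    prefix = id_prefix if id_prefix is not None else \
        f"s{sample_tag}_t{time_point:g}_"
    return simulate_fragments(parents, expression.expected[time_point],
                              config, rng, id_prefix=prefix)


def simulate_reads(parents: Mapping[str, ReferenceGenome],
                   expression: ExpressionTruth, config: SimulationConfig,
                   out_dir: str | Path, sample_name: str = "sample",
                   sample_tag: int = 0
                   ) -> tuple[dict[float, tuple[Path, Path]], GroundTruth]:
    """Simulate the full time course for one sample set and write FASTQ.

    One FASTQ pair per time point; returns the file map and a
    :class:`GroundTruth` holding each fragment's origin and gene, the
    expected-count matrix and the gene class labels.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[float, tuple[Path, Path]] = {}
    origin: dict[str, str] = {}
    gene_of: dict[str, str] = {}
    for t in config.time_points_h:
        frags = simulate_sample_reads(parents, expression, config, t,
                                      sample_tag,
                                      id_prefix=f"{sample_name}_t{t:g}_")
        r1 = out_dir / f"{sample_name}_t{t:g}_R1.fastq"
        r2 = out_dir / f"{sample_name}_t{t:g}_R2.fastq"
        write_fastq(frags, r1, r2)
        paths[t] = (r1, r2)
        for fr in frags:
            origin[fr.frag_id] = fr.origin
            gene_of[fr.frag_id] = fr.gene
    truth = GroundTruth(
        true_variants={}, true_origin=origin, true_gene=gene_of,
        true_expression=expression.expected,
        veh_truth=dict(expression.gene_class),
    )
    truth.validate()
    return paths, truth


# ---------------------------------------------------------------------------
# Synthetic category hierarchies (for enrichment testing)
# ---------------------------------------------------------------------------

def simulate_category_hierarchy(gene_ids: Sequence[str], n_categories: int = 120,
                                max_depth: int = 5,
                                size_range: tuple[int, int] = (5, 600),
                                seed: int | np.random.Generator = 0):
    """Random category DAG with member gene sets, GO-like in shape.

    Categories are assigned levels 1..``max_depth`` (level 1 = the single
    root); each non-root category draws one or two parents from shallower
    levels. Member sets are sampled independently per category with sizes
    log-uniform over ``size_range`` (clipped to the universe), which is all
    the structure the over-representation machinery consumes.
    Returns ``(categories, edges)`` with edges as (child, parent) pairs.
    """
    from .enrichment import CategoryAnnotation

    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)
    gene_ids = list(gene_ids)
    lo, hi = size_range
    hi = min(hi, len(gene_ids))
    cats: list[CategoryAnnotation] = []
    edges: list[tuple[str, str]] = []
    levels: dict[int, list[str]] = {1: ["CAT:0000"]}
    cats.append(CategoryAnnotation("CAT:0000", "root", 1,
                                   frozenset(gene_ids)))
    for i in range(1, n_categories):
        cid = f"CAT:{i:04d}"
        level = int(rng.integers(2, max_depth + 1))
        while level - 1 not in levels:
            level -= 1
        parents = rng.choice(levels[level - 1],
                             size=min(len(levels[level - 1]),
                                      int(rng.integers(1, 3))),
                             replace=False)
        size = int(np.exp(rng.uniform(np.log(lo), np.log(hi + 1))))
        size = max(1, min(size, len(gene_ids)))
        members = frozenset(
            gene_ids[j] for j in rng.choice(len(gene_ids), size=size,
                                            replace=False)
        )
        cats.append(CategoryAnnotation(cid, f"category {i}", level, members))
        levels.setdefault(level, []).append(cid)
        for p in parents:
            edges.append((cid, str(p)))
    return cats, edges
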