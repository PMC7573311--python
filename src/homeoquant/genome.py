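"""Core genomic containers shared across the pipeline.

A :class:`ReferenceGenome` bundles chromosome sequences with gene models and a
piecewise-linear coordinate map back to the base reference it was derived
from. :class:`VariantSet` records substitutions and short indels between two
such genomes. FASTA I/O goes through Biopython; the gene models are written
and read as a small GFF3 subset (gene/mRNA/exon features, 1-based inclusive
coordinates, ID/Parent attributes). Internally all coordinates are 0-based
half-open.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """One gene: chromosome, strand and ordered exon intervals.

    Exons are 0-based half-open ``(start, end)`` tuples, sorted and
    non-overlapping. The spliced transcript is the concatenation of exon
    sequences in genomic order, reverse-complemented for '-' strand genes.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        prev_end = -1
        for start, end in self.exons:
            if not (0 <= start < end):
                raise ValueError(f"bad exon ({start}, {end}) in {self.gene_id}")
            if start < prev_end:
                raise ValueError(f"overlapping/unsorted exons in {self.gene_id}")
            prev_end = end

    @property
    def length(self) -> int:
        """Summed exon length (spliced transcript length)."""
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def shifted(self, new_exons: Iterable[tuple[int, int]]) -> "GeneModel":
        return replace(self, exons=tuple(new_exons))


# ---------------------------------------------------------------------------
# Coordinate maps
# ---------------------------------------------------------------------------

@dataclass
class CoordinateMap:
    """Monotone piecewise shift from current coordinates to base coordinates.

    For each chromosome we keep parallel sorted lists of segment starts (in
    the *current* frame) and the shift to add to land in the base frame:
    ``base = pos + delta[i]`` for the segment containing ``pos``. Positions
    inserted relative to the base map to the nearest upstream base position,
    so the map is monotone but not necessarily injective.
    """

    starts: dict[str, list[int]] = field(default_factory=dict)
    deltas: dict[str, list[int]] = field(default_factory=dict)

    @classmethod
    def identity(cls, chroms: Iterable[str]) -> "CoordinateMap":
        return cls({c: [0] for c in chroms}, {c: [0] for c in chroms})

    def to_base(self, chrom: str, pos: int) -> int:
        starts = self.starts[chrom]
        i = bisect.bisect_right(starts, pos) - 1
        if i < 0:
            i = 0
        return pos + self.deltas[chrom][i]

    def compose(self, inner: "CoordinateMap") -> "CoordinateMap":
        """Map current -> base where ``self`` maps current -> mid and
        ``inner`` maps mid -> base."""
        out = CoordinateMap()
        for chrom in self.starts:
            starts, deltas = [], []
            s1, d1 = self.starts[chrom], self.deltas[chrom]
            s2 = inner.starts.get(chrom, [0])
            for i, (start, delta) in enumerate(zip(s1, d1)):
                end = s1[i + 1] if i + 1 < len(s1) else None
                # breakpoints of the inner map falling inside this segment's
                # image pull back to current-frame breakpoints
                cuts = {start}
                for b2 in s2:
                    cur = b2 - delta
                    if cur > start and (end is None or cur < end):
                        cuts.add(cur)
                for cut in sorted(cuts):
                    mid = cut + delta
                    total = delta + inner.deltas[chrom][
                        max(0, bisect.bisect_right(s2, mid) - 1)
                    ]
                    if not starts or total != deltas[-1]:
                        starts.append(cut)
                        deltas.append(total)
            if starts and starts[0] != 0:
                starts.insert(0, 0)
                deltas.insert(0, deltas[0])
            out.starts[chrom] = starts or [0]
            out.deltas[chrom] = deltas or [0]
        return out

    def check_monotone(self) -> None:
        for chrom, starts in self.starts.items():
            prev = None
            for i, s in enumerate(starts):
                b = s + self.deltas[chrom][i]
                if prev is not None and b < prev:
                    raise ValueError(f"coordinate map not monotone on {chrom}")
                prev = b


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Variant:
    """One substitution or short indel, VCF-style anchored, 0-based.

    SNP when both alleles have length 1; otherwise an indel. ``ref`` must
    match the genome the variant is called against at ``pos``.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    alt_depth: int = 0
    total_depth: int = 0

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("alleles must be non-empty")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        if self.alt_depth > self.total_depth:
            raise ValueError("alt_depth exceeds total_depth")

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def length_change(self) -> int:
        return len(self.alt) - len(self.ref)


class VariantSet:
    """An ordered collection of :class:`Variant` records."""

    def __init__(self, variants: Iterable[Variant] = ()) -> None:
        self.variants: list[Variant] = sorted(
            variants, key=lambda v: (v.chrom, v.pos)
        )

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self) -> Iterator[Variant]:
        return iter(self.variants)

    def __getitem__(self, i):
        return self.variants[i]

    @property
    def snps(self) -> "VariantSet":
        return VariantSet(v for v in self if v.is_snp)

    @property
    def indels(self) -> "VariantSet":
        return VariantSet(v for v in self if not v.is_snp)

    def validate_against(self, genome: "ReferenceGenome") -> None:
        for v in self:
            if v.chrom not in genome.chromosomes:
                raise ValueError(f"variant on unknown chromosome {v.chrom}")
            seq = genome.chromosomes[v.chrom]
            if seq[v.pos : v.pos + len(v.ref)] != v.ref:
                raise ValueError(
                    f"ref allele mismatch at {v.chrom}:{v.pos} "
                    f"({v.ref!r} vs genome {seq[v.pos:v.pos + len(v.ref)]!r})"
                )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tpos\tref\talt\talt_depth\ttotal_depth\n")
            for v in self:
                fh.write(
                    f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t"
                    f"{v.alt_depth}\t{v.total_depth}\n"
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "VariantSet":
        out = []
        with open(path) as fh:
            header = fh.readline()
            assert header.startswith("chrom")
            for line in fh:
                c, p, r, a, ad, td = line.rstrip("\n").split("\t")
                out.append(Variant(c, int(p), r, a, int(ad), int(td)))
        return cls(out)


# ---------------------------------------------------------------------------
# Reference genome
# ---------------------------------------------------------------------------

@dataclass
class ReferenceGenome:
    """Chromosome sequences plus gene models and a map back to the base
    reference.

    ``coordinate_map`` is ``None`` for a base genome (identity). Derived
    genomes (divergence simulation, pseudo-genome assembly) carry the
    composed map so any position can be traced to base coordinates.
    """

    chromosomes: dict[str, str]
    genes: list[GeneModel] = field(default_factory=list)
    coordinate_map: CoordinateMap | None = None

    def __post_init__(self) -> None:
        self._by_id = {g.gene_id: g for g in self.genes}

    def gene(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def total_length(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())

    def validate(self) -> None:
        for g in self.genes:
            if g.chrom not in self.chromosomes:
                raise ValueError(f"{g.gene_id} on unknown chromosome {g.chrom}")
            if g.span[1] > len(self.chromosomes[g.chrom]):
                raise ValueError(f"{g.gene_id} extends past chromosome end")
        if self.coordinate_map is not None:
            self.coordinate_map.check_monotone()

    def transcript(self, gene: GeneModel | str) -> str:
        """Spliced transcript sequence, strand-corrected."""
        if isinstance(gene, str):
            gene = self.gene(gene)
        seq = self.chromosomes[gene.chrom]
        spliced = "".join(seq[s:e] for s, e in gene.exons)
        return revcomp(spliced) if gene.strand == "-" else spliced

    def gene_lengths(self) -> dict[str, int]:
        return {g.gene_id: g.length for g in self.genes}

    # -- I/O ---------------------------------------------------------------

    def write_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.chromosomes.items()
        ]
        SeqIO.write(records, str(path), "fasta")

    def write_gff3(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for name, seq in self.chromosomes.items():
                fh.write(f"##sequence-region {name} 1 {len(seq)}\n")
            for g in self.genes:
                start, end = g.span
                base = f"{g.chrom}\thomeoquant\t"
                tail = f"\t.\t{g.strand}\t.\t"
                fh.write(
                    f"{base}gene\t{start + 1}\t{end}{tail}ID={g.gene_id}\n"
                )
                mrna = f"{g.gene_id}.t1"
                fh.write(
                    f"{base}mRNA\t{start + 1}\t{end}{tail}"
                    f"ID={mrna};Parent={g.gene_id}\n"
                )
                for i, (s, e) in enumerate(g.exons, 1):
                    fh.write(
                        f"{base}exon\t{s + 1}\t{e}{tail}"
                        f"ID={mrna}.exon{i};Parent={mrna}\n"
                    )

    @classmethod
    def from_files(cls, fasta: str | Path, gff3: str | Path | None = None
                   ) -> "ReferenceGenome":
        chroms = {
            rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(fasta), "fasta")
        }
        genes = read_gff3(gff3) if gff3 is not None else []
        return cls(chroms, genes)


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse the gene/mRNA/exon GFF3 subset written by this package."""
    gene_meta: dict[str, tuple[str, str]] = {}
    mrna_gene: dict[str, str] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                continue
            chrom, _, ftype, start, end, _, strand, _, attrs = cols
            a = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "gene":
                gene_meta[a["ID"]] = (chrom, strand)
                order.append(a["ID"])
            elif ftype == "mRNA":
                mrna_gene[a["ID"]] = a["Parent"]
            elif ftype == "exon":
                gid = mrna_gene.get(a["Parent"], a["Parent"])
                exons.setdefault(gid, []).append((int(start) - 1, int(end)))
    return [
        GeneModel(gid, gene_meta[gid][0], gene_meta[gid][1],
                  tuple(sorted(exons.get(gid, []))))
        for gid in order
    ]
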