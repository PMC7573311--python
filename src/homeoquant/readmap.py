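"""Lightweight read mapping against a spliced-transcript index.

The divergence between the parental genomes and the reads is small (sub-1%
SNP-level), so exact k-mer seeding plus ungapped extension recovers the
minimal-mismatch placement reliably. Reads are matched against the spliced
transcripts built from the gene models and every hit is projected back to
genome coordinates, so downstream consumers see genomic placements with
intron gaps. Externally produced SAM (from any spliced aligner) can be read
back into the same :class:`AlignmentRecord` stream for the real-data path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pysam

from .genome import ReferenceGenome, revcomp

DEFAULT_SEED_K = 21
DEFAULT_MAX_MISMATCHES = 8

# uint8 complement lookup for transcript->genome base conversion
_COMP = np.arange(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTacgt", b"TGCAtgca"):
    _COMP[_a] = _b


@dataclass
class AlignmentRecord:
    """One mate's best placement on one genome.

    ``blocks`` are genomic 0-based half-open intervals in ascending order
    (more than one when the alignment spans an intron). ``mismatches`` is the
    Hamming distance at the placement; ties among equally good placements set
    ``multimapped`` and report the leftmost.
    """

    fragment: str
    mate: int
    genome_label: str
    mapped: bool
    chrom: str | None = None
    start: int | None = None
    span: int = 0
    strand: str | None = None
    blocks: tuple[tuple[int, int], ...] = ()
    mismatches: int | None = None
    multimapped: bool = False
    gene: str | None = None

    def __post_init__(self) -> None:
        if self.mapped and self.mismatches is not None \
                and self.mismatches > self.span:
            raise ValueError("mismatch count exceeds alignment span")


@dataclass
class MapHit:
    """Internal transcript-space placement (pre-projection)."""

    ti: int
    tstart: int
    orient: str  # 'F': read as given matches transcript; 'R': its revcomp
    mismatches: int
    multimapped: bool


class TranscriptIndex:
    """Exact k-mer index over the spliced transcripts of a genome."""

    def __init__(self, genome: ReferenceGenome, k: int = DEFAULT_SEED_K,
                 max_hits_per_kmer: int = 64) -> None:
        self.genome = genome
        self.k = k
        self.names: list[str] = []
        self.seqs: list[np.ndarray] = []
        self.t2g: list[np.ndarray] = []
        self.chroms: list[str] = []
        self.strands: list[str] = []
        self._kmers: dict[bytes, list[tuple[int, int]]] = {}
        for g in genome.genes:
            seq = genome.transcript(g)
            gpos = np.concatenate([np.arange(s, e) for s, e in g.exons])
            if g.strand == "-":
                gpos = gpos[::-1]
            self.names.append(g.gene_id)
            self.seqs.append(np.frombuffer(seq.encode(), dtype=np.uint8))
            self.t2g.append(np.ascontiguousarray(gpos))
            self.chroms.append(g.chrom)
            self.strands.append(g.strand)
        for ti, arr in enumerate(self.seqs):
            raw = arr.tobytes()
            for i in range(len(raw) - k + 1):
                key = raw[i : i + k]
                hits = self._kmers.setdefault(key, [])
                if len(hits) < max_hits_per_kmer:
                    hits.append((ti, i))

    # -- core mapping ------------------------------------------------------

    def map_sequence(self, seq: str,
                     max_mismatches: int = DEFAULT_MAX_MISMATCHES
                     ) -> MapHit | None:
        """Minimal-mismatch ungapped placement of ``seq``, or None.

        Seeds at stride ``k`` plus the read's tail in both orientations;
        every seeded candidate is scored by full Hamming comparison. Ties on
        distinct genomic placements are flagged multimapped and resolved to
        the leftmost genomic coordinate for reproducibility.
        """
        k = self.k
        length = len(seq)
        if length < k:
            return None
        best_mm = max_mismatches + 1
        best: list[tuple[str, int, MapHit]] = []
        seen_placements: set[tuple[str, int, str]] = set()
        for orient, s in (("F", seq), ("R", revcomp(seq))):
            raw = s.encode()
            arr = np.frombuffer(raw, dtype=np.uint8)
            offsets = list(range(0, length - k + 1, k))
            if offsets[-1] != length - k:
                offsets.append(length - k)
            cands: set[tuple[int, int]] = set()
            for o in offsets:
                for ti, tpos in self._kmers.get(raw[o : o + k], ()):
                    cands.add((ti, tpos - o))
            for ti, st in cands:
                tarr = self.seqs[ti]
                if st < 0 or st + length > tarr.shape[0]:
                    continue
                mm = int(np.count_nonzero(tarr[st : st + length] != arr))
                if mm > max_mismatches or mm > best_mm:
                    continue
                gleft = int(min(self.t2g[ti][st], self.t2g[ti][st + length - 1]))
                key = (self.chroms[ti], gleft, orient)
                if mm < best_mm:
                    best_mm = mm
                    best = [(self.chroms[ti], gleft,
                             MapHit(ti, st, orient, mm, False))]
                    seen_placements = {key}
                elif key not in seen_placements:
                    seen_placements.add(key)
                    best.append((self.chroms[ti], gleft,
                                 MapHit(ti, st, orient, mm, False)))
        if not best:
            return None
        best.sort(key=lambda t: (t[0], t[1]))
        hit = best[0][2]
        hit.multimapped = len(best) > 1
        return hit

    # -- projection --------------------------------------------------------

    def genome_positions(self, hit: MapHit, length: int) -> np.ndarray:
        """Genomic position of every aligned base, in transcript order."""
        return self.t2g[hit.ti][hit.tstart : hit.tstart + length]

    def to_record(self, hit: MapHit | None, fragment: str, mate: int,
                  label: str, length: int) -> AlignmentRecord:
        if hit is None:
            return AlignmentRecord(fragment, mate, label, mapped=False)
        gpos = self.genome_positions(hit, length)
        asc = np.sort(gpos)
        breaks = np.nonzero(np.diff(asc) != 1)[0]
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [asc.shape[0] - 1]))
        blocks = tuple(
            (int(asc[s]), int(asc[e]) + 1) for s, e in zip(starts, ends)
        )
        tstrand = self.strands[hit.ti]
        if hit.orient == "F":
            gstrand = tstrand
        else:
            gstrand = "-" if tstrand == "+" else "+"
        return AlignmentRecord(
            fragment=fragment, mate=mate, genome_label=label, mapped=True,
            chrom=self.chroms[hit.ti], start=blocks[0][0], span=length,
            strand=gstrand, blocks=blocks, mismatches=hit.mismatches,
            multimapped=hit.multimapped, gene=self.names[hit.ti],
        )


def map_reads(reads: Iterable[tuple[str, str, str]],
              genome: ReferenceGenome | TranscriptIndex,
              label: str = "A",
              max_mismatches: int = DEFAULT_MAX_MISMATCHES,
              k: int = DEFAULT_SEED_K
              ) -> dict[str, tuple[AlignmentRecord, AlignmentRecord]]:
    """Map read pairs ``(fragment_id, seq1, seq2)`` onto one genome.

    Returns a mate pair of :class:`AlignmentRecord` per fragment; unmappable
    mates are present with ``mapped=False``.
    """
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    index = genome if isinstance(genome, TranscriptIndex) \
        else TranscriptIndex(genome, k=k)
    out: dict[str, tuple[AlignmentRecord, AlignmentRecord]] = {}
    for fid, s1, s2 in reads:
        recs = []
        for mate, s in ((1, s1), (2, s2)):
            hit = index.map_sequence(s, max_mismatches)
            recs.append(index.to_record(hit, fid, mate, label, len(s)))
        out[fid] = (recs[0], recs[1])
    return out


# ---------------------------------------------------------------------------
# Optional read filtering (stand-in for external quality trimming)
# ---------------------------------------------------------------------------

def filter_read_pairs(reads: Sequence[tuple[str, str, str]],
                      min_length: int = 50) -> list[tuple[str, str, str]]:
    """Drop pairs with either mate shorter than ``min_length`` bases."""
    return [r for r in reads if len(r[1]) >= min_length and len(r[2]) >= min_length]


# ---------------------------------------------------------------------------
# SAM I/O
# ---------------------------------------------------------------------------

def _cigar(blocks: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    ops = []
    for i, (s, e) in enumerate(blocks):
        if i:
            gap = s - blocks[i - 1][1]
            ops.append((3, gap))  # N
        ops.append((0, e - s))  # M
    return ops


def write_sam(records: Iterable[AlignmentRecord], genome: ReferenceGenome,
              path: str | Path) -> None:
    """Write alignment records as SAM with NM tags (mismatch counts)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": len(seq)}
               for name, seq in genome.chromosomes.items()],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec.fragment
            flag = 0x1 | (0x40 if rec.mate == 1 else 0x80)
            if not rec.mapped:
                a.flag = flag | 0x4
                out.write(a)
                continue
            if rec.strand == "-":
                flag |= 0x10
            a.flag = flag
            a.reference_name = rec.chrom
            a.reference_start = rec.start
            a.mapping_quality = 0 if rec.multimapped else 60
            a.cigartuples = _cigar(rec.blocks)
            a.set_tag("NM", int(rec.mismatches))
            out.write(a)


def read_sam(path: str | Path, label: str = "A"
             ) -> dict[str, tuple[AlignmentRecord | None, AlignmentRecord | None]]:
    """Load a SAM file (any aligner) into per-fragment mate records.

    Only primary alignments are kept; the NM tag supplies the mismatch
    count (0 if absent). Returns fragment id -> (mate1, mate2).
    """
    frags: dict[str, list[AlignmentRecord | None]] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for a in fh:
            if a.is_secondary or a.is_supplementary:
                continue
            mate = 2 if a.is_read2 else 1
            slot = frags.setdefault(a.query_name, [None, None])
            if a.is_unmapped:
                rec = AlignmentRecord(a.query_name, mate, label, mapped=False)
            else:
                blocks = tuple(a.get_blocks())
                span = sum(e - s for s, e in blocks)
                rec = AlignmentRecord(
                    fragment=a.query_name, mate=mate, genome_label=label,
                    mapped=True, chrom=a.reference_name,
                    start=a.reference_start,
                    span=span, strand="-" if a.is_reverse else "+",
                    blocks=blocks,
                    mismatches=int(a.get_tag("NM")) if a.has_tag("NM") else 0,
                    multimapped=a.mapping_quality == 0,
                )
            slot[mate - 1] = rec
    return {fid: (m1, m2) for fid, (m1, m2) in frags.items()}
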