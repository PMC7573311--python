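"""Dosage-aware homeolog quantification.

Classified fragments are counted fractionally per gene (a fragment
overlapping k gene models contributes 1/k to each), giving per-homeolog
A-origin, R-origin and unclassified counts a, r, u. The A-origin ratio
p = a/(a+r) then reallocates the unclassified mass, a' = a + u*p and
r' = r + u*(1-p), which conserves a'+r' = a+r+u exactly. FPKM for the
polyploid subgenome samples uses the allocated counts with homeolog lengths
taken on each subgenome's own pseudo-genome, 1e9 * a' / (L_A * A_s) with
A_s the sample's post-allocation A-origin total (so sum_h FPKM_h * L_h is
exactly 1e9); progenitor samples use the total count a+u+r with their own
genome's lengths. The per-homeolog ratio distribution and its mode summarise
whether expression follows subgenome dosage (1:2 gives a peak at 1/3).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .classify import (DISCARDED, ORIGIN_A, ORIGIN_R, UNCLASSIFIED,
                       ClassifiedFragment)
from .genome import ReferenceGenome

logger = logging.getLogger(__name__)

CONSERVATION_TOL = 1e-9


# ---------------------------------------------------------------------------
# Fractional counting
# ---------------------------------------------------------------------------

def gene_interval_index(genome: ReferenceGenome) -> dict[str, IntervalTree]:
    """Exon interval trees per chromosome, mapping to gene ids."""
    trees: dict[str, IntervalTree] = {c: IntervalTree()
                                      for c in genome.chromosomes}
    for g in genome.genes:
        for s, e in g.exons:
            trees[g.chrom][s:e] = g.gene_id
    return trees


def _overlapping_genes(frag: ClassifiedFragment, which: str,
                       trees: dict[str, IntervalTree]) -> set[str]:
    pair = frag.aln_A if which == "A" else frag.aln_R
    genes: set[str] = set()
    for rec in pair:
        if rec is None or not rec.mapped:
            continue
        if rec.chrom not in trees:
            raise ValueError(
                f"placement on unknown chromosome {rec.chrom}")
        for s, e in rec.blocks:
            for iv in trees[rec.chrom].overlap(s, e):
                genes.add(iv.data)
    return genes


@dataclass
class HomeologCountTable:
    """Per-homeolog fractional counts and homeolog lengths for one sample.

    ``counts`` holds columns a, r, u indexed by gene id; ``lengths`` holds
    the summed exon length of each homeolog on the A and R genomes.
    """

    counts: pd.DataFrame
    lengths: pd.DataFrame

    def to_tsv(self, path: str | Path) -> None:
        df = self.counts.join(self.lengths)
        df = with_allocation(df)
        df.to_csv(path, sep="\t", index_label="homeolog")


def count_fragments(classified: Iterable[ClassifiedFragment],
                    genome_A: ReferenceGenome, genome_R: ReferenceGenome,
                    unclassified_on: str = "R") -> HomeologCountTable:
    """Fractionally count classified fragments per homeolog.

    A-origin fragments are resolved to genes on the A genome, R-origin on
    the R genome; unclassified fragments use their placement on the
    ``unclassified_on`` genome (the majority subgenome by default), falling
    back to the other genome when unmapped there. Each fragment contributes
    total weight 1, split 1/k over the k gene models it overlaps; fragments
    overlapping no gene contribute nothing.
    """
    if unclassified_on not in ("A", "R"):
        raise ValueError("unclassified_on must be 'A' or 'R'")
    trees = {"A": gene_interval_index(genome_A),
             "R": gene_interval_index(genome_R)}
    gene_ids = sorted(set(genome_A.gene_ids) | set(genome_R.gene_ids))
    acc = {col: {g: 0.0 for g in gene_ids} for col in ("a", "r", "u")}
    for frag in classified:
        if frag.origin == DISCARDED:
            continue
        if frag.origin == ORIGIN_A:
            which, col = "A", "a"
        elif frag.origin == ORIGIN_R:
            which, col = "R", "r"
        else:
            col = "u"
            which = unclassified_on
            if not _mapped_on(frag, which):
                which = "A" if which == "R" else "R"
        genes = _overlapping_genes(frag, which, trees[which])
        if not genes:
            continue
        w = 1.0 / len(genes)
        for g in genes:
            acc[col][g] = acc[col].get(g, 0.0) + w
    counts = pd.DataFrame(acc).reindex(gene_ids).fillna(0.0)
    len_A = pd.Series(genome_A.gene_lengths(), dtype=float)
    len_R = pd.Series(genome_R.gene_lengths(), dtype=float)
    lengths = pd.DataFrame({"L_A": len_A, "L_R": len_R}).reindex(gene_ids)
    return HomeologCountTable(counts, lengths)


def _mapped_on(frag: ClassifiedFragment, which: str) -> bool:
    pair = frag.aln_A if which == "A" else frag.aln_R
    return any(r is not None and r.mapped for r in pair)


# ---------------------------------------------------------------------------
# A-origin ratio and allocation
# ---------------------------------------------------------------------------

def a_origin_ratio(a, r):
    """p = a / (a + r); NaN marks the undefined case a + r = 0."""
    a = np.asarray(a, dtype=float)
    r = np.asarray(r, dtype=float)
    if (a < 0).any() or (r < 0).any():
        raise ValueError("counts must be non-negative")
    total = a + r
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(total > 0, a / np.where(total > 0, total, 1.0), np.nan)
    return float(p) if p.ndim == 0 else p


def allocate_unclassified(a, r, u, p=None, fallback_p: float = 0.5):
    """Reallocate unclassified counts: a' = a + u*p, r' = r + u*(1-p).

    Where p is undefined (no classified fragments but u > 0) the fallback
    ratio splits the mass evenly by default and the homeolog is flagged.
    Returns ``(a_alloc, r_alloc, fallback_used)``.
    """
    a = np.asarray(a, dtype=float)
    r = np.asarray(r, dtype=float)
    u = np.asarray(u, dtype=float)
    if (u < 0).any():
        raise ValueError("unclassified counts must be non-negative")
    if p is None:
        p = a_origin_ratio(a, r)
    p = np.asarray(p, dtype=float)
    fallback = np.isnan(p) & (u > 0)
    p_eff = np.where(np.isnan(p), fallback_p, p)
    a2 = a + u * p_eff
    r2 = r + u * (1.0 - p_eff)
    return a2, r2, fallback


def with_allocation(df: pd.DataFrame, fallback_p: float = 0.5) -> pd.DataFrame:
    """Add p, a_alloc, r_alloc, fallback columns to an a/r/u count frame."""
    out = df.copy()
    p = a_origin_ratio(df["a"].values, df["r"].values)
    a2, r2, fb = allocate_unclassified(df["a"].values, df["r"].values,
                                       df["u"].values, p, fallback_p)
    out["p"] = p
    out["a_alloc"] = a2
    out["r_alloc"] = r2
    out["fallback"] = fb
    return out


# ---------------------------------------------------------------------------
# FPKM
# ---------------------------------------------------------------------------

def fpkm(counts, lengths, sample_total: float | None = None) -> pd.Series:
    """1e9 * count / (length * sample_total) per homeolog.

    ``sample_total`` defaults to the sum of the supplied counts. Homeologs
    with zero/missing length are skipped (NaN) with a warning.
    """
    counts = pd.Series(counts, dtype=float)
    lengths = pd.Series(lengths, dtype=float).reindex(counts.index)
    if sample_total is None:
        sample_total = float(counts.sum())
    if sample_total <= 0:
        raise ValueError("sample total must be positive")
    bad = ~(lengths > 0)
    if bad.any():
        logger.warning("%d homeologs with zero length skipped", int(bad.sum()))
    out = 1e9 * counts / (lengths.where(~bad) * sample_total)
    return out


def fpkm_polyploid(table: HomeologCountTable, subgenome: str,
                   post_allocation_total: bool = True,
                   fallback_p: float = 0.5) -> pd.Series:
    """FPKM of one subgenome's homeologs in a polyploid sample, computed
    from allocated counts (a' on the A genome lengths, r' on R)."""
    df = with_allocation(table.counts, fallback_p)
    if subgenome == "A":
        counts, lengths = df["a_alloc"], table.lengths["L_A"]
        pre_total = float((df["a"]).sum())
    elif subgenome == "R":
        counts, lengths = df["r_alloc"], table.lengths["L_R"]
        pre_total = float((df["r"]).sum())
    else:
        raise ValueError("subgenome must be 'A' or 'R'")
    total = float(counts.sum()) if post_allocation_total else pre_total
    return fpkm(counts, lengths, total)


def fpkm_progenitor(table: HomeologCountTable, species: str) -> pd.Series:
    """FPKM in a progenitor sample from the total count a+u+r, with homeolog
    lengths on that species' own genome and the sample's own total."""
    total_counts = table.counts[["a", "r", "u"]].sum(axis=1)
    lengths = table.lengths["L_A" if species == "A" else "L_R"]
    return fpkm(total_counts, lengths, float(total_counts.sum()))


# ---------------------------------------------------------------------------
# Ratio distribution and time-point correlation
# ---------------------------------------------------------------------------

@dataclass
class RatioDistribution:
    """Histogram of per-homeolog A-origin ratios with edge masses split out."""

    bin_edges: np.ndarray
    counts: np.ndarray
    mode: float          # midpoint of the highest-mass interior bin
    n_zero: int          # homeologs expressed only from R (p == 0)
    n_one: int           # homeologs expressed only from A (p == 1)
    n_defined: int

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame({"bin_start": self.bin_edges[:-1],
                           "bin_end": self.bin_edges[1:],
                           "count": self.counts})
        df.to_csv(path, sep="\t", index=False)


def ratio_distribution(p_values, bin_width: float = 0.02) -> RatioDistribution:
    """Distribution of A-origin ratios over homeologs with defined p.

    Exact 0 and 1 (single-subgenome expression, the sharp edge peaks) are
    counted separately; the mode is the midpoint of the highest-mass bin of
    the interior histogram, ties resolving to the lower bin.
    """
    p = np.asarray(pd.Series(p_values, dtype=float).dropna().values)
    if p.size == 0:
        raise ValueError("no defined A-origin ratios")
    n_zero = int((p == 0.0).sum())
    n_one = int((p == 1.0).sum())
    interior = p[(p > 0.0) & (p < 1.0)]
    n_bins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(interior, bins=edges)
    imax = int(np.argmax(counts))
    mode = float((edges[imax] + edges[imax + 1]) / 2.0)
    return RatioDistribution(edges, counts, mode, n_zero, n_one, int(p.size))


def ratio_timepoint_correlation(ratios: pd.DataFrame, t1, t2) -> float:
    """Pearson correlation of per-homeolog A-origin ratios between two time
    points, over homeologs with defined ratios at both. NaN marks the
    degenerate constant-vector case."""
    sub = ratios[[t1, t2]].dropna()
    if len(sub) < 3:
        raise ValueError("need at least 3 homeologs with defined ratios "
                         "at both time points")
    x, y = sub[t1].values, sub[t2].values
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y)[0])


# ---------------------------------------------------------------------------
# Time-course assembly
# ---------------------------------------------------------------------------

def fpkm_timecourse(tables: Mapping[float, HomeologCountTable], kind: str,
                    post_allocation_total: bool = True) -> pd.DataFrame:
    """Homeolog x time FPKM matrix for one sample set.

    ``kind`` selects the formula: 'I_A'/'I_R' are the polyploid subgenome
    sets (allocated counts), 'A'/'R' the progenitor sets (total counts).
    """
    cols = {}
    for t in sorted(tables):
        table = tables[t]
        if kind == "I_A":
            cols[t] = fpkm_polyploid(table, "A", post_allocation_total)
        elif kind == "I_R":
            cols[t] = fpkm_polyploid(table, "R", post_allocation_total)
        elif kind in ("A", "R"):
            cols[t] = fpkm_progenitor(table, kind)
        else:
            raise ValueError(f"unknown sample set {kind!r}")
    return pd.DataFrame(cols)


def ratio_timecourse(tables: Mapping[float, HomeologCountTable]) -> pd.DataFrame:
    """Per-homeolog A-origin ratio at every time point (NaN = undefined)."""
    cols = {t: pd.Series(
        a_origin_ratio(tables[t].counts["a"].values,
                       tables[t].counts["r"].values),
        index=tables[t].counts.index)
        for t in sorted(tables)}
    return pd.DataFrame(cols)


def pooled_origin_ratio(table: HomeologCountTable) -> float:
    """Whole-sample a : (a + r) ratio over all homeologs (dosage check)."""
    a = float(table.counts["a"].sum())
    r = float(table.counts["r"].sum())
    if a + r == 0:
        raise ValueError("no classified fragments")
    return a / (a + r)
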