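"""Subgenome origin classification of read pairs.

Each fragment is aligned to both parental genomes; the genome with strictly
fewer total mismatches wins. Fragments matching both genomes equally well —
typically because they span no diagnostic SNP — are *unclassified*, and
fragments unmappable on both genomes are *discarded*. This deterministic
mismatch-count comparison stands in for probabilistic read-sorting tools:
the downstream quantification consumes only the three-way label, and with
error-free reads the rule can never assign a wrong origin (a wrong call
would need fewer mismatches on the wrong genome, which divergence alone
cannot produce).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .readmap import AlignmentRecord

ORIGIN_A = "A-origin"
ORIGIN_R = "R-origin"
UNCLASSIFIED = "unclassified"
DISCARDED = "discarded"
LABELS = (ORIGIN_A, ORIGIN_R, UNCLASSIFIED, DISCARDED)

MatePair = Sequence["AlignmentRecord | None"]


@dataclass
class ClassifiedFragment:
    """One read pair with its mismatch totals on both genomes and the
    resulting origin label."""

    fragment: str
    mismatches_A: int | None
    mismatches_R: int | None
    origin: str
    single_genome: bool = False
    aln_A: MatePair = (None, None)
    aln_R: MatePair = (None, None)


def _mapped_mates(pair: MatePair) -> dict[int, AlignmentRecord]:
    out = {}
    for rec in pair:
        if rec is not None and rec.mapped:
            out[rec.mate] = rec
    return out


def classify_fragment(aln_A: MatePair, aln_R: MatePair,
                      tie_margin: int = 1) -> ClassifiedFragment:
    """Label one fragment from its alignments to the A and R genomes.

    Mate mismatch counts are summed; when a mate is unmapped on one genome
    the comparison is restricted to the mates mapped on both. A genome must
    beat the other by at least ``tie_margin`` mismatches to claim the
    fragment; fragments mapped on only one genome take that origin (flagged
    ``single_genome``).
    """
    ids = {r.fragment for r in (*aln_A, *aln_R) if r is not None}
    if len(ids) > 1:
        raise ValueError(f"alignments from different fragments: {ids}")
    fid = ids.pop() if ids else ""
    mates_A = _mapped_mates(aln_A)
    mates_R = _mapped_mates(aln_R)
    mm_A = sum(r.mismatches for r in mates_A.values()) if mates_A else None
    mm_R = sum(r.mismatches for r in mates_R.values()) if mates_R else None
    if not mates_A and not mates_R:
        return ClassifiedFragment(fid, None, None, DISCARDED,
                                  aln_A=tuple(aln_A), aln_R=tuple(aln_R))
    if not mates_R:
        return ClassifiedFragment(fid, mm_A, None, ORIGIN_A, True,
                                  tuple(aln_A), tuple(aln_R))
    if not mates_A:
        return ClassifiedFragment(fid, None, mm_R, ORIGIN_R, True,
                                  tuple(aln_A), tuple(aln_R))
    common = sorted(set(mates_A) & set(mates_R))
    if common:
        d_A = sum(mates_A[m].mismatches for m in common)
        d_R = sum(mates_R[m].mismatches for m in common)
    else:
        # disjoint mapped mates carry no comparable signal
        d_A = d_R = 0
    if d_R - d_A >= tie_margin:
        origin = ORIGIN_A
    elif d_A - d_R >= tie_margin:
        origin = ORIGIN_R
    else:
        origin = UNCLASSIFIED
    return ClassifiedFragment(fid, mm_A, mm_R, origin, False,
                              tuple(aln_A), tuple(aln_R))


def classify_fragments(aln_A: Mapping[str, MatePair],
                       aln_R: Mapping[str, MatePair],
                       tie_margin: int = 1) -> list[ClassifiedFragment]:
    """Classify every fragment seen on either genome (sorted by id)."""
    empty: MatePair = (None, None)
    out = []
    for fid in sorted(set(aln_A) | set(aln_R)):
        out.append(classify_fragment(aln_A.get(fid, empty),
                                     aln_R.get(fid, empty), tie_margin))
    return out


# ---------------------------------------------------------------------------
# Confidence evaluation on single-origin (diploid) read sets
# ---------------------------------------------------------------------------

@dataclass
class MisclassificationResult:
    """Outcome of classifying reads whose true origin is uniformly known."""

    true_origin: str
    n_fragments: int
    n_correct: int
    n_wrong: int
    n_unclassified: int
    n_discarded: int

    @property
    def misclassification_rate(self) -> float:
        classified = self.n_correct + self.n_wrong
        return self.n_wrong / classified if classified else 0.0

    @property
    def unclassified_fraction(self) -> float:
        return self.n_unclassified / self.n_fragments

    @property
    def discarded_fraction(self) -> float:
        return self.n_discarded / self.n_fragments


def evaluate_misclassification(classified: Iterable[ClassifiedFragment],
                               true_origin: str) -> MisclassificationResult:
    """Misclassification rate of a diploid (single-true-origin) read set:
    wrongly assigned fragments over all origin-assigned fragments, with
    unclassified and discarded fractions reported separately."""
    if true_origin not in (ORIGIN_A, ORIGIN_R):
        raise ValueError(f"true_origin must be {ORIGIN_A} or {ORIGIN_R}")
    wrong_label = ORIGIN_R if true_origin == ORIGIN_A else ORIGIN_A
    n = {label: 0 for label in LABELS}
    total = 0
    for frag in classified:
        n[frag.origin] += 1
        total += 1
    if total == 0:
        raise ValueError("cannot evaluate misclassification on empty input")
    return MisclassificationResult(
        true_origin=true_origin, n_fragments=total,
        n_correct=n[true_origin], n_wrong=n[wrong_label],
        n_unclassified=n[UNCLASSIFIED], n_discarded=n[DISCARDED],
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_classification_tsv(classified: Iterable[ClassifiedFragment],
                             path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("fragment\tmismatches_A\tmismatches_R\torigin\tsingle_genome\n")
        for f in classified:
            ma = "" if f.mismatches_A is None else f.mismatches_A
            mr = "" if f.mismatches_R is None else f.mismatches_R
            fh.write(f"{f.fragment}\t{ma}\t{mr}\t{f.origin}\t"
                     f"{int(f.single_genome)}\n")


def label_fractions(classified: Sequence[ClassifiedFragment]) -> dict[str, float]:
    total = len(classified)
    counts = {label: 0 for label in LABELS}
    for f in classified:
        counts[f.origin] += 1
    return {label: counts[label] / total if total else 0.0 for label in LABELS}


def write_summary_json(classified: Sequence[ClassifiedFragment],
                       path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(label_fractions(classified), fh, indent=2)
        fh.write("\n")
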