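"""Variant calling thresholds, substitution/lift-over, iterative assembly."""

import numpy as np
import pytest

from homeoquant import pseudogenome as pg
from homeoquant import simulate as sim
from homeoquant.genome import GeneModel, ReferenceGenome, Variant, VariantSet


@pytest.fixture()
def toy_genome():
    return ReferenceGenome(
        {"chr1": "ACGTACGTACGTACGTACGT"},
        [GeneModel("g1", "chr1", "+", ((2, 8), (12, 18)))])


class TestCallVariants:
    def _pileup(self, genome, pos, n_alt, n_ref, alt="T"):
        pile = pg.Pileup(genome)
        ref = genome.chromosomes["chr1"][pos]
        alt = "T" if ref != "T" else "G"
        for _ in range(n_alt):
            pile.add_base("chr1", pos, alt)
        for _ in range(n_ref):
            pile.add_base("chr1", pos, ref)
        return pile, alt

    @pytest.mark.parametrize("n_alt, n_ref, emitted", [
        (4, 1, False),   # fraction 0.8 passes but alt depth 4 < 5
        (5, 1, True),    # fraction 5/6 >= 0.8 and alt depth 5
        (5, 0, True),    # unanimous
        (5, 2, False),   # fraction 5/7 < 0.8
        (12, 3, True),   # fraction 0.8 exactly (inclusive threshold)
    ])
    def test_threshold_predicates(self, toy_genome, n_alt, n_ref, emitted):
        pile, alt = self._pileup(toy_genome, 4, n_alt, n_ref)
        variants = pg.call_variants(pile, toy_genome)
        if emitted:
            assert len(variants) == 1
            v = variants[0]
            assert (v.pos, v.alt, v.alt_depth, v.total_depth) == \
                (4, alt, n_alt, n_alt + n_ref)
        else:
            assert len(variants) == 0

    def test_all_reference_pileup_is_empty(self, toy_genome):
        pile = pg.Pileup(toy_genome)
        for pos in range(10):
            for _ in range(20):
                pile.add_base("chr1", pos,
                              toy_genome.chromosomes["chr1"][pos])
        assert len(pg.call_variants(pile, toy_genome)) == 0

    def test_unknown_chromosome_rejected(self, toy_genome):
        pile = pg.Pileup(toy_genome)
        with pytest.raises(ValueError, match="unknown chromosome"):
            pile.add_base("chrZ", 0, "A")

    def test_diploid_reads_recover_known_snps_exactly(self, small_cfg,
                                                      base_genome, parents):
        """With error-free 30x reads, every exonic true SNP with >=5
        alternative reads is called and nothing else is."""
        import dataclasses
        import pandas as pd
        cfg = dataclasses.replace(small_cfg, depth=75.0)
        expected = pd.Series(
            {f"{g.gene_id}|A": 2 * cfg.depth * g.length / 1000.0
             for g in base_genome.genes})
        frags = sim.simulate_fragments({"A": parents.A}, expected, cfg,
                                       cfg.rng(77))
        reads = [(f.frag_id, f.seq1, f.seq2) for f in frags]
        mapper = pg._transcript_mapper(pg.DEFAULT_SEED_K,
                                       pg.DEFAULT_MAX_MISMATCHES)
        pileup = pg.Pileup(base_genome)
        for aln in mapper(base_genome, reads):
            pileup.add_aligned(aln)
        called = pg.call_variants(pileup, base_genome)
        called_set = {(v.chrom, v.pos, v.alt) for v in called}
        masks = pg.exon_mask(base_genome)
        truth = {(v.chrom, v.pos, v.alt) for v in parents.variants["A"].snps
                 if masks[v.chrom][v.pos]}
        # no false calls at all
        assert called_set <= truth
        # every sufficiently covered true SNP is recovered
        missed = truth - called_set
        for chrom, pos, _alt in missed:
            assert pileup.coverage[chrom][pos] < pg.DEFAULT_MIN_ALT_DEPTH


class TestSubstitute:
    def test_empty_variant_set_is_identity(self, toy_genome):
        out, report = pg.substitute(toy_genome, VariantSet())
        assert out.chromosomes == toy_genome.chromosomes
        assert out.genes == toy_genome.genes
        assert report.applied == [] and report.conflicts == 0

    def test_single_exonic_snp_changes_one_base_only(self, toy_genome):
        out, _ = pg.substitute(
            toy_genome, VariantSet([Variant("chr1", 4, "A", "G")]))
        diff = [i for i, (a, b) in enumerate(zip(
            toy_genome.chromosomes["chr1"], out.chromosomes["chr1"]))
            if a != b]
        assert diff == [4]
        assert out.genes == toy_genome.genes

    def test_upstream_deletion_shifts_annotation(self, toy_genome):
        # 2-base intronic deletion (anchored at base 8) shifts the
        # downstream exon by -2 and leaves the upstream exon alone
        out, report = pg.substitute(
            toy_genome, VariantSet([Variant("chr1", 8, "ACG", "A")]))
        assert len(out.chromosomes["chr1"]) == 18
        assert out.genes[0].exons == ((2, 8), (10, 16))
        # independent re-check: lifted exon sequences match the originals
        for (s0, e0), (s1, e1) in zip(toy_genome.genes[0].exons,
                                      out.genes[0].exons):
            assert toy_genome.chromosomes["chr1"][s0:e0] == \
                out.chromosomes["chr1"][s1:e1]
        assert report.net_length_change == -2

    def test_overlapping_variants_first_wins(self, toy_genome):
        out, report = pg.substitute(toy_genome, VariantSet([
            Variant("chr1", 4, "ACG", "A"),
            Variant("chr1", 5, "C", "G"),
        ]))
        assert report.conflicts == 1
        assert len(report.applied) == 1
        assert out.chromosomes["chr1"] == "ACGTA" + "TACGTACGTACGT"

    def test_coordinate_map_leads_back_to_base(self, base_genome):
        parent, variants = sim.diverge_genome(base_genome, 0.002, 0.0005, 21)
        cm = parent.coordinate_map
        cm.check_monotone()
        # positions without upstream indels map to themselves; others shift
        # by the net indel balance upstream — verify via an independent scan
        indels = sorted((v.pos, v.length_change)
                        for v in variants.indels)
        for pos in (0, 1000, 50_000, 100_000, 149_000):
            shift = sum(d for p, d in indels if p < pos - 50)
            near = any(abs(p - pos) <= 50 for p, _ in indels)
            if not near:
                assert cm.to_base("chr1", pos + shift) == pos

    def test_lifted_exons_reproduce_base_after_reverting_variants(
            self, base_genome):
        """Lift-over correctness: parent exon sequences equal base exon
        sequences with the known variants applied."""
        parent, variants = sim.diverge_genome(base_genome, 0.003, 0.0006, 5)
        by_chrom: dict = {}
        for v in variants:
            by_chrom.setdefault(v.chrom, []).append(v)
        for g_base, g_par in zip(base_genome.genes, parent.genes):
            assert g_base.gene_id == g_par.gene_id
            for (s0, e0), (s1, e1) in zip(g_base.exons, g_par.exons):
                base_seq = base_genome.chromosomes[g_base.chrom][s0:e0]
                # apply the variants falling inside this exon, right to left
                edited = base_seq
                for v in sorted(by_chrom.get(g_base.chrom, []),
                                key=lambda v: -v.pos):
                    if s0 <= v.pos and v.pos + len(v.ref) <= e0:
                        off = v.pos - s0
                        edited = (edited[:off] + v.alt
                                  + edited[off + len(v.ref):])
                assert edited == parent.chromosomes[g_par.chrom][s1:e1]


class TestIterateAssembly:
    def test_reads_from_base_are_fixed_point(self, base_genome, small_cfg):
        import pandas as pd
        expected = pd.Series(
            {f"{g.gene_id}|A": 2 * 30.0 * g.length / 1000.0
             for g in base_genome.genes[:10]})
        frags = sim.simulate_fragments({"A": base_genome}, expected,
                                       small_cfg, small_cfg.rng(88))
        reads = [(f.frag_id, f.seq1, f.seq2) for f in frags]
        out, counts = pg.iterate_assembly(reads, base_genome, 3)
        assert counts == [0, 0, 0]
        assert out.chromosomes == base_genome.chromosomes

    def test_requires_at_least_one_iteration(self, base_genome):
        with pytest.raises(ValueError):
            pg.iterate_assembly([], base_genome, 0)

    def test_assembly_counts_non_increasing_and_length_preserved(
            self, base_genome, parents, small_cfg):
        import dataclasses
        import pandas as pd
        cfg = dataclasses.replace(small_cfg, depth=75.0)
        expected = pd.Series(
            {f"{g.gene_id}|A": 2 * cfg.depth * g.length / 1000.0
             for g in base_genome.genes})
        frags = sim.simulate_fragments({"A": parents.A}, expected, cfg,
                                       cfg.rng(78))
        reads = [(f.frag_id, f.seq1, f.seq2) for f in frags]
        out, counts = pg.iterate_assembly(reads, base_genome, 4)
        assert counts[0] > 0
        assert all(b <= a for a, b in zip(counts, counts[1:]))
        # SNP-only substitution conserves length
        assert out.total_length() == base_genome.total_length()
        rec = pg.snp_recovery(out, parents.variants["A"], base_genome)
        assert rec > 0.9
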