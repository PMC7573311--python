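"""Synthetic-data generator: determinism, divergence statistics, expression
classes, read simulation."""

import numpy as np
import pytest

from homeoquant import simulate as sim
from homeoquant.genome import VariantSet
from homeoquant.pseudogenome import substitute


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"dosage": (0, 0)},
        {"snp_rate": 1.5},
        {"error_rate": -0.1},
        {"time_points_h": (0.0, 2.0, 2.0)},
        {"gene_class_fractions": {"constant": 0.5, "induced": 0.4}},
        {"gene_class_fractions": {"constant": 0.5, "weird": 0.5}},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            sim.SimulationConfig(**kwargs)

    def test_dosage_single_subgenome_allowed(self):
        sim.SimulationConfig(dosage=(2, 0))


class TestBaseGenome:
    def test_no_genes_gives_empty_annotation(self):
        cfg = sim.SimulationConfig(n_genes=0, genome_length=10_000,
                                   n_chromosomes=1)
        genome = sim.generate_base_genome(cfg)
        assert genome.genes == []
        assert len(genome.chromosomes["chr1"]) == 10_000

    def test_deterministic_under_seed(self, tmp_path):
        cfg = sim.SimulationConfig(genome_length=30_000, n_chromosomes=1,
                                   n_genes=8, seed=3)
        outputs = []
        for run in ("a", "b"):
            genome = sim.generate_base_genome(cfg)
            fasta = tmp_path / f"{run}.fasta"
            gff = tmp_path / f"{run}.gff3"
            genome.write_fasta(fasta)
            genome.write_gff3(gff)
            outputs.append(fasta.read_bytes() + gff.read_bytes())
        assert outputs[0] == outputs[1]

    def test_places_200_genes_within_bounds(self):
        # interval-containment check on the documented 500 kb / 200 gene case
        cfg = sim.SimulationConfig(genome_length=500_000, n_chromosomes=1,
                                   n_genes=200, seed=11)
        genome = sim.generate_base_genome(cfg)
        assert len(genome.genes) == 200
        prev_end = {}
        for g in genome.genes:
            clen = len(genome.chromosomes[g.chrom])
            assert 0 <= g.span[0] < g.span[1] <= clen
            # genes must not overlap each other
            assert g.span[0] >= prev_end.get(g.chrom, 0)
            prev_end[g.chrom] = g.span[1]

    def test_too_small_genome_reports_deficit(self):
        cfg = sim.SimulationConfig(genome_length=5_000, n_chromosomes=1,
                                   n_genes=50)
        with pytest.raises(ValueError, match="genome too small"):
            sim.generate_base_genome(cfg)


class TestDivergence:
    def test_zero_rates_identity(self, base_genome):
        parent, variants = sim.diverge_genome(base_genome, 0.0, 0.0, 1)
        assert len(variants) == 0
        assert parent.chromosomes == base_genome.chromosomes
        assert parent.genes == base_genome.genes

    def test_snp_count_within_binomial_interval(self):
        cfg = sim.SimulationConfig(genome_length=1_000_000, n_chromosomes=1,
                                   n_genes=0)
        base = sim.generate_base_genome(cfg)
        rate, n = 0.0075, 1_000_000
        _, variants = sim.diverge_genome(base, rate, 0.0, 42)
        sigma = np.sqrt(n * rate * (1 - rate))
        assert abs(len(variants) - n * rate) < 4 * sigma

    def test_variants_reapply_to_reproduce_parent(self, base_genome):
        parent, variants = sim.diverge_genome(base_genome, 0.004, 0.0008, 9)
        assert len(variants.indels) > 0
        rebuilt, report = substitute(base_genome, variants)
        assert rebuilt.chromosomes == parent.chromosomes
        assert report.conflicts == 0
        # length accounting through indels
        assert parent.total_length() - base_genome.total_length() == \
            report.net_length_change

    def test_rate_out_of_range_rejected(self, base_genome):
        with pytest.raises(ValueError):
            sim.diverge_genome(base_genome, 1.2, 0.0, 0)


@pytest.fixture(scope="module")
def expr(base_genome, small_cfg):
    import dataclasses
    cfg = dataclasses.replace(
        small_cfg,
        gene_class_fractions={"constant": 0.4, "induced": 0.3,
                              "oscillating": 0.3})
    return cfg, sim.simulate_expression(base_genome, cfg)


class TestExpression:

    def test_constant_class_flat(self, expr):
        cfg, truth = expr
        for gene, cls in truth.gene_class.items():
            if cls == "constant":
                row = truth.expected.loc[f"{gene}|A"].values
                assert np.allclose(row, row[0])

    def test_dosage_scales_expected_counts(self, expr):
        cfg, truth = expr
        for gene in truth.gene_class:
            a = truth.expected.loc[f"{gene}|A"].values
            r = truth.expected.loc[f"{gene}|R"].values
            assert np.allclose(r, 2.0 * a)  # dosage (1, 2)

    def test_induced_class_monotone_with_8fold_range(self, expr):
        cfg, truth = expr
        assert cfg.induced_log2fc == 3.0
        seen = 0
        for gene, cls in truth.gene_class.items():
            if cls != "induced":
                continue
            row = truth.expected.loc[f"{gene}|A"].values
            assert (np.diff(row) >= 0).all()
            assert row.max() / row.min() == pytest.approx(8.0)
            seen += 1
        assert seen > 0

    def test_oscillating_class_is_24h_periodic(self, expr):
        cfg, truth = expr
        # 0 h, 24 h, 48 h, 72 h, 96 h sample the same phase of a 24 h cycle
        cols = [0.0, 24.0, 48.0, 72.0, 96.0]
        for gene, cls in truth.gene_class.items():
            if cls == "oscillating":
                row = truth.expected.loc[f"{gene}|A", cols].values
                assert np.allclose(row, row[0])


class TestReads:
    def test_fragment_count_poisson_interval(self, parents, small_cfg):
        import pandas as pd
        gene = parents.A.genes[0].gene_id
        expected = pd.Series({f"{gene}|A": 100.0})
        counts = [
            len(sim.simulate_fragments({"A": parents.A}, expected,
                                       small_cfg, np.random.default_rng(s)))
            for s in range(30)
        ]
        assert abs(np.mean(counts) - 100.0) < 4 * np.sqrt(100.0 / 30)

    def test_zero_expression_gives_empty_fastq(self, parents, small_cfg,
                                               tmp_path):
        import pandas as pd
        expected = pd.Series({f"{g.gene_id}|A": 0.0
                              for g in parents.A.genes})
        frags = sim.simulate_fragments({"A": parents.A}, expected,
                                       small_cfg, np.random.default_rng(0))
        assert frags == []
        sim.write_fastq(frags, tmp_path / "r1.fq", tmp_path / "r2.fq")
        assert (tmp_path / "r1.fq").read_bytes() == b""

    def test_fastq_bytes_reproducible(self, base_genome, parents, small_cfg,
                                      tmp_path):
        expr = sim.simulate_expression(base_genome, small_cfg)
        pair = {}
        for run in ("a", "b"):
            frags = sim.simulate_sample_reads(
                {"A": parents.A, "R": parents.R}, expr, small_cfg,
                time_point=0.0, sample_tag=0)
            r1, r2 = tmp_path / f"{run}1.fq", tmp_path / f"{run}2.fq"
            sim.write_fastq(frags, r1, r2)
            pair[run] = r1.read_bytes() + r2.read_bytes()
        assert pair["a"] == pair["b"]

    def test_short_transcript_skipped_with_warning(self, small_cfg, caplog):
        import pandas as pd
        from homeoquant.genome import GeneModel, ReferenceGenome
        tiny = ReferenceGenome({"chr1": "ACGT" * 20},
                               [GeneModel("g0", "chr1", "+", ((0, 40),))])
        with caplog.at_level("WARNING"):
            frags = sim.simulate_fragments(
                {"A": tiny}, pd.Series({"g0|A": 50.0}), small_cfg,
                np.random.default_rng(0))
        assert frags == []
        assert "shorter than read length" in caplog.text

    def test_error_rate_reflected_in_reads(self, parents, small_cfg):
        import dataclasses
        import pandas as pd
        cfg = dataclasses.replace(small_cfg, error_rate=0.01)
        gene = parents.A.genes[0]
        expected = pd.Series({f"{gene.gene_id}|A": 300.0})
        frags = sim.simulate_fragments({"A": parents.A}, expected, cfg,
                                       np.random.default_rng(5))
        transcript = parents.A.transcript(gene)
        mismatches = total = 0
        for f in frags:
            start = transcript.find(f.seq1)
            # most reads are error-free hence locatable; errored ones are
            # what we count via their error-free mates' positions
            total += len(f.seq1)
            if start < 0:
                ref = None
                for s in range(len(transcript) - len(f.seq1) + 1):
                    d = sum(a != b for a, b in
                            zip(transcript[s:s + len(f.seq1)], f.seq1))
                    if d <= 6:
                        ref = d
                        break
                mismatches += ref if ref is not None else 0
        rate = mismatches / total
        assert 0.003 < rate < 0.03

    def test_dosage_conservation_in_fragment_truth(self, triploid):
        origins = [f.origin for f in triploid.frags]
        n = len(origins)
        n_r = sum(1 for o in origins if o == "R")
        # pooled R fraction within 3 sigma of 2/3 under binomial sampling
        sigma = np.sqrt(n * (2 / 3) * (1 / 3))
        assert abs(n_r - n * 2 / 3) < 3 * sigma

    def test_ground_truth_covers_every_fragment(self, base_genome, parents,
                                                small_cfg, tmp_path):
        import dataclasses
        cfg = dataclasses.replace(small_cfg, time_points_h=(0.0, 2.0),
                                  depth=5.0)
        expr = sim.simulate_expression(base_genome, cfg)
        paths, truth = sim.simulate_reads(
            {"A": parents.A, "R": parents.R}, expr, cfg, tmp_path)
        truth.validate()
        n_lines = sum(
            len(p[0].read_text().splitlines()) for p in paths.values())
        assert n_lines == 4 * len(truth.true_origin)
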