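"""Shared fixtures: one small triploid simulation reused across test modules.

Everything is generated at test time from a fixed seed; no data files are
stored. The small design (one 150 kb chromosome, 50 genes, error-free
reads) keeps the full simulate-map-classify-count loop under a few seconds
while leaving enough fragments per homeolog for distributional checks.
"""

from types import SimpleNamespace

import pytest

from homeoquant import classify as cls
from homeoquant import quantify as qt
from homeoquant import readmap as rm
from homeoquant import simulate as sim


@pytest.fixture(scope="session")
def small_cfg() -> sim.SimulationConfig:
    return sim.SimulationConfig(
        genome_length=150_000, n_chromosomes=1, n_genes=50,
        error_rate=0.0, depth=50.0, seed=7,
        gene_class_fractions={"constant": 1.0, "induced": 0.0,
                              "oscillating": 0.0},
    )


@pytest.fixture(scope="session")
def base_genome(small_cfg):
    return sim.generate_base_genome(small_cfg)


@pytest.fixture(scope="session")
def parents(small_cfg, base_genome):
    parent_A, var_A = sim.diverge_genome(base_genome, small_cfg.snp_rate,
                                         0.0, small_cfg.rng(10))
    parent_R, var_R = sim.diverge_genome(base_genome, small_cfg.snp_rate,
                                         0.0, small_cfg.rng(11))
    return SimpleNamespace(A=parent_A, R=parent_R,
                           variants={"A": var_A, "R": var_R})


@pytest.fixture(scope="session")
def triploid(small_cfg, base_genome, parents):
    """One triploid sample, simulated, mapped to both parents, classified
    and counted, with the fragment-level truth attached."""
    expr = sim.simulate_expression(base_genome, small_cfg)
    t0 = small_cfg.time_points_h[0]
    frags = sim.simulate_fragments({"A": parents.A, "R": parents.R},
                                   expr.expected[t0], small_cfg,
                                   small_cfg.rng(3, 0))
    reads = [(f.frag_id, f.seq1, f.seq2) for f in frags]
    aln_A = rm.map_reads(reads, parents.A, "A")
    aln_R = rm.map_reads(reads, parents.R, "R")
    classified = cls.classify_fragments(aln_A, aln_R)
    table = qt.count_fragments(classified, parents.A, parents.R)
    truth = {f.frag_id: f.origin for f in frags}
    return SimpleNamespace(cfg=small_cfg, expr=expr, frags=frags,
                           reads=reads, aln_A=aln_A, aln_R=aln_R,
                           classified=classified, table=table, truth=truth)
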