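"""End-to-end orchestration: simulate -> assemble -> map -> classify ->
quantify -> stats -> enrich, from one config with deterministic seeding.

Every stage reads its inputs from, and writes its artifacts to, the
configured output directory, so any downstream stage can be rerun in
isolation from saved artifacts and reproduce the full-run result. A manifest
records parameters, per-stage seeds and the SHA-256 of every artifact;
rerunning with an identical config reproduces identical hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import classify as cls
from . import enrichment as enr
from . import pseudogenome as pg
from . import quantify as qt
from . import readmap as rm
from . import simulate as sim
from . import timecourse as tc
from .genome import ReferenceGenome

logger = logging.getLogger(__name__)

STAGES = ("simulate", "assemble", "map", "classify", "quantify", "stats",
          "enrich")

#: sample group -> (sample-set labels, dosage override, assembled parent)
SPECIES = {
    "triploid": (("I_A", "I_R"), None, None),
    "diploid_A": (("A",), (2, 0), "A"),
    "diploid_R": (("R",), (0, 2), "R"),
}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: str) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    out_dir: str = "pipeline_out"
    seed: int = 0
    simulation: sim.SimulationConfig = field(
        default_factory=sim.SimulationConfig)
    n_iterations: int = pg.DEFAULT_ITERATIONS
    min_alt_fraction: float = pg.DEFAULT_MIN_ALT_FRACTION
    min_alt_depth: int = pg.DEFAULT_MIN_ALT_DEPTH
    exonic_only: bool = True
    max_mismatches: int = rm.DEFAULT_MAX_MISMATCHES
    seed_k: int = rm.DEFAULT_SEED_K
    tie_margin: int = 1
    unclassified_on: str = "R"
    bin_width: float = 0.02
    fdr: float = enr.DEFAULT_FDR
    size_min: int = enr.DEFAULT_SIZE_MIN
    size_max: int = enr.DEFAULT_SIZE_MAX
    depth_min: int = enr.DEFAULT_DEPTH_MIN
    use_true_parents: bool = False
    stages: tuple[str, ...] = STAGES

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        # one global seed expands into per-stage simulation seeds
        self.simulation = dataclasses.replace(self.simulation, seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("simulation", {})
        if "exons_per_gene" in sim_raw:
            sim_raw["exons_per_gene"] = tuple(sim_raw["exons_per_gene"])
        for key in ("dosage", "time_points_h", "exon_length", "intron_length"):
            if key in sim_raw:
                sim_raw[key] = tuple(sim_raw[key])
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(simulation=sim.SimulationConfig(**sim_raw), **raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _need(path: Path, stage: str) -> Path:
    if not path.exists():
        raise StageError(stage, f"missing required input {path}")
    return path


def _genome(out: Path, name: str, stage: str) -> ReferenceGenome:
    fasta = _need(out / f"{name}.fasta", stage)
    gff = _need(out / f"{name}.gff3", stage)
    return ReferenceGenome.from_files(fasta, gff)


def _parent_names(config: PipelineConfig) -> dict[str, str]:
    if config.use_true_parents:
        return {"A": "parent_A", "R": "parent_R"}
    return {"A": "pseudo_A", "R": "pseudo_R"}


def _sample_fastqs(out: Path, species: str, t: float) -> tuple[Path, Path]:
    return (out / "reads" / f"{species}_t{t:g}_R1.fastq",
            out / "reads" / f"{species}_t{t:g}_R2.fastq")


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig, out: Path) -> list[Path]:
    sc = config.simulation
    base = sim.generate_base_genome(sc)
    base.write_fasta(out / "base.fasta")
    base.write_gff3(out / "base.gff3")
    parents, artifacts = {}, [out / "base.fasta", out / "base.gff3"]
    for i, label in enumerate(("A", "R")):
        parent, variants = sim.diverge_genome(
            base, sc.snp_rate, sc.indel_rate, sc.rng(10 + i))
        parents[label] = parent
        parent.write_fasta(out / f"parent_{label}.fasta")
        parent.write_gff3(out / f"parent_{label}.gff3")
        variants.to_tsv(out / f"true_variants_{label}.tsv")
        artifacts += [out / f"parent_{label}.fasta",
                      out / f"parent_{label}.gff3",
                      out / f"true_variants_{label}.tsv"]
    origin_rows = []
    for si, (species, (_sets, dosage, _lbl)) in enumerate(SPECIES.items()):
        species_cfg = sc if dosage is None else \
            dataclasses.replace(sc, dosage=dosage)
        expr = sim.simulate_expression(base, species_cfg)
        if si == 0:
            expr.expected.to_csv(out / "true_expression.tsv", sep="\t",
                                 index_label="homeolog")
            pd.Series(expr.gene_class, name="gene_class").to_csv(
                out / "true_gene_classes.tsv", sep="\t",
                index_label="gene")
            artifacts += [out / "true_expression.tsv",
                          out / "true_gene_classes.tsv"]
        paths, truth = sim.simulate_reads(
            parents, expr, species_cfg, out / "reads",
            sample_name=species, sample_tag=si)
        for t, (r1, r2) in paths.items():
            artifacts += [r1, r2]
        origin_rows += [(fid, truth.true_origin[fid], truth.true_gene[fid])
                        for fid in truth.true_origin]
    pd.DataFrame(origin_rows,
                 columns=["fragment", "origin", "gene"]).to_csv(
        out / "true_origin.tsv", sep="\t", index=False)
    artifacts.append(out / "true_origin.tsv")
    return artifacts


def stage_assemble(config: PipelineConfig, out: Path) -> list[Path]:
    if config.use_true_parents:
        return []
    sc = config.simulation
    base = _genome(out, "base", "assemble")
    artifacts = []
    for species, (_sets, _dosage, label) in SPECIES.items():
        if label is None:
            continue
        reads = []
        for t in sc.time_points_h:
            r1, r2 = _sample_fastqs(out, species, t)
            reads += sim.read_fastq_pair(_need(r1, "assemble"),
                                         _need(r2, "assemble"))
        genome, counts = pg.iterate_assembly(
            reads, base, config.n_iterations,
            min_alt_fraction=config.min_alt_fraction,
            min_alt_depth=config.min_alt_depth,
            exonic_only=config.exonic_only, k=config.seed_k,
            max_mismatches=config.max_mismatches)
        genome.write_fasta(out / f"pseudo_{label}.fasta")
        genome.write_gff3(out / f"pseudo_{label}.gff3")
        pd.Series(counts, name="variants_applied").to_csv(
            out / f"assembly_iterations_{label}.tsv", sep="\t",
            index_label="iteration")
        artifacts += [out / f"pseudo_{label}.fasta",
                      out / f"pseudo_{label}.gff3",
                      out / f"assembly_iterations_{label}.tsv"]
    return artifacts


def stage_map(config: PipelineConfig, out: Path) -> list[Path]:
    sc = config.simulation
    names = _parent_names(config)
    genomes = {lbl: _genome(out, name, "map") for lbl, name in names.items()}
    indexes = {lbl: rm.TranscriptIndex(g, k=config.seed_k)
               for lbl, g in genomes.items()}
    (out / "aln").mkdir(exist_ok=True)
    artifacts = []
    for species in SPECIES:
        for t in sc.time_points_h:
            r1, r2 = _sample_fastqs(out, species, t)
            reads = sim.read_fastq_pair(_need(r1, "map"), _need(r2, "map"))
            for lbl in ("A", "R"):
                recs = rm.map_reads(reads, indexes[lbl], lbl,
                                    config.max_mismatches)
                path = out / "aln" / f"{species}_t{t:g}_{lbl}.sam"
                flat = [r for pair in recs.values() for r in pair]
                rm.write_sam(flat, genomes[lbl], path)
                artifacts.append(path)
    return artifacts


def stage_classify(config: PipelineConfig, out: Path) -> list[Path]:
    sc = config.simulation
    (out / "classified").mkdir(exist_ok=True)
    artifacts = []
    for species in SPECIES:
        for t in sc.time_points_h:
            aln = {}
            for lbl in ("A", "R"):
                path = _need(out / "aln" / f"{species}_t{t:g}_{lbl}.sam",
                             "classify")
                aln[lbl] = rm.read_sam(path, lbl)
            frags = cls.classify_fragments(aln["A"], aln["R"],
                                           config.tie_margin)
            tsv = out / "classified" / f"{species}_t{t:g}.tsv"
            cls.write_classification_tsv(frags, tsv)
            summary = out / "classified" / f"{species}_t{t:g}.json"
            cls.write_summary_json(frags, summary)
            artifacts += [tsv, summary]
    return artifacts


def _reclassify(config: PipelineConfig, out: Path, species: str, t: float
                ) -> list[cls.ClassifiedFragment]:
    # counting needs placements, which the TSV does not carry; rebuild from SAM
    aln = {lbl: rm.read_sam(out / "aln" / f"{species}_t{t:g}_{lbl}.sam", lbl)
           for lbl in ("A", "R")}
    return cls.classify_fragments(aln["A"], aln["R"], config.tie_margin)


def stage_quantify(config: PipelineConfig, out: Path) -> list[Path]:
    sc = config.simulation
    names = _parent_names(config)
    genomes = {lbl: _genome(out, name, "quantify")
               for lbl, name in names.items()}
    (out / "quant").mkdir(exist_ok=True)
    artifacts = []
    fpkm_sets: dict[str, pd.DataFrame] = {}
    for species, (sets, _dosage, _lbl) in SPECIES.items():
        tables = {}
        for t in sc.time_points_h:
            _need(out / "aln" / f"{species}_t{t:g}_A.sam", "quantify")
            frags = _reclassify(config, out, species, t)
            table = qt.count_fragments(frags, genomes["A"], genomes["R"],
                                       config.unclassified_on)
            table.to_tsv(out / "quant" / f"counts_{species}_t{t:g}.tsv")
            artifacts.append(out / "quant" / f"counts_{species}_t{t:g}.tsv")
            tables[t] = table
        for sample_set in sets:
            fpkm_sets[sample_set] = qt.fpkm_timecourse(tables, sample_set)
        if species == "triploid":
            ratios = qt.ratio_timecourse(tables)
            ratios.to_csv(out / "quant" / "a_origin_ratio.tsv", sep="\t",
                          index_label="homeolog")
            artifacts.append(out / "quant" / "a_origin_ratio.tsv")
            hist = qt.ratio_distribution(
                ratios[sc.time_points_h[0]], config.bin_width)
            hist.to_tsv(out / "quant" / "ratio_histogram_t0.tsv")
            artifacts.append(out / "quant" / "ratio_histogram_t0.tsv")
    for sample_set, df in fpkm_sets.items():
        path = out / "quant" / f"fpkm_{sample_set}.tsv"
        df.to_csv(path, sep="\t", index_label="homeolog")
        artifacts.append(path)
    return artifacts


def _load_fpkm(out: Path, sample_set: str, stage: str) -> pd.DataFrame:
    path = _need(out / "quant" / f"fpkm_{sample_set}.tsv", stage)
    df = pd.read_csv(path, sep="\t", index_col="homeolog")
    df.columns = [float(c) for c in df.columns]
    return df


def stage_stats(config: PipelineConfig, out: Path) -> list[Path]:
    (out / "stats").mkdir(exist_ok=True)
    artifacts = []
    fpkm_sets = {s: _load_fpkm(out, s, "stats")
                 for s in ("I_A", "I_R", "A", "R")}
    # strip the subgenome suffix so homeolog pairs match across sets
    by_gene = {}
    for label, df in fpkm_sets.items():
        g = df.copy()
        g.index = [h.rsplit("|", 1)[0] for h in g.index]
        by_gene[label] = g
    expressed_union = sorted(set().union(
        *(tc.gate_expressed(df) for df in by_gene.values())))
    pd.Series(expressed_union, name="gene").to_csv(
        out / "stats" / "expressed_union.tsv", sep="\t", index=False)
    artifacts.append(out / "stats" / "expressed_union.tsv")
    stacked = tc.stack_sample_sets(
        {label: tc.log_transform(df.loc[expressed_union])
         for label, df in by_gene.items()})
    res = tc.pca(stacked)
    res.scores.to_csv(out / "stats" / "pca_scores.tsv", sep="\t",
                      index_label="sample")
    res.loadings.to_csv(out / "stats" / "pca_loadings.tsv", sep="\t",
                        index_label="gene")
    artifacts += [out / "stats" / "pca_scores.tsv",
                  out / "stats" / "pca_loadings.tsv"]
    for label, df in by_gene.items():
        veh = tc.detect_veh(df)
        path = out / "stats" / f"veh_{label}.tsv"
        veh.to_csv(path, sep="\t", index_label="gene")
        artifacts.append(path)
    return artifacts


def stage_enrich(config: PipelineConfig, out: Path) -> list[Path]:
    (out / "enrich").mkdir(exist_ok=True)
    artifacts = []
    base_genes = _genome(out, "base", "enrich").gene_ids
    cats, _edges = sim.simulate_category_hierarchy(
        base_genes, seed=config.simulation.rng(40))
    for label in ("I_A", "I_R", "A", "R"):
        veh_path = _need(out / "stats" / f"veh_{label}.tsv", "enrich")
        veh = pd.read_csv(veh_path, sep="\t", index_col="gene")
        universe = veh.index[veh["is_expressed"]]
        veh_ids = veh.index[veh["is_veh"]]
        table = enr.enrich(veh_ids, universe, cats, config.fdr,
                           config.size_min, config.size_max,
                           config.depth_min)
        path = out / "enrich" / f"enrichment_{label}.tsv"
        table.to_csv(path, sep="\t", index=False)
        artifacts.append(path)
    return artifacts


_STAGE_FUNCS = {
    "simulate": stage_simulate, "assemble": stage_assemble,
    "map": stage_map, "classify": stage_classify,
    "quantify": stage_quantify, "stats": stage_stats,
    "enrich": stage_enrich,
}


def run(config: PipelineConfig,
        stages: Sequence[str] | None = None) -> dict:
    """Execute the enabled stages and return the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    todo = list(stages) if stages is not None else list(config.stages)
    unknown = set(todo) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    manifest: dict = {
        "seed": config.seed,
        "parameters": {
            k: v for k, v in dataclasses.asdict(config).items()
            if k not in ("simulation",)
        },
        "simulation": dataclasses.asdict(config.simulation),
        "stages": {},
    }
    for stage in STAGES:
        if stage not in todo:
            continue
        t0 = time.monotonic()
        try:
            artifacts = _STAGE_FUNCS[stage](config, out)
        except StageError:
            raise
        except Exception as exc:  # halt with stage name and cause
            raise StageError(stage, str(exc)) from exc
        manifest["stages"][stage] = {
            "seconds": round(time.monotonic() - t0, 3),
            "artifacts": {str(p.relative_to(out)): _sha256(p)
                          for p in artifacts},
        }
        logger.info("stage %s done in %.1fs (%d artifacts)", stage,
                    time.monotonic() - t0, len(artifacts))
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
    return manifest
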