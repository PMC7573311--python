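# homeoquant

Subgenome-resolved homeolog expression quantification for allopolyploid
RNA-seq time courses.

## The problem

In an allopolyploid, every gene is typically present as two or more
*homeologs* — the copies contributed by the parental species. Bulk RNA-seq
reads from such a nucleus are a mixture: each fragment originates from one
subgenome, but standard quantification against a single reference cannot
say which. The problem is sharpest in a young allotriploid carrying one
copy of subgenome A and two copies of subgenome R: does each homeolog pair
follow the 1:2 copy-number dosage, or is expression rebalanced?

`homeoquant` implements the full computational path for answering this with
short paired-end reads, for researchers working on polyploid
transcriptomics who want a tested, reusable, scriptable version of the
analysis rather than a chain of one-off tools:

1. **Pseudo-genome construction** (`pseudogenome`). Each progenitor's
   genome is approximated from a related base reference plus that
   progenitor's own RNA-seq reads: map, call variants (a locus is accepted
   when ≥ 80 % of covering reads carry the alternative base and at least
   five reads carry it), substitute the alternatives into the reference,
   lift the gene annotations through the substitutions, and iterate the
   cycle (nine times by default) so initially unmappable reads can
   contribute.
2. **Read-origin classification** (`readmap`, `classify`). Every fragment
   is aligned to both parental pseudo-genomes; the genome with strictly
   fewer total mismatches claims it. Equal mismatch counts (no diagnostic
   SNP spanned) → *unclassified*; unmapped on both → *discarded*. With
   error-free reads this rule provably never assigns a wrong origin.
3. **Dosage-aware quantification** (`quantify`). Classified fragments are
   counted fractionally per homeolog (1/k to each of k overlapping gene
   models), giving counts a_hs, r_hs, u_hs. The A-origin ratio
   p_hs = a_hs/(a_hs + r_hs) reallocates the unclassified mass,

       a'_hs = a_hs + u_hs·p_hs        r'_hs = r_hs + u_hs·(1 − p_hs),

   conserving a' + r' = a + r + u exactly. FPKM for the polyploid
   subgenome sets is 10⁹·a'_hs/(L_hA·Aˢ) with homeolog lengths on each
   subgenome's own genome and Aˢ the post-allocation sample total (so
   Σ_h FPKM·L = 10⁹ exactly); progenitor samples use the total count
   a + u + r.
4. **Time-course statistics** (`timecourse`). Expressed homeologs
   (FPKM > 1.0 at ≥ 1 time point), log₁₀(FPKM + 1) transform, PCA across
   the four sample sets (polyploid-A, polyploid-R, and the two
   progenitors), and variably-expressed-homeolog (VEH) detection: mean of
   the log series > 1.0 and coefficient of variation > 0.20.
5. **Enrichment** (`enrichment`). Hypergeometric over-representation of
   VEH sets against the expressed universe, restricted to categories with
   10–500 members at hierarchy depth ≥ 3, Benjamini–Hochberg FDR < 0.1.
6. **Synthetic data** (`simulate`). A first-class generator for the whole
   design: base genome with exonic gene models, two SNP/indel-diverged
   parents, triploid expression at dosage A:R = 1:2 over nine time points
   (0–96 h) with constant / induced / oscillating gene classes, and
   100 bp paired-end reads with per-fragment origin ground truth.

The `pipeline` module and the `homeoquant` CLI chain the stages from one
YAML config with deterministic seeding and a hash manifest; `workflows`
packages the headline simulation studies as single calls.

## Worked example

Simulate a small triploid sample (50 homeolog pairs, dosage 1:2,
error-free reads), classify and quantify it:

```python
from homeoquant import *
from homeoquant.classify import label_fractions

cfg = SimulationConfig(genome_length=150_000, n_chromosomes=1, n_genes=50,
                       error_rate=0.0, depth=50.0, seed=7,
                       gene_class_fractions={"constant": 1.0, "induced": 0.0,
                                             "oscillating": 0.0})
base = generate_base_genome(cfg)
parent_A, _ = diverge_genome(base, cfg.snp_rate, 0.0, cfg.rng(10))
parent_R, _ = diverge_genome(base, cfg.snp_rate, 0.0, cfg.rng(11))

expr = simulate_expression(base, cfg)
frags = simulate_fragments({"A": parent_A, "R": parent_R},
                           expr.expected[0.0], cfg, cfg.rng(3, 0))
reads = [(f.frag_id, f.seq1, f.seq2) for f in frags]

aln_A = map_reads(reads, parent_A, "A")
aln_R = map_reads(reads, parent_R, "R")
classified = classify_fragments(aln_A, aln_R)
table = count_fragments(classified, parent_A, parent_R)

print(f"fragments: {len(frags)}")
print("label fractions:", {k: round(v, 3)
                           for k, v in label_fractions(classified).items()})
p = a_origin_ratio(table.counts["a"].values, table.counts["r"].values)
print(f"pooled A fraction: {pooled_origin_ratio(table):.4f}")
print(f"A-origin-ratio mode bin midpoint: {ratio_distribution(p).mode}")
```

Output:

```
fragments: 10650
label fractions: {'A-origin': 0.321, 'R-origin': 0.629, 'unclassified': 0.05, 'discarded': 0.0}
pooled A fraction: 0.3377
A-origin-ratio mode bin midpoint: 0.33
```

About a third of the fragments classify as A-origin and two thirds as
R-origin — the 1:2 subgenome dosage read back from sequence alone — and
the per-homeolog A-origin-ratio distribution peaks in the histogram bin
containing 1/3. The 5 % unclassified fragments are those spanning no
diagnostic SNP.

To run the staged pipeline end to end instead:

```
homeoquant --config config.yaml run-all
```

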