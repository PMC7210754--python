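# cistrans

Partitioning gene-regulatory divergence into *cis* and *trans* components
from allele-specific expression (ASE) in F1 hybrids — the classical design
for comparing regulation between two inbred lines, here modelled on crosses
between a reference cultivar (maternal parent) and wild or domesticated
accessions grown under control and short-term cold conditions.

## The design and the statistics

Cross two inbred parents M (maternal, the reference) and P and sequence
RNA from the parents and the F1. At transcribed SNPs where the parents are
opposite homozygotes and the hybrid is heterozygous ("informative" SNPs),
hybrid reads can be assigned to a parental allele. Per gene, three log2
quantities are tested:

- **A** = paternal parent − maternal parent: the parental divergence,
  which is the sum of cis and trans effects;
- **B** = paternal allele − maternal allele *within* the hybrid: both
  alleles share one trans environment, so B reflects cis effects only;
- **T** = A − B: the trans component.

Significance of (A, B, T) at FDR ≤ 0.01 (Benjamini–Hochberg, per contrast)
maps each gene to one of seven regulatory categories: *cis only*
(A✓ B✓ T✗), *trans only* (A✓ B✗ T✓), *cis+trans* (all ✓, B and T same
sign), *cis×trans* (all ✓, opposite signs), *compensatory* (A✗ B✓ T✓),
*conserved* (none), and *ambiguous* (anything else).

Two statistical engines are implemented and compared:

1. **Linear engine** — TMM scale factors, voom-style log2-CPM with
   precision weights from a lowess mean–variance trend, per-gene weighted
   least squares on a one-factor-per-(generation × allele × treatment)
   design, empirical-Bayes variance moderation, moderated-*t* contrasts.
2. **Exact engine** — replicate counts pooled per gene; exact binomial
   tests for A (against the library-size null proportion) and B (against
   0.5), and Fisher's exact test on the parent-vs-hybrid 2×2 table for T.

Because pooling discards between-replicate variability, the exact engine
over-calls trans effects on overdispersed data; the linear engine keeps
the conserved class large. The package also classifies hybrid inheritance
modes on total expression (additive, maternal/paternal dominant,
over-dominant, ambiguous) and ships a synthetic-data generator that
produces complete crosses — exome-like genotyping tables, per-SNP and
per-gene allele counts, total counts and ground-truth labels — so the whole
pipeline is testable without any sequencing data.

## Worked example

```python
import cistrans as ct

cfg = ct.RunConfig(
    simulation=ct.SimConfig(n_genes=150, seed=7),
    outdir="results/demo",
)
res = ct.run(cfg)
print(res["manifest"]["stage_counts"])
print(res["cross1"]["summary_linear"].to_string(index=False))
cmp = ct.compare_engines(
    res["cross1"]["tests_linear"][["gene_id", "context", "category"]],
    res["cross1"]["tests_exact"][["gene_id", "context", "category"]],
)
print(cmp["trans_containing"], cmp["conserved_fraction"])
```

prints

```
{'cross1': {'n_sites': 499, 'n_informative_snps': 453, 'n_informative_genes': 148, 'n_genes_tested': 148}}
      category  cold  control  intersection
      cis_only    14       15            13
    trans_only     2        3             2
cis_plus_trans     1        2             1
  cis_by_trans     0        0             0
  compensatory     3        4             2
     conserved   113      117           110
     ambiguous    15        7             3
         total   148      148           131
{'linear': 11, 'exact': 250} {'linear': 0.775, 'exact': 0.052}
```

Reading this: of 150 simulated genes, 148 had at least one informative SNP
passing the genotyping thresholds (opposite homozygous parents at ≥2 reads,
heterozygous hybrid at ≥6 reads) and ≥50 allele-informative reads. The
linear engine calls most genes conserved in both treatments, with the
intersection column counting genes assigned to the same category under
control and cold. The final line is the method contrast: on the same data
the pooled binomial/Fisher engine places 250 gene-context calls in
trans-containing categories against 11 for the linear engine, and its
conserved fraction collapses from 78% to 5% — the over-calling of trans
effects that pooling replicates produces.

The same pipeline runs from the shell:

```sh
cistrans run --seed 7 --engine both --out results/demo
cistrans simulate --seed 7 --out fixtures/        # write VCF + TSV fixtures
cistrans genotype --vcf fixtures/cross1/sites.vcf \
    --annotation fixtures/cross1/annotation.bed \
    --maternal cross1.exome.Pm --paternal cross1.exome.Pp \
    --hybrid cross1.exome.F1 --out informative.tsv
```

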