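# Methods

## The identifying model

The package rests on the standard decomposition of regulatory divergence in
an F1 design. On the log2 scale, a gene with baseline abundance `b`, cis
effect `c` and trans effect `t` has maternal-parent mean `b`,
paternal-parent mean `b + c + t`, and hybrid allele means `b − 1` and
`b − 1 + c` for the maternal and paternal allele respectively. The
parental contrast therefore estimates `c + t`, the within-hybrid allelic
contrast estimates `c`, and their difference estimates `t`. The `− 1`
halves each allele so that the hybrid's total expression equals the
additive (mid-parent) expectation whenever `t = 0`; deviations from
additivity are injected explicitly through a per-gene hybrid shift (see
"Inheritance modes"). The assumptions are the usual ones: no
parent-of-origin effects, no allele-specific mapping bias (an optional
`reference_bias` parameter exists to emulate bias toward the maternal
reference allele, default 0), and trans factors acting equally on both
hybrid alleles.

## Synthetic data generator

`simulate_cross` produces, per cross: an exome-capture-like site table for
the two parents and one hybrid individual; gene-level and per-SNP
allele-specific RNA counts; total counts; and a truth record. Counts are
negative-binomial via a gamma–Poisson mixture with variance
`mu + phi * mu^2`; allele-informative reads are a binomial thinning of
gene reads by `allelic_capture_fraction`, which reproduces the fact that
only reads overlapping informative SNPs can be assigned to an allele
(and, at the column level, is absorbed by scale-factor normalization).
Per-column expected counts are `2^level / sum(2^baseline) * library_size`,
so the average gene receives `library_size / n_genes` reads per column and
per-gene ratios across columns are exact in expectation.

Key parameters, defaults, and the reasoning behind them:

- `dispersion` (NB `phi`) = 0.05, i.e. a biological coefficient of
  variation of ~0.22 between replicates of inbred lines in one growth
  chamber.
- `baseline_log2_sd` = 1.5: a realistically wide spread of expression
  levels (about 3 log2 units between the 16th and 84th percentile).
- `architecture_proportions` default to a conserved-dominated profile
  (70% conserved, 12% cis only, 6% trans only, 4% cis+trans,
  3% cis×trans, 5% compensatory), reflecting the finding that most genes
  between wild and domesticated lines are conservatively regulated.
- `effect_magnitude`: when set, effects are ±that magnitude instead of
  N(0, sd) draws. For the antagonistic cis×trans class the trans side is
  drawn at twice the magnitude: equal-and-opposite fixed effects are
  definitionally the compensatory class (parental divergence exactly
  zero), so a fixed-magnitude cis×trans gene is constructed as
  `c = ±m, t = ∓2m`, which puts both observable contrasts (A and B) at
  magnitude `m`.
- `treatment_effect_sd` = 0.5: per-gene cold shifts applied equally to all
  genotypes, making cis/trans architecture treatment-invariant by default
  (matching the observed stability of regulation under short cold stress).
  Treatment-dependent architectures can be emulated by simulating
  treatments as separate crosses.
- `n_replicates` maps generation × treatment to 0–4 replicates, with a
  `dropout` map for missing cells (e.g. a hybrid/cold cell with no
  replicates, which the engines flag as not assessable rather than guess).
- Site tables: per-gene SNP counts are Poisson (`snps_per_gene_mean`,
  minimum one), parent depths Poisson around `site_depth_mean` floored at
  the genotyping minima for designed-informative sites, and a configurable
  `uninformative_site_fraction` of sites fail ascertainment by
  construction (shallow hybrid, shallow parent, or off-band hybrid ratio).

What the generator deliberately does not emulate: read-level artifacts
(alignment error, mapping bias beyond the scalar `reference_bias`),
contamination, per-gene dispersions, or correlated genes. Passing tests
therefore demonstrate the statistical machinery under the stated model,
not robustness to alignment pathology.

## Genotyping thresholds

Genotypes are called from the variant-allele fraction `r = DV/DP`:
`r < 0.20` hom-ref, `r > 0.80` hom-alt, `0.30 ≤ r ≤ 0.70` het (closed
interval), otherwise no call; zero depth is no call. A SNP is informative
for a cross when the parents are opposite homozygotes each at ≥2 reads and
the hybrid is heterozygous at ≥6 reads; no per-site missing-rate filter is
applied beyond the three samples involved. Boundary conventions: exactly
20% or 80% is a no-call; exactly 30% or 70% is het. The hom-ref band is
`< 20%` — the natural complement of the hom-alt band; sites where the
maternal parent is hom-alt are retained with flipped polarity. SNPs are
assigned to genes by interval containment (BED half-open, GFF3 converted);
SNPs in no gene or in overlapping genes are dropped and counted in the
log. Genes with fewer than 50 allele-informative reads summed over all
samples of a cross are removed before testing; the filter is per cross.

## Linear engine

Columns of the count matrix are (sample, allele) observations: hybrids
contribute two columns, parents one column carrying their own allele.
Normalization uses trimmed-mean-of-M-values factors (30% trim on
log-ratios, 5% on abundance, inverse asymptotic-variance weights,
reference column by the 75th-percentile rule, geometric mean one) on
allele-column library sizes. `y = log2((count + 0.5)/(lib·f + 1)·1e6)`;
per-gene OLS residual sqrt-sd is smoothed against average log2 count by
lowess (span 0.5, 3 robustness iterations) and each observation's weight
is the interpolated trend value at its fitted log-count to the −4th power,
with constant extrapolation beyond the trend range and a floor of 1e-3 on
the trend. Per-gene weighted least squares on the group-indicator design
yields residual variances that are moderated by moment matching of log
variances to a scaled-F model (Newton inversion of the trigamma function);
the prior degrees of freedom are capped at 1e8 when the between-gene
spread does not exceed its sampling expectation. Moderated *t* statistics
use `d0 + d` degrees of freedom; BH adjustment is applied per contrast per
context across genes. Contrasts whose design cells are absent are
reported as NaN and excluded from FDR denominators. The pooled-treatment
analysis refits the same model with treatment dropped from the factor,
turning the two treatments into additional replicates.

The implementation was verified against the Bioconductor reference
(edgeR's TMM, limma's voom/lmFit/contrasts.fit/eBayes/squeezeVar) on
identical matrices; agreement is to ~1e-4 on estimates and essentially
exact on p-value ordering. One deliberate consequence of the moment-match
formulation worth noting: when all residual variances are identical the
posterior variance equals the log-scale bias-corrected common value
(`exp(mean log s² − digamma(d/2) + log(d/2))`), not the raw `s²`.

## Exact engine

Counts are pooled over replicates per gene, treatment and cell. A is an
exact binomial test of the maternal parent's share of parental reads
against `p0` = maternal library total / parental library total (library
sizes from mapped allele-informative reads); B tests the hybrid's allele
split against 0.5; T is Fisher's exact test on
`[[parent maternal, parent paternal], [hybrid maternal, hybrid paternal]]`.
Both tests use the minimum-likelihood two-sided convention — the sum of
outcome probabilities not exceeding the observed probability, with a
relative guard of 1e-7 against floating-point ties — computed from
`gammaln` log-pmfs. Zero margins are flagged not assessable. Signed
estimates are log2 odds (paternal over maternal, A normalized by the null
odds, all with a 0.5 continuity offset). This engine exists as the
comparison method: pooling ignores replicate variance, so overdispersion
masquerades as allelic signal and inflates trans-containing calls.

## Classifiers

The regulatory decision table is total: any not-assessable component, any
unlisted significance pattern, and sign ties (a zero B or T estimate with
all tests significant) land in `ambiguous`, so category counts always sum
to the tested-gene total. The inheritance classifier runs on total
expression of the trio with contrasts H−M, H−P and M−P; the DE universe
is "any pairwise contrast significant" by default (`de_rule="mp"`
restricts to parental divergence). Decision order: additive (hybrid
significantly different from both parents, strictly between them);
dominant for the parent the hybrid matches, where matching requires both
non-significance and |log2FC| < `fc_band` (default 1.0) so low-power genes
are not called matches; overdominant (significantly above both parents,
labelled by the high parent); ambiguous when all three |log2FC| are inside
the band; otherwise not assigned. Underdominance is deliberately routed
to `not_assigned` rather than given its own label. Simulated
overdominance places the hybrid 1.5 log2 above the high parent so that
heterosis is outside the ambiguity band; note that an additive gene's
total always lies within one log2 of its high parent, so additive recovery
is intrinsically limited by the power of the near-parent contrast.

## Numerical and design choices

- Determinism: every simulation derives its generator from
  (seed, crc32(cross id)); identical configurations give byte-identical
  fixtures.
- The per-class recovery analysis is reported on the pooled-treatment fit,
  the design's own device for gaining trans-detection power; per-treatment
  recalls of trans-containing classes at the default dispersion are lower
  (~0.6–0.7) because the T contrast spans four groups.
- Problem sizes in the test suite and acceptance script (2000–3000 genes,
  4 replicates, mean allele depth ~100–200, 50-seed bias loops with 150
  genes each) were chosen so the whole suite completes in well under a
  minute while keeping per-class counts in the hundreds.
- Parents being homozygous, their allele-level table is all-own-allele by
  construction; per-SNP read rows are treated as independent evidence
  (reads spanning two SNPs would be counted twice — a known simplification
  of SNP-level counting).
- The hybrid ≥6-read ascertainment rule is applied to the genomic
  (exome-like) control only, not re-checked in RNA counts.

## Limitations

The generator's single global dispersion and gene-independence mean the
engines are tested under a smooth mean–variance relationship; real data
with per-gene dispersion outliers would lean harder on the robustness of
the moderation step. The exact engine implements only the plain two-sided
conventions (no mid-p or continuity corrections). The CLI's file-based
route expects the site VCF to carry DP/DV (or AD) FORMAT fields and
single-individual exome samples per cross.
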