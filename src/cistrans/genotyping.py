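"""Genotype calls from allelic read-depth ratios and informative-SNP ascertainment.

A site is genotyped from the ratio ``r = DV/DP`` (depth of the variant allele
over total depth).  A SNP is *informative* for a cross when the two inbred
parents are opposite homozygotes (each supported by at least
``min_parent_depth`` reads) and the F1 hybrid carries a heterozygous call
supported by at least ``min_hybrid_depth`` reads; only such transcribed sites
allow a read to be assigned to a parental allele.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

# Allelic-ratio bands for genotype calls.  Below HOM_REF_MAX -> hom_ref,
# above HOM_ALT_MIN -> hom_alt, within [HET_MIN, HET_MAX] -> het (closed
# interval); the gaps [0.20, 0.30) and (0.70, 0.80] yield no call.
HOM_REF_MAX = 0.20
HOM_ALT_MIN = 0.80
HET_MIN = 0.30
HET_MAX = 0.70


class Genotype(enum.Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    NO_CALL = "no_call"


@dataclass(frozen=True)
class SiteRecord:
    """One variant site with per-sample variant-allele depth (dv) and total depth (dp)."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    dv: Mapping[str, int]
    dp: Mapping[str, int]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for sample, d in self.dp.items():
            v = self.dv.get(sample, 0)
            if not (0 <= v <= d):
                raise ValueError(
                    f"invalid depths at {self.chrom}:{self.pos} sample {sample}: dv={v} dp={d}"
                )


@dataclass(frozen=True)
class InformativeSNP:
    """A site where parental reads can be told apart in the hybrid transcriptome."""

    chrom: str
    pos: int
    cross_id: str
    maternal_allele: str  # "ref" or "alt": allele carried by the maternal parent
    gene_id: Optional[str] = None


def call_genotype(dv: int, dp: int) -> Genotype:
    """Call a genotype from variant-allele depth ``dv`` out of total depth ``dp``.

    ``dp == 0`` yields no call.  Otherwise the variant-allele fraction is
    banded: < 20% hom_ref, 30-70% (inclusive) het, > 80% hom_alt, and the
    two in-between bands yield no call.
    """
    if dv < 0 or dp < 0 or dv > dp:
        raise ValueError(f"invalid depths: dv={dv}, dp={dp}")
    if dp == 0:
        return Genotype.NO_CALL
    r = dv / dp
    if r < HOM_REF_MAX:
        return Genotype.HOM_REF
    if r > HOM_ALT_MIN:
        return Genotype.HOM_ALT
    if HET_MIN <= r <= HET_MAX:
        return Genotype.HET
    return Genotype.NO_CALL


def ascertain_informative(
    site: SiteRecord,
    maternal_parent: str,
    paternal_parent: str,
    hybrid: str,
    cross_id: str = "cross",
    min_parent_depth: int = 2,
    min_hybrid_depth: int = 6,
) -> Optional[InformativeSNP]:
    """Return an :class:`InformativeSNP` if the site is informative for the cross.

    Requires opposite homozygous parental calls each with depth >=
    ``min_parent_depth`` and a heterozygous hybrid call with depth >=
    ``min_hybrid_depth``.  No per-site missing-rate filter is applied beyond
    the three samples of the cross.
    """
    for s in (maternal_parent, paternal_parent, hybrid):
        if s not in site.dp:
            raise KeyError(f"sample {s!r} absent from site {site.chrom}:{site.pos}")

    def _call(sample: str) -> Genotype:
        return call_genotype(site.dv.get(sample, 0), site.dp[sample])

    gm, gp, gh = _call(maternal_parent), _call(paternal_parent), _call(hybrid)
    homs = {Genotype.HOM_REF, Genotype.HOM_ALT}
    if gm not in homs or gp not in homs or gm == gp:
        return None
    if site.dp[maternal_parent] < min_parent_depth or site.dp[paternal_parent] < min_parent_depth:
        return None
    if gh is not Genotype.HET or site.dp[hybrid] < min_hybrid_depth:
        return None
    maternal_allele = "ref" if gm is Genotype.HOM_REF else "alt"
    return InformativeSNP(site.chrom, site.pos, cross_id, maternal_allele)


def annotate_genes(
    snps: Iterable[InformativeSNP],
    annotation: Sequence[tuple[str, int, int, str]],
) -> list[InformativeSNP]:
    """Attach gene identifiers to SNPs by interval containment.

    ``annotation`` rows are ``(chrom, start, end, gene_id)`` with 0-based
    half-open coordinates.  SNPs falling in no gene, or in two or more
    overlapping genes, are dropped; the drop counts are logged.
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end, gene_id in annotation:
        if end <= start:
            raise ValueError(f"empty interval for gene {gene_id}: [{start}, {end})")
        trees.setdefault(chrom, IntervalTree()).addi(start, end, gene_id)

    kept: list[InformativeSNP] = []
    n_no_gene = 0
    n_multi = 0
    for snp in snps:
        tree = trees.get(snp.chrom)
        hits = tree[snp.pos - 1] if tree is not None else set()
        if len(hits) == 1:
            kept.append(replace(snp, gene_id=next(iter(hits)).data))
        elif not hits:
            n_no_gene += 1
        else:
            n_multi += 1
    if n_no_gene or n_multi:
        logger.warning(
            "annotate_genes dropped %d SNPs outside genes and %d in overlapping genes",
            n_no_gene,
            n_multi,
        )
    return kept
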