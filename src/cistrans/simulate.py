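"""Synthetic F1-hybrid crosses with known cis/trans regulatory architecture.

The generator mirrors the wild x domesticated cross design: a maternal
reference parent crossed to one other inbred accession, F1 hybrids, two
treatments (control / cold) with up to four replicates per generation, and
exome-capture-like site depth tables for genotyping.  Ground truth follows
the standard identifying decomposition of the design: on the log2 scale a
gene with baseline ``b``, cis effect ``c`` and trans effect ``t`` has

* maternal parent mean ``b``;
* paternal parent mean ``b + c + t`` (parental difference = cis + trans);
* hybrid maternal-allele mean ``b - 1`` and paternal-allele mean
  ``b - 1 + c`` (allelic imbalance reflects cis only, both alleles sharing
  one trans environment; the ``-1`` halves each allele so hybrid totals
  match the additive expectation when trans is absent).

Counts are negative-binomial (variance ``mu + phi mu^2``) around means
scaled so that the average gene receives ``library_size / n_genes`` reads
per column; allele-informative reads are a binomial thinning of gene reads
by ``allelic_capture_fraction``.  Identical (config, seed) pairs give
byte-identical outputs.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

GENERATIONS = ("parent_maternal", "parent_paternal", "hybrid")
TREATMENTS = ("control", "cold")
TRUE_CATEGORIES = (
    "conserved",
    "cis_only",
    "trans_only",
    "cis_plus_trans",
    "cis_by_trans",
    "compensatory",
)

_DEFAULT_PROPORTIONS = {
    "conserved": 0.70,
    "cis_only": 0.12,
    "trans_only": 0.06,
    "cis_plus_trans": 0.04,
    "cis_by_trans": 0.03,
    "compensatory": 0.05,
}


def _default_replicates() -> dict:
    return {g: {t: 4 for t in TREATMENTS} for g in GENERATIONS}


@dataclass
class SimConfig:
    """Parameters of one synthetic study; defaults emulate the cross design."""

    n_genes: int = 1000
    snps_per_gene_mean: float = 3.0
    cross_ids: Sequence[str] = ("cross1",)
    n_replicates: Mapping[str, Mapping[str, int]] = field(default_factory=_default_replicates)
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 1.5
    dispersion: float = 0.05  # NB phi; variance = mu + phi mu^2
    library_size_range: tuple[int, int] = (1_000_000, 1_500_000)
    architecture_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_PROPORTIONS)
    )
    cis_effect_sd: float = 1.0
    trans_effect_sd: float = 1.0
    effect_magnitude: Optional[float] = None  # fixed |effect| instead of N(0, sd)
    treatment_effect_sd: float = 0.5
    allelic_capture_fraction: float = 0.2
    site_depth_mean: float = 20.0
    uninformative_site_fraction: float = 0.1
    reference_bias: float = 0.0  # log2 depression of the hybrid's paternal allele
    inheritance_proportions: Optional[Mapping[str, float]] = None
    dropout: Mapping[tuple[str, str], int] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.snps_per_gene_mean <= 0:
            raise ValueError("snps_per_gene_mean must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be nonnegative")
        if not (0.0 < self.allelic_capture_fraction <= 1.0):
            raise ValueError("allelic_capture_fraction must lie in (0, 1]")
        lo, hi = self.library_size_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid library_size_range")
        total = sum(self.architecture_proportions.get(c, 0.0) for c in TRUE_CATEGORIES)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("architecture_proportions must sum to 1")
        if set(self.architecture_proportions) - set(TRUE_CATEGORIES):
            raise ValueError("unknown architecture category")
        for g in GENERATIONS:
            reps = self.n_replicates.get(g, {})
            if any(not (0 <= reps.get(t, 0) <= 4) for t in TREATMENTS):
                raise ValueError("replicate counts must lie in 0..4")
            effective = [
                reps.get(t, 0) - self.dropout.get((g, t), 0) for t in TREATMENTS
            ]
            if all(n <= 0 for n in effective):
                raise ValueError(f"generation {g!r} has no replicates in any treatment")

    def effective_replicates(self, generation: str, treatment: str) -> int:
        n = self.n_replicates.get(generation, {}).get(treatment, 0)
        return max(0, n - self.dropout.get((generation, treatment), 0))


@dataclass
class SimBundle:
    """Output of :func:`simulate_cross` for one cross."""

    cross_id: str
    sites: pd.DataFrame  # exome site table: chrom, pos, ref, alt, dv_*/dp_*, informative
    snp_map: pd.DataFrame  # chrom, pos, gene_id, maternal_allele
    annotation: pd.DataFrame  # chrom, start, end, gene_id (0-based half-open)
    allele_counts: pd.DataFrame  # long: gene_id, sample_id, allele, count
    snp_rna_counts: Optional[pd.DataFrame]  # chrom, pos, gene_id, sample_id, dv, dp
    total_counts: pd.DataFrame  # genes x samples
    coldata: pd.DataFrame  # sample_id-indexed: generation, treatment, replicate, library_size
    truth: pd.DataFrame
    exome_samples: dict


def _rng_for(config: SimConfig, cross_id: str) -> np.random.Generator:
    return np.random.default_rng([config.seed % (2**31), zlib.crc32(cross_id.encode())])


def _nb(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    mu = np.asarray(mu, float)
    if phi <= 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / phi, scale=mu * phi)
    return rng.poisson(lam)


def _draw_effect(rng, sd: float, magnitude: Optional[float], sign=None) -> float:
    if magnitude is not None:
        s = sign if sign is not None else (1.0 if rng.random() < 0.5 else -1.0)
        return s * magnitude
    x = 0.0
    while x == 0.0:
        x = rng.normal(0.0, sd)
    return x if sign is None else abs(x) * sign


def _draw_truth(rng, config: SimConfig) -> pd.DataFrame:
    cats = rng.choice(
        TRUE_CATEGORIES,
        size=config.n_genes,
        p=[config.architecture_proportions.get(c, 0.0) for c in TRUE_CATEGORIES],
    )
    c = np.zeros(config.n_genes)
    t = np.zeros(config.n_genes)
    for i, cat in enumerate(cats):
        if cat == "cis_only":
            c[i] = _draw_effect(rng, config.cis_effect_sd, config.effect_magnitude)
        elif cat == "trans_only":
            t[i] = _draw_effect(rng, config.trans_effect_sd, config.effect_magnitude)
        elif cat == "cis_plus_trans":
            c[i] = _draw_effect(rng, config.cis_effect_sd, config.effect_magnitude)
            t[i] = _draw_effect(rng, config.trans_effect_sd, config.effect_magnitude,
                                sign=np.sign(c[i]))
        elif cat == "cis_by_trans":
            # antagonistic cis/trans.  With a fixed magnitude m, equal and
            # opposite effects (c = -t) are exactly the compensatory class,
            # so the trans side is drawn at 2m: the observable contrasts then
            # sit at |B| = m (cis) and |A| = m (parental divergence), keeping
            # the class identifiable at the same observable effect size.
            mag_t = None if config.effect_magnitude is None else 2.0 * config.effect_magnitude
            c[i] = _draw_effect(rng, config.cis_effect_sd, config.effect_magnitude)
            t[i] = _draw_effect(rng, config.trans_effect_sd, mag_t, sign=-np.sign(c[i]))
        elif cat == "compensatory":
            c[i] = _draw_effect(rng, config.cis_effect_sd, config.effect_magnitude)
            t[i] = -c[i]
    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, config.n_genes)
    shift = (
        rng.normal(0.0, config.treatment_effect_sd, config.n_genes)
        if config.treatment_effect_sd > 0
        else np.zeros(config.n_genes)
    )

    # Inheritance: hybrid total targets on the linear scale with baseline 1.
    modes = np.array(["additive"] * config.n_genes, dtype=object)
    delta = np.zeros(config.n_genes)
    m0 = np.ones(config.n_genes)
    p0 = 2.0 ** (c + t)
    current = 0.5 * (1.0 + 2.0**c)  # hybrid total before any shift
    if config.inheritance_proportions:
        req_modes = list(config.inheritance_proportions)
        req = rng.choice(
            req_modes, size=config.n_genes, p=[config.inheritance_proportions[m] for m in req_modes]
        )
        for i, mode in enumerate(req):
            if mode == "additive":
                target = 0.5 * (m0[i] + p0[i])
            elif mode == "maternal_dominant":
                target = m0[i]
            elif mode == "paternal_dominant":
                target = p0[i]
            elif mode in ("maternal_overdominant", "paternal_overdominant"):
                # heterosis 1.5 log2 above the high parent, clearly outside
                # the +/-1 fold-change ambiguity band of the classifier
                target = 2.0**1.5 * max(m0[i], p0[i])
                mode = "maternal_overdominant" if m0[i] >= p0[i] else "paternal_overdominant"
            else:
                raise ValueError(f"unknown inheritance mode {mode!r}")
            delta[i] = np.log2(target / current[i])
            modes[i] = mode
    else:
        modes[t != 0] = "unspecified"

    return pd.DataFrame(
        {
            "gene_id": [f"gene{i:05d}" for i in range(config.n_genes)],
            "true_category": cats,
            "c_g": c,
            "t_g": t,
            "baseline_log2": baseline,
            "treatment_shift": shift,
            "true_inheritance_mode": modes,
            "hybrid_shift": delta,
        }
    )


def _sample_frame(config: SimConfig, cross_id: str) -> pd.DataFrame:
    rows = []
    for gen in GENERATIONS:
        for treat in TREATMENTS:
            for rep in range(1, config.effective_replicates(gen, treat) + 1):
                rows.append(
                    {
                        "sample_id": f"{cross_id}.{gen}.{treat}.{rep}",
                        "generation": gen,
                        "treatment": treat,
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows).set_index("sample_id")


def _simulate_sites(rng, config: SimConfig, truth: pd.DataFrame, cross_id: str):
    """Exome-like site depth table plus gene annotation and SNP->gene map."""
    gene_len, spacing = 2000, 3000
    bases = np.array(list("ACGT"))
    exome = {
        "maternal": f"{cross_id}.exome.Pm",
        "paternal": f"{cross_id}.exome.Pp",
        "hybrid": f"{cross_id}.exome.F1",
    }
    ann_rows, site_rows, map_rows = [], [], []
    for i, gene_id in enumerate(truth["gene_id"]):
        start = 1000 + i * spacing
        ann_rows.append({"chrom": "chr1", "start": start, "end": start + gene_len,
                         "gene_id": gene_id})
        n_snps = max(1, int(rng.poisson(config.snps_per_gene_mean)))
        offsets = np.sort(rng.choice(gene_len, size=min(n_snps, gene_len), replace=False))
        for off in offsets:
            ref = rng.choice(bases)
            alt = rng.choice(bases[bases != ref])
            informative = rng.random() >= config.uninformative_site_fraction
            dp_pm = max(2, int(rng.poisson(config.site_depth_mean)))
            dp_pp = max(2, int(rng.poisson(config.site_depth_mean)))
            dp_f1 = max(6, int(rng.poisson(config.site_depth_mean)))
            dv_pm, dv_pp = 0, dp_pp
            if informative:
                dv_f1 = int(rng.binomial(dp_f1, 0.5))
                for _ in range(100):
                    if 0.3 <= dv_f1 / dp_f1 <= 0.7:
                        break
                    dv_f1 = int(rng.binomial(dp_f1, 0.5))
                else:
                    dv_f1 = dp_f1 // 2
            else:
                mode = rng.integers(3)
                if mode == 0:  # hybrid depth below threshold
                    dp_f1 = int(rng.integers(0, 6))
                    dv_f1 = int(rng.binomial(dp_f1, 0.5)) if dp_f1 else 0
                elif mode == 1:  # parent depth below threshold
                    dp_pm = int(rng.integers(0, 2))
                    dv_pm = 0
                    dv_f1 = dp_f1 // 2
                else:  # hybrid ratio outside the het band
                    dv_f1 = int(rng.binomial(dp_f1, 0.1))
                    while 0.3 <= dv_f1 / dp_f1 <= 0.7:
                        dv_f1 = int(rng.binomial(dp_f1, 0.1))
            pos = start + int(off) + 1  # 1-based
            site_rows.append(
                {
                    "chrom": "chr1",
                    "pos": pos,
                    "ref": str(ref),
                    "alt": str(alt),
                    f"dp_{exome['maternal']}": dp_pm,
                    f"dv_{exome['maternal']}": dv_pm,
                    f"dp_{exome['paternal']}": dp_pp,
                    f"dv_{exome['paternal']}": dv_pp,
                    f"dp_{exome['hybrid']}": dp_f1,
                    f"dv_{exome['hybrid']}": dv_f1,
                    "informative": informative,
                }
            )
            if informative:
                map_rows.append(
                    {"chrom": "chr1", "pos": pos, "gene_id": gene_id, "maternal_allele": "ref"}
                )
    return (
        pd.DataFrame(site_rows),
        pd.DataFrame(map_rows),
        pd.DataFrame(ann_rows),
        exome,
    )


def simulate_cross(config: SimConfig, cross_id: str = "cross1",
                   snp_level: bool = True) -> SimBundle:
    """Generate one complete synthetic cross.

    Returns the exome site table, the gene annotation, gene-level allele
    counts (long form), optional per-SNP RNA counts (a multinomial split of
    the gene counts across the gene's informative SNPs), total counts and
    the ground-truth record.  Deterministic in (config, seed, cross_id).
    """
    rng = _rng_for(config, cross_id)
    truth = _draw_truth(rng, config)
    coldata = _sample_frame(config, cross_id)
    sites, snp_map, annotation, exome = _simulate_sites(rng, config, truth, cross_id)

    n = config.n_genes
    b = truth["baseline_log2"].to_numpy()
    c = truth["c_g"].to_numpy()
    t = truth["t_g"].to_numpy()
    shift = truth["treatment_shift"].to_numpy()
    delta = truth["hybrid_shift"].to_numpy()
    scale = float(np.sum(2.0**b))  # average gene gets library_size / n_genes reads

    lib_sizes = {}
    allele_rows = {}
    total_cols = {}
    capture = config.allelic_capture_fraction
    for sample_id, row in coldata.iterrows():
        L = int(rng.integers(config.library_size_range[0], config.library_size_range[1] + 1))
        lib_sizes[sample_id] = L
        b_eff = b + (shift if row["treatment"] == "cold" else 0.0)
        if row["generation"] == "parent_maternal":
            mu = 2.0**b_eff / scale * L
            total = _nb(rng, mu, config.dispersion)
            allele = rng.binomial(total, capture)
            allele_rows[(sample_id, "maternal")] = allele
            allele_rows[(sample_id, "paternal")] = np.zeros(n, dtype=int)
            total_cols[sample_id] = total
        elif row["generation"] == "parent_paternal":
            mu = 2.0 ** (b_eff + c + t) / scale * L
            total = _nb(rng, mu, config.dispersion)
            allele = rng.binomial(total, capture)
            allele_rows[(sample_id, "maternal")] = np.zeros(n, dtype=int)
            allele_rows[(sample_id, "paternal")] = allele
            total_cols[sample_id] = total
        else:  # hybrid: two allele observations, totals are allele sums
            mu_mat = 2.0 ** (b_eff - 1.0 + delta) / scale * L
            mu_pat = 2.0 ** (b_eff - 1.0 + c + delta - config.reference_bias) / scale * L
            full_mat = _nb(rng, mu_mat, config.dispersion)
            full_pat = _nb(rng, mu_pat, config.dispersion)
            am = rng.binomial(full_mat, capture)
            ap = rng.binomial(full_pat, capture)
            allele_rows[(sample_id, "maternal")] = am
            allele_rows[(sample_id, "paternal")] = ap
            total_cols[sample_id] = am + ap
    coldata = coldata.assign(library_size=[lib_sizes[s] for s in coldata.index])

    gene_ids = truth["gene_id"].to_numpy()
    recs = []
    for (sample_id, allele), counts in allele_rows.items():
        recs.append(
            pd.DataFrame(
                {"gene_id": gene_ids, "sample_id": sample_id, "allele": allele, "count": counts}
            )
        )
    allele_counts = (
        pd.concat(recs, ignore_index=True)
        .sort_values(["gene_id", "sample_id", "allele"], kind="mergesort")
        .reset_index(drop=True)
    )
    total_counts = pd.DataFrame(total_cols, index=gene_ids)
    total_counts.index.name = "gene_id"

    snp_rna = _split_snp_counts(rng, allele_counts, snp_map) if snp_level else None

    return SimBundle(
        cross_id=cross_id,
        sites=sites,
        snp_map=snp_map,
        annotation=annotation,
        allele_counts=allele_counts,
        snp_rna_counts=snp_rna,
        total_counts=total_counts,
        coldata=coldata,
        truth=truth,
        exome_samples=exome,
    )


def _split_snp_counts(rng, allele_counts: pd.DataFrame, snp_map: pd.DataFrame) -> pd.DataFrame:
    """Distribute gene-level allele counts over the gene's informative SNPs.

    Maternal reads land on the reference allele (dv counts alternative-allele
    reads, i.e. paternal ones, since the maternal parent carries the
    reference).  Summing the split back per gene recovers the input exactly.
    """
    snps_by_gene = {g: grp for g, grp in snp_map.groupby("gene_id", observed=True)}
    wide = allele_counts.pivot_table(
        index=["gene_id", "sample_id"], columns="allele", values="count", aggfunc="sum"
    ).reset_index()
    rows = []
    for _, row in wide.iterrows():
        snps = snps_by_gene.get(row["gene_id"])
        if snps is None:
            continue
        k = len(snps)
        probs = np.full(k, 1.0 / k)
        mat = rng.multinomial(int(row.get("maternal", 0)), probs)
        pat = rng.multinomial(int(row.get("paternal", 0)), probs)
        for j in range(k):
            rows.append(
                {
                    "chrom": snps["chrom"].iat[j],
                    "pos": snps["pos"].iat[j],
                    "gene_id": row["gene_id"],
                    "sample_id": row["sample_id"],
                    "dv": int(pat[j]),
                    "dp": int(mat[j] + pat[j]),
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "pos", "gene_id", "sample_id", "dv", "dp"])


# ---------------------------------------------------------------------------
# Fixture writing

def write_fixture(bundle: SimBundle, directory) -> dict[str, Path]:
    """Write a bundle to plain-text files readable by the pipeline.

    Emits a VCF 4.2 site table (FORMAT DP, DV and AD), TSVs for per-SNP RNA
    counts, gene-level allele counts, total counts, samples and truth, a BED
    annotation and a JSON manifest recording the cross id.  Round-trips
    losslessly through :mod:`cistrans.io` readers.
    """
    from . import io as cio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}

    samples = list(bundle.exome_samples.values())
    paths["vcf"] = directory / "sites.vcf"
    cio.write_vcf_sites(paths["vcf"], bundle.sites, samples)

    paths["annotation"] = directory / "annotation.bed"
    cio.write_annotation_bed(paths["annotation"], bundle.annotation)

    def _tsv(name, df, **kw):
        p = directory / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=kw.pop("index", False), lineterminator="\n")
        paths[name] = p

    _tsv("allele_counts", bundle.allele_counts)
    if bundle.snp_rna_counts is not None:
        _tsv("snp_rna_counts", bundle.snp_rna_counts)
    _tsv("total_counts", bundle.total_counts.reset_index())
    _tsv("samples", bundle.coldata.reset_index())
    _tsv("truth", bundle.truth)

    manifest = {"cross_id": bundle.cross_id, "exome_samples": bundle.exome_samples}
    paths["manifest"] = directory / "sim_manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return paths
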