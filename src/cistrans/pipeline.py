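"""End-to-end orchestration: simulate/load -> genotype -> count -> test -> classify.

Every intermediate artifact is a plain TSV so any stage can be rerun
standalone, and the manifest records the per-stage accounting (sites,
informative SNPs, informative genes, genes passing the read filter) that
makes the gene bookkeeping auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from ._version import __version__
from .categories import assign_table, summarize_cross
from .counts import aggregate_snp_table, allele_long_table, filter_low_expression
from .exact_tests import pool_allele_counts, run_ase_exact
from .genotyping import SiteRecord, annotate_genes, ascertain_informative
from .inheritance import classify_table, tabulate_modes
from .linear_model import run_ase_linear, run_trio_linear
from .simulate import SimConfig, SimBundle, simulate_cross

logger = logging.getLogger(__name__)

TRANS_CATEGORIES = ("trans_only", "cis_plus_trans", "cis_by_trans")


@dataclass
class RunConfig:
    """Configuration of one pipeline run (simulated or file-based inputs)."""

    simulation: Optional[SimConfig] = None
    inputs: Optional[dict] = None  # vcf, snp_counts, total_counts, samples, annotation, crosses
    engine: str = "both"  # linear | exact | both
    fdr_threshold: float = 0.01
    min_gene_reads: int = 50
    min_parent_depth: int = 2
    min_hybrid_depth: int = 6
    fc_band: float = 1.0
    de_rule: str = "any"
    pooled: bool = True  # also run the treatments-as-replicates analysis
    outdir: str = "results"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.engine not in ("linear", "exact", "both"):
            raise ValueError(f"unknown engine {self.engine!r}")
        if not (0 < self.fdr_threshold < 1):
            raise ValueError("fdr_threshold must lie in (0, 1)")
        if min(self.min_gene_reads, self.min_parent_depth, self.min_hybrid_depth) < 0:
            raise ValueError("thresholds must be nonnegative")
        if self.simulation is None and self.inputs is None:
            self.simulation = SimConfig(seed=self.seed)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            if "dropout" in sim:
                sim["dropout"] = {tuple(k.split("/")): v for k, v in sim["dropout"].items()}
            cfg.simulation = SimConfig(**sim)
        return cfg

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        if self.simulation is not None:
            sim = asdict(self.simulation)
            sim["cross_ids"] = list(sim["cross_ids"])
            sim["library_size_range"] = list(sim["library_size_range"])
            sim["dropout"] = {"/".join(k): v for k, v in sim["dropout"].items()}
            raw["simulation"] = sim
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=True))

    def digest(self) -> str:
        raw = asdict(self)
        raw.pop("outdir", None)  # execution detail, not part of the analysis
        if self.simulation is not None:
            sim = raw["simulation"]
            sim["cross_ids"] = list(sim["cross_ids"])
            sim["dropout"] = {"/".join(k): v for k, v in sim["dropout"].items()}
        blob = json.dumps(raw, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Stage helpers

def sites_frame_to_records(sites: pd.DataFrame) -> list[SiteRecord]:
    """Convert a wide site table (dv_<sample>/dp_<sample> columns) to records."""
    samples = [c[3:] for c in sites.columns if c.startswith("dp_")]
    records = []
    for _, row in sites.iterrows():
        records.append(
            SiteRecord(
                chrom=row["chrom"],
                pos=int(row["pos"]),
                ref=row["ref"],
                alt=row["alt"],
                dv={s: int(row[f"dv_{s}"]) for s in samples},
                dp={s: int(row[f"dp_{s}"]) for s in samples},
            )
        )
    return records


def genotype_stage(
    site_records: list[SiteRecord],
    maternal: str,
    paternal: str,
    hybrid: str,
    annotation,
    cross_id: str,
    min_parent_depth: int = 2,
    min_hybrid_depth: int = 6,
) -> pd.DataFrame:
    """Ascertain informative SNPs for one cross and attach gene ids."""
    snps = []
    for rec in site_records:
        snp = ascertain_informative(
            rec, maternal, paternal, hybrid, cross_id, min_parent_depth, min_hybrid_depth
        )
        if snp is not None:
            snps.append(snp)
    annotated = annotate_genes(snps, annotation)
    return pd.DataFrame(
        [
            {
                "chrom": s.chrom,
                "pos": s.pos,
                "cross_id": s.cross_id,
                "maternal_allele": s.maternal_allele,
                "gene_id": s.gene_id,
            }
            for s in annotated
        ],
        columns=["chrom", "pos", "cross_id", "maternal_allele", "gene_id"],
    )


def count_stage(
    snp_rna_counts: pd.DataFrame,
    informative_snps: pd.DataFrame,
    min_gene_reads: int = 50,
) -> pd.DataFrame:
    """Aggregate per-SNP RNA counts over informative SNPs to gene level.

    Returns the long (gene_id, sample_id, allele, count) table after the
    low-expression filter.
    """
    merged = snp_rna_counts.drop(columns=["gene_id"], errors="ignore").merge(
        informative_snps[["chrom", "pos", "maternal_allele", "gene_id"]],
        on=["chrom", "pos"],
        how="inner",
    )
    if merged.empty:
        return pd.DataFrame(columns=["gene_id", "sample_id", "allele", "count"])
    gene_table = aggregate_snp_table(merged)
    long = allele_long_table(gene_table)
    return filter_low_expression(long, min_gene_reads)


def allele_matrix(allele_counts: pd.DataFrame, coldata: pd.DataFrame):
    """Build the allele-level count matrix and its column metadata.

    Hybrid samples contribute two columns (one per allele); parent samples
    one column carrying their own allele.  Column ids are
    ``<sample_id>|<allele>``.
    """
    df = allele_counts.merge(
        coldata[["generation", "treatment"]], left_on="sample_id", right_index=True
    )
    parent_gen = df["generation"].isin(["parent_maternal", "parent_paternal"])
    own = df["generation"].map(
        {"parent_maternal": "maternal", "parent_paternal": "paternal"}
    )
    df = df[~parent_gen | (df["allele"] == own)]
    df["column"] = df["sample_id"] + "|" + df["allele"]
    mat = df.pivot_table(index="gene_id", columns="column", values="count",
                         aggfunc="sum", fill_value=0)
    meta = (
        df[["column", "sample_id", "generation", "treatment", "allele"]]
        .drop_duplicates("column")
        .set_index("column")
    )
    meta["generation"] = meta["generation"].map(
        {"parent_maternal": "parent", "parent_paternal": "parent", "hybrid": "hybrid"}
    )
    return mat[sorted(mat.columns)], meta.loc[sorted(mat.columns)]


# ---------------------------------------------------------------------------
# Full run

def _analyze_cross(cross_id, bundle: SimBundle, config: RunConfig) -> dict:
    out: dict = {"cross_id": cross_id}
    annotation = [
        (r["chrom"], int(r["start"]), int(r["end"]), r["gene_id"])
        for _, r in bundle.annotation.iterrows()
    ]
    site_records = sites_frame_to_records(bundle.sites)
    exome = bundle.exome_samples
    informative = genotype_stage(
        site_records,
        exome["maternal"],
        exome["paternal"],
        exome["hybrid"],
        annotation,
        cross_id,
        config.min_parent_depth,
        config.min_hybrid_depth,
    )
    out["informative_snps"] = informative

    if bundle.snp_rna_counts is not None:
        allele_long = count_stage(bundle.snp_rna_counts, informative, config.min_gene_reads)
    else:
        # gene-level route: restrict the simulated gene table to informative genes
        keep = set(informative["gene_id"])
        allele_long = filter_low_expression(
            bundle.allele_counts[bundle.allele_counts["gene_id"].isin(keep)].reset_index(drop=True),
            config.min_gene_reads,
        )
    out["allele_counts"] = allele_long

    counts_mat, meta = allele_matrix(allele_long, bundle.coldata)
    treatments = sorted(bundle.coldata["treatment"].unique())
    engines = ("linear", "exact") if config.engine == "both" else (config.engine,)
    for engine in engines:
        if engine == "linear":
            tests = run_ase_linear(counts_mat, meta, fdr=config.fdr_threshold)
            if config.pooled:
                pooled_tests = run_ase_linear(
                    counts_mat, meta, fdr=config.fdr_threshold, pool_treatments=True
                )
                tests = pd.concat([tests, pooled_tests], ignore_index=True)
        else:
            coldata2 = bundle.coldata.copy()
            coldata2["generation"] = coldata2["generation"].map(
                {"parent_maternal": "parent", "parent_paternal": "parent", "hybrid": "hybrid"}
            )
            pooled_counts = pool_allele_counts(allele_long, coldata2)
            tests = run_ase_exact(pooled_counts, fdr=config.fdr_threshold)
            if config.pooled:
                tests = pd.concat(
                    [tests, run_ase_exact(pooled_counts, fdr=config.fdr_threshold,
                                          pool_treatments=True)],
                    ignore_index=True,
                )
        assigned = assign_table(tests)
        out[f"tests_{engine}"] = assigned
        if len(treatments) == 2:
            per_treat = assigned[assigned["context"].isin(treatments)]
            out[f"summary_{engine}"] = summarize_cross(per_treat, tuple(treatments))

    trio = run_trio_linear(bundle.total_counts, bundle.coldata, fdr=config.fdr_threshold)
    modes = classify_table(trio, fc_band=config.fc_band, de_rule=config.de_rule)
    out["inheritance"] = modes
    out["inheritance_summary"] = pd.concat(
        [
            tabulate_modes(grp).assign(context=ctx)
            for ctx, grp in modes.groupby("context", observed=True)
        ],
        ignore_index=True,
    ) if len(modes) else pd.DataFrame(columns=["mode", "count", "percent", "context"])

    out["stage_counts"] = {
        "n_sites": int(len(bundle.sites)),
        "n_informative_snps": int(len(informative)),
        "n_informative_genes": int(informative["gene_id"].nunique()),
        "n_genes_tested": int(allele_long["gene_id"].nunique()),
    }
    return out


def run(config: RunConfig, outdir=None) -> dict:
    """Execute the full pipeline; returns {cross_id: results} plus a manifest.

    With ``outdir`` (or ``config.outdir``) set, all tables are written as
    TSV and the manifest as JSON.
    """
    outdir = Path(outdir) if outdir is not None else Path(config.outdir)
    results = {}
    if config.simulation is not None:
        sim = config.simulation
        for cross_id in sim.cross_ids:
            bundle = simulate_cross(sim, cross_id)
            results[cross_id] = _analyze_cross(cross_id, bundle, config)
            results[cross_id]["truth"] = bundle.truth
    else:
        from . import io as cio

        inputs = config.inputs
        site_records = cio.read_vcf_sites(inputs["vcf"])
        annotation = (
            cio.read_annotation_gff3(inputs["annotation"])
            if str(inputs["annotation"]).endswith((".gff", ".gff3"))
            else cio.read_annotation_bed(inputs["annotation"])
        )
        snp_counts = cio.read_tsv(inputs["snp_counts"])
        total_counts = cio.read_total_counts(inputs["total_counts"])
        coldata = cio.read_samples(inputs["samples"])
        ann_df = pd.DataFrame(annotation, columns=["chrom", "start", "end", "gene_id"])
        for cross in inputs["crosses"]:
            cross_id = cross["cross_id"]
            sites_df = _records_to_frame(site_records)
            bundle = SimBundle(
                cross_id=cross_id,
                sites=sites_df,
                snp_map=pd.DataFrame(),
                annotation=ann_df,
                allele_counts=pd.DataFrame(columns=["gene_id", "sample_id", "allele", "count"]),
                snp_rna_counts=snp_counts,
                total_counts=total_counts,
                coldata=coldata,
                truth=pd.DataFrame(),
                exome_samples={k: cross[k] for k in ("maternal", "paternal", "hybrid")},
            )
            results[cross_id] = _analyze_cross(cross_id, bundle, config)

    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config_digest": config.digest(),
        "seed": config.seed,
        "engine": config.engine,
        "stage_counts": {c: results[c]["stage_counts"] for c in results},
    }
    results["manifest"] = manifest

    if outdir is not None:
        _write_results(results, outdir, config)
    return results


def _records_to_frame(records: list[SiteRecord]) -> pd.DataFrame:
    samples = sorted({s for r in records for s in r.dp})
    rows = []
    for r in records:
        row = {"chrom": r.chrom, "pos": r.pos, "ref": r.ref, "alt": r.alt}
        for s in samples:
            row[f"dp_{s}"] = r.dp.get(s, 0)
            row[f"dv_{s}"] = r.dv.get(s, 0)
        rows.append(row)
    return pd.DataFrame(rows)


def _write_results(results: dict, outdir: Path, config: RunConfig) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for cross_id, res in results.items():
        if cross_id == "manifest":
            continue
        cdir = outdir / cross_id
        cdir.mkdir(exist_ok=True)
        for key, value in res.items():
            if isinstance(value, pd.DataFrame):
                value.to_csv(cdir / f"{key}.tsv", sep="\t", index=False, lineterminator="\n")
    (outdir / "manifest.json").write_text(
        json.dumps(results["manifest"], indent=2, sort_keys=True) + "\n"
    )
    config.to_yaml(outdir / "config.yaml")


# ---------------------------------------------------------------------------
# Engine comparison

def compare_engines(linear_assigned: pd.DataFrame, exact_assigned: pd.DataFrame) -> dict:
    """Cross-tabulate category calls of the two engines on the same genes.

    Returns the category cross-tabulation, per-method totals of
    trans-containing categories (trans_only + cis_plus_trans +
    cis_by_trans), conserved fractions, and the per-gene discordance list.
    """
    lin = linear_assigned.set_index(["gene_id", "context"])["category"]
    exa = exact_assigned.set_index(["gene_id", "context"])["category"]
    if not lin.index.equals(exa.index):
        common = lin.index.intersection(exa.index)
        if len(common) != len(lin) or len(common) != len(exa):
            raise ValueError("engines were run on different gene universes")
        lin, exa = lin.loc[common], exa.loc[common]
    tab = pd.crosstab(lin, exa, rownames=["linear"], colnames=["exact"])
    trans_lin = int(lin.isin(TRANS_CATEGORIES).sum())
    trans_exa = int(exa.isin(TRANS_CATEGORIES).sum())
    discordant = pd.DataFrame(
        {"linear": lin[lin != exa], "exact": exa[lin != exa]}
    ).reset_index()
    return {
        "crosstab": tab,
        "trans_containing": {"linear": trans_lin, "exact": trans_exa},
        "conserved_fraction": {
            "linear": float((lin == "conserved").mean()),
            "exact": float((exa == "conserved").mean()),
        },
        "discordant": discordant,
    }
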