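"""Gene-level aggregation of per-SNP allele-specific read counts.

Per-SNP (dv, dp) pairs from the RNA-seq data are summed within a gene and
polarity-resolved into maternal/paternal read counts: at a SNP whose maternal
parent carries the reference allele, reference-supporting reads (dp - dv)
are maternal; where the maternal parent carries the alternative allele, dv
itself is maternal.  A DV/DP ratio of 0.5 means both alleles are expressed
equally.  Genes with fewer than ``min_total`` reads summed over every sample
of a cross are removed before testing.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)


def aggregate_gene(
    snp_counts: Iterable[tuple[int, int]],
    polarity: Sequence[str],
) -> dict:
    """Aggregate one gene x sample set of per-SNP (dv, dp) rows.

    ``polarity[i]`` is the maternal allele ("ref" or "alt") of SNP i.
    Returns dv_sum, dp_sum, maternal_count, paternal_count and the DV/DP
    ratio (None when dp_sum is 0).
    """
    dv_sum = dp_sum = maternal = 0
    for (dv, dp), mat in zip(snp_counts, polarity, strict=True):
        if not (0 <= dv <= dp):
            raise ValueError(f"invalid SNP counts dv={dv}, dp={dp}")
        if mat not in ("ref", "alt"):
            raise ValueError(f"invalid maternal allele {mat!r}")
        dv_sum += dv
        dp_sum += dp
        maternal += (dp - dv) if mat == "ref" else dv
    return {
        "dv_sum": dv_sum,
        "dp_sum": dp_sum,
        "maternal_count": maternal,
        "paternal_count": dp_sum - maternal,
        "ratio": dv_sum / dp_sum if dp_sum else None,
    }


def aggregate_snp_table(snp_table: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a per-SNP count table to gene level.

    ``snp_table`` columns: gene_id, sample_id, dv, dp, maternal_allele.
    Returns one row per (gene_id, sample_id) with dv_sum, dp_sum,
    maternal_count, paternal_count.
    """
    df = snp_table.copy()
    if ((df["dv"] < 0) | (df["dv"] > df["dp"])).any():
        bad = df[(df["dv"] < 0) | (df["dv"] > df["dp"])].iloc[0]
        raise ValueError(f"invalid SNP counts dv={bad['dv']}, dp={bad['dp']}")
    df["maternal"] = (df["dp"] - df["dv"]).where(df["maternal_allele"] == "ref", df["dv"])
    out = (
        df.groupby(["gene_id", "sample_id"], sort=True, observed=True)
        .agg(dv_sum=("dv", "sum"), dp_sum=("dp", "sum"), maternal_count=("maternal", "sum"))
        .reset_index()
    )
    out["paternal_count"] = out["dp_sum"] - out["maternal_count"]
    return out


def allele_long_table(gene_table: pd.DataFrame) -> pd.DataFrame:
    """Melt a gene x sample aggregate into long (gene_id, sample_id, allele, count) form."""
    long = gene_table.melt(
        id_vars=["gene_id", "sample_id"],
        value_vars=["maternal_count", "paternal_count"],
        var_name="allele",
        value_name="count",
    )
    long["allele"] = long["allele"].str.replace("_count", "", regex=False)
    return long.sort_values(["gene_id", "sample_id", "allele"]).reset_index(drop=True)


def filter_low_expression(
    gene_table: pd.DataFrame,
    min_total: int = 50,
    count_col: str = "count",
) -> pd.DataFrame:
    """Drop genes with fewer than ``min_total`` reads across all samples of the cross.

    Works on the long (gene_id, sample_id, allele, count) table; idempotent.
    """
    if gene_table.empty:
        return gene_table.copy()
    totals = gene_table.groupby("gene_id", observed=True)[count_col].sum()
    keep = set(totals.index[totals >= min_total])
    dropped = totals.size - len(keep)
    if dropped:
        logger.info("filter_low_expression removed %d genes with < %d reads", dropped, min_total)
    return gene_table[gene_table["gene_id"].isin(keep)].reset_index(drop=True)
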