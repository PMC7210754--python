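"""Readers and writers for the standard formats the pipeline touches.

VCF 4.2 site tables are read with cyvcf2 (FORMAT fields DP and DV, with AD
as a fallback: dv = second AD value); gene annotations come from BED
(0-based half-open) or GFF3 (1-based closed, converted on read); counts and
metadata travel as TSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .genotyping import SiteRecord

VCF_HEADER = """\
##fileformat=VCFv4.2
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total read depth">
##FORMAT=<ID=DV,Number=1,Type=Integer,Description="Depth of the variant allele">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">
##contig=<ID=chr1>
"""


def write_vcf_sites(path, sites: pd.DataFrame, samples: list[str]) -> None:
    """Write a site depth table as VCF 4.2 with DP/DV/AD FORMAT fields."""
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for _, row in sites.iterrows():
            cells = [
                str(row["chrom"]),
                str(int(row["pos"])),
                ".",
                str(row["ref"]),
                str(row["alt"]),
                ".",
                ".",
                ".",
                "DP:DV:AD",
            ]
            for s in samples:
                dp = int(row[f"dp_{s}"])
                dv = int(row[f"dv_{s}"])
                cells.append(f"{dp}:{dv}:{dp - dv},{dv}")
            fh.write("\t".join(cells) + "\n")


def read_vcf_sites(path) -> list[SiteRecord]:
    """Read per-sample DV/DP site records from a VCF (AD fallback)."""
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records = []
    for variant in vcf:
        dp = variant.format("DP")
        dv = variant.format("DV")
        if dv is None:
            ad = variant.format("AD")
            if ad is None:
                raise ValueError(f"no DV or AD FORMAT field at {variant.CHROM}:{variant.POS}")
            dv = ad[:, 1]
            if dp is None:
                dp = ad.sum(axis=1)
        if dp is None:
            raise ValueError(f"no DP FORMAT field at {variant.CHROM}:{variant.POS}")
        dp_arr = np.asarray(dp).reshape(len(samples), -1)[:, 0]
        dv_arr = np.asarray(dv).reshape(len(samples), -1)[:, 0]
        dp_map = {s: max(0, int(dp_arr[i])) for i, s in enumerate(samples)}
        dv_map = {s: max(0, int(dv_arr[i])) for i, s in enumerate(samples)}
        records.append(
            SiteRecord(
                chrom=variant.CHROM,
                pos=variant.POS,
                ref=variant.REF,
                alt=variant.ALT[0] if variant.ALT else ".",
                dv=dv_map,
                dp=dp_map,
            )
        )
    return records


def write_annotation_bed(path, annotation: pd.DataFrame) -> None:
    annotation[["chrom", "start", "end", "gene_id"]].to_csv(
        path, sep="\t", header=False, index=False, lineterminator="\n"
    )


def read_annotation_bed(path) -> list[tuple[str, int, int, str]]:
    """BED4 gene intervals, kept 0-based half-open."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: BED line needs 4 columns")
            try:
                out.append((parts[0], int(parts[1]), int(parts[2]), parts[3]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED line") from exc
    return out


def read_annotation_gff3(path, feature: str = "gene", id_attr: str = "ID") -> list[tuple[str, int, int, str]]:
    """GFF3 gene intervals, converted from 1-based closed to 0-based half-open."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: GFF3 line needs 9 columns")
            if parts[2] != feature:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gene_id = attrs.get(id_attr)
            if gene_id is None:
                raise ValueError(f"{path}:{lineno}: missing {id_attr} attribute")
            try:
                start, end = int(parts[3]), int(parts[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed coordinates") from exc
            out.append((parts[0], start - 1, end, gene_id))
    return out


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def read_total_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df.set_index("gene_id")


def read_samples(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t").set_index("sample_id")
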