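"""Exact-test engine: binomial and Fisher tests on pooled allele counts.

This is the comparison method: replicate counts are pooled per gene, the
parental divergence is tested with an exact binomial test against the
library-size-derived null proportion, the hybrid allelic imbalance against
0.5, and the trans component with Fisher's exact test on the 2x2 table of
parental vs hybrid maternal/paternal reads.  Because pooling discards
between-replicate variability, this engine over-calls trans effects on
overdispersed data relative to the linear engine — the behaviour the two
engines are meant to contrast.

Two-sided p-values use the minimum-likelihood summation rule: the sum of
P(outcome) over all outcomes whose probability does not exceed the observed
one, with a 1e-7 relative guard against floating-point ties.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .linear_model import bh_adjust

_LOG_GUARD = np.log1p(1e-7)


def _binom_logpmf(k, n, p):
    k = np.asarray(k, float)
    return (
        gammaln(n + 1.0)
        - gammaln(k + 1.0)
        - gammaln(n - k + 1.0)
        + k * np.log(p)
        + (n - k) * np.log1p(-p)
    )


def _hypergeom_logpmf(a, n, r1, c1):
    a = np.asarray(a, float)
    return (
        gammaln(r1 + 1.0)
        - gammaln(a + 1.0)
        - gammaln(r1 - a + 1.0)
        + gammaln(n - r1 + 1.0)
        - gammaln(c1 - a + 1.0)
        - gammaln(n - r1 - c1 + a + 1.0)
        - gammaln(n + 1.0)
        + gammaln(c1 + 1.0)
        + gammaln(n - c1 + 1.0)
    )


def binom_two_sided(k: int, n: int, p0: float) -> float:
    """Exact two-sided binomial p-value by minimum-likelihood summation."""
    if not 0 <= k <= n:
        raise ValueError(f"require 0 <= k <= n, got k={k}, n={n}")
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must lie strictly in (0, 1)")
    logpmf = _binom_logpmf(np.arange(n + 1), n, p0)
    p = float(np.exp(logpmf[logpmf <= logpmf[k] + _LOG_GUARD]).sum())
    return min(p, 1.0)


def fisher_two_sided(table) -> float:
    """Exact two-sided Fisher p-value for a 2x2 table, or NaN for a zero margin.

    Enumerates all tables with the observed margins and sums the
    hypergeometric probabilities not exceeding the observed one.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("table cells must be nonnegative")
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or (b + d) == 0:
        return float("nan")
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    logpmf = _hypergeom_logpmf(support, n, r1, c1)
    log_obs = _hypergeom_logpmf(a, n, r1, c1)
    p = float(np.exp(logpmf[logpmf <= log_obs + _LOG_GUARD]).sum())
    return min(p, 1.0)


def pool_allele_counts(allele_counts: pd.DataFrame, coldata: pd.DataFrame) -> pd.DataFrame:
    """Pool replicate allele counts per gene per treatment.

    ``allele_counts`` is long (gene_id, sample_id, allele, count); ``coldata``
    is indexed by sample_id with fields generation in {parent, hybrid} and
    treatment.  Returns one row per (gene_id, treatment) with columns
    parent_maternal, parent_paternal, hybrid_maternal, hybrid_paternal and
    the null maternal proportion ``p0_parent`` derived from the two parents'
    summed allele-informative library sizes.
    """
    df = allele_counts.merge(
        coldata[["generation", "treatment"]], left_on="sample_id", right_index=True
    )
    # Parents carry only their own allele; drop the zero cross-allele rows
    # so library sizes reflect mapped allele-informative reads per parent.
    df["cell"] = df["generation"] + "_" + df["allele"]
    wide = (
        df.groupby(["gene_id", "treatment", "cell"], observed=True)["count"]
        .sum()
        .unstack("cell", fill_value=0)
        .reset_index()
    )
    for col in ("parent_maternal", "parent_paternal", "hybrid_maternal", "hybrid_paternal"):
        if col not in wide:
            wide[col] = 0
    libs = wide.groupby("treatment")[["parent_maternal", "parent_paternal"]].transform("sum")
    denom = libs["parent_maternal"] + libs["parent_paternal"]
    wide["p0_parent"] = (libs["parent_maternal"] / denom).where(denom > 0, np.nan)
    return wide[
        [
            "gene_id",
            "treatment",
            "parent_maternal",
            "parent_paternal",
            "hybrid_maternal",
            "hybrid_paternal",
            "p0_parent",
        ]
    ]


def _log2_odds(num: float, den: float) -> float:
    return float(np.log2((num + 0.5) / (den + 0.5)))


def run_ase_exact(
    pooled: pd.DataFrame,
    fdr: float = 0.01,
    pool_treatments: bool = False,
) -> pd.DataFrame:
    """Apply the binomial/Fisher engine to a pooled count table.

    Per gene and context: A is an exact binomial test of the paternal
    parent's share against the library-size null p0; B an exact binomial
    test of the hybrid's paternal-allele share against 0.5; T a Fisher test
    of parental vs hybrid allele tables.  Signed estimates are log2 odds,
    paternal over maternal, A normalized by the null odds; FDR is applied
    per test family across genes within a context.
    """
    pooled = pooled.copy()
    if pool_treatments:
        p0 = (
            pooled.groupby("gene_id", observed=True)[
                ["parent_maternal", "parent_paternal", "hybrid_maternal", "hybrid_paternal"]
            ].sum()
        ).reset_index()
        libs = p0[["parent_maternal", "parent_paternal"]].sum()
        p0["p0_parent"] = libs["parent_maternal"] / (libs["parent_maternal"] + libs["parent_paternal"])
        p0["treatment"] = "pooled"
        pooled = p0

    out_frames = []
    for context, grp in pooled.groupby("treatment", observed=True):
        grp = grp.reset_index(drop=True)
        est_a = np.full(len(grp), np.nan)
        est_b = np.full(len(grp), np.nan)
        p_a = np.full(len(grp), np.nan)
        p_b = np.full(len(grp), np.nan)
        p_t = np.full(len(grp), np.nan)
        for i, row in grp.iterrows():
            pm, pp = int(row["parent_maternal"]), int(row["parent_paternal"])
            hm, hp = int(row["hybrid_maternal"]), int(row["hybrid_paternal"])
            p0_parent = row["p0_parent"]
            if pm + pp >= 1 and np.isfinite(p0_parent) and 0 < p0_parent < 1:
                p_a[i] = binom_two_sided(pm, pm + pp, p0_parent)
                null_odds = np.log2((1 - p0_parent) / p0_parent)
                est_a[i] = _log2_odds(pp, pm) - null_odds
            if hm + hp >= 1:
                p_b[i] = binom_two_sided(hm, hm + hp, 0.5)
                est_b[i] = _log2_odds(hp, hm)
            p_t[i] = fisher_two_sided([[pm, pp], [hm, hp]])
        block = pd.DataFrame(
            {
                "gene_id": grp["gene_id"],
                "context": context,
                "est_A": est_a,
                "est_B": est_b,
                "est_T": est_a - est_b,
                "p_A": p_a,
                "p_B": p_b,
                "p_T": p_t,
            }
        )
        for name in ("A", "B", "T"):
            q = bh_adjust(block[f"p_{name}"].to_numpy())
            block[f"fdr_{name}"] = q
            sig = pd.array(q <= fdr, dtype="boolean")
            sig[np.isnan(q)] = pd.NA
            block[f"sig_{name}"] = sig
        out_frames.append(block)
    return pd.concat(out_frames, ignore_index=True)
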