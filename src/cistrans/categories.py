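"""Seven-category regulatory classification from the (A, B, T) test triple.

With A the parental-divergence test, B the hybrid allelic-imbalance test and
T (= A - B) the trans test, each gene falls into exactly one category:

========================  ===========================================
cis_only                  A and B significant, T not
trans_only                A significant, B not, T significant
cis_plus_trans            all significant, B and T of the same sign
cis_by_trans              all significant, B and T of opposite sign
compensatory              A not significant, B and T significant
conserved                 nothing significant
ambiguous                 any other pattern, or any test not assessable
========================  ===========================================
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CATEGORIES = (
    "cis_only",
    "trans_only",
    "cis_plus_trans",
    "cis_by_trans",
    "compensatory",
    "conserved",
    "ambiguous",
)


def assign_category(sig_a, sig_b, sig_t, est_b=None, est_t=None) -> str:
    """Map one gene's test triple to a regulatory category.

    Significance flags may be True, False or None/NA (not assessable); any
    not-assessable flag yields ``ambiguous``.  ``est_b``/``est_t`` are only
    consulted to split cis_plus_trans from cis_by_trans; a zero estimate
    there cannot be signed and is routed to ``ambiguous``.
    """
    flags = [sig_a, sig_b, sig_t]
    if any(f is None or f is pd.NA or (isinstance(f, float) and np.isnan(f)) for f in flags):
        return "ambiguous"
    a, b, t = (bool(f) for f in flags)
    if a and b and not t:
        return "cis_only"
    if a and not b and t:
        return "trans_only"
    if a and b and t:
        if est_b is None or est_t is None or est_b == 0 or est_t == 0:
            return "ambiguous"
        if not (np.isfinite(est_b) and np.isfinite(est_t)):
            return "ambiguous"
        return "cis_plus_trans" if np.sign(est_b) == np.sign(est_t) else "cis_by_trans"
    if not a and b and t:
        return "compensatory"
    if not (a or b or t):
        return "conserved"
    return "ambiguous"


def assign_table(tests: pd.DataFrame) -> pd.DataFrame:
    """Assign a category to every row of an engine output frame.

    Expects columns sig_A, sig_B, sig_T, est_B, est_T (engine schema); adds
    a ``category`` column.
    """
    out = tests.copy()
    out["category"] = [
        assign_category(
            row["sig_A"] if pd.notna(row["sig_A"]) else None,
            row["sig_B"] if pd.notna(row["sig_B"]) else None,
            row["sig_T"] if pd.notna(row["sig_T"]) else None,
            row["est_B"],
            row["est_T"],
        )
        for _, row in out.iterrows()
    ]
    return out


def summarize_cross(assignments: pd.DataFrame, contexts=("control", "cold")) -> pd.DataFrame:
    """Category x context count table with an intersection column.

    ``assignments`` has columns gene_id, context, category covering the same
    gene universe in each context.  The intersection counts genes assigned
    to the same category in both contexts; per category it cannot exceed
    either single-context count, and each context column sums to the gene
    universe size.
    """
    c1, c2 = contexts
    u1 = set(assignments.loc[assignments["context"] == c1, "gene_id"])
    u2 = set(assignments.loc[assignments["context"] == c2, "gene_id"])
    if u1 != u2:
        raise ValueError("contexts cover different gene universes")
    pivot = assignments.pivot(index="gene_id", columns="context", values="category")
    rows = []
    for cat in CATEGORIES:
        in1 = pivot[c1] == cat
        in2 = pivot[c2] == cat
        rows.append(
            {
                "category": cat,
                c1: int(in1.sum()),
                c2: int(in2.sum()),
                "intersection": int((in1 & in2).sum()),
            }
        )
    summary = pd.DataFrame(rows)
    total = {
        "category": "total",
        c1: int(len(pivot)),
        c2: int(len(pivot)),
        "intersection": int((pivot[c1] == pivot[c2]).sum()),
    }
    return pd.concat([summary, pd.DataFrame([total])], ignore_index=True)
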