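"""Inheritance-mode classification of hybrid total expression.

Works on total (not allele-specific) expression of the trio: maternal
parent M, paternal parent P, F1 hybrid H, using the three linear-engine
contrasts HM = H - M, HP = H - P and MP = M - P (log2 fold changes with
FDR flags).  Among differentially expressed genes, the hybrid may sit
between the parents (additive), match one parent (dominant for the matched
parent's allele), or exceed both (overdominant for the high parent).

"Matching" a parent requires both a non-significant contrast against it and
an absolute log2 fold change below ``fc_band``, so that low-power genes are
not called matches on non-significance alone.  Genes whose hybrid is
significantly below both parents (underdominance) are not a category here
and fall into ``not_assigned``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

MODES = (
    "additive",
    "maternal_dominant",
    "paternal_dominant",
    "maternal_overdominant",
    "paternal_overdominant",
    "ambiguous",
    "not_assigned",
)


def classify_mode(
    est_hm: float,
    est_hp: float,
    est_mp: float,
    sig_hm,
    sig_hp,
    sig_mp,
    fc_band: float = 1.0,
) -> str:
    """Classify one gene's inheritance mode from the trio contrasts."""
    flags = (sig_hm, sig_hp, sig_mp)
    if any(f is None or f is pd.NA or (isinstance(f, float) and np.isnan(f)) for f in flags) or not all(
        np.isfinite([est_hm, est_hp, est_mp])
    ):
        return "not_assigned"
    s_hm, s_hp, s_mp = (bool(f) for f in flags)
    maternal_high = est_mp > 0

    def matches(sig, est):
        return (not sig) and abs(est) < fc_band

    # 1. additive: hybrid differs from both parents and lies strictly between.
    if s_hm and s_hp and np.sign(est_hm) != np.sign(est_hp) and est_hm != 0 and est_hp != 0:
        return "additive"
    # 2./3. dominance: hybrid matches one parent, differs from the other.
    if matches(s_hm, est_hm) and s_hp:
        return "maternal_dominant"
    if matches(s_hp, est_hp) and s_hm:
        return "paternal_dominant"
    # 4. overdominance: hybrid significantly above both parents.
    if s_hm and s_hp and est_hm > 0 and est_hp > 0:
        return "maternal_overdominant" if maternal_high else "paternal_overdominant"
    # 5. ambiguous: everything within the fold-change band.
    if abs(est_hm) < fc_band and abs(est_hp) < fc_band and abs(est_mp) < fc_band:
        return "ambiguous"
    return "not_assigned"


def classify_table(
    trio: pd.DataFrame,
    fc_band: float = 1.0,
    de_rule: str = "any",
) -> pd.DataFrame:
    """Classify every differentially expressed gene in a trio-contrast frame.

    ``trio`` is the ``run_trio_linear`` output (est_/sig_ HM, HP, MP per
    gene per context).  The DE universe is defined by ``de_rule``: "any"
    keeps genes with any significant pairwise contrast, "mp" only genes
    with a significant parental contrast.  Adds a ``mode`` column.
    """
    df = trio.copy()
    sig = df[["sig_HM", "sig_HP", "sig_MP"]].fillna(False).astype(bool)
    if de_rule == "any":
        de = sig.any(axis=1)
    elif de_rule == "mp":
        de = sig["sig_MP"]
    else:
        raise ValueError(f"unknown de_rule {de_rule!r}")
    df = df[de].reset_index(drop=True)
    df["mode"] = [
        classify_mode(
            row["est_HM"],
            row["est_HP"],
            row["est_MP"],
            row["sig_HM"] if pd.notna(row["sig_HM"]) else None,
            row["sig_HP"] if pd.notna(row["sig_HP"]) else None,
            row["sig_MP"] if pd.notna(row["sig_MP"]) else None,
            fc_band,
        )
        for _, row in df.iterrows()
    ]
    return df


def tabulate_modes(assignments: pd.DataFrame) -> pd.DataFrame:
    """Mode count and percentage table (percentages of the DE-gene total)."""
    total = len(assignments)
    rows = []
    for mode in MODES:
        n = int((assignments["mode"] == mode).sum())
        rows.append(
            {"mode": mode, "count": n, "percent": round(100.0 * n / total, 1) if total else 0.0}
        )
    out = pd.DataFrame(rows)
    out.loc[len(out)] = {"mode": "total", "count": total, "percent": 100.0 if total else 0.0}
    return out
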