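"""Precision-weighted linear-model engine for allele-specific expression.

The engine follows the mean-variance-aware pipeline that is standard for
RNA-seq linear modelling: trimmed-mean-of-log-ratios (TMM) scale factors to
absorb composition and depth differences between columns; conversion of
counts to log2 counts-per-million with per-observation precision weights
derived from a lowess fit of sqrt residual standard deviation against mean
log2 count; per-gene weighted least squares on a one-indicator-per-group
design (generation x allele x treatment); empirical-Bayes moderation of the
residual variances by moment matching on the log scale; and moderated-t
contrasts with Benjamini-Hochberg adjustment per contrast.

Contrasts for the ASE design:

* ``A`` = paternal parent - maternal parent (parental divergence),
* ``B`` = paternal allele - maternal allele within the hybrid (cis),
* ``T`` = ``A - B`` (trans component),

each per treatment context, all in log2 units.  A contrast whose groups are
absent from the design (e.g. a missing hybrid/cold cell) is flagged not
assessable and excluded from the FDR denominator.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

logger = logging.getLogger(__name__)

D0_CAP = 1e8  # sentinel for an effectively infinite prior df


# ---------------------------------------------------------------------------
# Benjamini-Hochberg

def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1.  NaN entries are
    excluded from m and returned as NaN.
    """
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return q
    if (pv < 0).any() or (pv > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    q[ok] = out
    return q


# ---------------------------------------------------------------------------
# TMM scale factors

def _tmm_pair(obs, ref, lib_obs, lib_ref, trim_m=0.3, trim_a=0.05):
    pos = (obs > 0) & (ref > 0)
    obs, ref = obs[pos], ref[pos]
    if obs.size == 0:
        return 1.0
    po, pr = obs / lib_obs, ref / lib_ref
    m = np.log2(po / pr)
    a = 0.5 * np.log2(po * pr)
    v = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm = stats.rankdata(m)
    ra = stats.rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def scale_factors(counts, lib_sizes=None, trim_m: float = 0.3, trim_a: float = 0.05) -> np.ndarray:
    """TMM normalization factors per column, geometric mean 1.

    The reference column is the one whose 75th count-fraction percentile is
    closest to the column mean of those percentiles; per-column log-ratios
    are doubly trimmed (30% on M, 5% on A) and averaged with inverse
    asymptotic-variance weights.
    """
    x = np.asarray(counts, dtype=float)
    if x.ndim != 2:
        raise ValueError("counts must be a 2-D matrix (genes x columns)")
    lib = np.asarray(lib_sizes, dtype=float) if lib_sizes is not None else x.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("every column must have positive total count")
    if x.shape[1] == 1:
        return np.ones(1)
    f75 = np.array([np.quantile(x[:, j] / lib[j], 0.75) for j in range(x.shape[1])])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array(
        [
            1.0 if j == ref else _tmm_pair(x[:, j], x[:, ref], lib[j], lib[ref], trim_m, trim_a)
            for j in range(x.shape[1])
        ]
    )
    return factors / np.exp(np.mean(np.log(factors)))


# ---------------------------------------------------------------------------
# voom: log-CPM + mean-variance precision weights

def voom(counts, design, lib_sizes=None, norm_factors=None, span: float = 0.5):
    """Transform counts to log2-CPM with inverse-variance observation weights.

    ``y = log2((count + 0.5) / (effective library size + 1) * 1e6)``; the
    design is fitted per gene by OLS, sqrt residual sd is smoothed against
    mean log2 count by lowess (``span``), and each observation's weight is
    the predicted sqrt-sd at its fitted log-count raised to the -4th power.
    Falls back to constant weights (with a warning) when the trend cannot be
    estimated.
    """
    x = np.asarray(counts, dtype=float)
    X = np.asarray(design, dtype=float)
    n_genes, n_obs = x.shape
    lib = np.asarray(lib_sizes, dtype=float) if lib_sizes is not None else x.sum(axis=0)
    eff = lib * (np.asarray(norm_factors, float) if norm_factors is not None else 1.0)
    y = np.log2((x + 0.5) / (eff + 1.0) * 1e6)

    rank = np.linalg.matrix_rank(X)
    df_resid = n_obs - rank
    pinv = np.linalg.pinv(X)
    coef = y @ pinv.T
    fitted = coef @ X.T
    resid = y - fitted
    if df_resid < 1:
        warnings.warn("no residual degrees of freedom; using constant voom weights")
        return y, np.ones_like(y)
    sigma = np.sqrt((resid**2).sum(axis=1) / df_resid)

    amean = y.mean(axis=1)
    sx = amean + np.mean(np.log2(eff + 1.0)) - np.log2(1e6)
    sy = np.sqrt(sigma)
    usable = np.isfinite(sx) & np.isfinite(sy)
    if usable.sum() < 2 or np.ptp(sx[usable]) < 1e-12:
        warnings.warn("too few distinct gene means to fit a mean-variance trend; "
                      "using constant voom weights")
        return y, np.ones_like(y)
    trend = sm_lowess(sy[usable], sx[usable], frac=span, it=3, return_sorted=True)
    tx, ty = trend[:, 0], np.maximum(trend[:, 1], 1e-3)

    fitted_count = np.log2(2.0**fitted * (eff + 1.0) / 1e6)
    w = np.interp(fitted_count, tx, ty) ** -4
    return y, w


# ---------------------------------------------------------------------------
# Weighted least squares + empirical-Bayes moderation

@dataclass
class WLSFit:
    """Per-gene weighted least-squares fit on a shared design matrix."""

    coef: np.ndarray  # genes x p
    cov_unscaled: np.ndarray  # genes x p x p, (X'WX)^-1
    sigma2: np.ndarray  # genes, residual variance
    df_resid: int
    columns: list  # design column labels


def fit_wls(y, w, design, columns=None) -> WLSFit:
    """Fit one weighted linear model per gene (rows of ``y``/``w``)."""
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    X = np.asarray(design, float)
    n_obs, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is not of full column rank")
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    df_resid = n_obs - p
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom")
    xtwx = np.einsum("np,gn,nq->gpq", X, w, X)
    xtwy = np.einsum("np,gn->gp", X, w * y)
    coef = np.linalg.solve(xtwx, xtwy[..., None])[..., 0]
    cov = np.linalg.inv(xtwx)
    resid = y - coef @ X.T
    sigma2 = (w * resid**2).sum(axis=1) / df_resid
    cols = list(columns) if columns is not None else list(range(p))
    return WLSFit(coef, cov, sigma2, df_resid, cols)


def _trigamma_inverse(y: float) -> float:
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x + dif
        if -dif / x < 1e-8:
            break
    return float(x)


def squeeze_var(s2, df):
    """Empirical-Bayes moderation of per-gene variances.

    Moment-matches the log residual variances to a scaled F distribution to
    estimate the prior df ``d0`` and prior variance ``s0²``; the posterior
    variance is ``(d0 s0² + d s²)/(d0 + d)``.  When the between-gene spread
    of log variances does not exceed its sampling expectation, ``d0`` is
    capped at a large sentinel and every posterior equals the common value.
    Returns ``(d0, s0_2, s2_post)``.
    """
    s2 = np.asarray(s2, float)
    if s2.size < 2:
        return D0_CAP, float(s2.mean()) if s2.size else np.nan, s2.copy()
    z = np.log(np.maximum(s2, 1e-300))
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        d0 = min(d0, D0_CAP)
        s0_2 = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = D0_CAP
        s0_2 = float(np.exp(emean))
    s2_post = (d0 * s0_2 + df * s2) / (d0 + df)
    return float(d0), s0_2, s2_post


def contrast_stats(fit: WLSFit, contrast, d0: float, s2_post):
    """Moderated-t statistics for one contrast vector over the design columns.

    Returns (estimate, t, p) arrays; two-sided p from t with ``d0 + d`` df.
    """
    c = np.asarray(contrast, float)
    if c.shape != (fit.coef.shape[1],):
        raise ValueError("contrast length does not match design columns")
    if not np.any(c):
        raise ValueError("contrast vector is all zeros")
    est = fit.coef @ c
    var_unscaled = np.einsum("gpq,p,q->g", fit.cov_unscaled, c, c)
    se = np.sqrt(var_unscaled * s2_post)
    t = est / se
    df_total = min(d0 + fit.df_resid, D0_CAP)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return est, t, p


# ---------------------------------------------------------------------------
# High-level engines

def _group_design(groups: pd.Series):
    """One-indicator-per-group design; returns (matrix, group labels)."""
    labels = sorted(groups.unique())
    X = np.zeros((groups.size, len(labels)))
    for j, g in enumerate(labels):
        X[:, j] = (groups == g).to_numpy()
    return X, labels


def _fit_counts(counts: pd.DataFrame, groups: pd.Series, span: float):
    X, labels = _group_design(groups)
    lib = counts.to_numpy(float).sum(axis=0)
    factors = scale_factors(counts.to_numpy(float), lib)
    y, w = voom(counts.to_numpy(float), X, lib, factors, span=span)
    fit = fit_wls(y, w, X, columns=labels)
    d0, s0_2, s2_post = squeeze_var(fit.sigma2, fit.df_resid)
    return fit, d0, s2_post, labels


def _contrast_vec(labels, weights):
    """Contrast vector from a {group: weight} map, or None if any group is absent."""
    if not set(weights) <= set(labels):
        return None
    c = np.zeros(len(labels))
    for g, wt in weights.items():
        c[labels.index(g)] += wt
    return c


def _run_engine(counts, coldata, group_cols, contrast_spec, fdr, span):
    """Shared driver: fit grouped design, evaluate named contrasts per context.

    ``contrast_spec`` maps context -> {name: {group: weight}}.
    """
    groups = coldata[group_cols].astype(str).agg(".".join, axis=1)
    groups = groups.loc[counts.columns]
    fit, d0, s2_post, labels = _fit_counts(counts, groups, span)
    frames = []
    for context, contrasts in contrast_spec.items():
        block = pd.DataFrame({"gene_id": counts.index, "context": context})
        for name, weights in contrasts.items():
            c = _contrast_vec(labels, weights)
            if c is None:
                logger.warning("contrast %s not assessable in context %s", name, context)
                block[f"est_{name}"] = np.nan
                block[f"p_{name}"] = np.nan
                block[f"fdr_{name}"] = np.nan
                block[f"sig_{name}"] = pd.array([pd.NA] * len(counts), dtype="boolean")
                continue
            est, _t, p = contrast_stats(fit, c, d0, s2_post)
            q = bh_adjust(p)
            block[f"est_{name}"] = est
            block[f"p_{name}"] = p
            block[f"fdr_{name}"] = q
            sig = pd.array(q <= fdr, dtype="boolean")
            sig[np.isnan(q)] = pd.NA
            block[f"sig_{name}"] = sig
        frames.append(block)
    return pd.concat(frames, ignore_index=True)


def run_ase_linear(
    counts: pd.DataFrame,
    coldata: pd.DataFrame,
    fdr: float = 0.01,
    pool_treatments: bool = False,
    span: float = 0.5,
) -> pd.DataFrame:
    """Run the linear engine on an allele-level count matrix.

    ``counts``: genes x columns, one column per (sample, allele) observation
    (parent samples contribute one column carrying their own allele).
    ``coldata``: indexed by column id with fields ``generation`` in
    {parent, hybrid}, ``allele`` in {maternal, paternal}, ``treatment``.
    Returns a long frame per gene per context with est/p/fdr/sig for the
    contrasts A (parental divergence), B (hybrid imbalance), T = A - B.
    """
    coldata = coldata.loc[counts.columns]
    if pool_treatments:
        group_cols = ["generation", "allele"]
        contexts = {"pooled": ""}
    else:
        group_cols = ["generation", "allele", "treatment"]
        contexts = {t: f".{t}" for t in sorted(coldata["treatment"].unique())}
    spec = {}
    for context, suffix in contexts.items():
        pm, pp = f"parent.maternal{suffix}", f"parent.paternal{suffix}"
        hm, hp = f"hybrid.maternal{suffix}", f"hybrid.paternal{suffix}"
        spec[context] = {
            "A": {pp: 1.0, pm: -1.0},
            "B": {hp: 1.0, hm: -1.0},
            "T": {pp: 1.0, hm: 1.0, pm: -1.0, hp: -1.0},
        }
    return _run_engine(counts, coldata, group_cols, spec, fdr, span)


def run_trio_linear(
    total_counts: pd.DataFrame,
    coldata: pd.DataFrame,
    fdr: float = 0.01,
    span: float = 0.5,
) -> pd.DataFrame:
    """Run the linear engine on total (not allele-specific) expression.

    ``coldata`` fields: ``generation`` in {parent_maternal, parent_paternal,
    hybrid}, ``treatment``.  Contrasts per treatment: HM = hybrid - maternal
    parent, HP = hybrid - paternal parent, MP = maternal - paternal parent.
    """
    coldata = coldata.loc[total_counts.columns]
    spec = {}
    for t in sorted(coldata["treatment"].unique()):
        m, p, h = f"parent_maternal.{t}", f"parent_paternal.{t}", f"hybrid.{t}"
        spec[t] = {
            "HM": {h: 1.0, m: -1.0},
            "HP": {h: 1.0, p: -1.0},
            "MP": {m: 1.0, p: -1.0},
        }
    return _run_engine(total_counts, coldata, ["generation", "treatment"], spec, fdr, span)
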