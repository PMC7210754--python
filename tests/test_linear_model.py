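"""TMM factors, voom weights, moderated fits, contrasts and BH adjustment."""

import subprocess
import sys

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from cistrans.linear_model import (
    bh_adjust,
    contrast_stats,
    fit_wls,
    run_ase_linear,
    scale_factors,
    squeeze_var,
    voom,
)
from cistrans.pipeline import allele_matrix
from cistrans.counts import filter_low_expression
from cistrans.simulate import SimConfig, simulate_cross
from conftest import linear_assignments, truth_joined


# ---------------------------------------------------------------------------
# Benjamini-Hochberg

def bh_bruteforce(p):
    """O(m^2) literal step-up: q_(i) = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ps = p[order]
    ranks = np.arange(1, m + 1)
    grid = ps * m / ranks  # candidate values per sorted position
    q_sorted = np.array([grid[k:].min() for k in range(m)])
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestBH:
    def test_textbook_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_value_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.5]), [0.5])

    def test_ties_map_to_themselves(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_nan_excluded_and_returned_nan(self):
        q = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(q[1])
        np.testing.assert_allclose(q[[0, 2]], bh_adjust([0.01, 0.04]))

    def test_matches_bruteforce_and_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(123)
        for _ in range(200):
            m = int(rng.integers(1, 120))
            p = rng.random(m) ** rng.uniform(0.5, 3.0)
            q = bh_adjust(p)
            np.testing.assert_allclose(q, bh_bruteforce(p), atol=1e-12)
            np.testing.assert_allclose(
                q, multipletests(p, method="fdr_bh")[1], atol=1e-12
            )

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([1.5])


# ---------------------------------------------------------------------------
# TMM scale factors

class TestScaleFactors:
    def test_identical_columns_give_unit_factors(self):
        rng = np.random.default_rng(0)
        col = rng.integers(1, 500, 300)
        x = np.column_stack([col, col, col])
        np.testing.assert_allclose(scale_factors(x), np.ones(3), atol=1e-12)

    def test_single_column_gives_unit_factor(self):
        np.testing.assert_allclose(scale_factors(np.arange(1, 50)[:, None]), [1.0])

    def test_pure_depth_doubling_is_absorbed_by_library_size(self):
        rng = np.random.default_rng(1)
        a = rng.integers(10, 1000, 400)
        x = np.column_stack([a, 2 * a])  # all M-values are exactly 0
        np.testing.assert_allclose(scale_factors(x), np.ones(2), atol=1e-12)

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(2)
        x = rng.negative_binomial(5, 0.1, size=(500, 6)) + 1
        f = scale_factors(x)
        assert np.isclose(np.exp(np.mean(np.log(f))), 1.0)

    def test_all_zero_column_rejected(self):
        with pytest.raises(ValueError):
            scale_factors(np.array([[1, 0], [2, 0]]))


# ---------------------------------------------------------------------------
# voom

class TestVoom:
    def test_zero_count_logcpm_formula(self):
        # log2((0 + 0.5) / (999999 + 1) * 1e6) = log2(0.5) = -1
        counts = np.array([[0.0], [100.0]])
        design = np.ones((1, 1))
        y, _ = voom(counts, design, lib_sizes=np.array([999_999.0]),
                    norm_factors=np.array([1.0]))
        assert np.isclose(y[0, 0], -1.0)

    def test_poisson_counts_yield_decreasing_sd_trend(self):
        """Under Poisson noise sqrt-sd falls with abundance, so voom weights
        rise with the mean count."""
        rng = np.random.default_rng(5)
        mu = np.exp(rng.uniform(np.log(5), np.log(2000), 2000))
        counts = rng.poisson(mu[:, None], size=(2000, 6)).astype(float)
        design = np.ones((6, 1))
        _, w = voom(counts, design)
        rho = stats.spearmanr(mu, w.mean(axis=1)).statistic
        assert rho > 0.8

    def test_identical_constant_genes_get_equal_weights(self):
        counts = np.full((20, 4), 50.0)
        design = np.ones((4, 1))
        with pytest.warns(UserWarning):
            _, w = voom(counts, design)
        assert np.allclose(w, w[0, 0])

    def test_weights_positive_and_logcpm_finite(self):
        rng = np.random.default_rng(6)
        counts = rng.poisson(50, size=(300, 8)).astype(float)
        design = np.kron(np.eye(2), np.ones((4, 1)))
        y, w = voom(counts, design)
        assert np.isfinite(y).all() and (w > 0).all()


# ---------------------------------------------------------------------------
# WLS + moderation

def _design_two_groups(reps=4):
    return np.kron(np.eye(2), np.ones((reps, 1)))


class TestFitAndModeration:
    def test_equal_weights_reduce_to_ols(self):
        rng = np.random.default_rng(7)
        X = _design_two_groups()
        y = rng.normal(size=(50, 8))
        w = np.full_like(y, 3.7)
        fit = fit_wls(y, w, X)
        beta_ols = y @ np.linalg.pinv(X).T
        np.testing.assert_allclose(fit.coef, beta_ols, atol=1e-10)
        resid = y - beta_ols @ X.T
        s2 = (resid**2).sum(axis=1) / (8 - 2)
        np.testing.assert_allclose(fit.sigma2, s2 * 3.7, atol=1e-10)

    def test_homogeneous_variances_shrink_to_common_value(self):
        # No between-gene heterogeneity: the prior df diverges and every
        # posterior equals the common value implied by the log-scale moment
        # match, exp(mean(log s2) - digamma(d/2) + log(d/2)) — the unbiased
        # back-transform of the mean log variance, slightly above s2 itself.
        from scipy.special import digamma

        s2 = np.full(100, 2.5)
        d0, s0_2, post = squeeze_var(s2, df=4)
        assert d0 >= 1e7  # effectively infinite prior df
        expected = 2.5 * np.exp(-digamma(2.0) + np.log(2.0))
        np.testing.assert_allclose(post, expected, rtol=1e-6)
        assert np.allclose(post, post[0])

    def test_moderation_interpolates_between_prior_and_observed(self):
        rng = np.random.default_rng(8)
        s2 = s2_chi2(rng, n=500, d=4, d0=10.0, s0_2=1.0)
        d0, s0_2, post = squeeze_var(s2, df=4)
        manual = (d0 * s0_2 + 4 * s2) / (d0 + 4)
        np.testing.assert_allclose(post, manual)
        assert (np.abs(np.log(post / 1.0)) <= np.abs(np.log(s2 / 1.0)) + 1e-9).mean() > 0.9

    def test_prior_df_recovery_from_scaled_f_variances(self):
        """Moment matching recovers the simulated prior df within +/-30%."""
        est = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            s2 = s2_chi2(rng, n=200, d=4, d0=10.0, s0_2=1.0)
            d0, _, _ = squeeze_var(s2, df=4)
            est.append(d0)
        assert 7.0 <= np.median(est) <= 13.0

    def test_zero_contrast_rejected(self):
        rng = np.random.default_rng(9)
        X = _design_two_groups()
        y = rng.normal(size=(10, 8))
        fit = fit_wls(y, np.ones_like(y), X)
        with pytest.raises(ValueError):
            contrast_stats(fit, np.zeros(2), 10.0, fit.sigma2)

    def test_rank_deficient_design_rejected(self):
        X = np.ones((8, 2))
        with pytest.raises(ValueError):
            fit_wls(np.zeros((3, 8)), np.ones((3, 8)), X)


def s2_chi2(rng, n, d, d0, s0_2):
    """Sample residual variances from the hierarchical scaled-chi2 model."""
    sigma2 = s0_2 * d0 / rng.chisquare(d0, n)
    return sigma2 * rng.chisquare(d, n) / d


# ---------------------------------------------------------------------------
# Cross-check against the Bioconductor reference implementations

R_SCRIPT = """
suppressMessages({library(edgeR); library(limma)})
args <- commandArgs(trailingOnly=TRUE)
dir <- args[1]
x <- as.matrix(read.delim(file.path(dir, 'counts.tsv'), row.names=1, check.names=FALSE))
g <- read.delim(file.path(dir, 'groups.tsv'), row.names=1)$group
design <- model.matrix(~0+factor(g)); colnames(design) <- levels(factor(g))
d <- calcNormFactors(DGEList(counts=x))
write.table(data.frame(f=d$samples$norm.factors), file.path(dir, 'tmm_r.tsv'),
            sep='\\t', quote=FALSE, row.names=FALSE)
v <- voom(d, design)
fit <- lmFit(v, design)
cm <- makeContrasts(A=parent_paternal-parent_maternal,
                    B=hybrid_paternal-hybrid_maternal,
                    T=(parent_paternal-parent_maternal)-(hybrid_paternal-hybrid_maternal),
                    levels=design)
fit2 <- eBayes(contrasts.fit(fit, cm))
out <- data.frame(gene_id=rownames(x), est_A=fit2$coefficients[,'A'], p_A=fit2$p.value[,'A'],
                  est_B=fit2$coefficients[,'B'], p_B=fit2$p.value[,'B'],
                  est_T=fit2$coefficients[,'T'], p_T=fit2$p.value[,'T'])
write.table(out, file.path(dir, 'fit_r.tsv'), sep='\\t', quote=FALSE, row.names=FALSE)
sv <- squeezeVar(fit$sigma^2, fit$df.residual[1])
write.table(data.frame(d0=sv$df.prior, s02=sv$var.prior, post=sv$var.post),
            file.path(dir, 'squeeze_r.tsv'), sep='\\t', quote=FALSE, row.names=FALSE)
"""


def test_engine_matches_limma_voom_reference(tmp_path):
    """TMM factors, moderated variances and contrast tests agree with the
    edgeR/limma reference implementation on a simulated single-treatment
    matrix."""
    cfg = SimConfig(
        n_genes=300, seed=17, effect_magnitude=1.5,
        n_replicates={g: {"control": 4, "cold": 0} for g in
                      ("parent_maternal", "parent_paternal", "hybrid")},
        library_size_range=(400_000, 400_000),
    )
    bundle = simulate_cross(cfg, "c1", snp_level=False)
    long = filter_low_expression(bundle.allele_counts, 50)
    mat, meta = allele_matrix(long, bundle.coldata)
    mat.to_csv(tmp_path / "counts.tsv", sep="\t")
    groups = meta["generation"] + "_" + meta["allele"]
    groups.to_frame("group").to_csv(tmp_path / "groups.tsv", sep="\t")
    (tmp_path / "oracle.R").write_text(R_SCRIPT)
    subprocess.run(
        ["Rscript", str(tmp_path / "oracle.R"), str(tmp_path)],
        check=True, capture_output=True,
    )

    f_mine = scale_factors(mat.to_numpy(float))
    f_r = pd.read_csv(tmp_path / "tmm_r.tsv", sep="\t")["f"].to_numpy()
    np.testing.assert_allclose(f_mine, f_r, rtol=1e-6)

    mine = run_ase_linear(mat, meta, fdr=0.01)
    mine = mine[mine["context"] == "control"].set_index("gene_id")
    ref = pd.read_csv(tmp_path / "fit_r.tsv", sep="\t").set_index("gene_id")
    for c in ("A", "B", "T"):
        np.testing.assert_allclose(mine[f"est_{c}"], ref[f"est_{c}"], atol=5e-3)
        logp_mine = -np.log10(mine[f"p_{c}"] + 1e-300)
        logp_ref = -np.log10(ref[f"p_{c}"] + 1e-300)
        assert np.corrcoef(logp_mine, logp_ref)[0, 1] > 0.999

    sq_r = pd.read_csv(tmp_path / "squeeze_r.tsv", sep="\t")
    groups_design = pd.get_dummies(groups).to_numpy(float)
    lib = mat.to_numpy(float).sum(axis=0)
    y, w = voom(mat.to_numpy(float), groups_design, lib, f_mine)
    fit = fit_wls(y, w, groups_design)
    d0, s0_2, _ = squeeze_var(fit.sigma2, fit.df_resid)
    d0_r = sq_r["d0"].iloc[0]
    if np.isinf(d0_r):
        assert d0 >= 1e7
    else:
        assert np.isclose(d0, d0_r, rtol=0.05)
    assert np.isclose(s0_2, sq_r["s02"].iloc[0], rtol=0.05)


# ---------------------------------------------------------------------------
# Engine-level behaviour on simulated truth

def test_null_simulation_controls_type_one_error():
    cfg = SimConfig(
        n_genes=800, seed=31, dispersion=0.1,
        architecture_proportions={"conserved": 1.0, "cis_only": 0, "trans_only": 0,
                                  "cis_plus_trans": 0, "cis_by_trans": 0,
                                  "compensatory": 0},
    )
    _, assigned = linear_assignments(cfg)
    per = assigned[assigned["context"].isin(["control", "cold"])]
    escaped = ~per["category"].isin(["conserved", "ambiguous"])
    assert escaped.mean() <= 0.02

def test_pure_cis_genes_show_parental_and_allelic_but_no_trans_signal():
    cfg = SimConfig(
        n_genes=400, seed=32, effect_magnitude=1.5,
        architecture_proportions={"conserved": 0.7, "cis_only": 0.3, "trans_only": 0,
                                  "cis_plus_trans": 0, "cis_by_trans": 0,
                                  "compensatory": 0},
        library_size_range=(1_000_000, 1_000_000),
    )
    bundle, assigned = linear_assignments(cfg)
    df = truth_joined(bundle, assigned, "control")
    cis = df[df["true_category"] == "cis_only"]
    assert cis["sig_A"].fillna(False).mean() > 0.9
    assert cis["sig_B"].fillna(False).mean() > 0.9
    assert cis["sig_T"].fillna(False).mean() < 0.05


def test_missing_design_cell_flags_contrasts_not_assessable():
    """Without any hybrid/cold replicates the cold B and T contrasts cannot
    be formed and are excluded rather than invented."""
    reps = {
        "parent_maternal": {"control": 4, "cold": 4},
        "parent_paternal": {"control": 4, "cold": 4},
        "hybrid": {"control": 4, "cold": 0},
    }
    cfg = SimConfig(n_genes=80, seed=33, n_replicates=reps)
    bundle = simulate_cross(cfg, "c1", snp_level=False)
    long = filter_low_expression(bundle.allele_counts, 50)
    mat, meta = allele_matrix(long, bundle.coldata)
    tests = run_ase_linear(mat, meta)
    cold = tests[tests["context"] == "cold"]
    assert cold["p_B"].isna().all() and cold["p_T"].isna().all()
    assert cold["p_A"].notna().all()
    ctrl = tests[tests["context"] == "control"]
    assert ctrl["p_B"].notna().all()
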