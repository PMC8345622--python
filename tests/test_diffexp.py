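"""Moderated-t pipeline: gene-wise arithmetic, hyperparameter recovery,
shrinkage limits, BH correction, ranked lists, and agreement with the
reference Bioconductor implementation on a small fixture."""

import shutil
import subprocess

import numpy as np
import pytest
from scipy import stats

import nacsig as ns
from nacsig.cohort import ExpressionCohort
from nacsig.diffexp import trigamma_inverse


def _cohort_from(matrix, n_resp):
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[1]
    return ExpressionCohort(matrix, [f"g{i}" for i in range(matrix.shape[0])],
                            [f"s{i}" for i in range(n)],
                            ["responder"] * n_resp + ["non-responder"] * (n - n_resp))


class TestGenewiseFit:
    def test_hand_computed_three_vs_three(self):
        # responders (1,2,3), non-responders (5,6,10):
        # log_fc = 7 - 2 = 5; pooled s2 = (2 + 14)/4 = 4
        c = _cohort_from([[1, 2, 3, 5, 6, 10]], 3)
        fit = ns.fit_genewise(c)
        assert fit.log_fc[0] == pytest.approx(5.0)
        assert fit.s2[0] == pytest.approx(4.0)
        assert fit.df_residual == 4

    def test_identical_groups_give_zero_logfc(self):
        c = _cohort_from([[1, 2, 3, 1, 2, 3]], 3)
        fit = ns.fit_genewise(c)
        assert fit.log_fc[0] == pytest.approx(0.0)
        assert fit.s2[0] == pytest.approx(1.0)  # within-group scatter only

    def test_constant_gene_has_zero_variance(self):
        c = _cohort_from([[2, 2, 2, 2, 2, 2], [0, 1, 2, 3, 4, 5]], 3)
        fit = ns.fit_genewise(c)
        assert fit.s2[0] == 0.0

    def test_small_group_rejected(self):
        m = np.random.default_rng(0).normal(size=(3, 4))
        c = ExpressionCohort(m, ["a", "b", "c"], list("wxyz"),
                             ["responder"] * 3 + ["non-responder"])
        with pytest.raises(ValueError):
            ns.fit_genewise(c)


class TestHyperparams:
    def test_recovery_from_scaled_f_model(self):
        """Variances simulated from the assumed scaled-chi-square hierarchy
        (d0=4, s0^2=1, df=28, 10,000 genes) are recovered closely."""
        rng = np.random.default_rng(42)
        d0_true, s0_true, df = 4.0, 1.0, 28
        true_var = s0_true * d0_true / rng.chisquare(d0_true, size=10000)
        s2 = true_var * rng.chisquare(df, size=10000) / df
        d0, s0_sq = ns.estimate_hyperparams(s2, df)
        assert d0 == pytest.approx(d0_true, abs=0.5)
        assert s0_sq == pytest.approx(s0_true, abs=0.1)

    def test_homogeneous_variances_give_infinite_prior_df(self):
        s2 = np.full(100, 2.5)
        d0, s0_sq = ns.estimate_hyperparams(s2, 10)
        assert np.isinf(d0)
        assert s0_sq == pytest.approx(2.5, rel=0.3)

    def test_two_wild_genes_no_crash(self):
        d0, s0_sq = ns.estimate_hyperparams(np.array([1e-4, 1e4]), 4)
        assert d0 > 0 and s0_sq > 0

    def test_all_zero_variances_rejected(self):
        with pytest.raises(ValueError):
            ns.estimate_hyperparams(np.zeros(10), 4)

    def test_trigamma_inverse_roundtrip(self):
        from scipy.special import polygamma
        for y in (1e-5, 0.01, 0.5, 2.0, 100.0):
            x = trigamma_inverse(y)
            assert float(polygamma(1, x)) == pytest.approx(y, rel=1e-6)


class TestModerate:
    def test_d0_zero_equals_ordinary_pooled_t(self, null_cohort):
        fit = ns.fit_genewise(null_cohort)
        tab = ns.moderate(fit, 0.0, 1.0).table
        resp = null_cohort.matrix[:, :19]
        nonr = null_cohort.matrix[:, 19:]
        t_ref, p_ref = stats.ttest_ind(nonr, resp, axis=1, equal_var=True)
        assert np.allclose(tab["t_moderated"], t_ref, atol=1e-10)
        assert np.allclose(tab["p_value"], p_ref, atol=1e-10)

    def test_infinite_d0_shrinks_fully_to_prior(self, null_cohort):
        fit = ns.fit_genewise(null_cohort)
        tab = ns.moderate(fit, float("inf"), 0.7)
        se = np.sqrt(0.7 * (1 / 19 + 1 / 11))
        assert np.allclose(tab.table["t_moderated"], fit.log_fc / se)

    def test_toy_posterior_variance_arithmetic(self):
        # d0=4, s0^2=1, s2=1, df=4 -> s2_post = 1; n1=n2=3 -> se^2 = 2/3
        c = _cohort_from([[0, 0, 0, 2, 2, 2]], 3)
        fit = ns.fit_genewise(c)
        fit.s2[:] = 1.0
        tab = ns.moderate(fit, 4.0, 1.0).table
        assert tab["t_moderated"].iloc[0] == pytest.approx(2.0 / np.sqrt(2 / 3))
        assert tab["df_total"].iloc[0] == 8.0

    def test_shrinkage_direction(self, null_cohort):
        """Moderation pulls each variance toward s0^2, so the moderated |t|
        exceeds the ordinary |t| exactly for genes with s2 >= s0_sq
        (posterior variance below the raw variance) and vice versa."""
        fit = ns.fit_genewise(null_cohort)
        d0, s0_sq = ns.estimate_hyperparams(fit.s2, fit.df_residual)
        mod = ns.moderate(fit, d0, s0_sq).table
        ord_t = ns.moderate(fit, 0.0, 1.0).table["t_moderated"].to_numpy()
        gain = np.abs(mod["t_moderated"].to_numpy()) >= np.abs(ord_t) - 1e-12
        assert np.array_equal(gain, fit.s2 >= s0_sq - 1e-12)

    def test_type_i_error_calibrated_on_null(self):
        """Unadjusted p < 0.05 for ~5% of null genes (binomial tolerance)."""
        hits, total = 0, 0
        for rep in range(5):
            c = ns.generate_null_cohort(ns.SimulationSpec(19, 11, 2000, 0,
                                                          seed=500 + rep))
            tab = ns.moderated_t_table(c).table
            hits += int((tab["p_value"] < 0.05).sum())
            total += len(tab)
        rate = hits / total
        se = np.sqrt(0.05 * 0.95 / total)
        assert abs(rate - 0.05) < 5 * se + 0.005

    def test_null_pvalues_approximately_uniform(self):
        ps = []
        for rep in range(3):
            c = ns.generate_null_cohort(ns.SimulationSpec(19, 11, 1000, 0,
                                                          seed=900 + rep))
            ps.append(ns.moderated_t_table(c).table["p_value"].to_numpy())
        stat = stats.kstest(np.concatenate(ps), "uniform")
        assert stat.pvalue > 0.01


class TestBH:
    def test_hand_step_up_example(self):
        assert np.allclose(ns.adjust_bh(np.array([0.01, 0.02, 0.03])),
                           [0.03, 0.03, 0.03])

    def test_identity_and_caps(self):
        assert ns.adjust_bh(np.array([0.4]))[0] == 0.4
        assert np.all(ns.adjust_bh(np.ones(5)) == 1.0)

    def test_permutation_invariance_and_reference_agreement(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=200)
        adj = ns.adjust_bh(p)
        perm = rng.permutation(200)
        assert np.allclose(ns.adjust_bh(p[perm]), adj[perm])
        sm = pytest.importorskip("statsmodels.stats.multitest")
        assert np.allclose(adj, sm.multipletests(p, method="fdr_bh")[1])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ns.adjust_bh(np.array([0.5, 1.2]))


class TestRankedLists:
    def test_threshold_and_direction(self, planted_cohort):
        tab = ns.moderated_t_table(planted_cohort)
        rup, nup = ns.ranked_lists(tab, fc_threshold=3.0)
        # planted genes alternate: even-index up in non-responders
        assert planted_cohort.informative_genes[0] in set(nup.entries["gene_id"])
        assert planted_cohort.informative_genes[1] in set(rup.entries["gene_id"])
        for lst in (rup, nup):
            fc = lst.entries["fold_change"].to_numpy()
            assert np.all(fc > 3.0)
            assert np.all(np.diff(fc) <= 0)

    def test_infinite_threshold_empties_lists(self, planted_cohort):
        tab = ns.moderated_t_table(planted_cohort)
        rup, nup = ns.ranked_lists(tab, fc_threshold=np.inf)
        assert rup.entries.empty and nup.entries.empty

    def test_dominant_marker_ranks_first(self):
        """One overwhelming non-responder-up gene tops the list in nearly
        every replicate (the resistance-marker reading)."""
        hits = 0
        for rep in range(20):
            c = ns.generate_two_group_cohort(
                ns.SimulationSpec(19, 11, 300, 1, 5.0, seed=4000 + rep))
            tab = ns.moderated_t_table(c)
            _, nup = ns.ranked_lists(tab, fc_threshold=3.0)
            hits += (not nup.entries.empty and
                     nup.entries["gene_id"].iloc[0] == c.informative_genes[0])
        assert hits >= 19


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="Rscript not available")
def test_agrees_with_bioconductor_reference(tmp_path):
    """Independent oracle: limma's eBayes on the same small matrix gives
    the same moderated t and hyperparameters."""
    c = ns.generate_two_group_cohort(ns.SimulationSpec(6, 5, 150, 10, 2.0,
                                                       seed=77))
    mat = tmp_path / "x.tsv"
    np.savetxt(mat, c.matrix, delimiter="\t")
    script = tmp_path / "ref.R"
    script.write_text(f"""
suppressMessages(library(limma))
x <- as.matrix(read.delim("{mat}", header=FALSE))
design <- cbind(Intercept=1, NonResp=c(rep(0,6), rep(1,5)))
fit <- eBayes(lmFit(x, design))
out <- cbind(fit$t[,2], fit$df.prior, fit$s2.prior)
write.table(out, "{tmp_path / 'out.tsv'}", sep="\\t",
            row.names=FALSE, col.names=FALSE)
""")
    res = subprocess.run(["Rscript", str(script)], capture_output=True,
                         text=True, timeout=300)
    assert res.returncode == 0, res.stderr
    ref = np.loadtxt(tmp_path / "out.tsv")
    fit = ns.fit_genewise(c)
    d0, s0_sq = ns.estimate_hyperparams(fit.s2, fit.df_residual)
    tab = ns.moderate(fit, d0, s0_sq).table
    assert d0 == pytest.approx(ref[0, 1], rel=1e-4)
    assert s0_sq == pytest.approx(ref[0, 2], rel=1e-4)
    assert np.allclose(tab["t_moderated"], ref[:, 0], atol=1e-6)
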