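"""Differential-expression stage: fold change, moderated t, DEG rule."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from crossdx.diffexpr import (
    DataError,
    ExpressionStudy,
    adjust_bh,
    adjust_pvalues,
    classify_degs,
    compute_alog2fc,
    fit_moderated_t,
    run_diffexpr,
    trigamma_inverse,
)
from crossdx.synthdata import SimulationConfig, generate_two_disease_studies


def make_study(case_cols, ctrl_cols, gene_ids=None):
    case = np.atleast_2d(np.asarray(case_cols, float))
    ctrl = np.atleast_2d(np.asarray(ctrl_cols, float))
    matrix = np.hstack([case, ctrl])
    gene_ids = gene_ids or [f"g{i}" for i in range(matrix.shape[0])]
    return ExpressionStudy(gene_ids=gene_ids, matrix=matrix,
                           groups=["case"] * case.shape[1] + ["control"] * ctrl.shape[1])


class TestALog2FC:
    @pytest.mark.parametrize(
        "case, ctrl, expected",
        [
            ([[4, 8]], [[1, 2]], 2.0),       # equal n: paired branch
            ([[4, 4]], [[4, 4]], 0.0),       # identical values
            ([[8, 8]], [[2, 2, 2]], 2.0),    # unequal n: difference of means
        ],
    )
    def test_hand_examples(self, case, ctrl, expected):
        study = make_study(case, ctrl)
        assert compute_alog2fc(study, "g0") == pytest.approx(expected)

    @given(st.integers(2, 6), st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_equal_n_branches_agree(self, n, seed):
        """Paired log-ratio and difference-of-means coincide when n1 = n2."""
        rng = np.random.default_rng(seed)
        case = 2.0 ** rng.normal(6, 2, size=(3, n))
        ctrl = 2.0 ** rng.normal(6, 2, size=(3, n))
        paired = np.mean(np.log2(case) - np.log2(ctrl), axis=1)
        diff = np.log2(case).mean(axis=1) - np.log2(ctrl).mean(axis=1)
        np.testing.assert_allclose(paired, diff, rtol=0, atol=1e-10)
        study = make_study(case, ctrl)
        np.testing.assert_allclose(compute_alog2fc(study), diff, atol=1e-10)

    def test_nonpositive_intensity_rejected(self):
        with pytest.raises(DataError, match="g0"):
            make_study([[0.0, 1.0]], [[1.0, 1.0]])


class TestModeratedT:
    def test_d0_zero_equals_classical_t(self, small_sim):
        """With no shrinkage the moderated t is the pooled two-sample t."""
        _, studies1, _, _ = small_sim
        study = studies1[0]
        _, t_mod, _ = fit_moderated_t(study, prior_df=0.0)
        case = study.log2_matrix[:, study.case_mask]
        ctrl = study.log2_matrix[:, ~study.case_mask]
        t_classic = stats.ttest_ind(case.T, ctrl.T, equal_var=True).statistic
        np.testing.assert_allclose(t_mod, t_classic, rtol=1e-10)

    def test_d0_infinite_pins_variance_at_prior(self, small_sim):
        _, studies1, _, _ = small_sim
        summary, _, _ = fit_moderated_t(studies1[0], prior_df=np.inf,
                                        prior_variance=0.07)
        np.testing.assert_allclose(summary.posterior_variance, 0.07)

    def test_shrinkage_bound(self, small_sim):
        """Posterior variance always lies between s_g^2 and s0^2."""
        _, studies1, _, _ = small_sim
        summary, _, _ = fit_moderated_t(studies1[0])
        lo = np.minimum(summary.residual_variance, summary.prior_variance)
        hi = np.maximum(summary.residual_variance, summary.prior_variance)
        post = summary.posterior_variance
        assert np.all(post >= lo - 1e-12) and np.all(post <= hi + 1e-12)

    def test_null_p_uniform_and_prior_recovery(self):
        """Known (d0=4, s0^2=0.05) hierarchical nulls: calibrated p, recovered prior."""
        cfg = SimulationConfig(seed=11, n_genes=5000, n_datasets_per_disease=1,
                               samples_per_group=[(12, 12)], n_shared_up=0,
                               n_shared_down=0, n_specific_per_disease=0)
        studies, _, _ = generate_two_disease_studies(cfg)
        summary, _, p = fit_moderated_t(studies[0])
        assert stats.kstest(p, "uniform").pvalue > 0.01
        assert abs(summary.prior_df - 4.0) / 4.0 < 0.5
        assert abs(summary.prior_variance - 0.05) / 0.05 < 0.25

    def test_trigamma_inverse_roundtrip(self):
        from scipy.special import polygamma
        for x in (0.1, 0.5, 2.0, 17.0):
            assert trigamma_inverse(float(polygamma(1, x))) == pytest.approx(x, rel=1e-6)

    def test_matches_limma_ebayes(self, tmp_path, small_sim):
        """Independent oracle: limma's eBayes on the same log2 matrix."""
        _, studies1, _, _ = small_sim
        study = studies1[0]
        np.savetxt(tmp_path / "x.tsv", study.log2_matrix, delimiter="\t")
        (tmp_path / "groups.txt").write_text("\n".join(study.groups) + "\n")
        summary, t, p = fit_moderated_t(study)
        script = tmp_path / "check.R"
        script.write_text(
            'suppressMessages(library(limma))\n'
            'x <- as.matrix(read.table("x.tsv", sep="\\t"))\n'
            'groups <- readLines("groups.txt")\n'
            'design <- cbind(1, as.integer(groups == "case"))\n'
            'fit <- eBayes(lmFit(x, design))\n'
            'write.table(cbind(fit$t[, 2], fit$p.value[, 2], fit$df.prior,'
            ' fit$s2.prior), "out.tsv", sep="\\t",'
            ' row.names=FALSE, col.names=FALSE)\n'
        )
        subprocess.run(["Rscript", script.name], cwd=tmp_path, check=True,
                       capture_output=True)
        ref = np.loadtxt(tmp_path / "out.tsv")
        np.testing.assert_allclose(t, ref[:, 0], rtol=1e-8)
        np.testing.assert_allclose(p, ref[:, 1], rtol=1e-8)
        assert summary.prior_df == pytest.approx(ref[0, 2], rel=1e-6)
        assert summary.prior_variance == pytest.approx(ref[0, 3], rel=1e-6)


class TestAdjustment:
    def test_step_up_hand_example(self):
        np.testing.assert_allclose(adjust_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_singleton_passthrough(self):
        np.testing.assert_allclose(adjust_bh([1.0]), [1.0])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30),
           st.randoms(use_true_random=False))
    @settings(max_examples=50, deadline=None)
    def test_permutation_equivariance(self, pvals, rnd):
        perm = list(range(len(pvals)))
        rnd.shuffle(perm)
        base = adjust_bh(pvals)
        shuffled = adjust_bh([pvals[i] for i in perm])
        np.testing.assert_allclose(shuffled, [base[i] for i in perm], atol=1e-12)

    def test_adjusted_not_below_raw_and_capped(self):
        p = np.array([0.001, 0.5, 0.9, 0.04, 1.0])
        for method in ("bh", "bonferroni"):
            adj = adjust_pvalues(p, method=method)
            assert np.all(adj >= p - 1e-15) and np.all(adj <= 1.0)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.5])


class TestDEGRule:
    @pytest.mark.parametrize(
        "adj_p, fc, expected",
        [
            (0.01, 1.5, "up"),
            (0.01, -1.5, "down"),
            (0.5, 3.0, "none"),    # fails p condition
            (0.01, 0.8, "none"),   # fails fc condition
            (0.01, 1.0, "none"),   # boundary: strict inequality
        ],
    )
    def test_rule(self, adj_p, fc, expected):
        tab = pd.DataFrame({"gene_id": ["g"], "alog2fc": [fc], "adj_p": [adj_p]})
        deg = classify_degs(tab)
        assert deg.table["direction"].iloc[0] == expected

    def test_counts_recomputable(self, small_sim):
        _, studies1, _, _ = small_sim
        deg, _ = run_diffexpr(studies1[0])
        assert deg.up_count == (deg.table["direction"] == "up").sum()
        assert deg.down_count == (deg.table["direction"] == "down").sum()
        assert deg.up_count + deg.down_count <= len(deg.table)
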