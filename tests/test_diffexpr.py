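"""Ratio/z statistic, empirical-Bayes moderated t, BH adjustment and the
dual-threshold DEP call."""

import math
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from traplfq import (
    bh_adjust,
    call_deps,
    ebayes_moderated_t,
    group_ratio_z,
    impute_noise,
    median_normalize,
)
from traplfq.diffexpr import DegenerateDataError, fit_variance_prior
from conftest import tiny_matrix, two_group_design


def preprocessed_from(inten, n_per_group=2):
    pre = impute_noise(tiny_matrix(np.asarray(inten, float)))
    return pre, two_group_design(n_per_group=n_per_group)


class TestGroupRatioZ:
    def test_hand_arithmetic_three_proteins(self):
        # x = {-1, 0, +1}: mu = 0, sample sd = 1, so z = x
        inten = np.array([
            [4.0, 4.0, 2.0, 2.0],   # ratio 0.5, x = -1
            [4.0, 4.0, 4.0, 4.0],   # ratio 1,   x = 0
            [2.0, 2.0, 4.0, 4.0],   # ratio 2,   x = +1
        ])
        pre, design = preprocessed_from(inten)
        t = group_ratio_z(pre, design, ("B", "A"), ["P0", "P1", "P2"])
        np.testing.assert_allclose(t.log2_ratio, [-1.0, 0.0, 1.0], atol=1e-12)
        np.testing.assert_allclose(t.z, [-1.0, 0.0, 1.0], atol=1e-12)

    def test_degenerate_sigma_zero(self):
        inten = np.full((3, 4), 7.0)
        pre, design = preprocessed_from(inten)
        with pytest.raises(DegenerateDataError):
            group_ratio_z(pre, design, ("B", "A"), ["P0", "P1", "P2"])

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        inten = np.abs(rng.lognormal(3, 1, size=(20, 4)))
        pre1, design = preprocessed_from(inten)
        pre2, _ = preprocessed_from(inten * 2.0)
        ids = [f"P{i}" for i in range(20)]
        t1 = group_ratio_z(pre1, design, ("B", "A"), ids)
        t2 = group_ratio_z(pre2, design, ("B", "A"), ids)
        np.testing.assert_allclose(t1.ratio, t2.ratio, rtol=1e-12)
        np.testing.assert_allclose(t1.z, t2.z, rtol=1e-9)

    def test_z_standardization_exact(self, preprocessed):
        cfg, design, pre, kept, _, _ = preprocessed
        t = group_ratio_z(pre, design, ("test", "ref"), kept)
        assert abs(t.z.mean()) < 1e-9
        assert abs(t.z.std(ddof=1) - 1.0) < 1e-9


class TestModeratedT:
    def _random_pre(self, seed=1, n=50):
        rng = np.random.default_rng(seed)
        inten = np.abs(rng.lognormal(8, 1, size=(n, 8)))
        pre = impute_noise(tiny_matrix(inten))
        return pre, two_group_design(n_per_group=4), [f"P{i}" for i in range(n)]

    def test_d0_zero_equals_classical_t(self):
        """With shrinkage forced off, the statistic is the textbook
        equal-variance two-sample t, protein by protein."""
        pre, design, ids = self._random_pre()
        _, t_mod, p = ebayes_moderated_t(pre, design, ("B", "A"), ids, d0_override=0.0)
        log2i = np.log2(pre.matrix.intensities)
        for i in range(len(ids)):
            t_ref, p_ref = stats.ttest_ind(log2i[i, 4:], log2i[i, :4], equal_var=True)
            assert t_mod[i] == pytest.approx(t_ref, rel=1e-10)
            assert p[i] == pytest.approx(p_ref, rel=1e-10)

    def test_d0_infinity_is_pooled_z(self):
        pre, design, ids = self._random_pre(seed=2)
        fit, t_mod, p = ebayes_moderated_t(
            pre, design, ("B", "A"), ids, d0_override=math.inf
        )
        log2i = np.log2(pre.matrix.intensities)
        diff = log2i[:, 4:].mean(axis=1) - log2i[:, :4].mean(axis=1)
        expected = diff / (math.sqrt(fit.s0_sq) * math.sqrt(0.5))
        np.testing.assert_allclose(t_mod, expected, rtol=1e-10)
        np.testing.assert_allclose(p, 2 * stats.norm.sf(np.abs(t_mod)), rtol=1e-10)

    def test_moderated_variance_between_prior_and_sample(self):
        pre, design, ids = self._random_pre(seed=3)
        fit, _, _ = ebayes_moderated_t(pre, design, ("B", "A"), ids)
        s_tilde = fit.moderated_var()
        lo = np.minimum(fit.s0_sq, fit.s_g_sq)
        hi = np.maximum(fit.s0_sq, fit.s_g_sq)
        assert ((s_tilde >= lo - 1e-12) & (s_tilde <= hi + 1e-12)).all()

    def test_null_p_calibration(self, preprocessed):
        """On null proteins the moderated-t p-values are close to uniform."""
        from traplfq import SimConfig, simulate_lfq, quantifiability_filter, drop_artifacts

        cfg = SimConfig(n_proteins=2000, frac_de=0.0,
                        sample_scale_log2=[0.0] * 8, seed=11)
        m, _ = simulate_lfq(cfg)
        design = cfg.design()
        pre = impute_noise(median_normalize(drop_artifacts(m)))
        kept, _ = quantifiability_filter(
            pre.matrix, design, ("test", "ref"),
            pre_imputation_missing=pre.pre_imputation_missing,
        )
        _, _, p = ebayes_moderated_t(pre, design, ("test", "ref"), kept)
        assert 0.03 <= (p < 0.05).mean() <= 0.07

    def test_matches_limma_reference(self, tmp_path):
        """Independent cross-check of the variance-prior fit and moderated t
        against the Bioconductor reference implementation."""
        rng = np.random.default_rng(5)
        data = rng.normal(20, 1, size=(200, 8)) + rng.normal(0, 0.5, size=(200, 1))
        mat_path = tmp_path / "mat.tsv"
        out_path = tmp_path / "limma.tsv"
        np.savetxt(mat_path, data, delimiter="\t")
        script = textwrap.dedent(f"""
            m <- as.matrix(read.table("{mat_path}"))
            suppressMessages(library(limma))
            design <- cbind(1, c(rep(0,4), rep(1,4)))
            fit <- eBayes(lmFit(m, design))
            write.table(cbind(fit$df.prior, fit$s2.prior, fit$t[,2], fit$sigma^2),
                        "{out_path}", row.names=FALSE, col.names=FALSE)
        """)
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        ref = np.loadtxt(out_path)
        d0, s0 = fit_variance_prior(ref[:, 3], d_g=6)
        assert d0 == pytest.approx(ref[0, 0], rel=1e-6)
        assert s0 == pytest.approx(ref[0, 1], rel=1e-6)
        diff = data[:, 4:].mean(1) - data[:, :4].mean(1)
        s_tilde = (d0 * s0 + 6 * ref[:, 3]) / (d0 + 6)
        t_mine = diff / np.sqrt(s_tilde * 0.5)
        np.testing.assert_allclose(t_mine, ref[:, 2], rtol=1e-9)

    def test_all_zero_variance_errors(self):
        inten = np.tile(np.array([[2.0, 2.0, 2.0, 2.0, 3.0, 3.0, 3.0, 3.0]]), (5, 1))
        pre = impute_noise(tiny_matrix(inten))
        design = two_group_design(n_per_group=4)
        with pytest.raises(DegenerateDataError):
            ebayes_moderated_t(pre, design, ("B", "A"), [f"P{i}" for i in range(5)])


def brute_force_bh(p):
    """Exhaustive step-up definition: q_i = min over p_(j) >= p_i of m p_(j)/rank_j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for i in range(m):
        candidates = [
            m * p[order[j]] / (j + 1)
            for j in range(m)
            if p[order[j]] >= p[i]
        ]
        q[i] = min(1.0, min(candidates))
    return q


class TestBH:
    def test_worked_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
                 min_size=1, max_size=12)
    )
    @settings(max_examples=300, deadline=None)
    def test_matches_brute_force(self, p):
        np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
                 min_size=2, max_size=12)
    )
    @settings(max_examples=100, deadline=None)
    def test_order_preserving(self, p):
        q = bh_adjust(p)
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()


class TestCallDeps:
    @pytest.mark.parametrize(
        "q,z,expected",
        [
            (0.04, 2.5, "up"),
            (0.04, 1.0, "ns"),
            (0.30, 3.0, "ns"),
            (0.04, -2.5, "down"),
            (0.05, 2.5, "ns"),   # q must be strictly below the cut
            (0.04, 1.96, "ns"),  # |z| must strictly exceed the cut
        ],
    )
    def test_dual_rule(self, q, z, expected):
        table = pd.DataFrame({"q": [q], "z": [z]})
        assert call_deps(table)["call"].iloc[0] == expected

    def test_counts_attached(self):
        table = pd.DataFrame({"q": [0.01, 0.01, 0.5], "z": [3.0, -3.0, 0.1]})
        out = call_deps(table)
        assert out.attrs["n_up"] == 1 and out.attrs["n_down"] == 1
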