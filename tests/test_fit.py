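"""GLS fitting, consensus correlation, variance moderation, moderated tests."""

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from mprakit import (
    create_element_frame,
    create_variant_frame,
    estimate_consensus_correlation,
    fit_elements,
    fit_variants,
    moderated_test,
    squeeze_variances,
)
from mprakit._gls import BlockedGLS
from mprakit.data_model import BarcodeCountTable, WideCountFrame
from mprakit.fit import ConsensusCorrelationError, benjamini_hochberg, gls_fit_rows


def _wframe(y, w, design, n_blocks):
    return SimpleNamespace(logratio=y, weight=w, design=design,
                           frame=SimpleNamespace(n_blocks=n_blocks))


class TestGLS:
    def test_reduces_to_ols_with_zero_rho_equal_weights(self, rng):
        n, c = 50, 12
        y = rng.normal(size=(n, c))
        X = np.column_stack([np.ones(c), np.tile([0, 1], c // 2)])
        gls = BlockedGLS(y, np.ones((n, c)), X, n_blocks=3)
        beta, su, sigma, df, ok = gls.fit(rho=0.0)
        assert ok.all()
        for i in range(n):
            ref, *_ = np.linalg.lstsq(X, y[i], rcond=None)
            np.testing.assert_allclose(beta[i], ref, atol=1e-10)
        # unscaled SE matches sqrt(diag((X'X)^-1))
        np.testing.assert_allclose(
            su[0], np.sqrt(np.diag(np.linalg.inv(X.T @ X))), atol=1e-10)

    def test_exact_fit_recovers_group_means(self):
        # ref logratios all 0, alt all 1 -> intercept 0, logFC 1
        y = np.array([[0.0, 0.0, 1.0, 1.0, 0.0, 0.0, 1.0, 1.0]])
        X = np.column_stack([np.ones(8), np.tile([0, 0, 1, 1], 2)])
        gls = BlockedGLS(y, np.ones_like(y), X, n_blocks=2)
        beta, _, sigma, df, ok = gls.fit(rho=0.3)
        assert beta[0] == pytest.approx([0.0, 1.0], abs=1e-12)
        assert sigma[0] == pytest.approx(0.0, abs=1e-10)

    def test_matches_dense_whitening_oracle(self, rng):
        """Closed-form CS inverse agrees with an explicit dense GLS solve
        and with a numeric minimizer of the Gaussian deviance."""
        from scipy.optimize import minimize
        c, n_blocks = 12, 3
        width = c // n_blocks
        X = np.column_stack([np.ones(c), rng.integers(0, 2, c).astype(float)])
        for rho in (-0.2, 0.0, 0.4, 0.9):
            y = rng.normal(size=(1, c))
            w = rng.uniform(0.2, 3.0, size=(1, c))
            gls = BlockedGLS(y, w, X, n_blocks)
            beta, su, sigma, df, ok = gls.fit(rho)
            # dense V = W^{-1/2} Sigma W^{-1/2}
            Sigma = np.kron(np.eye(n_blocks),
                            (1 - rho) * np.eye(width) + rho * np.ones((width, width)))
            Winvs = np.diag(1.0 / np.sqrt(w[0]))
            Vinv = np.linalg.inv(Winvs @ Sigma @ Winvs)
            ref = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y[0])
            np.testing.assert_allclose(beta[0], ref, atol=1e-8)
            np.testing.assert_allclose(
                su[0], np.sqrt(np.diag(np.linalg.inv(X.T @ Vinv @ X))), atol=1e-8)
            # numeric maximizer of the Gaussian likelihood in beta
            obj = lambda b: (y[0] - X @ b) @ Vinv @ (y[0] - X @ b)
            num = minimize(obj, np.zeros(2), method="Nelder-Mead",
                           options={"xatol": 1e-12, "fatol": 1e-14}).x
            np.testing.assert_allclose(beta[0], num, atol=1e-6)

    def test_zero_weight_cells_have_no_influence(self, rng):
        c = 8
        X = np.column_stack([np.ones(c), np.tile([0, 1], 4)])
        y = rng.normal(size=(1, c))
        w = np.ones((1, c))
        w[0, 3] = 0.0
        gls = BlockedGLS(y, w, X, n_blocks=2)
        beta, *_ = gls.fit(0.5)
        y2 = y.copy()
        y2[0, 3] = 99.0  # value at the zero-weight cell is irrelevant
        gls2 = BlockedGLS(y2, w, X, n_blocks=2)
        beta2, *_ = gls2.fit(0.5)
        np.testing.assert_allclose(beta, beta2, atol=1e-12)

    def test_rank_deficient_row_flagged(self, rng):
        c = 8
        X = np.column_stack([np.ones(c), np.tile([0, 1], 4)])
        y = rng.normal(size=(2, c))
        w = np.ones((2, c))
        w[0, X[:, 1] == 1] = 0.0  # row 0: all alt cells missing
        beta, su, sigma, df, ok = BlockedGLS(y, w, X, n_blocks=2).fit(0.0)
        assert not ok[0] and ok[1]
        assert np.isnan(beta[0]).all()


class TestConsensusCorrelation:
    def test_independent_columns_estimate_near_zero(self, rng):
        n, b, m = 2000, 3, 4
        y = rng.normal(size=(n, b * m))
        X = np.ones((b * m, 1))
        rho = estimate_consensus_correlation(_wframe(y, np.ones_like(y), X, b))
        assert abs(rho) < 0.05

    def test_block_random_effects_estimate_high(self, rng):
        n, b, m = 300, 3, 4
        block_effect = np.repeat(rng.normal(size=(n, b)), m, axis=1)
        y = block_effect + 0.05 * rng.normal(size=(n, b * m))
        X = np.ones((b * m, 1))
        rho = estimate_consensus_correlation(_wframe(y, np.ones_like(y), X, b))
        assert rho > 0.9

    def test_matches_reference_estimator_at_intermediate_correlation(self, rng):
        """At rho=0.5 with only 12 observations per row the consensus
        estimator is shrunk toward zero; limma::duplicateCorrelation on this
        exact dataset returns 0.40473 (frozen external oracle)."""
        n, b, m = 2000, 3, 4
        rho_true = 0.5
        shared = np.repeat(rng.normal(size=(n, b)), m, axis=1)
        y = np.sqrt(rho_true) * shared + np.sqrt(1 - rho_true) * rng.normal(size=(n, b * m))
        X = np.ones((b * m, 1))
        rho = estimate_consensus_correlation(_wframe(y, np.ones_like(y), X, b))
        assert rho == pytest.approx(0.40473, abs=0.02)

    def test_singleton_blocks_unidentifiable(self, rng):
        y = rng.normal(size=(10, 3))
        X = np.ones((3, 1))
        with pytest.raises(ConsensusCorrelationError, match="aggregated"):
            estimate_consensus_correlation(_wframe(y, np.ones_like(y), X, 3))


class TestSqueezeVariances:
    def test_identical_variances_hit_infinite_prior_df(self):
        df = np.full(50, 40.0)
        s2 = np.full(50, 0.7)
        d0, s20, s2_post = squeeze_variances(s2, df)
        assert np.isinf(d0)
        np.testing.assert_allclose(s2_post, s20)
        # s20 equals s2 times the known finite-df log-chi-square factor
        factor = np.exp(np.log(20.0) - special.digamma(20.0))
        assert s20 == pytest.approx(0.7 * factor, rel=1e-10)
        assert s20 == pytest.approx(0.7, rel=0.05)

    def test_posterior_is_convex_combination(self, rng):
        s2 = rng.uniform(0.1, 5.0, 200)
        df = rng.integers(2, 30, 200).astype(float)
        d0, s20, s2_post = squeeze_variances(s2, df)
        lo = np.minimum(s2, s20) - 1e-12
        hi = np.maximum(s2, s20) + 1e-12
        assert ((s2_post >= lo) & (s2_post <= hi)).all()

    def test_prior_parameters_recovered_from_own_model(self, rng):
        d0_true, s20_true, df = 4.0, 0.25, 10.0
        n = 5000
        sigma2 = d0_true * s20_true / rng.chisquare(d0_true, n)
        s2 = sigma2 * rng.chisquare(df, n) / df
        d0, s20, _ = squeeze_variances(s2, np.full(n, df))
        assert d0 == pytest.approx(d0_true, rel=0.3)
        assert s20 == pytest.approx(s20_true, rel=0.1)

    def test_too_few_rows_skips_moderation(self):
        with pytest.warns(UserWarning, match="skipped"):
            d0, s20, s2_post = squeeze_variances(np.array([1.0]), np.array([5.0]))
        assert d0 == 0.0
        np.testing.assert_allclose(s2_post, [1.0])


class TestModeratedTest:
    def test_bh_step_up_example(self):
        adj = benjamini_hochberg(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(adj, 0.04)

    def test_bh_matches_brute_force_definition(self, rng):
        for _ in range(5):
            p = rng.uniform(size=rng.integers(3, 40))
            m = len(p)
            order = np.argsort(p)
            ranked = p[order]
            brute = np.empty(m)
            for i in range(m):
                brute[i] = min(1.0, (ranked[i:] * m / np.arange(i + 1, m + 1)).min())
            expected = np.empty(m)
            expected[order] = brute
            np.testing.assert_allclose(benjamini_hochberg(p), expected, atol=1e-12)

    def test_t_statistic_identity_and_pvalues(self, rng):
        coef = rng.normal(size=20)
        su = rng.uniform(0.1, 1.0, 20)
        s2 = rng.uniform(0.5, 2.0, 20)
        df = np.full(20, 10.0)
        t, p, adj = moderated_test(coef, su, s2, df, df_prior=4.0)
        np.testing.assert_allclose(np.abs(t), np.abs(coef) / (np.sqrt(s2) * su))
        np.testing.assert_allclose(p, 2 * stats.t.sf(np.abs(t), 14.0))
        assert (adj >= p - 1e-12).all()
        assert ((p >= 0) & (p <= 1)).all()

    def test_infinite_prior_uses_normal(self):
        t, p, _ = moderated_test(np.array([2.0]), np.array([1.0]),
                                 np.array([1.0]), np.array([10.0]), np.inf)
        assert p[0] == pytest.approx(2 * stats.norm.sf(2.0))


class TestFitVariants:
    def test_group_mean_logfc_recovery(self, small_sim):
        counts, truth, vmap = small_sim
        fit = fit_variants(create_variant_frame(counts, vmap), "barcode")
        means = pd.Series(fit.coef, index=fit.row_ids).groupby(
            truth.set_index("variant_id")["group"]).mean()
        assert means["strong_activating"] == pytest.approx(2.0, abs=0.15)
        assert means["neutral"] == pytest.approx(0.0, abs=0.1)
        assert means["strong_repressing"] == pytest.approx(-2.0, abs=0.15)

    def test_barcode_and_aggregate_modes_agree(self, small_sim):
        counts, truth, vmap = small_sim
        frame = create_variant_frame(counts, vmap)
        bc = fit_variants(frame, "barcode")
        ag = fit_variants(frame, "aggregate")
        r = stats.pearsonr(bc.coef, ag.coef).statistic
        assert r > 0.99

    def test_result_invariants(self, small_sim):
        counts, _, vmap = small_sim
        fit = fit_variants(create_variant_frame(counts, vmap), "barcode")
        ok = fit.ok
        # |t| = |coef| / (sqrt(s2_post) * stdev_unscaled)
        np.testing.assert_allclose(
            np.abs(fit.t[ok]),
            np.abs(fit.coef[ok]) / (np.sqrt(fit.s2_post[ok]) * fit.stdev_unscaled[ok]))
        assert (fit.adj_p_value[ok] >= fit.p_value[ok] - 1e-12).all()
        lo = np.minimum(fit.sigma[ok] ** 2, fit.s2_prior) - 1e-9
        hi = np.maximum(fit.sigma[ok] ** 2, fit.s2_prior) + 1e-9
        assert ((fit.s2_post[ok] >= lo) & (fit.s2_post[ok] <= hi)).all()

    def test_element_frame_rejected(self, small_sim):
        counts, _, _ = small_sim
        with pytest.raises(ValueError, match="variant-mode"):
            fit_variants(create_element_frame(counts), "barcode")


def _element_counts(rng, n_low=60, n_high=60, n_bc=30, n_reps=6,
                    mu=100.0, phi=3.0, high_mult=4.0):
    """Two element groups whose true activity difference is log2(high_mult)."""
    recs = []
    reps = [f"rep{r+1}" for r in range(n_reps)]
    n, p = mu**2 / (phi * mu - mu), None
    for group, n_elem, rna_mu in (("low", n_low, mu), ("high", n_high, mu * high_mult)):
        for i in range(n_elem):
            oligo = f"{group}{i:03d}"
            for j in range(n_bc):
                bc = f"{oligo}b{j:02d}"
                for r in reps:
                    dna = rng.negative_binomial(n, n / (n + mu))
                    n_r = rna_mu**2 / (phi * rna_mu - rna_mu)
                    rna = rng.negative_binomial(n_r, n_r / (n_r + rna_mu))
                    recs.append((r, bc, oligo, int(dna), int(rna)))
    df = pd.DataFrame(recs, columns=["replicate", "barcode", "oligo",
                                     "dna_count", "rna_count"])
    return BarcodeCountTable.from_frame(df, validate=False)


class TestFitElements:
    def test_constant_logratio_returns_that_activity(self):
        y = np.full((1, 12), 1.7)
        X = np.ones((12, 1))
        gls = BlockedGLS(y, np.ones_like(y), X, n_blocks=3)
        beta, *_ = gls.fit(0.4)
        assert beta[0, 0] == pytest.approx(1.7, abs=1e-12)

    def test_activity_difference_recovered_with_small_bias(self, rng):
        counts = _element_counts(rng)
        fit = fit_elements(create_element_frame(counts), "barcode")
        coef = pd.Series(fit.coef, index=fit.row_ids)
        diff = coef[coef.index.str.startswith("high")].mean() \
            - coef[coef.index.str.startswith("low")].mean()
        assert diff == pytest.approx(2.0, abs=0.05)

    def test_missing_padding_does_not_change_coefficients(self, rng):
        counts = _element_counts(rng, n_low=30, n_high=30, n_bc=10, n_reps=3)
        frame = create_element_frame(counts)
        fit = fit_elements(frame, "barcode")
        # append one all-missing slot to every replicate block
        R, B, W = frame.n_rows, frame.n_blocks, frame.block_width

        def pad(arr, fill):
            a3 = arr.reshape(R, B, W)
            extra = np.full((R, B, 1), fill, dtype=arr.dtype)
            return np.concatenate([a3, extra], axis=2).reshape(R, -1)

        padded = WideCountFrame(
            row_ids=frame.row_ids, dna=pad(frame.dna, 0.0), rna=pad(frame.rna, 0.0),
            block=np.repeat(np.array(frame.blocks, dtype=object), W + 1),
            allele=None, missing_mask=pad(frame.missing_mask, True),
            row_meta=frame.row_meta)
        fit_padded = fit_elements(padded, "barcode")
        np.testing.assert_allclose(fit_padded.coef, fit.coef, atol=1e-10)

    def test_aggregate_mode_runs_without_correlation(self, rng):
        counts = _element_counts(rng, n_low=30, n_high=30, n_bc=10, n_reps=3)
        fit = fit_elements(create_element_frame(counts), "aggregate")
        assert fit.consensus_rho == 0.0
        assert np.isfinite(fit.coef).all()
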