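"""NB GLM engine: oracle equivalence, dispersion recovery, LRT calibration."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
import scipy.optimize
import scipy.stats

from riboplate import diffra, simdata
from riboplate.diffra import (
    ALPHA_FLOOR,
    DesignError,
    bh_adjust,
    differential_ra,
    estimate_dispersions,
    fit_nb_glm,
    lrt_interaction,
    nb_loglik,
)


def _random_instance(rng, n=6, p=2):
    X = np.column_stack([np.ones(n), rng.integers(0, 2, size=(n, p - 1))])
    while np.linalg.matrix_rank(X) < p:
        X = np.column_stack([np.ones(n), rng.integers(0, 2, size=(n, p - 1))])
    y = rng.poisson(rng.uniform(2, 40), size=n).astype(float)
    return y, X


class TestFitNbGlm:
    def test_intercept_only_closed_form(self):
        y = np.array([4.0, 4, 4, 4])
        beta, ll = fit_nb_glm(y, np.ones((4, 1)), alpha=0.1)
        assert beta[0] == pytest.approx(np.log(4), abs=1e-6)
        assert ll == pytest.approx(float(nb_loglik(y, np.full(4, 4.0), 0.1)), abs=1e-8)

    def test_saturated_two_by_two_fits_cell_means(self):
        # full interaction design on a balanced 2x2: fitted means = cell means
        y = np.array([3.0, 5, 10, 14, 20, 24, 40, 36])
        cond = np.array([0, 0, 1, 1, 0, 0, 1, 1], dtype=float)
        lib = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=float)
        X = np.column_stack([np.ones(8), cond, lib, cond * lib])
        beta, _ = fit_nb_glm(y, X, alpha=0.05)
        mu = np.exp(X @ beta)
        cells = {(c, l): y[(cond == c) & (lib == l)].mean() for c in (0, 1) for l in (0, 1)}
        for i in range(8):
            assert mu[i] == pytest.approx(cells[(cond[i], lib[i])], rel=1e-5)

    def test_poisson_limit_matches_statsmodels_irls(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(0)
        for _ in range(20):
            y, X = _random_instance(rng)
            off = rng.normal(scale=0.1, size=len(y))
            beta, ll = fit_nb_glm(y, X, offset=off, alpha=0.0)
            ref = sm.GLM(y, X, family=sm.families.Poisson(), offset=off).fit()
            np.testing.assert_allclose(beta, ref.params, atol=1e-5)
            assert ll == pytest.approx(ref.llf, abs=1e-6)

    def test_loglik_matches_direct_optimization_oracle(self):
        """Maximized NB log-likelihood vs scipy direct numerical optimization."""
        rng = np.random.default_rng(1)
        for _ in range(20):
            y, X = _random_instance(rng)
            alpha = rng.uniform(0.01, 0.5)
            beta, ll = fit_nb_glm(y, X, alpha=alpha)

            def neg(b):
                mu = np.exp(np.clip(X @ b, -30, 30))
                return -float(nb_loglik(y, mu, alpha))

            res = scipy.optimize.minimize(
                neg, np.zeros(X.shape[1]), method="Nelder-Mead",
                options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 5000},
            )
            assert ll >= -res.fun - 1e-4
            assert abs(ll - (-res.fun)) < 1e-4

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(4), np.ones(4)])
        with pytest.raises(DesignError):
            fit_nb_glm(np.ones(4), X)


class TestDispersion:
    def _design(self, n_wells=4):
        n = 4 * n_wells
        cond = np.tile(np.repeat([0.0, 1.0], n_wells), 2)
        lib = np.repeat([1.0, 0.0], 2 * n_wells)
        return np.column_stack([np.ones(n), cond, lib, cond * lib])

    def test_poisson_counts_give_near_zero_dispersion(self):
        rng = np.random.default_rng(2)
        X = self._design()
        mu = rng.uniform(100, 500, size=1000)
        Y = rng.poisson(mu[:, None], size=(1000, X.shape[0])).astype(float)
        fit = estimate_dispersions(Y, X, np.zeros(X.shape[0]))
        assert np.median(fit.alpha_moderated) <= 0.01

    def test_nb_dispersion_recovered(self):
        X = self._design()
        medians = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            mu = rng.uniform(50, 500, size=400)
            r = 1 / 0.1
            Y = rng.negative_binomial(r, r / (r + mu[:, None]), size=(400, X.shape[0]))
            fit = estimate_dispersions(Y.astype(float), X, np.zeros(X.shape[0]))
            medians.append(np.median(fit.alpha_moderated))
        assert 0.05 <= np.mean(medians) <= 0.2

    def test_constant_genes_sit_at_floor(self):
        X = self._design()
        Y = np.full((50, X.shape[0]), 7.0)
        fit = estimate_dispersions(Y, X, np.zeros(X.shape[0]))
        assert np.all(fit.alpha_moderated <= 10 * ALPHA_FLOOR)


class TestLrt:
    def test_equal_likelihoods_give_zero_stat(self):
        # constant response: interaction adds nothing
        y = np.full(8, 20.0)
        X_full = np.column_stack(
            [np.ones(8), np.tile([0, 0, 1, 1], 2), np.repeat([0, 1], 4)]
        )
        X_full = np.column_stack([X_full, X_full[:, 1] * X_full[:, 2]])
        stat, p = lrt_interaction(y, X_full, X_full[:, :3], alpha=0.1)
        assert stat == pytest.approx(0.0, abs=1e-6)
        assert p == pytest.approx(1.0, abs=1e-4)

    def test_chi_square_tail_oracle(self):
        assert scipy.stats.chi2.sf(3.84, 1) == pytest.approx(0.050, abs=5e-4)


class TestBH:
    def test_hand_step_up_enumeration(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_and_degenerate_inputs(self):
        np.testing.assert_allclose(bh_adjust([0.3]), [0.3])
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_matches_statsmodels_step_up(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        p = rng.uniform(size=200)
        expected = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)

    def test_nan_passthrough_excluded_from_m(self):
        out = bh_adjust([0.01, np.nan, 0.02])
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]], [0.02, 0.02])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_step_up_properties_hold_for_arbitrary_inputs(self):
        from hypothesis import given, settings
        from hypothesis import strategies as st

        @settings(max_examples=50, deadline=None, derandomize=True)
        @given(
            st.lists(
                st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
                min_size=1,
                max_size=40,
            )
        )
        def check(p):
            p = np.array(p)
            adj = bh_adjust(p)
            assert np.all((adj >= p - 1e-12) & (adj <= 1.0))
            order = np.argsort(p, kind="mergesort")
            assert np.all(np.diff(adj[order]) >= -1e-12)

        check()

    def test_monotone_in_p(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=100)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestDifferentialRA:
    def test_label_swap_flips_lfc_sign_exactly(self, small_sim):
        pc, meta, anno, _ = small_sim
        res = differential_ra(pc, meta, "mTORi", anno=anno)
        swapped = dataclasses.replace(pc, ribo=pc.total.copy(), total=pc.ribo.copy())
        res_sw = differential_ra(swapped, meta, "mTORi", anno=anno)
        ok = res["status"].eq("ok") & res_sw["status"].eq("ok")
        np.testing.assert_allclose(
            res.loc[ok, "lfcRA"], -res_sw.loc[ok, "lfcRA"], atol=1e-4
        )

    def test_spikeins_and_all_zero_genes_excluded(self, small_sim):
        pc, meta, anno, _ = small_sim
        res = differential_ra(pc, meta, "mTORi", anno=anno)
        spikes = anno.biotype_mask(pc.genes, "spikein")
        assert (res.loc[spikes, "status"] == "excluded").all()
        assert res.loc[spikes, "pvalue"].isna().all()
        # excluded genes do not enter the BH denominator
        tested = res["pvalue"].notna()
        np.testing.assert_allclose(
            res.loc[tested, "fdr"], bh_adjust(res.loc[tested, "pvalue"].to_numpy())
        )

    def test_fdr_not_below_pvalue(self, small_sim):
        pc, meta, anno, _ = small_sim
        res = differential_ra(pc, meta, "mTORi", anno=anno)
        ok = res["pvalue"].notna()
        assert (res.loc[ok, "fdr"] >= res.loc[ok, "pvalue"] - 1e-12).all()

    def test_targets_recovered_with_negative_sign(self, small_sim):
        pc, meta, anno, truth = small_sim
        res = differential_ra(pc, meta, "mTORi", anno=anno)
        targets = truth.targets("mTORi")
        sub = res.loc[targets].dropna(subset=["lfcRA"])
        assert (sub["lfcRA"] < 0).mean() >= 0.9

    def test_missing_condition_raises(self, small_sim):
        pc, meta, anno, _ = small_sim
        with pytest.raises(DesignError):
            differential_ra(pc, meta, "no_such_drug", anno=anno)
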