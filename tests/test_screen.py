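"""Screen analytics: PCA, outliers, enrichment, attenuation, network."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from riboplate import screen
from riboplate.screen import (
    ScreenError,
    _classic_es,
    attenuation_analysis,
    attenuation_fractions,
    build_target_sets,
    detect_outliers,
    enrichment_network,
    fisher_enrichment,
    gsea_preranked,
    pca_ra,
    shift_test,
)


def _ra_matrix(seed=0, n_genes=60, n_wells=10, shift_wells=(), shift=0.0):
    rng = np.random.default_rng(seed)
    mat = rng.normal(size=(n_genes, n_wells))
    for w in shift_wells:
        mat[: n_genes // 2, w] += shift
    return pd.DataFrame(
        mat,
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"w{j}" for j in range(n_wells)],
    )


class TestPCA:
    def test_duplicated_sample_gets_identical_scores(self):
        m = _ra_matrix()
        m["w_dup"] = m["w0"]
        scores, _, _ = pca_ra(m)
        np.testing.assert_allclose(
            scores.loc["w0"], scores.loc["w_dup"], atol=1e-10
        )

    def test_explained_variance_non_increasing(self):
        scores, _, evr = pca_ra(_ra_matrix(), n_components=5)
        assert np.all(np.diff(evr) <= 1e-12)
        assert evr.sum() <= 1 + 1e-9

    def test_strong_condition_shift_separates_on_pc1(self):
        for seed in range(5):
            m = _ra_matrix(seed=seed, shift_wells=range(5), shift=3.0)
            scores, _, _ = pca_ra(m)
            pc1 = scores["PC1"].to_numpy()
            a, b = pc1[:5], pc1[5:]
            # silhouette-like separation: group means far apart vs within-spread
            assert abs(a.mean() - b.mean()) > a.std() + b.std()

    def test_disjoint_subset_rejected(self):
        with pytest.raises(ScreenError):
            pca_ra(_ra_matrix(), gene_subset=["nope"])


class TestOutliers:
    def test_tight_cloud_rarely_flagged(self):
        flagged = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            scores = pd.DataFrame(
                rng.normal(size=(96, 2)), columns=["PC1", "PC2"]
            )
            flagged += detect_outliers(scores, k=4).outlier.sum()
        assert flagged / 10 <= 1.0

    def test_planted_outlier_flagged(self):
        rng = np.random.default_rng(1)
        scores = pd.DataFrame(rng.normal(size=(30, 2)), columns=["PC1", "PC2"])
        scores.iloc[0, 0] += 20 * 1.4826 * np.median(
            np.abs(scores["PC1"] - scores["PC1"].median())
        )
        out = detect_outliers(scores, k=4)
        assert bool(out["outlier"].iloc[0])

    def test_infinite_threshold_flags_nothing(self):
        rng = np.random.default_rng(2)
        scores = pd.DataFrame(rng.normal(size=(20, 2)), columns=["PC1", "PC2"])
        assert detect_outliers(scores, k=np.inf)["outlier"].sum() == 0


def _result(genes, lfc, fdr, condition="drug"):
    return pd.DataFrame(
        {"lfcRA": lfc, "fdr": fdr, "condition": condition},
        index=pd.Index(genes, name="gene"),
    )


class TestTargetSets:
    def test_empty_results_give_empty_sets(self):
        ts = build_target_sets({"A": _result([], [], [])})
        assert ts.up["A"] == set() and ts.down["A"] == set()

    def test_threshold_and_direction(self):
        res = _result(["g1", "g2", "g3"], [1.0, -1.0, 2.0], [0.01, 0.01, 0.5])
        ts = build_target_sets({"A": res}, q=0.05)
        assert ts.up["A"] == {"g1"} and ts.down["A"] == {"g2"}

    def test_exclusive_removes_shared_genes_from_all(self):
        a = _result(["g1", "g2"], [1.0, 1.0], [0.01, 0.01])
        b = _result(["g1", "g3"], [1.0, 1.0], [0.01, 0.01])
        ts = build_target_sets({"A": a, "B": b}, exclusive=True)
        assert ts.up["A"] == {"g2"} and ts.up["B"] == {"g3"}
        # disjointness across conditions per direction
        assert not (ts.up["A"] & ts.up["B"])


class TestShiftTest:
    def test_exact_small_sample_enumeration(self):
        _, p = shift_test([1, 2], [3, 4], "less")
        assert p == pytest.approx(1 / 6)

    def test_identical_groups_null(self):
        _, p = shift_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "less")
        assert p >= 0.5

    def test_large_shift_highly_significant(self):
        rng = np.random.default_rng(0)
        top = rng.normal(-1.0, 0.3, size=97)
        bg = rng.normal(0.0, 0.3, size=2000)
        _, p = shift_test(top, bg, "less")
        assert p < 1e-6

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            shift_test([], [1.0], "less")


class TestGseaPreranked:
    def _scores(self, n=4):
        return pd.Series(
            np.arange(n, 0, -1, dtype=float), index=[f"g{i}" for i in range(n)]
        )

    def test_top_ranked_singleton_has_es_one(self):
        r = gsea_preranked(self._scores(), ["g0"], n_perm=50, seed=0)
        assert r.es == pytest.approx(1.0)

    def test_bottom_ranked_singleton_has_es_minus_one(self):
        r = gsea_preranked(self._scores(), ["g3"], n_perm=50, seed=0)
        assert r.es == pytest.approx(-1.0)

    def test_full_universe_set_degenerate(self):
        r = gsea_preranked(self._scores(), ["g0", "g1", "g2", "g3"], n_perm=10, seed=0)
        assert r.direction == "degenerate"
        assert r.es == pytest.approx(1.0)

    def test_es_matches_running_sum_enumeration(self):
        """Brute-force running-sum oracle on all subsets of a 7-gene universe."""
        scores = pd.Series(
            [9.0, 7.0, 5.0, 4.0, 3.0, 2.0, 1.0],
            index=[f"g{i}" for i in range(7)],
        )
        genes = list(scores.index)
        for r in (1, 2, 3):
            for members in itertools.combinations(genes, r):
                hit = np.array([g in members for g in genes])
                nh, n = hit.sum(), len(genes)
                run, best = 0.0, 0.0
                for h in hit:
                    run += 1 / nh if h else -1 / (n - nh)
                    if abs(run) > abs(best) or (abs(run) == abs(best) and run > best):
                        best = run
                got = gsea_preranked(scores, list(members), n_perm=10, seed=0).es
                assert got == pytest.approx(best, abs=1e-12)

    def test_es_bounded_and_p_in_range(self):
        rng = np.random.default_rng(5)
        scores = pd.Series(rng.normal(size=200), index=[f"g{i}" for i in range(200)])
        for seed in range(5):
            members = rng.choice(scores.index, size=20, replace=False)
            r = gsea_preranked(scores, list(members), n_perm=100, seed=seed)
            assert -1 <= r.es <= 1
            assert 1 / 101 <= r.pvalue <= 1

    def test_es_bounded_for_arbitrary_hit_patterns(self):
        from hypothesis import given, settings
        from hypothesis import strategies as st

        @settings(max_examples=100, deadline=None, derandomize=True)
        @given(st.lists(st.booleans(), min_size=2, max_size=50))
        def check(hits):
            hits = np.array(hits, dtype=bool)
            es = _classic_es(hits)
            assert -1.0 <= es <= 1.0
            if hits.any() and not hits.all():
                assert es != 0.0  # the first step already deviates from zero

        check()

    def test_planted_enrichment_detected(self):
        rng = np.random.default_rng(6)
        scores = pd.Series(rng.normal(size=500), index=[f"g{i}" for i in range(500)])
        members = scores.nlargest(30).index
        r = gsea_preranked(scores, list(members), n_perm=500, seed=1)
        assert r.es > 0.8
        assert r.pvalue <= 5 / 501

    def test_deterministic_tie_break_by_gene_id(self):
        scores = pd.Series([1.0, 1.0, 1.0, 0.0], index=["gb", "ga", "gc", "gd"])
        r1 = gsea_preranked(scores, ["ga"], n_perm=10, seed=0)
        r2 = gsea_preranked(scores.iloc[::-1], ["ga"], n_perm=10, seed=0)
        assert r1.es == r2.es


class TestAttenuation:
    def _trio(self, xa, xb, y):
        genes = [f"g{i}" for i in range(len(xa))]
        a = _result(genes, xa, [0.01] * len(xa), "A")
        b = _result(genes, xb, [0.5] * len(xb), "B")
        c = _result(genes, y, [0.5] * len(y), "A+B")
        return a, b, c

    def test_definition_instance_attenuated(self):
        a, b, c = self._trio([-2.0], [-0.5], [-1.0])
        tab = attenuation_analysis(a, b, c)
        assert tab["class"].iloc[0] == "attenuated"
        assert tab["x_individual"].iloc[0] == -2.0

    def test_combo_equal_to_individual_is_enhanced_boundary(self):
        a, b, c = self._trio([-2.0, 1.5], [0.0, 0.0], [-2.0, 1.5])
        tab = attenuation_analysis(a, b, c)
        assert (tab["class"] == "enhanced").all()

    def test_zero_combo_counts_as_attenuated(self):
        a, b, c = self._trio([1.0], [0.5], [0.0])
        assert attenuation_analysis(a, b, c)["class"].iloc[0] == "attenuated"

    def test_sign_flip_is_reversed(self):
        a, b, c = self._trio([1.0], [0.5], [-0.4])
        assert attenuation_analysis(a, b, c)["class"].iloc[0] == "reversed"

    def test_classes_partition_and_fractions_sum_to_one(self):
        rng = np.random.default_rng(7)
        n = 50
        a, b, c = self._trio(
            rng.normal(size=n), rng.normal(size=n), rng.normal(size=n)
        )
        tab = attenuation_analysis(a, b, c)
        assert len(tab) == n  # all genes significant in A
        frac = attenuation_fractions(tab)
        for _, sub in frac.groupby("direction"):
            assert sub["fraction"].sum() == pytest.approx(1.0)

    def test_missing_combo_rejected(self):
        a, b, _ = self._trio([1.0], [0.5], [0.0])
        with pytest.raises(ScreenError):
            attenuation_analysis(a, b, pd.DataFrame())


class TestNetwork:
    def test_fisher_matches_hypergeometric_enumeration(self):
        """One-sided Fisher vs direct hypergeometric tail sums, all N <= 30."""
        rng = np.random.default_rng(8)
        for _ in range(60):
            N = rng.integers(4, 31)
            K = rng.integers(1, N)
            n = rng.integers(1, N)
            a = rng.integers(max(0, K + n - N), min(K, n) + 1)
            table = [[a, n - a], [K - a, N - K - n + a]]
            p_fisher = scipy.stats.fisher_exact(table, alternative="greater")[1]
            support = np.arange(max(0, K + n - N), min(K, n) + 1)
            pmf = scipy.stats.hypergeom.pmf(support, N, K, n)
            p_enum = pmf[support >= a].sum()
            assert p_fisher == pytest.approx(p_enum, rel=1e-9)

    def test_known_two_by_two(self):
        # a=3,b=1,c=1,d=3 over N=8: one-sided p = 17/70
        universe = {f"u{i}" for i in range(8)}
        region = {"u0", "u1", "u2", "u3"}
        top = {"u0", "u1", "u2", "u4"}
        assert fisher_enrichment(region, top, universe) == pytest.approx(17 / 70)

    def test_disjoint_top_set_gives_p_one(self):
        kin = {"K1": {"a", "b"}, "K2": {"b", "c"}}
        top = {"TOP": ["x", "y"]}
        universe = ["a", "b", "c", "x", "y", "z"]
        table, _ = enrichment_network(kin, top, universe)
        assert (table["pvalue"] == 1.0).all()

    def test_regions_partition_target_union(self):
        kin = {
            "K1": {"a", "b", "c", "d"},
            "K2": {"c", "d", "e"},
            "K3": {"d", "e", "f"},
        }
        universe = list("abcdefghij")
        table, edges = enrichment_network(kin, {"TOP": ["a", "c"]}, universe)
        sizes = table.drop_duplicates("region")["region_size"].sum()
        union = set().union(*kin.values())
        assert sizes == len(union)
        assert set(edges["gene"]) == union

    def test_single_set_rejected(self):
        with pytest.raises(ScreenError):
            enrichment_network({"K1": {"a"}}, {"TOP": ["a"]}, ["a", "b"])
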