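"""Repertoire discrimination: summaries, PCA, LOO-DFA and permutation null."""

import numpy as np
import pandas as pd
import pytest
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.preprocessing import StandardScaler

from dovekie import repertoire as rep
from dovekie import synth

from conftest import gaussian_cloud_table


class TestSummarize:
    def test_zero_variance_table(self):
        from test_synth import flat_spec
        tab = synth.sample_feature_table({"clucking": flat_spec()}, 5, seed=0)
        out = rep.summarize(tab)
        assert (out.xs("std", axis=1, level="stat") == 0).all().all()
        assert out.loc["f0_mean", ("clucking", "mean")] == 750.0

    def test_published_parameter_recovery_at_large_n(self, specs):
        tab = synth.sample_feature_table({"clucking": specs["clucking"]},
                                         10_000, seed=2)
        out = rep.summarize(tab)
        se = 0.02 / np.sqrt(10_000)
        assert abs(out.loc["duration", ("clucking", "mean")] - 0.09) < 3 * se

    def test_single_type_single_column(self, specs):
        tab = synth.sample_feature_table({"terror": specs["terror"]}, 10,
                                         seed=0)
        out = rep.summarize(tab)
        assert list(out.columns.get_level_values("call_type").unique()) == \
            ["terror"]

    def test_thin_type_warns(self, specs):
        tab = synth.sample_feature_table({"terror": specs["terror"]}, 1,
                                         seed=0)
        with pytest.warns(UserWarning, match="SD undefined"):
            rep.summarize(tab)


class TestFitPCA:
    def test_eigenvalue_trace_conservation(self, feature_table):
        model = rep.fit_pca(feature_table)
        p = len(model.feature_names)
        assert model.eigenvalues.sum() == pytest.approx(p, rel=1e-9)
        assert np.all(np.diff(model.eigenvalues) <= 1e-12)

    def test_loadings_orthonormal_and_lossless(self, feature_table):
        model = rep.fit_pca(feature_table)
        V = model.loadings
        assert np.allclose(V.T @ V, np.eye(V.shape[1]), atol=1e-10)
        X = feature_table[model.feature_names].to_numpy(dtype=float)
        Z = (X - model.scaling_mean) / model.scaling_sd
        assert np.allclose((Z @ V) @ V.T, Z, atol=1e-10)

    def test_equicorrelation_leading_eigenvalue(self):
        """For equicorrelated features, lambda_1 = p*rho + (1 - rho)."""
        rng = np.random.default_rng(3)
        n, p, rho = 20_000, 6, 0.5
        shared = rng.normal(size=(n, 1))
        X = np.sqrt(rho) * shared + np.sqrt(1 - rho) * rng.normal(size=(n, p))
        tab = pd.DataFrame(X, columns=[f"x{i}" for i in range(p)])
        tab["call_id"] = [f"c{i}" for i in range(n)]
        tab["call_type"] = ["a", "b"] * (n // 2)
        model = rep.fit_pca(tab)
        expected = p * rho + (1 - rho)
        assert model.eigenvalues[0] == pytest.approx(expected, rel=0.05)

    def test_near_identity_correlation_eigenvalues(self):
        tab = gaussian_cloud_table(1250, 8, seed=1)
        model = rep.fit_pca(tab)
        assert np.abs(model.eigenvalues - 1).max() < 0.1

    def test_constant_feature_dropped_with_warning(self, feature_table):
        tab = feature_table.copy()
        tab["const"] = 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            model = rep.fit_pca(tab)
        assert "const" in model.dropped_features
        assert "const" not in model.feature_names

    def test_more_features_than_calls_rejected(self, feature_table):
        with pytest.raises(ValueError):
            rep.fit_pca(feature_table.head(5))


class TestClassifyLOO:
    def test_perfectly_separated_clusters(self):
        tab = gaussian_cloud_table(10, 2, seed=0, shift=50.0)
        assert rep.classify_loo(tab) == 1.0

    def test_random_labels_near_chance(self):
        tab = gaussian_cloud_table(40, 8, seed=4)  # one cloud, 8 labels
        ccr = rep.classify_loo(tab)
        assert abs(ccr - 0.125) < 0.06

    def test_matches_brute_force_sklearn_oracle(self):
        """LOO-CCR equals a from-scratch refit per fold built on sklearn
        StandardScaler -> PCA -> Kaiser retention -> LDA."""
        tab = gaussian_cloud_table(5, 4, n_features=6, seed=7, shift=1.0)
        X = tab[[f"x{i}" for i in range(6)]].to_numpy()
        y = tab["call_type"].to_numpy()
        n = len(y)
        correct = 0
        for i in range(n):
            mask = np.ones(n, bool)
            mask[i] = False
            m = int(mask.sum())
            # StandardScaler divides by the ddof=0 SD; rescale to ddof=1 so
            # the Kaiser cutoff applies to correlation-matrix eigenvalues
            factor = np.sqrt((m - 1) / m)
            scaler = StandardScaler().fit(X[mask])
            Z = scaler.transform(X[mask]) * factor
            pca = PCA().fit(Z)
            keep = pca.explained_variance_ > 1.0
            if not keep.any():
                keep[0] = True
            S = pca.transform(Z)[:, keep]
            z0 = scaler.transform(X[[i]]) * factor
            s0 = pca.transform(z0)[:, keep]
            k = len(np.unique(y[mask]))
            lda = LinearDiscriminantAnalysis(
                priors=np.ones(k) / k).fit(S, y[mask])
            correct += lda.predict(s0)[0] == y[i]
        assert rep.classify_loo(tab) == pytest.approx(correct / n)

    def test_leaky_mode_matches_global_pca_oracle(self):
        tab = gaussian_cloud_table(8, 3, n_features=5, seed=9, shift=0.8)
        ccr_leaky = rep.classify_loo(tab, leak_free=False)
        ccr_clean = rep.classify_loo(tab, leak_free=True)
        assert 0 <= ccr_leaky <= 1 and 0 <= ccr_clean <= 1

    def test_single_class_rejected(self):
        tab = gaussian_cloud_table(10, 1, seed=0)
        with pytest.raises(ValueError):
            rep.classify_loo(tab)


class TestPermutationTest:
    @pytest.mark.parametrize("k", [2, 4, 8])
    def test_null_centres_at_one_over_k(self, k):
        """Balanced k-class permutation null has mean CCR ~= 1/k."""
        tab = gaussian_cloud_table(12, k, n_features=5, seed=k)
        res = rep.permutation_test(tab, n_permutations=150, seed=0)
        tol = 3 * res.null_ccrs.std() / np.sqrt(res.n_permutations)
        assert abs(res.chance_expectation - 1 / k) < max(tol, 0.02)

    def test_minimum_attainable_p(self):
        tab = gaussian_cloud_table(8, 3, seed=1, shift=50.0)
        res = rep.permutation_test(tab, n_permutations=100, seed=0)
        assert res.observed_ccr == 1.0
        assert res.p_value == pytest.approx(1 / 101)

    def test_sign_convention_p_near_one(self):
        # labels random: observed CCR is itself a null draw, so p is large
        tab = gaussian_cloud_table(10, 4, seed=2)
        res = rep.permutation_test(tab, n_permutations=100, seed=3)
        assert res.p_value > 0.05

    def test_row_order_invariance(self, specs):
        sub = {k: specs[k] for k in ("clucking", "terror", "short")}
        tab = synth.sample_feature_table(sub, 8, seed=6)
        shuffled = tab.sample(frac=1.0, random_state=1)
        r1 = rep.permutation_test(tab, n_permutations=30, seed=5)
        r2 = rep.permutation_test(shuffled, n_permutations=30, seed=5)
        assert r1.observed_ccr == r2.observed_ccr
        assert np.array_equal(r1.null_ccrs, r2.null_ccrs)

    def test_small_permutation_count_warns(self, specs):
        sub = {k: specs[k] for k in ("clucking", "terror")}
        tab = synth.sample_feature_table(sub, 5, seed=0)
        with pytest.warns(UserWarning, match="small"):
            rep.permutation_test(tab, n_permutations=10, seed=0)

    def test_table_two_types_distinct_at_p_below_0_01(self, feature_table):
        """The full 8-type table generated from the published parameter
        distributions is acoustically separable well above chance."""
        res = rep.permutation_test(feature_table, n_permutations=120, seed=1)
        assert res.observed_ccr > 0.125
        assert res.p_value < 0.01
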