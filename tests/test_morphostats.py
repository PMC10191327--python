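import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from caryomorph.morphostats import (
    FeatureMatrix,
    kruskal_wallis,
    manova,
    pairwise_permanova,
    pca,
    permanova,
    rarefaction_sufficiency,
    size_correlations,
    wilcoxon_pairs,
)


def _fm(X, labels_dict):
    labels = pd.DataFrame(labels_dict)
    labels.index = [f"g{i}" for i in range(len(labels))]
    return FeatureMatrix(
        values=np.asarray(X, float),
        feature_names=[f"f{j}" for j in range(np.shape(X)[1])],
        labels=labels,
    )


class TestSizeCorrelations:
    def test_duplicated_index_correlates_perfectly(self):
        rng = np.random.default_rng(0)
        L = rng.normal(9, 0.5, 50)
        df = pd.DataFrame({
            "length_mm": L, "width_mm": rng.normal(3, 0.2, 50),
            "thickness_mm": rng.normal(2.8, 0.2, 50),
            "cs_lateral": rng.normal(60, 3, 50), "cs_ventral": L,
        })
        corr = size_correlations(df)
        assert corr.loc["length_mm", "cs_ventral"] == pytest.approx(1.0)
        np.testing.assert_allclose(np.diag(corr), 1.0)
        np.testing.assert_allclose(corr.to_numpy(), corr.to_numpy().T)

    def test_independent_indices_near_zero(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            rng.normal(size=(1000, 5)),
            columns=["length_mm", "width_mm", "thickness_mm", "cs_lateral", "cs_ventral"],
        )
        corr = size_correlations(df)
        off = corr.to_numpy()[~np.eye(5, dtype=bool)]
        assert np.abs(off).max() < 0.1

    def test_coupled_sizes_strongly_correlated(self, small_dataset):
        """The shared per-grain size factor couples centroid sizes and
        length across views."""
        _, records, _ = small_dataset
        df = pd.DataFrame([r.sizes.as_dict() for r in records])
        corr = size_correlations(df)
        assert corr.loc["length_mm", "cs_ventral"] > 0.8
        assert corr.loc["cs_lateral", "cs_ventral"] > 0.7

    def test_zero_variance_rejected(self):
        df = pd.DataFrame({
            "length_mm": [9.0, 9.0, 9.0], "width_mm": [3, 3.1, 3.2],
            "thickness_mm": [2.8, 2.9, 3.0], "cs_lateral": [60, 61, 62],
            "cs_ventral": [60, 61, 62],
        })
        with pytest.raises(ValueError, match="zero-variance"):
            size_correlations(df)


class TestPCA:
    def test_rank_one_data_single_component(self):
        t = np.linspace(0, 1, 30)
        X = np.column_stack([2 * t, -3 * t])
        res = pca(X)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_variance_conserved_and_reconstruction(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 6))
        res = pca(X)
        ev = res.explained_variance_ratio
        assert ev.sum() == pytest.approx(1.0)
        recon = res.scores @ res.loadings.T + res.mean
        np.testing.assert_allclose(recon, X, atol=1e-10)

    def test_agrees_with_sklearn_oracle(self):
        from sklearn.decomposition import PCA as SKPCA

        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 6))
        res = pca(X)
        sk = SKPCA().fit(X)
        np.testing.assert_allclose(
            res.explained_variance_ratio[:5], sk.explained_variance_ratio_[:5],
            atol=1e-8,
        )
        for j in range(5):
            dot = abs(np.dot(res.loadings[:, j], sk.components_[j]))
            assert dot == pytest.approx(1.0, abs=1e-8)


class TestManova:
    def test_univariate_equals_anova_f(self):
        rng = np.random.default_rng(4)
        y = np.repeat(["a", "b", "c"], 12)
        x = rng.normal(size=36) + np.repeat([0, 0.5, 1.0], 12)
        fm = _fm(x[:, None], {"g": y})
        res = manova(fm, "g")
        F, p = sps.f_oneway(x[:12], x[12:24], x[24:])
        assert res.statistic == pytest.approx(F, rel=1e-10)
        assert res.p_value == pytest.approx(p, rel=1e-10)

    def test_agrees_with_statsmodels_pillai(self):
        from statsmodels.multivariate.manova import MANOVA as SM

        rng = np.random.default_rng(5)
        X = rng.normal(size=(60, 4))
        y = np.repeat(["a", "b", "c"], 20)
        X[y == "b"] += 0.8
        fm = _fm(X, {"g": y})
        res = manova(fm, "g")
        df = pd.DataFrame(X, columns=["x1", "x2", "x3", "x4"])
        df["g"] = y
        sm_res = SM.from_formula("x1 + x2 + x3 + x4 ~ g", data=df).mv_test()
        tab = sm_res.results["g"]["stat"]
        assert res.statistic == pytest.approx(tab.loc["Pillai's trace", "F Value"], rel=1e-6)
        assert res.p_value == pytest.approx(tab.loc["Pillai's trace", "Pr > F"], rel=1e-6)

    def test_strong_category_effect_significant(self, small_tables):
        from caryomorph.classify import build_features

        coeffs, sizes, meta = small_tables
        fm = build_features(coeffs, sizes, meta, "combined_shape")
        res = manova(fm, "category")
        assert res.p_value < 1e-3

    def test_rank_deficient_features_are_reduced(self):
        rng = np.random.default_rng(6)
        base = rng.normal(size=(30, 3))
        X = np.hstack([base, base @ rng.normal(size=(3, 5))])  # rank 3 in 8 cols
        y = np.repeat(["a", "b"], 15)
        res = manova(_fm(X, {"g": y}), "g")
        assert 0 <= res.p_value <= 1
        assert "features=3" in res.note

    def test_too_few_groups_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        with pytest.raises(ValueError):
            manova(_fm(X, {"g": ["a"] * 10}), "g")


class TestPermanova:
    def test_two_single_point_groups_rejected(self):
        X = np.array([[0.0, 0], [1, 1]])
        with pytest.raises(ValueError):
            permanova(X, np.array(["a", "b"]), B=99)

    def test_adjusted_p_monotone(self, small_tables):
        from caryomorph.classify import build_features

        coeffs, sizes, meta = small_tables
        fm = build_features(coeffs, sizes, meta, "lateral_shape")
        results = pairwise_permanova(fm, "category", B=99, seed=1)
        assert len(results) == 6
        for r in results:
            assert r.adjusted_p >= r.p_value - 1e-12

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(24, 3))
        y = np.repeat(["a", "b"], 12)
        r1 = permanova(X, y, B=199, seed=5)
        r2 = permanova(X, y, B=199, seed=5)
        assert r1.p_value == r2.p_value
        assert r1.permutations == 199

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(30, 3))
        X[15:] += 4.0
        res = permanova(X, np.repeat(["a", "b"], 15), B=199, seed=0)
        assert res.p_value == pytest.approx(1 / 200)


class TestRankTests:
    def test_worked_example_h_statistic(self):
        """Two groups {1,2,3} and {4,5,6}: H = 12/(6*7) * (3*(2-3.5)^2 +
        3*(5-3.5)^2) = 3.857."""
        res = kruskal_wallis(
            np.array([1, 2, 3, 4, 5, 6], float),
            np.array(["a", "a", "a", "b", "b", "b"]),
        )
        assert res.statistic == pytest.approx(3.857, abs=5e-4)
        assert res.statistic_name == "KW_chi2"

    def test_identical_values_flagged(self):
        res = kruskal_wallis(np.ones(10), np.repeat(["a", "b"], 5))
        assert res.statistic == 0.0
        assert res.p_value == 1.0
        assert "identical" in res.note

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=30)
        g = np.repeat(["a", "b", "c"], 10)
        r1 = kruskal_wallis(x, g)
        r2 = kruskal_wallis(np.exp(3 * x) + 7, g)
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-12)

    def test_two_group_h_equals_wilcoxon_chi2_form(self):
        """For two groups without ties, H equals the squared standardized
        rank-sum statistic (chi-square-1 form of the rank-sum test)."""
        rng = np.random.default_rng(10)
        x = rng.permutation(np.arange(20, dtype=float))
        g = np.repeat(["a", "b"], 10)
        res = kruskal_wallis(x, g)
        ranks = sps.rankdata(x)
        W = ranks[g == "a"].sum()
        n1, n2 = 10, 10
        z = (W - n1 * (n1 + n2 + 1) / 2) / np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
        assert res.statistic == pytest.approx(z**2, rel=1e-10)

    def test_wilcoxon_pairs_adjustment(self):
        rng = np.random.default_rng(11)
        x = np.concatenate([rng.normal(0, 1, 15), rng.normal(2, 1, 15),
                            rng.normal(4, 1, 15)])
        g = np.repeat(["a", "b", "c"], 15)
        res = wilcoxon_pairs(x, g, adjust="bonferroni")
        assert len(res) == 3
        for r in res:
            assert r.adjusted_p >= r.p_value - 1e-12
            assert r.statistic_name == "wilcoxon_W"


class TestRarefaction:
    def _accession_fm(self, n=50, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 8))
        return _fm(X, {"accession_id": ["acc1"] * n})

    def test_full_sample_ratio_one(self):
        fm = self._accession_fm()
        curve, rec = rarefaction_sufficiency(fm, "acc1", n_grid=[10, 30, 50], B=50)
        assert curve.loc[curve["n"] == 50, "mean_ratio"].iloc[0] == pytest.approx(1.0)
        assert rec is not None and rec <= 50

    def test_curve_non_decreasing_in_expectation(self):
        fm = self._accession_fm(seed=3)
        curve, _ = rarefaction_sufficiency(
            fm, "acc1", n_grid=[5, 10, 20, 35, 50], B=200, seed=1
        )
        diffs = np.diff(curve["mean_ratio"].to_numpy())
        assert (diffs > -0.02).all()

    def test_n_grid_exceeding_accession_rejected(self):
        fm = self._accession_fm(n=20)
        with pytest.raises(ValueError, match="exceeds"):
            rarefaction_sufficiency(fm, "acc1", n_grid=[10, 25], B=10)

    def test_mean_stable_in_b(self):
        fm = self._accession_fm(seed=5)
        c1, _ = rarefaction_sufficiency(fm, "acc1", n_grid=[20], B=20, seed=2)
        c2, _ = rarefaction_sufficiency(fm, "acc1", n_grid=[20], B=500, seed=3)
        assert c1["mean_ratio"].iloc[0] == pytest.approx(
            c2["mean_ratio"].iloc[0], abs=0.03
        )
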