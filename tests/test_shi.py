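"""Index construction: standardization, PCA, MDS selection, scoring,
weighting, the weighted index and the yield regression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from soilhealth import shi as S
from soilhealth.shi import DegenerateInputError


def _make_pca(eigenvalues, loadings=None, attrs=None):
    ev = np.asarray(eigenvalues, dtype=float)
    p = len(ev)
    attrs = attrs or [f"a{i}" for i in range(p)]
    if loadings is None:
        loadings = np.eye(p)
    prop = ev / ev.sum()
    L = pd.DataFrame(loadings, index=attrs,
                     columns=[f"PC{i+1}" for i in range(p)])
    corr = pd.DataFrame(np.eye(p), index=attrs, columns=attrs)
    return S.PcaResult(ev, prop, np.cumsum(prop), L, corr)


class TestStandardize:
    def test_columns_centred_and_unit_sd(self, wheat_table):
        z = S.standardize(wheat_table)
        np.testing.assert_allclose(z.mean(), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(ddof=1), 1.0, atol=1e-12)

    def test_two_row_closed_form(self):
        df = pd.DataFrame({"x": [3.0, 7.0]})
        z = S.standardize(df, ["x"])
        np.testing.assert_allclose(z["x"], [-0.7071067811865475, 0.7071067811865475])

    def test_constant_column_named_in_error(self, wheat_table):
        df = wheat_table.copy()
        df["DHA"] = 1.0
        with pytest.raises(DegenerateInputError, match="DHA"):
            S.standardize(df)


class TestPca:
    def test_trace_identity(self, wheat_table):
        pca = S.run_pca(S.standardize(wheat_table))
        assert pca.eigenvalues.sum() == pytest.approx(pca.n_attributes, rel=1e-10)
        assert pca.proportions.sum() == pytest.approx(1.0, rel=1e-12)

    def test_two_column_closed_form(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=4000)
        y = 0.6 * x + np.sqrt(1 - 0.36) * rng.normal(size=4000)
        df = pd.DataFrame({"x": x, "y": y})
        z = S.standardize(df, ["x", "y"])
        r = np.corrcoef(z["x"], z["y"])[0, 1]
        pca = S.run_pca(z)
        np.testing.assert_allclose(pca.eigenvalues, [1 + r, 1 - r], rtol=1e-10)

    def test_uncorrelated_columns_near_unit_eigenvalues(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(20000, 4)), columns=list("abcd"))
        pca = S.run_pca(S.standardize(df, list("abcd")))
        np.testing.assert_allclose(pca.eigenvalues, 1.0, atol=0.06)

    def test_matches_reference_eigensolver(self):
        from sklearn.decomposition import PCA as SkPCA

        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(30, 5)) @ rng.normal(size=(5, 5)),
                          columns=list("abcde"))
        z = S.standardize(df, list("abcde"))
        mine = S.run_pca(z)
        sk = SkPCA(n_components=5).fit(z.to_numpy())
        np.testing.assert_allclose(mine.eigenvalues, sk.explained_variance_,
                                   rtol=1e-8)
        np.testing.assert_allclose(np.abs(mine.loadings.to_numpy().T),
                                   np.abs(sk.components_), atol=1e-8)

    def test_sign_convention(self, wheat_table):
        pca = S.run_pca(S.standardize(wheat_table))
        for col in pca.loadings.columns:
            v = pca.loadings[col].to_numpy()
            assert v[np.argmax(np.abs(v))] > 0

    def test_loadings_unit_norm(self, wheat_table):
        pca = S.run_pca(S.standardize(wheat_table))
        np.testing.assert_allclose(
            np.linalg.norm(pca.loadings.to_numpy(), axis=0), 1.0, rtol=1e-10
        )


class TestRetention:
    def test_threshold_comparison(self):
        pca = _make_pca([3.0, 1.2, 0.99, 0.4, 0.41])
        assert S.retain_pcs(pca, 1.0, 0.05) == [0, 1]

    def test_lowered_eigen_threshold_admits_borderline_pc(self):
        pca = _make_pca([3.0, 1.2, 0.99, 0.4, 0.41])
        # PC3 share = 0.99/5.99 > 5%, so the 0.99 threshold admits it
        assert S.retain_pcs(pca, 0.99, 0.05) == [0, 1, 2]

    def test_empty_retention_allowed(self):
        pca = _make_pca([0.9, 0.8, 0.7])
        assert S.retain_pcs(pca, 1.0, 0.05) == []

    def test_var_min_filters_small_share(self):
        pca = _make_pca([30.0, 1.1, 0.5])
        # PC2 eigenvalue passes but its share (1.1/31.6) is below 5%
        assert S.retain_pcs(pca, 1.0, 0.05) == [0]


class TestSelection:
    def test_within_ten_percent_rule(self):
        load = np.zeros((5, 5))
        load[:, 0] = [0.41, 0.39, 0.30, 0.2, 0.1]
        pca = _make_pca([2.0, 1.0, 0.8, 0.7, 0.5], load,
                        attrs=["alpha_glu", "MBC", "DHA", "Ur", "pH_s"])
        sel = S.select_indicators(pca, [0], within_frac=0.10)
        assert sel.indicators == ["alpha_glu", "MBC"]

    def test_single_dominant_loading(self):
        load = np.zeros((3, 3))
        load[:, 0] = [0.9, 0.3, 0.3]
        pca = _make_pca([1.5, 1.0, 0.5], load)
        sel = S.select_indicators(pca, [0])
        assert sel.indicators == ["a0"]

    def test_tie_at_maximum_keeps_both_in_input_order(self):
        load = np.zeros((3, 3))
        load[:, 0] = [0.6, 0.6, 0.1]
        pca = _make_pca([1.5, 1.0, 0.5], load)
        sel = S.select_indicators(pca, [0])
        assert sel.indicators == ["a0", "a1"]

    def test_earlier_selection_skipped_in_later_pcs(self):
        load = np.zeros((3, 3))
        load[:, 0] = [0.9, 0.2, 0.1]
        load[:, 1] = [0.9, 0.85, 0.1]
        pca = _make_pca([1.5, 1.2, 0.3], load)
        sel = S.select_indicators(pca, [0, 1])
        # a0 taken by PC1; in PC2 a1 remains the top available loading
        assert sel.indicators == ["a0", "a1"]
        assert list(sel.table["pc"]) == [1, 2]

    def test_negative_loadings_use_absolute_value(self):
        load = np.zeros((3, 3))
        load[:, 0] = [-0.44, 0.44, 0.1]
        pca = _make_pca([1.5, 1.0, 0.5], load)
        sel = S.select_indicators(pca, [0])
        assert sel.indicators == ["a0", "a1"]

    def test_redundancy_pruning(self):
        load = np.zeros((3, 3))
        load[:, 0] = [0.6, 0.58, 0.1]
        pca = _make_pca([1.5, 1.0, 0.5], load)
        pca.correlation.loc["a0", "a1"] = pca.correlation.loc["a1", "a0"] = 0.95
        sel = S.select_indicators(pca, [0], redundancy_r=0.7)
        assert sel.indicators == ["a0"]


class TestWeights:
    def test_pc_share_over_cumulative(self):
        load = np.zeros((4, 4))
        load[:, 0] = [0.7, 0.69, 0.1, 0.1]
        load[:, 1] = [0.0, 0.0, 0.9, 0.1]
        # proportions 0.30 and 0.20 for the retained pair
        pca = _make_pca([1.2, 0.8, 1.2, 0.8], load)
        pca.proportions = np.array([0.30, 0.20, 0.30, 0.20])
        pca.cumulative = np.cumsum(pca.proportions)
        sel = S.select_indicators(pca, [0, 1])
        sel = S.compute_weights(pca, sel)
        w = sel.weights()
        assert w["a0"] == pytest.approx(0.6)
        assert w["a1"] == pytest.approx(0.6)
        assert w["a2"] == pytest.approx(0.4)

    def test_single_pc_single_indicator_weight_one(self):
        load = np.zeros((3, 3))
        load[:, 0] = [0.9, 0.1, 0.1]
        pca = _make_pca([1.8, 0.7, 0.5], load)
        sel = S.compute_weights(pca, S.select_indicators(pca, [0]))
        assert sel.weights()["a0"] == pytest.approx(1.0)

    def test_normalized_weights_sum_to_one_over_pcs(self, wheat_table):
        pca = S.run_pca(S.standardize(wheat_table))
        kept = S.retain_pcs(pca)
        sel = S.compute_weights(pca, S.select_indicators(pca, kept),
                                normalize=True)
        distinct = sel.table.drop_duplicates("pc")["weight"].sum()
        assert distinct == pytest.approx(1.0, rel=1e-12)


class TestScoring:
    def test_more_is_better_minmax(self):
        df = pd.DataFrame({"x": [2.0, 4.0, 6.0]})
        sel = S.MdsSelection(
            pd.DataFrame({"indicator": ["x"], "pc": [1], "loading": [0.9],
                          "weight": [1.0]}),
            [1], 0.1, 1.0, 0.05,
        )
        spec = S.ScoringSpec(directions={"x": "more_is_better"})
        np.testing.assert_allclose(
            S.score_indicators(df, sel, spec)["x"], [0.0, 0.5, 1.0]
        )

    def test_less_is_better_minmax(self):
        df = pd.DataFrame({"EC_e": [4.0, 6.0, 8.0]})
        sel = S.MdsSelection(
            pd.DataFrame({"indicator": ["EC_e"], "pc": [1], "loading": [0.9],
                          "weight": [1.0]}),
            [1], 0.1, 1.0, 0.05,
        )
        scores = S.score_indicators(df, sel)  # default: EC_e less_is_better
        np.testing.assert_allclose(scores["EC_e"], [1.0, 0.5, 0.0])

    def test_optimum_tent(self):
        df = pd.DataFrame({"x": [2.0, 6.0, 10.0]})
        sel = S.MdsSelection(
            pd.DataFrame({"indicator": ["x"], "pc": [1], "loading": [0.9],
                          "weight": [1.0]}),
            [1], 0.1, 1.0, 0.05,
        )
        spec = S.ScoringSpec(directions={"x": "optimum"},
                             optimum_midpoints={"x": 6.0})
        np.testing.assert_allclose(S.score_indicators(df, sel, spec)["x"],
                                   [0.0, 1.0, 0.0])

    def test_observed_bounds_attained(self, wheat_table):
        pca = S.run_pca(S.standardize(wheat_table))
        sel = S.compute_weights(pca, S.select_indicators(pca, S.retain_pcs(pca)))
        scores = S.score_indicators(wheat_table, sel)
        assert ((scores >= 0) & (scores <= 1)).all().all()
        np.testing.assert_allclose(scores.min(), 0.0, atol=1e-12)
        spec = S.default_scoring_spec()
        monotone = [i for i in sel.indicators if spec.direction(i) != "optimum"]
        np.testing.assert_allclose(scores[monotone].max(), 1.0, atol=1e-12)

    def test_constant_indicator_rejected(self):
        df = pd.DataFrame({"x": [5.0, 5.0, 5.0]})
        sel = S.MdsSelection(
            pd.DataFrame({"indicator": ["x"], "pc": [1], "loading": [0.9],
                          "weight": [1.0]}),
            [1], 0.1, 1.0, 0.05,
        )
        spec = S.ScoringSpec(directions={"x": "more_is_better"})
        with pytest.raises(DegenerateInputError):
            S.score_indicators(df, sel, spec)

    @given(
        a=st.floats(0.01, 100, allow_nan=False),
        b=st.floats(-100, 100, allow_nan=False),
        direction=st.sampled_from(["more_is_better", "less_is_better"]),
    )
    def test_affine_rescaling_invariance(self, a, b, direction):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        df1 = pd.DataFrame({"x": x})
        df2 = pd.DataFrame({"x": a * x + b})
        sel = S.MdsSelection(
            pd.DataFrame({"indicator": ["x"], "pc": [1], "loading": [0.9],
                          "weight": [1.0]}),
            [1], 0.1, 1.0, 0.05,
        )
        spec = S.ScoringSpec(directions={"x": direction})
        s1 = S.score_indicators(df1, sel, spec)["x"].to_numpy()
        s2 = S.score_indicators(df2, sel, spec)["x"].to_numpy()
        np.testing.assert_allclose(s1, s2, atol=1e-9)


class TestIndex:
    def _selection(self, weights):
        names = list(weights)
        return S.MdsSelection(
            pd.DataFrame({
                "indicator": names,
                "pc": range(1, len(names) + 1),
                "loading": [0.5] * len(names),
                "weight": [weights[n] for n in names],
            }),
            list(range(1, len(names) + 1)), 0.1, 1.0, 0.05,
        )

    def test_all_unit_scores_sum_published_sorghum_weights(self):
        # published index footnote weights: 0.10, 0.10, 0.09, 0.09, 0.07, 0.07
        w = {"alpha_glu": 0.10, "MBC": 0.10, "EC_e": 0.09, "KMnO4_N": 0.09,
             "MBN": 0.07, "MBCN": 0.07}
        sel = self._selection(w)
        scores = pd.DataFrame({k: [1.0, 1.0] for k in w})
        res = S.compute_shi(scores, sel)
        np.testing.assert_allclose(res.values, 0.52)

    def test_all_zero_scores_give_zero(self):
        sel = self._selection({"a": 0.3, "b": 0.2})
        scores = pd.DataFrame({"a": [0.0], "b": [0.0]})
        assert S.compute_shi(scores, sel).values.iloc[0] == 0.0

    def test_matches_elementwise_loop_oracle(self):
        rng = np.random.default_rng(4)
        names = [f"i{k}" for k in range(5)]
        w = dict(zip(names, rng.uniform(0.01, 0.3, 5)))
        sel = self._selection(w)
        scores = pd.DataFrame(rng.uniform(0, 1, (20, 5)), columns=names)
        res = S.compute_shi(scores, sel)
        for i in range(20):
            expected = sum(w[n] * scores.loc[i, n] for n in names)
            assert res.values.iloc[i] == pytest.approx(expected, abs=1e-12)

    def test_bounds_zero_to_weight_sum(self, wheat_table):
        pca = S.run_pca(S.standardize(wheat_table))
        sel = S.compute_weights(pca, S.select_indicators(pca, S.retain_pcs(pca)))
        res = S.compute_shi(S.score_indicators(wheat_table, sel), sel)
        assert (res.values >= 0).all()
        assert (res.values <= res.weight_sum + 1e-12).all()

    def test_missing_score_column_rejected(self):
        sel = self._selection({"a": 0.3, "b": 0.2})
        with pytest.raises(ValueError, match="b"):
            S.compute_shi(pd.DataFrame({"a": [1.0]}), sel)

    def test_lower_salinity_never_decreases_index(self, wheat_table):
        # with fixed scoring bounds, reducing any plot's EC_e (scored
        # less-is-better) can only raise its index
        pca = S.run_pca(S.standardize(wheat_table))
        sel = S.compute_weights(pca, S.select_indicators(pca, S.retain_pcs(pca)))
        if "EC_e" not in sel.indicators:
            pytest.skip("EC_e not selected in this MDS")
        spec = S.default_scoring_spec()
        spec.bounds = {
            ind: (float(wheat_table[ind].min()), float(wheat_table[ind].max()))
            for ind in sel.indicators
        }
        base = S.compute_shi(S.score_indicators(wheat_table, sel, spec), sel)
        rng = np.random.default_rng(9)
        lowered = wheat_table.copy()
        lowered["EC_e"] = lowered["EC_e"] - rng.uniform(0, 1.0, len(lowered))
        new = S.compute_shi(S.score_indicators(lowered, sel, spec), sel)
        assert (new.values >= base.values - 1e-12).all()


class TestRegression:
    def test_exact_line_r2_one(self):
        x = pd.Series(np.linspace(0.1, 0.9, 10))
        res = S.shi_yield_regression(x, 2.0 * x + 1.0)
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)

    def test_constant_yield_r2_zero(self):
        x = pd.Series([0.1, 0.4, 0.9, 0.3])
        res = S.shi_yield_regression(x, pd.Series([5.0] * 4))
        assert res.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations(self):
        x = np.array([0.2, 0.35, 0.5, 0.65, 0.8])
        y = np.array([10.0, 12.5, 11.0, 14.0, 15.5])
        res = S.shi_yield_regression(pd.Series(x), pd.Series(y))
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        r2 = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
        assert res.intercept == pytest.approx(beta[0], abs=1e-10)
        assert res.slope == pytest.approx(beta[1], abs=1e-10)
        assert res.r_squared == pytest.approx(r2, abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            S.shi_yield_regression(pd.Series([0.5] * 5),
                                   pd.Series([1.0, 2, 3, 4, 5.0]))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            S.shi_yield_regression(pd.Series([0.1, 0.2]), pd.Series([1.0, 2.0]))
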