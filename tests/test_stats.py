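"""Individuality statistics: CV/PIC formulas, screening, QDA, stepwise.

The classifier is checked against independent per-fold scikit-learn
oracles; the rank and variance formulas against hand computations.
"""

import numpy as np
import pandas as pd
import pytest

from callid import stats


class TestCoefficientsOfVariation:
    def test_constant_vector_has_zero_cv(self):
        assert stats.cv_between([3.0, 3.0, 3.0]) == 0.0
        assert stats.cv_within([3.0, 3.0, 3.0]) == 0.0

    def test_cvb_hand_formula(self):
        # {4, 6}: SD = sqrt(2), mean = 5
        assert stats.cv_between([4.0, 6.0]) == pytest.approx(28.2843, abs=1e-4)

    def test_cvw_small_sample_correction(self):
        # n = 2: correction factor 1 + 1/8
        assert stats.cv_within([4.0, 6.0]) == pytest.approx(
            28.2843 * 1.125, abs=1e-3
        )

    def test_cvw_approaches_cvb_for_large_samples(self):
        rng = np.random.default_rng(0)
        x = rng.normal(50, 5, 100000)
        ratio = stats.cv_within(x) / stats.cv_between(x)
        assert ratio == pytest.approx(1.0, abs=1e-4)

    @pytest.mark.parametrize("func", [stats.cv_between, stats.cv_within])
    def test_degenerate_inputs_rejected(self, func):
        with pytest.raises(ValueError):
            func([5.0])
        with pytest.raises(ValueError):
            func([-1.0, 1.0])


class TestPic:
    def test_published_style_cv_pairs(self):
        assert round(stats.pic(28.18, [20.41]), 2) == 1.38
        assert round(stats.pic(29.13, [18.60]), 2) == 1.57
        assert round(stats.pic(57.01, [38.54]), 2) == 1.48
        assert round(stats.pic(32.76, [32.66]), 2) == 1.00

    def test_equal_between_and_within_gives_unity(self):
        assert stats.pic(25.0, [25.0, 25.0, 25.0]) == pytest.approx(1.0)

    def test_zero_mean_cvw_rejected(self):
        with pytest.raises(ValueError):
            stats.pic(10.0, [0.0, 0.0])

    def test_table_pic_identity_holds_to_machine_precision(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {
                "individual": np.repeat(list("ABCD"), 25),
                "x": rng.lognormal(2, 0.4, 100),
                "y": rng.normal(40, 6, 100),
            }
        )
        table = stats.pic_table(df, ["x", "y"]).table
        for _, row in table.iterrows():
            assert abs(row["PIC"] - row["CVb"] / row["mean_CVw"]) < 1e-12

    def test_control_feature_with_common_mean_has_pic_below_one(self):
        # identical value multisets per individual: equal means, within
        # variance as large as the pooled variance, so only the small-sample
        # correction separates CVb from mean CVw and PIC < 1 exactly
        block = np.array([8.0, 9.0, 10.0, 11.0, 12.0])
        df = pd.DataFrame(
            {"individual": np.repeat(list("ABCD"), 5), "x": np.tile(block, 4)}
        )
        table = stats.pic_table(df, ["x"]).table
        pic = table.loc["x", "PIC"]
        n_all, n_grp = 20, 5
        cvb = np.sqrt(4 * 10.0 / (n_all - 1)) / 10.0 * 100
        cvw = np.sqrt(10.0 / (n_grp - 1)) / 10.0 * 100 * (1 + 1 / (4 * n_grp))
        assert pic == pytest.approx(cvb / cvw)
        assert pic < 1.0


class TestGroupTests:
    def test_kruskal_wallis_matches_hand_rank_sum_oracle(self):
        groups = [np.array([1.0, 4.0, 5.0]), np.array([2.0, 3.0, 6.0])]
        h, df, p = stats.kruskal_wallis(groups)
        # brute-force oracle: rank every value by sorting the pooled sample
        pooled = np.sort(np.concatenate(groups))
        ranks = {v: i + 1 for i, v in enumerate(pooled)}
        n = len(pooled)
        h_oracle = 12 / (n * (n + 1)) * sum(
            sum(ranks[v] for v in g) ** 2 / len(g) for g in groups
        ) - 3 * (n + 1)
        assert h == pytest.approx(h_oracle, abs=1e-9)
        assert df == 1

    def test_separated_groups_rejected_at_one_percent(self):
        rng = np.random.default_rng(0)
        g = rng.normal(0, 1, 10)
        _, _, p = stats.kruskal_wallis([g, g + 100.0])
        assert p < 0.01

    def test_identical_values_warn_and_return_zero(self):
        with pytest.warns(UserWarning):
            h, _, _ = stats.kruskal_wallis([[2.0, 2.0], [2.0, 2.0]])
        assert h == 0.0

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            stats.kruskal_wallis([[1.0, 2.0]])

    def test_two_group_anova_equals_squared_t(self):
        from scipy.stats import ttest_ind

        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 15), rng.normal(0.8, 1, 12)
        f, df1, df2, p = stats.one_way_anova([a, b])
        t, p_t = ttest_ind(a, b)
        assert f == pytest.approx(t**2, rel=1e-10)
        assert p == pytest.approx(p_t, rel=1e-10)

    def test_degrees_of_freedom_for_five_group_design(self):
        # class sizes 16/97/20/21/33 -> df (4, 182)
        rng = np.random.default_rng(4)
        groups = [rng.normal(0, 1, n) for n in (16, 97, 20, 21, 33)]
        _, df1, df2, _ = stats.one_way_anova(groups)
        assert (df1, df2) == (4, 182)

    def test_zero_within_variance_flagged(self):
        with pytest.warns(UserWarning):
            f, _, _, _ = stats.one_way_anova([[1.0, 1.0], [2.0, 2.0]])
        assert np.isnan(f)


class TestVifScreen:
    def test_orthogonal_features_have_unit_vif(self):
        n = 64
        t = np.arange(n)
        X = pd.DataFrame(
            {
                "a": np.cos(2 * np.pi * t / n),
                "b": np.sin(2 * np.pi * t / n),
                "c": np.cos(4 * np.pi * t / n),
            }
        )
        report = stats.vif_screen(X)
        assert report.removed == []
        for v in report.vif.values():
            assert v == pytest.approx(1.0, abs=1e-8)

    def test_closed_form_for_exactly_correlated_pair(self):
        # construct sample correlation exactly 0.6: VIF = 1/(1-0.36)
        n = 50
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, n)
        x = (x - x.mean()) / x.std()
        z = rng.normal(0, 1, n)
        z -= z.mean() + x * (z @ x) / (x @ x)  # orthogonalize against x
        z /= z.std()
        X = pd.DataFrame({"a": x, "b": 0.6 * x + 0.8 * z})
        report = stats.vif_screen(X)
        for v in report.vif_initial.values():
            assert v == pytest.approx(1 / (1 - 0.36), rel=1e-9)

    def test_duplicated_feature_removed_first(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 40)
        X = pd.DataFrame({"a": x, "a_copy": x, "b": rng.normal(0, 1, 40)})
        report = stats.vif_screen(X)
        assert report.removed
        assert report.removed[0] in {"a", "a_copy"}
        assert "b" in report.retained

    def test_input_shape_preconditions(self):
        with pytest.raises(ValueError):
            stats.vif_screen(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))


class TestRobustOutliers:
    def test_flagged_fraction_calibrated_on_clean_gaussian(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, size=(500, 2))
        flags, _ = stats.robust_outliers(X, quantile=0.975)
        assert 0.01 <= flags.mean() <= 0.05

    def test_planted_outlier_has_largest_distance(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, size=(100, 3))
        X[17] = 20.0
        flags, d2 = stats.robust_outliers(X)
        assert flags[17]
        assert np.argmax(d2) == 17

    def test_identical_rows_raise_singular_error(self):
        with pytest.raises(ValueError, match="singular"):
            stats.robust_outliers(np.ones((30, 2)))


class TestBalanceClasses:
    @staticmethod
    def frame(sizes):
        labels = np.concatenate([[lab] * n for lab, n in sizes.items()])
        return pd.DataFrame({"individual": labels, "x": np.arange(labels.size)})

    def test_only_classes_above_cap_are_reduced(self):
        df = self.frame({"H": 16, "T": 97, "G": 20, "N": 21, "M": 33})
        out = stats.balance_classes(df, "individual", 33, seed=0)
        sizes = out["individual"].value_counts().to_dict()
        assert sizes == {"H": 16, "T": 33, "G": 20, "N": 21, "M": 33}

    def test_cap_at_or_above_maximum_is_identity(self):
        df = self.frame({"A": 10, "B": 7})
        out = stats.balance_classes(df, "individual", 10, seed=0)
        pd.testing.assert_frame_equal(out, df)

    def test_same_seed_gives_same_subsample(self):
        df = self.frame({"A": 50, "B": 10})
        o1 = stats.balance_classes(df, "individual", 10, seed=7)
        o2 = stats.balance_classes(df, "individual", 10, seed=7)
        pd.testing.assert_frame_equal(o1, o2)

    def test_nonpositive_cap_rejected(self):
        with pytest.raises(ValueError):
            stats.balance_classes(self.frame({"A": 5}), "individual", 0, seed=0)


def _random_classes(rng, n_per, means, scales):
    X, y = [], []
    for k, (mu, sc) in enumerate(zip(means, scales)):
        A = rng.normal(0, 1, size=(len(mu), len(mu)))
        cov = sc * (A @ A.T / len(mu) + np.eye(len(mu)))
        X.append(rng.multivariate_normal(mu, cov, size=n_per))
        y.extend([f"c{k}"] * n_per)
    return np.vstack(X), np.array(y)


class TestQdaLoocv:
    def test_well_separated_classes_classified_perfectly(self):
        rng = np.random.default_rng(0)
        X, y = _random_classes(
            rng, 20, means=[(0.0, 0.0), (10.0, 10.0)], scales=[1.0, 1.0]
        )
        result = stats.qda_loocv(X, y)
        assert result.overall_rate_pct == 100.0

    def test_matches_per_fold_sklearn_refit_oracle(self):
        from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis

        rng = np.random.default_rng(1)
        X, y = _random_classes(
            rng, 20,
            means=[(0, 0, 0), (1.5, 0, 1), (0, 2, 0.5)],
            scales=[1.0, 2.0, 0.5],
        )
        result = stats.qda_loocv(X, y)
        classes = sorted(set(y))
        priors = np.array([np.mean(y == c) for c in classes])
        oracle = np.empty(len(y), dtype=object)
        for i in range(len(y)):
            mask = np.arange(len(y)) != i
            clf = QuadraticDiscriminantAnalysis(priors=priors)
            clf.fit(X[mask], y[mask])
            oracle[i] = clf.predict(X[i][None, :])[0]
        conf_oracle = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
        for yi, pi in zip(y, oracle):
            conf_oracle.loc[yi, pi] += 1
        pd.testing.assert_frame_equal(result.confusion, conf_oracle)

    def test_equal_covariance_classes_match_linear_discriminant(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(2)
        base = rng.normal(0, 1, size=(30, 2))
        X = np.vstack([base, base + [6.0, 6.0]])  # identical class scatter
        y = np.array(["a"] * 30 + ["b"] * 30)
        result = stats.qda_loocv(X, y)
        correct = 0
        for i in range(len(y)):
            mask = np.arange(len(y)) != i
            clf = LinearDiscriminantAnalysis(priors=[0.5, 0.5])
            clf.fit(X[mask], y[mask])
            correct += clf.predict(X[i][None, :])[0] == y[i]
        assert result.overall_rate_pct == pytest.approx(100.0 * correct / len(y))

    def test_permuted_labels_score_near_chance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, size=(60, 3))
        y = rng.permutation(np.repeat([f"c{k}" for k in range(5)], 12))
        result = stats.qda_loocv(X, y)
        assert 5.0 <= result.overall_rate_pct <= 35.0

    def test_uniform_priors_option(self):
        rng = np.random.default_rng(4)
        X, y = _random_classes(rng, 15, means=[(0, 0), (4, 4)], scales=[1, 1])
        res = stats.qda_loocv(X, y, priors="uniform")
        assert res.priors_used == {"c0": 0.5, "c1": 0.5}

    def test_singular_class_covariance_names_the_class(self):
        X = np.column_stack([np.arange(20.0), np.ones(20)])
        y = np.array(["a"] * 10 + ["b"] * 10)
        with pytest.raises(ValueError, match="'a'|'b'"):
            stats.qda_loocv(X, y)

    def test_confusion_rows_sum_to_class_sizes(self):
        rng = np.random.default_rng(5)
        X, y = _random_classes(rng, 12, means=[(0, 0), (1, 1), (2, 0)],
                               scales=[1, 1, 1])
        result = stats.qda_loocv(X, y)
        assert (result.confusion.sum(axis=1) == 12).all()
        trace = np.trace(result.confusion.to_numpy())
        assert result.overall_rate_pct == pytest.approx(100 * trace / len(y))


class TestStepwise:
    def test_perfectly_separating_feature_ranked_first(self):
        rng = np.random.default_rng(0)
        y = np.repeat(["a", "b"], 25)
        X = pd.DataFrame(
            {
                "noise1": rng.normal(0, 1, 50),
                "signal": np.where(y == "a", 0.0, 10.0) + rng.normal(0, 0.1, 50),
                "noise2": rng.normal(0, 1, 50),
            }
        )
        result = stats.stepwise_select(X, y)
        assert result.order[0] == "signal"

    def test_huge_improvement_threshold_selects_exactly_one(self):
        rng = np.random.default_rng(1)
        y = np.repeat(["a", "b"], 20)
        X = pd.DataFrame(rng.normal(0, 1, size=(40, 3)), columns=list("xyz"))
        result = stats.stepwise_select(X, y, improvement_min=1.01)
        assert len(result.order) == 1

    def test_accuracy_trace_is_monotone(self):
        rng = np.random.default_rng(2)
        y = np.repeat(["a", "b", "c"], 15)
        X = pd.DataFrame(
            {
                "s1": np.repeat([0, 3, 6], 15) + rng.normal(0, 1, 45),
                "s2": np.repeat([0, 0, 3], 15) + rng.normal(0, 1, 45),
                "n": rng.normal(0, 1, 45),
            }
        )
        result = stats.stepwise_select(X, y, improvement_min=0.01)
        assert all(b >= a for a, b in zip(result.accuracy_trace,
                                          result.accuracy_trace[1:]))


class TestDiagnostics:
    def test_box_m_detects_tenfold_covariance_difference(self):
        rng = np.random.default_rng(0)
        X = np.vstack(
            [rng.normal(0, 1, size=(50, 3)), rng.normal(0, np.sqrt(10), size=(50, 3))]
        )
        y = np.repeat(["a", "b"], 50)
        out = stats.covariance_diagnostics(X, y)
        assert out["box_m"]["p"] < 0.01

    def test_same_distribution_not_strongly_rejected(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, size=(400, 3))
        y = np.repeat(["a", "b"], 200)
        out = stats.covariance_diagnostics(X, y)
        assert out["box_m"]["p"] > 1e-4
        assert out["mardia"]["skew_p"] > 1e-4

    def test_skewed_data_fail_mardia(self):
        rng = np.random.default_rng(2)
        X = rng.lognormal(0, 1, size=(200, 3))
        y = np.repeat(["a", "b"], 100)
        out = stats.covariance_diagnostics(X, y)
        assert out["mardia"]["skew_p"] < 0.01

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            stats.covariance_diagnostics(np.random.default_rng(0).normal(size=(30, 2)),
                                         np.array(["a"] * 30))


class TestDropDegenerateWithin:
    def test_class_constant_column_is_dropped(self):
        y = np.repeat(["a", "b"], 10)
        rng = np.random.default_rng(0)
        X = pd.DataFrame(
            {
                "ok": rng.normal(0, 1, 20),
                "pinned": np.where(y == "a", 5.0, rng.normal(0, 1, 20)),
            }
        )
        assert stats.drop_degenerate_within(X, y) == ["ok"]
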