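"""Autoscaling, PCA, PLS-DA/VIP, permutation validation, summary ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from netpharm import chemometrics as cm
from netpharm import synthetic


class TestAutoscale:
    def test_columns_standardized(self, rng):
        x = rng.normal(5, 3, size=(30, 4))
        xs, mean, sd = cm.autoscale(x)
        np.testing.assert_allclose(xs.mean(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(xs.std(axis=0, ddof=1), 1, atol=1e-10)

    def test_already_scaled_unchanged(self, rng):
        x = rng.normal(size=(50, 3))
        x = (x - x.mean(0)) / x.std(0, ddof=1)
        xs, *_ = cm.autoscale(x)
        np.testing.assert_allclose(xs, x, atol=1e-10)

    def test_round_trip(self, rng):
        x = rng.normal(2, 7, size=(20, 5))
        xs, mean, sd = cm.autoscale(x)
        np.testing.assert_allclose(cm.unscale(xs, mean, sd), x, atol=1e-10)

    def test_constant_column_named(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "FIB": [3.0, 3.0]})
        with pytest.raises(ValueError, match="FIB"):
            cm.autoscale(df)


class TestPca:
    def test_rank_one_matrix_fully_explained(self, rng):
        x = np.outer(rng.normal(size=12), rng.normal(size=5))
        model = cm.pca(x, n_components=1, cv_folds=None)
        assert model.r2x_per_component[0] == pytest.approx(1.0)

    def test_reconstruction_matches_r2x(self, rng):
        x = rng.normal(size=(25, 6))
        a = 4
        model = cm.pca(x, n_components=a, cv_folds=None)
        recon = model.scores @ model.loadings.T + model.mean
        xc = x - x.mean(axis=0)
        resid_frac = ((x - recon) ** 2).sum() / (xc**2).sum()
        assert resid_frac == pytest.approx(1 - model.r2x, abs=1e-10)

    def test_loadings_orthonormal(self, rng):
        model = cm.pca(rng.normal(size=(30, 8)), n_components=3, cv_folds=None)
        np.testing.assert_allclose(model.loadings.T @ model.loadings, np.eye(3), atol=1e-10)

    def test_control_model_cohort_separates(self, control_model_cohort):
        """Control and disease-model animals split cleanly along the first
        component of an autoscaled PCA (positive silhouette)."""
        from sklearn.metrics import silhouette_score

        df = control_model_cohort
        xs, *_ = cm.autoscale(df.drop(columns="group"))
        model = cm.pca(np.asarray(xs), n_components=2)
        s = silhouette_score(model.scores[:, :1], df["group"])
        assert s > 0

    def test_too_many_components_raise(self, rng):
        with pytest.raises(ValueError):
            cm.pca(rng.normal(size=(4, 10)), n_components=5)


class TestPlsda:
    def test_no_signal_q2_nonpositive(self, rng):
        x = rng.normal(size=(24, 6))
        groups = np.repeat(["a", "b", "c"], 8)
        model = cm.plsda(x, rng.permutation(groups), n_components=2)
        assert model.q2 <= 0.05  # label-independent X carries no prediction

    def test_noiseless_limit_r2y_one(self, rng):
        groups = np.repeat(["a", "b"], 10)
        x = np.column_stack([
            (groups == "a").astype(float) + rng.normal(0, 1e-8, 20),
            rng.normal(size=20),
        ])
        model = cm.plsda(x, groups, n_components=2, cv_folds=None)
        assert model.r2y == pytest.approx(1.0, abs=1e-6)

    def test_planted_shift_gives_predictive_model(self):
        """A 3-SD mean shift on 5 of 10 variables yields Q2 > 0.5 in at
        least 95 of 100 seeded replicates."""
        wins = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=(16, 10))
            x[8:, :5] += 3.0
            groups = np.repeat(["control", "model"], 8)
            model = cm.plsda(x, groups, n_components=2)
            wins += model.q2 > 0.5
        assert wins >= 95

    def test_scores_orthogonal(self, control_model_cohort):
        df = control_model_cohort
        model = cm.plsda(df.drop(columns="group"), df["group"], n_components=3)
        g = model.T.T @ model.T
        off = g - np.diag(np.diag(g))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(g)).max()

    def test_r2y_nondecreasing_in_components(self, control_model_cohort):
        df = control_model_cohort
        x, g = df.drop(columns="group"), df["group"]
        r2 = [cm.plsda(x, g, n_components=a, cv_folds=None).r2y for a in (1, 2, 3)]
        assert r2[0] <= r2[1] + 1e-12 <= r2[2] + 2e-12
        m = cm.plsda(x, g, n_components=3, cv_folds=None)
        assert (m.r2y_per_component >= -1e-12).all()
        assert m.q2 is None

    def test_q2_not_above_r2y(self, control_model_cohort):
        df = control_model_cohort
        model = cm.plsda(df.drop(columns="group"), df["group"], n_components=2)
        assert model.q2 <= model.r2y + 1e-12

    def test_tiny_group_rejected(self, rng):
        x = rng.normal(size=(5, 3))
        with pytest.raises(ValueError, match="< 2"):
            cm.plsda(x, ["a", "a", "a", "a", "b"], n_components=1)

    def test_matches_sklearn_pls2(self, control_model_cohort):
        """In-sample predictions of the NIPALS fit agree with the reference
        PLS2 implementation in scikit-learn."""
        from sklearn.cross_decomposition import PLSRegression

        df = control_model_cohort
        x = df.drop(columns="group").to_numpy()
        y, _ = cm._one_hot(df["group"].to_numpy())
        model = cm.plsda(x, df["group"], n_components=2, cv_folds=None)
        ref = PLSRegression(n_components=2, scale=True).fit(x, y)
        np.testing.assert_allclose(
            model.predict_scores(x), ref.predict(x), atol=1e-8
        )
        # scores agree up to column sign
        for a in range(2):
            c = np.corrcoef(model.T[:, a], ref.x_scores_[:, a])[0, 1]
            assert abs(c) == pytest.approx(1.0, abs=1e-8)


class TestVip:
    def test_sum_of_squares_equals_variable_count(self, control_model_cohort):
        df = control_model_cohort
        for a in (1, 2, 3):
            model = cm.plsda(df.drop(columns="group"), df["group"],
                             n_components=a, cv_folds=None)
            v = cm.vip(model)
            assert (v**2).sum() == pytest.approx(len(v), abs=1e-8)

    def test_identical_variables_all_one(self):
        groups = np.repeat(["a", "b"], 6)
        base = np.r_[np.zeros(6), np.ones(6)] + np.linspace(0, 0.1, 12)
        x = np.column_stack([base] * 4)
        model = cm.plsda(x, groups, n_components=1, cv_folds=None)
        np.testing.assert_allclose(cm.vip(model), 1.0, atol=1e-8)

    def test_single_informative_variable_dominates(self, rng):
        groups = np.repeat(["a", "b"], 10)
        x = rng.normal(size=(20, 8))
        x[10:, 0] += 4.0
        model = cm.plsda(x, groups, n_components=2, cv_folds=None)
        v = cm.vip(model)
        assert v.idxmax() == "x0" and v["x0"] > 1.0

    def test_reference_cohort_selects_blood_viscosity_and_fib(self):
        """Across seeded replicates of the printed control/model summaries,
        each of WBV5, WBV1, WBV200, FIB, WBV50 exceeds VIP 1 more often
        than not, and TT/APTT stay below 1 on average."""
        five = ["WBV5", "WBV1", "WBV200", "FIB", "WBV50"]
        vips = []
        for seed in range(40):
            c = synthetic.reference_cohort(seed=(97, seed))
            m = cm.plsda(c.drop(columns="group"), c["group"], n_components=2,
                         cv_folds=None)
            vips.append(cm.vip(m))
        V = pd.DataFrame(vips)
        assert ((V[five] > 1).mean() > 0.5).all()
        assert V["TT"].mean() < 1 and V["APTT"].mean() < 1


class TestPermutationValidation:
    def test_deterministic_for_fixed_seed(self, control_model_cohort):
        df = control_model_cohort
        x, g = df.drop(columns="group"), df["group"].to_numpy()
        a = cm.permutation_validate(x, g, n_perm=20, seed=5)
        b = cm.permutation_validate(x, g, n_perm=20, seed=5)
        np.testing.assert_array_equal(a.q2_perm, b.q2_perm)
        assert a.r2_intercept == b.r2_intercept

    def test_strong_signal_validates(self, control_model_cohort):
        df = control_model_cohort
        res = cm.permutation_validate(
            df.drop(columns="group"), df["group"].to_numpy(), n_perm=50, seed=0
        )
        assert res.valid
        assert res.q2_intercept < 0

    def test_pure_noise_fails_validation(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(16, 10))
        groups = np.repeat(["a", "b"], 8)
        res = cm.permutation_validate(x, groups, n_perm=50, seed=1)
        assert not res.valid

    def test_few_permutations_warn(self, control_model_cohort):
        df = control_model_cohort
        with pytest.warns(UserWarning):
            cm.permutation_validate(
                df.drop(columns="group"), df["group"].to_numpy(), n_perm=5, seed=0
            )


class TestGroupDistance:
    def test_coincident_group_ranks_first(self):
        scores = np.array([[0.0, 0], [0, 0], [5, 5], [5, 5], [0, 0], [0, 0]])
        groups = np.array(["ref", "ref", "far", "far", "near", "near"])
        df = cm.group_distance_ranking(scores, groups, "ref").set_index("group")
        assert df.loc["near", "distance"] == 0.0
        assert df.loc["near", "rank"] == 1

    def test_distance_between_published_centers(self):
        # control (1.69, -0.4) vs disease model (-4.36, -0.61)
        scores = np.array([[1.69, -0.4], [1.69, -0.4], [-4.36, -0.61], [-4.36, -0.61]])
        groups = np.array(["control", "control", "model", "model"])
        df = cm.group_distance_ranking(scores, groups, "control")
        assert df.loc[0, "distance"] == pytest.approx(6.0536, abs=1e-3)

    def test_ranking_follows_planted_offsets(self):
        offsets = {"g1": 1.0, "g2": 3.0, "g3": 0.5}
        rows, groups = [], []
        for g, d in offsets.items():
            rows += [[d, 0.0]] * 2
            groups += [g] * 2
        rows += [[0.0, 0.0]] * 2
        groups += ["ref"] * 2
        df = cm.group_distance_ranking(np.array(rows), np.array(groups), "ref")
        assert list(df["group"]) == ["g3", "g1", "g2"]

    def test_missing_reference_raises(self):
        with pytest.raises(ValueError):
            cm.group_distance_ranking(np.zeros((2, 2)), np.array(["a", "b"]), "zzz")


class TestSummaryAnova:
    def _frames(self, means, sds, groups=None, variables=("v",)):
        groups = groups or [f"g{i}" for i in range(len(means))]
        m = pd.DataFrame(np.atleast_2d(means).T if np.ndim(means) == 1 else means,
                         index=groups, columns=list(variables))
        s = pd.DataFrame(np.atleast_2d(sds).T if np.ndim(sds) == 1 else sds,
                         index=groups, columns=list(variables))
        return m, s

    def test_equal_means_give_f_zero(self):
        m, s = self._frames([5.0, 5.0, 5.0], [1.0, 1.0, 1.0])
        res = cm.summary_anova(m, s, {g: 8 for g in m.index})
        assert res.anova.loc[0, "F"] == 0.0 and res.anova.loc[0, "p"] == 1.0

    def test_two_groups_f_equals_t_squared(self):
        m, s = self._frames([3.0, 4.2], [0.8, 1.1])
        res = cm.summary_anova(m, s, {"g0": 7, "g1": 9})
        # pooled-variance two-sample t
        sp2 = (6 * 0.8**2 + 8 * 1.1**2) / 14
        t = (3.0 - 4.2) / np.sqrt(sp2 * (1 / 7 + 1 / 9))
        assert res.anova.loc[0, "F"] == pytest.approx(t**2)

    def test_agrees_with_raw_data_anova(self, rng):
        """Feeding a cohort's own summaries reproduces scipy's raw ANOVA."""
        x = [rng.normal(loc, 1.0, size=n) for loc, n in ((0, 8), (0.5, 6), (1.2, 7))]
        m, s = self._frames(
            [v.mean() for v in x], [v.std(ddof=1) for v in x]
        )
        res = cm.summary_anova(m, s, {f"g{i}": len(v) for i, v in enumerate(x)})
        f, p = stats.f_oneway(*x)
        assert res.anova.loc[0, "F"] == pytest.approx(f)
        assert res.anova.loc[0, "p"] == pytest.approx(p)

    def test_fibrinogen_elevation_significant(self):
        """Control vs disease-model FIB (2.94+/-0.40 vs 4.81+/-0.47, n=8)
        is significant at p < 0.01."""
        m, s = self._frames([2.94, 4.81], [0.40, 0.47],
                            groups=["control", "model"], variables=["FIB"])
        res = cm.summary_anova(m, s, {"control": 8, "model": 8})
        row = res.pairwise.query("group == 'model' and reference == 'control'").iloc[0]
        assert row["p"] < 0.01 and row["p_lt_01"]

    def test_nonpositive_sd_rejected(self):
        m, s = self._frames([1.0, 2.0], [1.0, 0.0])
        with pytest.raises(ValueError):
            cm.summary_anova(m, s, {"g0": 8, "g1": 8})
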