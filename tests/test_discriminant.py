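"""Canonical discriminant analysis: rank rules, geometry, reclassification."""

import numpy as np
import pytest

import netburst as nb
from netburst.core import ValidationError
from netburst.discriminant import Ellipse, leave_one_out_accuracy


def two_clouds(rng, n=30, gap=10.0, p=2, cov=None):
    """Two Gaussian groups separated by `gap` within-group SDs along axis 0."""
    cov = np.eye(p) if cov is None else cov
    a = rng.multivariate_normal(np.zeros(p), cov, size=n)
    b = rng.multivariate_normal(np.r_[gap, np.zeros(p - 1)], cov, size=n)
    X = np.vstack([a, b])
    labels = np.array(["a"] * n + ["b"] * n)
    return nb.FeatureMatrix(X, labels, tuple(f"f{i}" for i in range(p)))


class TestFitDiscriminant:
    def test_rank_rule_two_groups_five_features(self, rng):
        X = rng.normal(size=(20, 5))
        labels = np.array(["a"] * 10 + ["b"] * 10)
        model = nb.fit_discriminant(nb.FeatureMatrix(X, labels, tuple("abcde")))
        assert model.n_functions == 1

    def test_rank_rule_three_groups(self, rng):
        X = rng.normal(size=(30, 5))
        labels = np.array(["a"] * 10 + ["b"] * 10 + ["c"] * 10)
        model = nb.fit_discriminant(nb.FeatureMatrix(X, labels, tuple("abcde")))
        assert model.n_functions == 2

    def test_canonical_axis_matches_whitened_centroid_difference(self, rng):
        cov = np.array([[2.0, 0.8], [0.8, 1.0]])
        data = two_clouds(rng, n=200, gap=10.0, cov=cov)
        model = nb.fit_discriminant(data)
        # closed form in the model's standardized space
        Z = (data.X - model.feature_mean) / model.feature_scale
        za, zb = Z[:200], Z[200:]
        d = zb.mean(axis=0) - za.mean(axis=0)
        W = (np.cov(za, rowvar=False) + np.cov(zb, rowvar=False)) / 2
        expected = np.linalg.solve(W, d)
        got = model.coefficients[:, 0]
        cos = abs(expected @ got) / (np.linalg.norm(expected) * np.linalg.norm(got))
        assert np.degrees(np.arccos(np.clip(cos, -1, 1))) < 5.0

    def test_canonical_variates_have_unit_pooled_within_variance(self, rng):
        data = two_clouds(rng, n=100, gap=4.0, p=3)
        model = nb.fit_discriminant(data)
        scores = model.transform(data.X)
        within = np.concatenate(
            [scores[data.labels == g] - scores[data.labels == g].mean(axis=0)
             for g in model.group_names]
        )
        pooled = (within ** 2).sum(axis=0) / (len(within) - len(model.group_names))
        np.testing.assert_allclose(pooled, 1.0, rtol=1e-8)

    def test_rejects_missing_values_and_tiny_groups(self, rng):
        X = rng.normal(size=(6, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValidationError):
            nb.FeatureMatrix(X, np.array(["a"] * 3 + ["b"] * 3), ("x", "y"))
        with pytest.raises(ValidationError):
            nb.FeatureMatrix(rng.normal(size=(3, 2)), np.array(["a", "a", "b"]), ("x", "y"))


class TestReclassify:
    def test_perfect_separation_is_100_percent(self, rng):
        data = two_clouds(rng, n=20, gap=10.0)
        model = nb.fit_discriminant(data)
        predicted, pct = nb.reclassify(model, data)
        assert pct == 100.0
        assert np.array_equal(predicted, data.labels)

    def test_row_at_centroid_assigned_to_that_group(self, rng):
        data = two_clouds(rng, n=30, gap=6.0)
        model = nb.fit_discriminant(data)
        centroid_a = data.X[data.labels == "a"].mean(axis=0)
        centroid_b = data.X[data.labels == "b"].mean(axis=0)
        probe = nb.FeatureMatrix(
            np.vstack([centroid_b, centroid_b, centroid_a, centroid_a]),
            np.array(["b", "b", "a", "a"]),
            data.feature_names,
        )
        predicted, pct = nb.reclassify(model, probe)
        assert list(predicted) == ["b", "b", "a", "a"] and pct == 100.0

    def test_accuracy_invariant_to_affine_feature_rescaling(self, rng):
        data = two_clouds(rng, n=25, gap=3.0, p=4)
        model = nb.fit_discriminant(data)
        _, pct = nb.reclassify(model, data)
        X2 = data.X * np.array([100.0, 1e-3, 7.0, 1.0]) + np.array([5.0, -3.0, 0.0, 9.0])
        data2 = nb.FeatureMatrix(X2, data.labels, data.feature_names)
        model2 = nb.fit_discriminant(data2)
        _, pct2 = nb.reclassify(model2, data2)
        assert pct == pytest.approx(pct2)

    def test_column_mismatch_raises(self, rng):
        data = two_clouds(rng)
        model = nb.fit_discriminant(data)
        other = nb.FeatureMatrix(data.X, data.labels, ("u", "v"))
        with pytest.raises(ValidationError):
            nb.reclassify(model, other)

    def test_agrees_with_sklearn_on_separable_data(self, rng):
        # independent cross-check: sklearn LDA predictions on the same data
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        data = two_clouds(rng, n=40, gap=2.5, p=3)
        model = nb.fit_discriminant(data)
        predicted, _ = nb.reclassify(model, data)
        sk = LinearDiscriminantAnalysis(priors=[0.5, 0.5]).fit(data.X, data.labels)
        agreement = np.mean(predicted == sk.predict(data.X))
        assert agreement >= 0.95

    def test_leave_one_out_not_above_resubstitution_on_noise(self, rng):
        X = rng.normal(size=(40, 3))
        labels = np.array(["a"] * 20 + ["b"] * 20)
        data = nb.FeatureMatrix(X, labels, ("x", "y", "z"))
        model = nb.fit_discriminant(data)
        _, resub = nb.reclassify(model, data)
        loo = leave_one_out_accuracy(data)
        assert loo <= resub + 1e-9


class TestGroupEnvelopes:
    def test_center_equals_centroid_and_isotropic_axes(self, rng):
        data = two_clouds(rng, n=2000, gap=8.0)
        model = nb.fit_discriminant(data)
        # 2 groups -> one canonical function; the padded second dimension is
        # degenerate by construction and must be flagged
        with pytest.warns(UserWarning, match="degenerate"):
            envelopes = nb.group_envelopes(model, data)
        scores = model.transform(data.X)
        scores = np.hstack([scores, np.zeros_like(scores)])[:, :2]
        for env, grp in zip(envelopes, model.group_names):
            mean = scores[data.labels == grp].mean(axis=0)
            np.testing.assert_allclose(env.center, mean, atol=1e-10)

    @staticmethod
    def _three_clouds(rng, n=2000, cov=None):
        # three well-separated groups -> a genuine 2-D canonical space
        cov = np.eye(2) if cov is None else cov
        centers = [(0.0, 0.0), (50.0, 0.0), (0.0, 50.0)]
        X = np.vstack([rng.multivariate_normal(c, cov, size=n) for c in centers])
        labels = np.repeat(["g", "h", "k"], n)
        return nb.FeatureMatrix(X, labels, ("c1", "c2"))

    def test_isotropic_unit_scores_have_chi2_radius(self, rng):
        from scipy.stats import chi2

        data = self._three_clouds(rng)
        model = nb.fit_discriminant(data)
        envelopes = nb.group_envelopes(model, data, confidence=0.95)
        q = np.sqrt(chi2.ppf(0.95, 2))
        # canonical variates are whitened within groups, so each group's
        # score cloud is isotropic with unit variance
        for env in envelopes:
            assert env.semi_axes[0] == pytest.approx(q, rel=0.10)
            assert env.semi_axes[1] == pytest.approx(q, rel=0.10)

    def test_95pct_ellipse_coverage(self, rng):
        data = self._three_clouds(rng, cov=np.array([[3.0, 1.0], [1.0, 1.5]]))
        model = nb.fit_discriminant(data)
        envelopes = nb.group_envelopes(model, data, confidence=0.95)
        scores = model.transform(data.X)
        scores = np.hstack([scores, np.zeros_like(scores)])[:, :2]
        for env, grp in zip(envelopes, model.group_names):
            s = scores[data.labels == grp] - np.asarray(env.center)
            theta = np.radians(env.angle_deg)
            rot = np.array([[np.cos(theta), np.sin(theta)],
                            [-np.sin(theta), np.cos(theta)]])
            u = s @ rot.T
            a, b = env.semi_axes
            b = max(b, 1e-12)
            inside = (u[:, 0] / a) ** 2 + (u[:, 1] / b) ** 2 <= 1.0
            assert 0.92 <= inside.mean() <= 0.98

    def test_too_few_rows_per_group_raises(self, rng):
        data = two_clouds(rng, n=30, gap=5.0)
        model = nb.fit_discriminant(data)
        small = nb.FeatureMatrix(data.X[:4], np.array(["a", "a", "b", "b"]), data.feature_names)
        with pytest.raises(ValidationError):
            nb.group_envelopes(model, small)
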