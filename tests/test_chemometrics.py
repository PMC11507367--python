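"""Scaling, PCA, PLS/VIP, selection and validation logic against independent oracles."""

import numpy as np
import pytest

import spoilmark as sm
from spoilmark import chemometrics as chem
from spoilmark.exceptions import (ConfigurationError, DegenerateClassError,
                                  DegenerateDataError)

rng = np.random.default_rng  # shorthand


def nipals_pls1(X, y, A):
    """Independent NIPALS PLS1 oracle: X-deflation, unit-norm weights."""
    X = np.asarray(X, float).copy()
    y = np.asarray(y, float).reshape(-1).copy()
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    W, T, P, q = [], [], [], []
    for _ in range(A):
        w = Xc.T @ yc
        w = w / np.linalg.norm(w)
        t = Xc @ w
        p = Xc.T @ t / (t @ t)
        qa = yc @ t / (t @ t)
        Xc = Xc - np.outer(t, p)
        W.append(w); T.append(t); P.append(p); q.append(qa)
    return (np.column_stack(W), np.column_stack(T), np.column_stack(P), np.array(q))


class TestMinMax:
    def test_simple_column(self):
        s = chem.minmax_scale(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(s.values.ravel(), [0, 0.5, 1])

    def test_constant_column_maps_to_zero(self):
        s = chem.minmax_scale(np.array([[5.0, 1.0], [5.0, 2.0], [5.0, 4.0]]))
        np.testing.assert_allclose(s.values[:, 0], 0.0)

    def test_inverse_roundtrip(self):
        X = rng(0).uniform(10, 1000, size=(12, 7))
        X[:, 3] = 42.0
        s = chem.minmax_scale(X)
        np.testing.assert_allclose(s.inverse(), X, atol=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ConfigurationError):
            chem.minmax_scale(np.empty((0, 3)))


class TestPCA:
    def test_collinear_data_one_component_explains_all(self):
        t = np.linspace(0, 1, 9)[:, None]
        X = t @ np.array([[2.0, -1.0, 0.5]])
        model = chem.pca(X, k=2)
        assert model.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-12)

    def test_loadings_orthonormal(self):
        X = rng(1).normal(size=(10, 20))
        model = chem.pca(X, k=4)
        np.testing.assert_allclose(model.loadings.T @ model.loadings, np.eye(4), atol=1e-10)

    def test_matches_svd_oracle_up_to_sign(self):
        X = rng(2).normal(size=(10, 20))
        model = chem.pca(X, k=3)
        Xc = X - X.mean(axis=0)
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        for j in range(3):
            sign = np.sign(Vt[j] @ model.loadings[:, j])
            np.testing.assert_allclose(model.loadings[:, j], sign * Vt[j], atol=1e-10)
            np.testing.assert_allclose(model.scores[:, j], sign * U[:, j] * s[j], atol=1e-9)
        # scores reconstruct the centred data at full rank
        full = chem.pca(X, k=9)
        np.testing.assert_allclose(full.scores @ full.loadings.T, Xc, atol=1e-9)

    def test_excessive_k_rejected(self):
        with pytest.raises(ConfigurationError):
            chem.pca(rng(0).normal(size=(5, 3)), k=5)


class TestPLS:
    def test_exact_linear_single_component(self):
        # orthogonal zero-mean design: one component isolates the active column
        A = rng(3).normal(size=(15, 5))
        Q = np.linalg.qr(A - A.mean(axis=0))[0][:, :4]
        y = 2.5 * Q[:, 1] + 1.0
        model = chem.pls_fit(Q, y, 1)
        _, r2 = chem.evaluate(model, Q, y)
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_feature_permutation_equivariance(self):
        X = rng(4).normal(size=(12, 6))
        y = rng(4).normal(size=12)
        perm = rng(5).permutation(6)
        m1 = chem.pls_fit(X, y, 2)
        m2 = chem.pls_fit(X[:, perm], y, 2)
        np.testing.assert_allclose(m2.x_weights, m1.x_weights[perm], atol=1e-10)
        np.testing.assert_allclose(m2.predict(X[:, perm]), m1.predict(X), atol=1e-10)

    def test_first_weight_proportional_to_xty(self):
        X = rng(6).normal(size=(8, 5))
        y = rng(6).normal(size=8)
        model = chem.pls_fit(X, y, 1)
        Xc, yc = X - X.mean(0), y - y.mean()
        expected = Xc.T @ yc
        expected /= np.linalg.norm(expected)
        sign = np.sign(expected @ model.x_weights[:, 0])
        np.testing.assert_allclose(model.x_weights[:, 0], sign * expected, atol=1e-10)

    def test_agrees_with_nipals_oracle(self):
        X = rng(7).normal(size=(14, 6))
        y = rng(7).normal(size=14)
        model = chem.pls_fit(X, y, 3)
        W, T, P, q = nipals_pls1(X, y, 3)
        for a in range(3):
            sign = np.sign(W[:, a] @ model.x_weights[:, a])
            np.testing.assert_allclose(model.x_weights[:, a], sign * W[:, a], atol=1e-8)
            np.testing.assert_allclose(model.x_scores[:, a], sign * T[:, a], atol=1e-7)
        # scores mutually orthogonal
        G = model.x_scores.T @ model.x_scores
        np.testing.assert_allclose(G - np.diag(np.diag(G)), 0, atol=1e-8)

    def test_full_rank_equals_ols(self):
        X = rng(8).normal(size=(20, 5))
        y = rng(8).normal(size=20)
        model = chem.pls_fit(X, y, 5)
        Xd = np.column_stack([np.ones(20), X])
        beta = np.linalg.lstsq(Xd, y, rcond=None)[0]
        np.testing.assert_allclose(model.predict(X), Xd @ beta, atol=1e-8)

    def test_component_count_beyond_rank_rejected(self):
        X = rng(9).normal(size=(6, 3))
        with pytest.raises(ConfigurationError):
            chem.pls_fit(X, rng(9).normal(size=6), 4)


class TestVIP:
    @pytest.mark.parametrize("scale", [False, True])
    def test_mean_squared_vip_is_one(self, scale):
        X = rng(10).normal(size=(16, 9))
        y = rng(10).normal(size=16)
        model = chem.pls_fit(X, y, 3, scale=scale)
        vip = chem.vip_scores(model)
        assert np.mean(vip ** 2) == pytest.approx(1.0, rel=1e-12)

    def test_single_informative_feature(self):
        # y depends on feature 0 only; remaining features are constant
        X = np.zeros((10, 4))
        X[:, 0] = np.arange(10.0)
        y = 3.0 * X[:, 0]
        model = chem.pls_fit(X, y, 1)
        vip = chem.vip_scores(model)
        assert vip[0] == pytest.approx(np.sqrt(4), rel=1e-9)
        np.testing.assert_allclose(vip[1:], 0.0, atol=1e-9)

    def test_matches_direct_formula(self):
        X = rng(11).normal(size=(18, 7))
        y = rng(11).normal(size=18)
        model = chem.pls_fit(X, y, 3)
        W, ssy, p = model.x_weights, model.ssy, 7
        direct = np.sqrt(
            p * sum(ssy[a] * (W[:, a] / np.linalg.norm(W[:, a])) ** 2 for a in range(3))
            / ssy.sum())
        np.testing.assert_allclose(chem.vip_scores(model), direct, atol=1e-10)


class TestFSelect:
    def test_perfect_feature_ranked_first(self):
        X = rng(12).normal(size=(10, 5))
        y = rng(12).normal(size=10)
        X[:, 3] = y
        res = chem.f_select(X, y, k=2)
        assert 3 in res.selected
        # exact correlation: the F statistic saturates (inf or huge) and wins
        assert np.isinf(res.statistic[3]) or res.statistic[3] > 1e12
        assert np.argmax(res.statistic) == 3

    def test_constant_feature_scores_zero_and_loses(self):
        X = rng(13).normal(size=(10, 3))
        X[:, 1] = 7.0
        y = rng(13).normal(size=10)
        res = chem.f_select(X, y, k=2)
        assert res.statistic[1] == 0.0
        assert 1 not in res.selected

    def test_matches_regression_anova_oracle(self):
        X = rng(14).normal(size=(20, 10))
        y = rng(14).normal(size=20)
        res = chem.f_select(X, y, k=10)
        n = 20
        for j in range(10):
            r = np.corrcoef(X[:, j], y)[0, 1]
            expected = r ** 2 / (1 - r ** 2) * (n - 2)
            assert res.statistic[j] == pytest.approx(expected, rel=1e-9)

    def test_feature_order_invariance(self):
        X = rng(15).normal(size=(12, 8))
        y = X[:, 2] + 0.1 * rng(15).normal(size=12)
        ids = [f"f{j}" for j in range(8)]
        perm = rng(16).permutation(8)
        r1 = chem.f_select(X, y, k=3, feature_ids=ids)
        r2 = chem.f_select(X[:, perm], y, k=3, feature_ids=[ids[j] for j in perm])
        assert set(r1.selected_ids) == set(r2.selected_ids)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ConfigurationError):
            chem.f_select(np.ones((2, 3)), np.array([1.0, 2.0]), k=1)


class TestVIPFilter:
    def test_zero_threshold_keeps_everything(self):
        X = rng(17).normal(size=(20, 10))
        classes = ["a"] * 10 + ["b"] * 10
        res = chem.vip_filter(X, classes, threshold=0.0)
        assert len(res.selected) == 10

    def test_pure_noise_retains_minority(self):
        X = rng(18).normal(size=(40, 200))
        classes = ["a"] * 20 + ["b"] * 20
        res = chem.vip_filter(X, classes, threshold=1.5)
        assert len(res.selected) / 200 < 0.40

    def test_planted_discriminative_feature_retained(self):
        X = rng(19).normal(size=(30, 50))
        classes = np.array(["a"] * 15 + ["b"] * 15)
        X[classes == "b", 7] += 5.0
        res = chem.vip_filter(X, classes, threshold=1.5, scale=True)
        assert 7 in res.selected


class TestSplitsAndTargets:
    def test_use_by_boundary(self):
        labels = chem.split_by_use_by([4, 5])
        assert list(labels) == [chem.FRESH, chem.PAST_USE_BY]

    def test_single_class_fails_downstream(self):
        X = rng(20).normal(size=(10, 4))
        classes = chem.split_by_use_by([1, 2, 3, 4] * 2 + [1, 2])
        with pytest.raises(DegenerateClassError):
            chem.plsda(X, classes)

    def test_published_split_sizes(self):
        train, test = chem.train_test_split(range(50), train_frac=0.8, seed=42)
        assert (len(train), len(test)) == (40, 10)

    def test_split_deterministic_disjoint_exhaustive(self):
        a = chem.train_test_split(range(23), seed=5)
        b = chem.train_test_split(range(23), seed=5)
        assert a == b
        assert set(a[0]) | set(a[1]) == set(range(23))
        assert set(a[0]) & set(a[1]) == set()

    def test_bad_fraction_rejected(self):
        with pytest.raises(ConfigurationError):
            chem.train_test_split(range(10), train_frac=1.0)


class TestEvaluation:
    def _fit(self):
        X = rng(21).normal(size=(20, 3))
        y = X @ np.array([1.0, -2.0, 0.5])
        return chem.pls_fit(X, y, 3), X, y

    def test_perfect_predictions(self):
        model, X, y = self._fit()
        mse, r2 = chem.evaluate(model, X, y)
        assert mse == pytest.approx(0.0, abs=1e-12)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_mean_predictor_r2_zero(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        model, _, _ = self._fit()
        model.coef = np.zeros(3)
        model.x_mean = np.zeros(3)
        model.intercept = float(y.mean())
        mse, r2 = chem.evaluate(model, np.zeros((4, 3)), y)
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_constant_target_flagged(self):
        model, X, _ = self._fit()
        with pytest.raises(DegenerateDataError):
            chem.evaluate(model, X, np.ones(20))

    def test_two_latent_factor_response_selects_two_components(self):
        g = rng(22)
        t1, t2 = g.normal(size=(2, 60))
        loadings = g.normal(size=(2, 30))
        X = np.outer(t1, loadings[0]) + np.outer(t2, loadings[1])
        y = 2.0 * t1 - 1.0 * t2
        a_star, records = chem.choose_components(X, y, a_max=5, seed=0)
        assert a_star == 2
        assert records[1]["r2"] == pytest.approx(1.0, abs=1e-8)


class TestPLSDA:
    def test_separable_classes_perfect_confusion(self):
        g = rng(23)
        X = g.normal(size=(30, 5))
        classes = np.array(["a"] * 15 + ["b"] * 15)
        X[classes == "b", 0] += 10.0
        res = chem.plsda(X, classes, seed=0)
        assert res.accuracy == 1.0
        assert res.confusion[0, 1] == 0 and res.confusion[1, 0] == 0

    def test_label_swap_symmetry(self):
        g = rng(24)
        X = g.normal(size=(24, 4))
        classes = np.array(["a"] * 12 + ["b"] * 12)
        X[classes == "b", 1] += 4.0
        res_ab = chem.plsda(X, classes, seed=0)
        swapped = np.where(classes == "a", "b", "a")
        res_ba = chem.plsda(X, swapped, seed=0)
        np.testing.assert_array_equal(res_ab.confusion, res_ba.confusion[::-1, ::-1])

    def test_default_synthetic_holdout_accuracy(self, default_timecourse):
        # published order of operations: VIP > 1.5 pre-filter, then PLS-DA
        table, _ = default_timecourse
        X = table.intensity_matrix()
        classes = chem.split_by_use_by(table.samples["day"].to_numpy())
        kept = chem.vip_filter(X, classes, threshold=1.5, scale=True)
        res = chem.plsda(X[:, kept.selected], classes, seed=42, scale=True)
        assert res.accuracy > 0.9


class TestSerialisation:
    def test_model_json_roundtrip_preserves_predictions(self, tmp_path):
        X = rng(30).normal(size=(15, 6))
        y = rng(30).normal(size=15)
        model = chem.pls_fit(X, y, 2, scale=True)
        chem.save_model(model, tmp_path / "model.json")
        back = chem.load_model(tmp_path / "model.json")
        np.testing.assert_allclose(back.predict(X), model.predict(X), atol=1e-12)
        np.testing.assert_allclose(chem.vip_scores(back), chem.vip_scores(model),
                                   atol=1e-12)

    def test_selection_result_frame(self):
        X = rng(31).normal(size=(12, 5))
        y = X[:, 2] + 0.01 * rng(31).normal(size=12)
        res = chem.f_select(X, y, k=2, feature_ids=list("abcde"))
        frame = res.to_frame()
        assert set(frame.columns) == {"feature_id", "statistic", "rank", "retained"}
        assert frame["retained"].sum() == 2
        assert frame.loc[frame["rank"] == 1, "feature_id"].iloc[0] == "c"
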