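import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import silhouette_score

from sf12risk import reducers as rd
from sf12risk.reducers import (
    FeatureMatrix,
    ReducerModel,
    assign_features,
    fit_ccpca,
    fit_gpca,
    fit_kpca,
    fit_lda_hybrid,
    fit_pca,
    rank_discriminant_power,
    standardize,
    variance_explained_k,
)
from tests.conftest import make_spectrum_data


def angle_deg(u, v):
    return np.degrees(np.arccos(min(1.0, abs(float(u @ v)))))


def eigh_oracle(X):
    """Independent dense eigendecomposition of the sample covariance."""
    C = np.cov(X - X.mean(axis=0), rowvar=False)
    w, v = np.linalg.eigh(C)
    return w[::-1], v[:, ::-1]


class TestStandardize:
    def test_hand_computed_zscores(self):
        X = np.array([[1.0, 10.0], [2.0, 20.0], [3.0, 60.0]])
        out = standardize(X)
        # manual arithmetic: col0 mean 2 sd 1; col1 mean 30 sd ~26.4575
        np.testing.assert_allclose(out.values[:, 0], [-1.0, 0.0, 1.0], atol=1e-12)
        sd1 = np.std([10, 20, 60], ddof=1)
        np.testing.assert_allclose(
            out.values[:, 1], (np.array([10, 20, 60]) - 30) / sd1, atol=1e-12
        )

    def test_idempotent(self, rng):
        X = rng.normal(size=(40, 5))
        once = standardize(X)
        twice = standardize(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)

    def test_constant_column_dropped_with_warning(self, rng):
        X = rng.normal(size=(30, 3))
        X[:, 1] = 4.2
        with pytest.warns(UserWarning, match="constant"):
            out = standardize(FeatureMatrix(X, ["a", "b", "c"]))
        assert out.feature_names == ["a", "c"]

    def test_all_constant_rejected(self):
        with pytest.raises(ValueError):
            standardize(np.ones((10, 3)))

    def test_non_finite_rejected(self):
        X = np.ones((5, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            FeatureMatrix(X)


class TestPCA:
    def test_isotropic_split(self):
        r = np.random.default_rng(0)
        X = r.normal(size=(4000, 2))
        m = fit_pca(standardize(X), 2)
        assert m.variance_explained[0] == pytest.approx(0.5, abs=0.05)
        assert m.variance_explained[1] == pytest.approx(0.5, abs=0.05)

    def test_rank_one_data(self):
        t = np.linspace(-1, 1, 30)
        X = np.column_stack([t, 2 * t, -t])
        m = fit_pca(X, 1)
        assert m.variance_explained[0] == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dense_eigendecomposition(self, seed):
        r = np.random.default_rng(seed)
        X = r.normal(size=(50, 6))
        m = fit_pca(X, 6)
        w, v = eigh_oracle(X)
        np.testing.assert_allclose(m.axis_variances, w, atol=1e-10)
        for j in range(6):
            assert angle_deg(m.axes[j], v[:, j]) < 0.01

    def test_k_out_of_range(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValueError):
            fit_pca(X, 4)

    def test_variance_conservation_full_rank(self, rng):
        X = standardize(rng.normal(size=(60, 7)))
        m = fit_pca(X, 7)
        assert float(np.sum(m.variance_explained)) == pytest.approx(1.0, abs=1e-10)

    def test_orthonormal_axes(self, rng):
        X = rng.normal(size=(80, 6))
        m = fit_pca(X, 5)
        np.testing.assert_allclose(m.axes @ m.axes.T, np.eye(5), atol=1e-8)


class TestKPCA:
    def test_linear_kernel_matches_pca(self, rng):
        X = standardize(rng.normal(size=(60, 5)))
        pca = fit_pca(X, 4)
        kl = fit_kpca(X, 4, kernel="linear")
        np.testing.assert_allclose(
            kl.variance_explained, pca.variance_explained, atol=1e-8
        )

    def test_large_bandwidth_approaches_linear(self, rng):
        X = standardize(rng.normal(size=(50, 4)))
        kl = fit_kpca(X, 3, kernel="linear")
        kr = fit_kpca(X, 3, kernel="rbf", bandwidth=1e4)
        np.testing.assert_allclose(
            kr.variance_explained, kl.variance_explained, atol=1e-6
        )

    def test_concentric_circles_separated(self):
        r = np.random.default_rng(42)
        n = 150
        theta = r.uniform(0, 2 * np.pi, 2 * n)
        radius = np.r_[np.full(n, 1.0), np.full(n, 4.0)] + r.normal(0, 0.05, 2 * n)
        X = np.column_stack([radius * np.cos(theta), radius * np.sin(theta)])
        y = np.r_[np.zeros(n), np.ones(n)]
        m = fit_kpca(X, 2, kernel="rbf", bandwidth=1.0)
        scores = m.transform(X)
        assert silhouette_score(scores, y) > 0.5

    def test_axes_unavailable(self, rng):
        m = fit_kpca(standardize(rng.normal(size=(30, 3))), 2)
        assert m.axes is None

    def test_transform_matches_fit_scores(self, rng):
        X = standardize(rng.normal(size=(40, 4)))
        m = fit_kpca(X, 3)
        scores = m.transform(X.values)
        np.testing.assert_allclose(
            np.var(scores, axis=0, ddof=1), m.axis_variances, atol=1e-10
        )


class TestGPCA:
    def test_oracle_equivalence_20_seeds(self):
        worst = 0.0
        for seed in range(20):
            X = make_spectrum_data(seed)
            m = fit_gpca(X, 6, seed=seed)
            _, v = eigh_oracle(X)
            for j in range(6):
                worst = max(worst, angle_deg(m.axes[j], v[:, j]))
        assert worst < 2.0

    def test_rank_one_variance(self):
        t = np.linspace(-2, 2, 50)
        X = np.column_stack([t, -3 * t, 0.5 * t])
        m = fit_gpca(X, 1, seed=0)
        assert m.variance_explained[0] == pytest.approx(1.0, abs=1e-6)

    def test_seed_stability_up_to_sign(self):
        X = make_spectrum_data(3, n=120)
        a = fit_gpca(X, 3, seed=1)
        b = fit_gpca(X, 3, seed=2)
        for j in range(3):
            assert angle_deg(a.axes[j], b.axes[j]) < 1.0

    def test_well_separated_spectrum(self):
        r = np.random.default_rng(1)
        X = r.normal(size=(500, 3)) * np.sqrt([5.0, 1.0, 0.1])
        q, _ = np.linalg.qr(r.normal(size=(3, 3)))
        X = X @ q.T
        m = fit_gpca(X, 3, seed=0)
        _, v = eigh_oracle(X)
        for j in range(3):
            assert angle_deg(m.axes[j], v[:, j]) < 2.0

    def test_convergence_metadata(self):
        m = fit_gpca(make_spectrum_data(0), 2, seed=0)
        assert m.meta["converged"] is True
        assert len(m.meta["epochs_per_axis"]) == 2


def two_class_fixture(rng, shift=6.0, n=100, p=4):
    X0 = rng.normal(size=(n, p))
    X1 = rng.normal(size=(n, p))
    X1[:, 0] += shift
    return np.vstack([X0, X1]), np.r_[np.zeros(n, int), np.ones(n, int)]


class TestCCPCA:
    def test_single_class_equals_pca(self, rng):
        X = standardize(rng.normal(size=(50, 5)))
        pca = fit_pca(X, 4)
        cc = fit_ccpca(X, np.zeros(50, int), 4)
        assert cc.method == "CCPCA"
        np.testing.assert_allclose(
            np.abs(cc.axes @ pca.axes.T), np.eye(4), atol=1e-8
        )

    def test_centroid_axis_geometry(self, rng):
        X, y = two_class_fixture(rng)
        cc = fit_ccpca(X, y, 2)
        e0 = np.eye(4)[0]
        assert angle_deg(cc.axes[0], e0) < 5.0
        assert cc.meta["n_class_axes"] == 1

    def test_supervised_advantage_on_orthogonal_class_structure(self):
        # max-variance direction carries no class signal; class signal lives
        # in a low-variance feature
        r = np.random.default_rng(8)
        n = 200
        y = np.r_[np.zeros(n, int), np.ones(n, int)]
        noise = r.normal(size=2 * n)
        X = np.column_stack(
            [
                noise * 3.0,                      # high-variance, no signal
                noise * 3.0 + r.normal(0, 0.5, 2 * n),  # correlated partner
                (y - 0.5) * 1.2 + r.normal(0, 0.4, 2 * n),  # class signal
            ]
        )
        Xs = standardize(X)
        pca = fit_pca(Xs, 1)
        cc = fit_ccpca(Xs, y, 1)
        assert angle_deg(cc.axes[0], pca.axes[0]) > 30.0

        def downstream_accuracy(model):
            scores = model.transform(Xs.values)
            clf = LogisticRegression().fit(scores, y)
            return clf.score(scores, y)

        assert downstream_accuracy(cc) > downstream_accuracy(pca) + 0.2

    def test_small_class_rejected(self, rng):
        X = rng.normal(size=(20, 3))
        y = np.r_[np.zeros(19, int), [1]]
        with pytest.raises(ValueError, match="fewer than 2"):
            fit_ccpca(X, y, 2)

    def test_coincident_centroids_fall_back(self, rng):
        X = rng.normal(size=(40, 3))
        y = np.r_[np.zeros(20, int), np.ones(20, int)]
        X[y == 1] = X[y == 0]  # identical classes -> coincident centroids
        with pytest.warns(UserWarning, match="coincide"):
            cc = fit_ccpca(X, y, 2)
        assert cc.meta.get("fallback") == "coincident_centroids"

    def test_orthonormal_axes(self, rng):
        X, y = two_class_fixture(rng)
        cc = fit_ccpca(X, y, 4)
        np.testing.assert_allclose(cc.axes @ cc.axes.T, np.eye(4), atol=1e-8)


class TestLDAHybrid:
    def test_identity_within_class_matches_ccpca_axis(self):
        # whiten the class clouds so the pooled within-class covariance is
        # exactly the identity; the Fisher axis then equals the centroid axis
        r = np.random.default_rng(5)
        n, p = 150, 4
        Z = r.normal(size=(n, p))
        Z -= Z.mean(axis=0)
        C = np.cov(Z, rowvar=False)
        W = Z @ np.linalg.cholesky(np.linalg.inv(C))  # sample cov exactly I
        shift = np.array([2.0, -1.0, 0.5, 0.0])
        X = np.vstack([W, W + shift])
        y = np.r_[np.zeros(n, int), np.ones(n, int)]
        ld = fit_lda_hybrid(X, y, 2)
        cc = fit_ccpca(X, y, 2)
        assert angle_deg(ld.axes[0], cc.axes[0]) < 1e-6

    def test_matches_closed_form_fisher(self, rng):
        X, y = two_class_fixture(rng, shift=3.0)
        X[:, 1] *= 4.0  # anisotropic within-class noise
        ld = fit_lda_hybrid(X, y, 1)
        # closed-form oracle
        mu0, mu1 = X[y == 0].mean(axis=0), X[y == 1].mean(axis=0)
        sw = np.zeros((4, 4))
        for c, mu in ((0, mu0), (1, mu1)):
            d = X[y == c] - mu
            sw += d.T @ d
        sw /= len(y) - 2
        w = np.linalg.solve(sw, mu1 - mu0)
        w /= np.linalg.norm(w)
        assert angle_deg(ld.axes[0], w) < 1e-6

    def test_k1_variance_length(self, rng):
        X, y = two_class_fixture(rng)
        ld = fit_lda_hybrid(X, y, 1)
        assert len(ld.variance_explained) == 1

    def test_singular_scatter_gets_ridge(self, rng):
        X, y = two_class_fixture(rng, n=30)
        X[:, 3] = X[:, 0] * 2.0  # exactly collinear -> singular scatter
        ld = fit_lda_hybrid(X, y, 1)
        assert ld.meta["ridge"] > 0

    def test_non_binary_rejected(self, rng):
        X = rng.normal(size=(30, 3))
        y = np.arange(30) % 3
        with pytest.raises(ValueError, match="2 classes"):
            fit_lda_hybrid(X, y, 1)


class TestVarianceReporting:
    def test_published_fraction_cumulative_pct(self):
        model = _model_with(ve=[0.3155, 0.2755, 0.1533, 0.0743])
        assert variance_explained_k(model, 2) == 59.10

    def test_full_rank_hits_100(self, rng):
        X = standardize(rng.normal(size=(40, 5)))
        m = fit_pca(X, 5)
        assert variance_explained_k(m, 5) == pytest.approx(100.0, abs=0.01)

    def test_rank_one(self):
        t = np.linspace(0, 1, 20)
        m = fit_pca(np.column_stack([t, 2 * t]), 1)
        assert variance_explained_k(m, 1) == 100.0

    def test_k_beyond_fit_rejected(self, rng):
        m = fit_pca(rng.normal(size=(30, 4)), 2)
        with pytest.raises(ValueError):
            variance_explained_k(m, 3)


def _model_with(loadings=None, ve=None, names=None, supervised=True, n_class_axes=1):
    ve = np.asarray(ve if ve is not None else [0.5, 0.3])
    k = len(ve)
    if loadings is None:
        loadings = np.zeros((2, k))
    loadings = np.asarray(loadings, dtype=float)
    p = loadings.shape[0]
    return ReducerModel(
        method="CCPCA",
        feature_names=names or [f"f{i}" for i in range(p)],
        axes=np.eye(max(p, k))[:k, :p],
        axis_variances=ve * p,
        loadings=loadings,
        variance_explained=ve,
        supervised=supervised,
        meta={"n_class_axes": n_class_axes},
    )


class TestDiscriminantRanking:
    def test_single_component_dominant_loading(self):
        m = _model_with(loadings=[[0.9], [0.1]], ve=[0.6])
        ranking = rank_discriminant_power(m)
        assert ranking.iloc[0]["feature"] == "f0"

    def test_only_separating_feature_ranks_first(self):
        # feature 2 carries the class signal; brute-force per-feature class
        # separation confirms it before the ranking is asserted
        r = np.random.default_rng(9)
        n = 150
        y = np.r_[np.zeros(n, int), np.ones(n, int)]
        X = r.normal(size=(2 * n, 3))
        X[:, 2] += y * 2.0
        # independent check: standardized mean separation per feature
        seps = [
            abs(X[y == 1, j].mean() - X[y == 0, j].mean()) / X[:, j].std()
            for j in range(3)
        ]
        assert int(np.argmax(seps)) == 2
        Xs = standardize(FeatureMatrix(X, ["a", "b", "c"], y))
        cc = fit_ccpca(Xs, y, 3)
        ranking = rank_discriminant_power(cc)
        assert ranking.iloc[0]["feature"] == "c"

    def test_permutation_invariance(self, rng):
        X, y = two_class_fixture(rng)
        names = ["w", "x", "y", "z"]
        cc = fit_ccpca(FeatureMatrix(X, names, y), y, 3)
        perm = [2, 0, 3, 1]
        cc_p = fit_ccpca(
            FeatureMatrix(X[:, perm], [names[i] for i in perm], y), y, 3
        )
        a = rank_discriminant_power(cc)["feature"].tolist()
        b = rank_discriminant_power(cc_p)["feature"].tolist()
        assert a == b

    def test_unsupervised_rejected(self, rng):
        m = fit_pca(rng.normal(size=(30, 3)), 2)
        with pytest.raises(ValueError, match="supervised"):
            rank_discriminant_power(m)


class TestAssignFeatures:
    def test_threshold_is_strict(self):
        m = _model_with(loadings=[[0.70], [0.71]], ve=[0.5], names=["a", "b"])
        fa = assign_features(m, 0.7)
        assert fa.assignments[0] == ["b"]

    def test_negative_loading_included_by_absolute_value(self):
        m = _model_with(loadings=[[-0.85], [0.2]], ve=[0.5], names=["a", "b"])
        assert assign_features(m).assignments[0] == ["a"]

    def test_multi_component_claimed_by_larger(self):
        m = _model_with(
            loadings=[[0.8, 0.9], [0.75, 0.1]], ve=[0.4, 0.3], names=["a", "b"]
        )
        fa = assign_features(m)
        assert fa.assignments[1] == ["a"]
        assert fa.assignments[0] == ["b"]
        assert fa.all_features() == ["b", "a"] or fa.all_features() == ["a", "b"]

    def test_empty_assignment_allowed(self):
        m = _model_with(loadings=[[0.1], [0.2]], ve=[0.5])
        fa = assign_features(m)
        assert fa.assignments[0] == []


class TestSerialization:
    @pytest.mark.parametrize("method", ["pca", "kpca", "ccpca", "lda"])
    def test_json_round_trip_preserves_transform(self, rng, method, tmp_path):
        X, y = two_class_fixture(rng)
        Xs = standardize(FeatureMatrix(X, labels=y))
        model = {
            "pca": lambda: fit_pca(Xs, 3),
            "kpca": lambda: fit_kpca(Xs, 3),
            "ccpca": lambda: fit_ccpca(Xs, y, 3),
            "lda": lambda: fit_lda_hybrid(Xs, y, 3),
        }[method]()
        path = tmp_path / "model.json"
        model.to_json(path)
        again = ReducerModel.from_json(path)
        np.testing.assert_allclose(
            again.transform(Xs.values), model.transform(Xs.values), atol=1e-10
        )
        np.testing.assert_allclose(
            again.variance_explained, model.variance_explained, atol=1e-12
        )
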