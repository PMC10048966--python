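"""Five dimensionality reducers under one estimator contract.

Methods
-------
PCA
    Classical principal components via SVD of the centered data matrix.
KPCA
    Kernel PCA: eigendecomposition of the doubly-centered Gram matrix
    (default RBF kernel with median-heuristic bandwidth).
GPCA
    "Gradient" PCA: principal axes estimated by stochastic gradient ascent
    on projected variance (Oja/Hebbian updates) with deflation, instead of
    an eigensolver.  Converges to the PCA axes on well-conditioned data;
    convergence diagnostics are recorded on the model.
CCPCA
    Centroid-class PCA: the leading axes are the orthonormalized class-
    centroid offset directions (supervised, "class-oriented" axes); the
    remaining axes are ordinary PCA in the orthogonal complement of that
    span.  This is a reconstruction of the centroid-rotation idea: the
    feature space is rotated so that between-class structure is isolated in
    the leading subspace.
LDA_hybrid
    Axis 1 is the Fisher discriminant direction (within-class-scatter
    whitened centroid difference); axes 2..k are PCA in its orthogonal
    complement — the same block construction as CCPCA, so that a full
    variance accounting is available even for a binary problem.

All models expose the same fields (axes, per-axis variances, loadings as
feature–score Pearson correlations, variance-explained fractions) and a
``transform``; ``axes`` is None for KPCA where feature-space pre-images are
not available.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from scipy.spatial.distance import cdist, pdist

__all__ = [
    "FeatureMatrix",
    "ReducerModel",
    "FeatureAssignment",
    "standardize",
    "fit_pca",
    "fit_kpca",
    "fit_gpca",
    "fit_ccpca",
    "fit_lda_hybrid",
    "variance_explained_k",
    "rank_discriminant_power",
    "assign_features",
]

METHODS = ("PCA", "KPCA", "GPCA", "CCPCA", "LDA_hybrid")


@dataclass
class FeatureMatrix:
    """n × p feature matrix with names and optional binary labels."""

    values: np.ndarray
    feature_names: list[str] = None
    labels: np.ndarray | None = None
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        n, p = self.values.shape
        if p < 2:
            raise ValueError(f"need at least 2 features, got {p}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite entries")
        if self.feature_names is None:
            self.feature_names = [f"f{i}" for i in range(p)]
        self.feature_names = list(self.feature_names)
        if len(self.feature_names) != p:
            raise ValueError("feature_names length must match number of columns")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (n,):
                raise ValueError("labels must have one entry per row")
            if len(np.unique(self.labels)) >= 2:
                pass  # both classes non-empty by construction of unique()

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _as_matrix(X, labels=None) -> FeatureMatrix:
    if isinstance(X, FeatureMatrix):
        if labels is not None and X.labels is None:
            return FeatureMatrix(X.values, X.feature_names, labels, X.standardized)
        return X
    return FeatureMatrix(np.asarray(X, dtype=float), labels=labels)


def standardize(X, *, ddof: int = 1) -> FeatureMatrix:
    """Z-score every column (mean 0, SD 1, sample SD by default).

    Constant columns carry no information for any of the reducers and are
    dropped with a warning; an all-constant matrix is an error.
    """
    fm = _as_matrix(X)
    vals = fm.values
    means = vals.mean(axis=0)
    sds = vals.std(axis=0, ddof=ddof)
    # tolerance guards against constant columns whose SD is float fuzz
    keep = sds > 1e-12 * np.maximum(1.0, np.abs(means))
    if not np.any(keep):
        raise ValueError("all features are constant; nothing to standardize")
    if not np.all(keep):
        dropped = [n for n, k in zip(fm.feature_names, keep) if not k]
        warnings.warn(f"dropping constant feature(s): {dropped}", stacklevel=2)
    z = (vals[:, keep] - means[keep]) / sds[keep]
    names = [n for n, k in zip(fm.feature_names, keep) if k]
    return FeatureMatrix(z, names, fm.labels, standardized=True)


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------


@dataclass
class ReducerModel:
    """Fitted reducer: axes, variances, loadings and variance accounting.

    ``loadings`` are Pearson correlations between the original features and
    the component scores on the fitted data — a definition that is method-
    agnostic (it is the classical factor loading for PCA on standardized
    data and remains meaningful for KPCA, whose axes have no feature-space
    pre-image).
    """

    method: str
    feature_names: list[str]
    axes: np.ndarray | None          # (k, p), orthonormal; None for KPCA
    axis_variances: np.ndarray       # (k,)
    loadings: np.ndarray             # (p, k)
    variance_explained: np.ndarray   # (k,) fractions of total variance
    supervised: bool = False
    meta: dict = field(default_factory=dict)
    _state: dict = field(default_factory=dict, repr=False)

    @property
    def k(self) -> int:
        return len(self.axis_variances)

    def transform(self, X) -> np.ndarray:
        """Project (already standardized) data onto the fitted components."""
        vals = _as_matrix(X).values if not isinstance(X, np.ndarray) else np.asarray(X, float)
        if vals.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.method == "KPCA":
            return self._transform_kernel(vals)
        centered = vals - self._state.get("center", 0.0)
        return centered @ self.axes.T

    def _transform_kernel(self, vals: np.ndarray) -> np.ndarray:
        st = self._state
        K = _kernel(vals, st["X_train"], st["kernel"], st["bandwidth"])
        Kc = K - st["row_means"][None, :] - K.mean(axis=1, keepdims=True) + st["grand_mean"]
        return Kc @ st["dual_coefs"]

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        def arr(a):
            return None if a is None else np.asarray(a).tolist()

        state = {
            key: (value.tolist() if isinstance(value, np.ndarray) else value)
            for key, value in self._state.items()
        }
        return {
            "method": self.method,
            "feature_names": self.feature_names,
            "axes": arr(self.axes),
            "axis_variances": arr(self.axis_variances),
            "loadings": arr(self.loadings),
            "variance_explained": arr(self.variance_explained),
            "supervised": self.supervised,
            "meta": self.meta,
            "state": state,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "ReducerModel":
        def arr(a):
            return None if a is None else np.asarray(a, dtype=float)

        state = {
            key: (np.asarray(value) if isinstance(value, list) else value)
            for key, value in payload.get("state", {}).items()
        }
        return cls(
            method=payload["method"],
            feature_names=list(payload["feature_names"]),
            axes=arr(payload["axes"]),
            axis_variances=arr(payload["axis_variances"]),
            loadings=arr(payload["loadings"]),
            variance_explained=arr(payload["variance_explained"]),
            supervised=payload.get("supervised", False),
            meta=payload.get("meta", {}),
            _state=state,
        )

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ReducerModel":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            return cls.from_dict(json.loads(source))
        with open(source) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Shared helpers
# ---------------------------------------------------------------------------


def _check_k(k: int, n: int, p: int, *, kmax: int | None = None) -> None:
    kmax = min(n - 1, p) if kmax is None else kmax
    if not (1 <= k <= kmax):
        raise ValueError(f"k must be in 1..{kmax}, got {k}")


def _total_variance(vals: np.ndarray) -> float:
    return float(np.sum(np.var(vals, axis=0, ddof=1)))


def _loadings(vals: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Pearson correlations feature × component score (zero-safe)."""
    p, k = vals.shape[1], scores.shape[1]
    out = np.zeros((p, k))
    xc = vals - vals.mean(axis=0)
    sc = scores - scores.mean(axis=0)
    xn = np.linalg.norm(xc, axis=0)
    sn = np.linalg.norm(sc, axis=0)
    for j in range(k):
        if sn[j] == 0:
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            col = (xc.T @ sc[:, j]) / (xn * sn[j])
        out[:, j] = np.nan_to_num(col)
    return out


def _orient(axes: np.ndarray, loadings: np.ndarray, scores: np.ndarray):
    """Flip each axis so its largest-|loading| feature loads positively."""
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
            if axes is not None:
                axes[j] *= -1
    return axes, loadings, scores


def _finalize_linear(
    method: str,
    fm: FeatureMatrix,
    axes: np.ndarray,
    *,
    supervised: bool,
    meta: dict | None = None,
) -> ReducerModel:
    vals = fm.values
    center = vals.mean(axis=0)
    scores = (vals - center) @ axes.T
    axis_var = np.var(scores, axis=0, ddof=1)
    total = _total_variance(vals)
    loadings = _loadings(vals, scores)
    axes, loadings, scores = _orient(axes, loadings, scores)
    return ReducerModel(
        method=method,
        feature_names=list(fm.feature_names),
        axes=axes,
        axis_variances=axis_var,
        loadings=loadings,
        variance_explained=axis_var / total,
        supervised=supervised,
        meta=meta or {},
        _state={"center": center},
    )


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def fit_pca(X, k: int) -> ReducerModel:
    """Top-k principal components via SVD of the centered data matrix."""
    fm = _as_matrix(X)
    n, p = fm.shape
    _check_k(k, n, p)
    centered = fm.values - fm.values.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return _finalize_linear("PCA", fm, vt[:k].copy(), supervised=False)


# ---------------------------------------------------------------------------
# Kernel PCA
# ---------------------------------------------------------------------------


def _kernel(A: np.ndarray, B: np.ndarray, kind: str, bandwidth: float | None) -> np.ndarray:
    if kind == "linear":
        return A @ B.T
    if kind == "rbf":
        d2 = cdist(A, B, metric="sqeuclidean")
        return np.exp(-d2 / (2.0 * bandwidth**2))
    raise ValueError(f"unknown kernel {kind!r}")


def median_bandwidth(vals: np.ndarray) -> float:
    """Median of pairwise Euclidean distances (the median heuristic)."""
    d = pdist(vals)
    med = float(np.median(d[d > 0])) if np.any(d > 0) else 1.0
    return med


def fit_kpca(
    X,
    k: int,
    *,
    kernel: str = "rbf",
    bandwidth: float | None = None,
    jitter: float = 1e-10,
) -> ReducerModel:
    """Kernel PCA via eigendecomposition of the doubly-centered Gram matrix.

    ``variance_explained`` entries are kernel-eigenvalue fractions of the
    total (sum of positive eigenvalues of the centered kernel), which for
    the linear kernel coincide with PCA's variance fractions.  Eigenvalues
    that are negative beyond ``-jitter·trace`` indicate a non-PSD kernel
    and raise; smaller negatives are clipped (the jitter policy).
    """
    fm = _as_matrix(X)
    n, p = fm.shape
    _check_k(k, n, p, kmax=n - 1)
    vals = fm.values
    if kernel == "rbf" and bandwidth is None:
        bandwidth = median_bandwidth(vals)
    K = _kernel(vals, vals, kernel, bandwidth)
    ones = np.full((n, n), 1.0 / n)
    Kc = K - ones @ K - K @ ones + ones @ K @ ones
    Kc = 0.5 * (Kc + Kc.T)
    eigvals, eigvecs = eigh(Kc)
    eigvals, eigvecs = eigvals[::-1], eigvecs[:, ::-1]
    trace = float(np.sum(np.abs(eigvals)))
    if trace > 0 and eigvals.min() < -1e-6 * trace - jitter:
        raise np.linalg.LinAlgError(
            f"centered kernel is not PSD (min eigenvalue {eigvals.min():.3e})"
        )
    eigvals = np.clip(eigvals, 0.0, None)
    if eigvals[k - 1] <= 0:
        raise ValueError(f"kernel has fewer than k={k} positive components")
    total = float(eigvals.sum())
    lam = eigvals[:k]
    alphas = eigvecs[:, :k]
    # Dual coefficients normalized so that transform(train) has variance lam/n.
    dual = alphas / np.sqrt(lam)[None, :]
    scores = Kc @ dual  # = alphas * sqrt(lam)
    loadings = _loadings(vals, scores)
    # Orientation: flip dual coefficients together with loadings/scores.
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
            dual[:, j] *= -1
    return ReducerModel(
        method="KPCA",
        feature_names=list(fm.feature_names),
        axes=None,  # feature-space pre-images unavailable
        axis_variances=lam / (n - 1),
        loadings=loadings,
        variance_explained=lam / total,
        supervised=False,
        meta={"kernel": kernel, "bandwidth": bandwidth},
        _state={
            "X_train": vals,
            "kernel": kernel,
            "bandwidth": bandwidth,
            "row_means": K.mean(axis=0),
            "grand_mean": float(K.mean()),
            "dual_coefs": dual,
        },
    )


# ---------------------------------------------------------------------------
# Gradient (Hebbian) PCA
# ---------------------------------------------------------------------------


def _oja_axis(
    Xd: np.ndarray,
    rng: np.random.Generator,
    *,
    eta0: float,
    eta_min: float,
    stage_epochs: int,
    tol_factor: float,
) -> tuple[np.ndarray, bool, int]:
    """One principal axis of ``Xd`` by per-sample Oja updates.

    w ← w + η x (xᵀw), renormalized after every update.  The step size is
    annealed in stages: within a stage η is constant and the stage ends
    when the per-epoch angular drift of w falls below ``tol_factor·η²``
    (the stochastic noise floor at that step size) or after
    ``stage_epochs`` epochs; η is then halved, down to ``eta_min``.  The
    axis counts as converged when every stage hit its drift criterion.
    """
    n, p = Xd.shape
    w = rng.normal(size=p)
    w /= np.linalg.norm(w)
    eta = eta0
    epochs = 0
    stage_converged = False
    while eta > eta_min:
        stage_converged = False
        for _ in range(stage_epochs):
            w_prev = w.copy()
            for i in rng.permutation(n):
                x = Xd[i]
                w += eta * x * (x @ w)
                w /= np.linalg.norm(w)
            epochs += 1
            if 1.0 - abs(w @ w_prev) < tol_factor * eta**2:
                stage_converged = True
                break
        eta *= 0.5
    # convergence is judged at the final (smallest-step) stage, where the
    # noise floor is negligible and residual drift means a true transient
    return w, stage_converged, epochs


def fit_gpca(
    X,
    k: int,
    *,
    seed: int = 0,
    eta0: float = 0.1,
    eta_min: float = 1e-8,
    stage_epochs: int = 80,
    tol_factor: float = 1e-4,
) -> ReducerModel:
    """PCA axes estimated by stochastic gradient (Oja) ascent with deflation.

    Components are extracted one at a time; after each axis the data are
    deflated (projected onto the orthogonal complement) and the next axis is
    estimated on the residual.  Axes are re-orthonormalized exactly at the
    end.  On well-conditioned data the converged axes agree with exact PCA
    to a fraction of a degree.  Non-convergence is flagged in
    ``meta['converged']`` rather than raised — the model is still returned
    with diagnostics.
    """
    fm = _as_matrix(X)
    n, p = fm.shape
    _check_k(k, n, p)
    rng = np.random.default_rng(seed)
    centered = fm.values - fm.values.mean(axis=0)
    Xd = centered.copy()
    axes = np.zeros((k, p))
    converged_flags, epochs_used = [], []
    for j in range(k):
        w, conv, ep = _oja_axis(
            Xd, rng, eta0=eta0, eta_min=eta_min,
            stage_epochs=stage_epochs, tol_factor=tol_factor,
        )
        # exact re-orthonormalization against previously extracted axes
        for i in range(j):
            w -= (w @ axes[i]) * axes[i]
        w /= np.linalg.norm(w)
        axes[j] = w
        Xd = Xd - np.outer(Xd @ w, w)
        converged_flags.append(bool(conv))
        epochs_used.append(int(ep))
    meta = {
        "optimizer": "oja-sgd-annealed",
        "seed": seed,
        "eta0": eta0,
        "eta_min": eta_min,
        "stage_epochs": stage_epochs,
        "tol_factor": tol_factor,
        "converged": all(converged_flags),
        "converged_per_axis": converged_flags,
        "epochs_per_axis": epochs_used,
    }
    if not all(converged_flags):
        warnings.warn(
            f"GPCA convergence criterion missed on axes "
            f"{[i for i, c in enumerate(converged_flags) if not c]}",
            stacklevel=2,
        )
    return _finalize_linear("GPCA", fm, axes, supervised=False, meta=meta)


# ---------------------------------------------------------------------------
# Centroid-class PCA and the LDA hybrid
# ---------------------------------------------------------------------------


def _class_stats(vals: np.ndarray, labels: np.ndarray):
    classes = np.unique(labels)
    centroids = np.stack([vals[labels == c].mean(axis=0) for c in classes])
    counts = np.array([int(np.sum(labels == c)) for c in classes])
    return classes, centroids, counts


def _complement_pca(centered: np.ndarray, basis: np.ndarray, m: int) -> np.ndarray:
    """Top-m PCA axes of the data projected out of ``basis`` (q × p)."""
    if m <= 0:
        return np.zeros((0, centered.shape[1]))
    resid = centered - (centered @ basis.T) @ basis
    _, s, vt = np.linalg.svd(resid, full_matrices=False)
    return vt[:m]


def fit_ccpca(X, labels=None, k: int = 2) -> ReducerModel:
    """Centroid-class PCA (see module docstring for the construction).

    With ``K`` classes the first up-to-``K−1`` axes are the orthonormalized
    class-centroid offsets from the grand mean, ordered by projected
    variance; the remaining axes are PCA in the orthogonal complement.
    Degenerate cases: a single class reduces exactly to PCA; coincident
    centroids fall back to PCA with a warning.
    """
    fm = _as_matrix(X, labels)
    if fm.labels is None:
        raise ValueError("fit_ccpca requires labels")
    n, p = fm.shape
    _check_k(k, n, p)
    vals = fm.values
    classes, centroids, counts = _class_stats(vals, fm.labels)
    if len(classes) == 1:
        model = fit_pca(fm, k)
        model.method = "CCPCA"
        model.supervised = True
        model.meta.update(n_class_axes=0, fallback="single_class")
        return model
    if np.any(counts < 2):
        small = [c for c, m in zip(classes, counts) if m < 2]
        raise ValueError(f"class(es) {small} have fewer than 2 members")
    grand = vals.mean(axis=0)
    offsets = centroids - grand
    # Orthonormal basis of the centroid-offset span (rank ≤ K-1).
    q_full, r = np.linalg.qr(offsets.T)
    rank = int(np.sum(np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())))
    if rank == 0:
        warnings.warn("class centroids coincide; falling back to plain PCA", stacklevel=2)
        model = fit_pca(fm, k)
        model.method = "CCPCA"
        model.supervised = True
        model.meta.update(n_class_axes=0, fallback="coincident_centroids")
        return model
    class_axes = q_full[:, :rank].T  # (q, p)
    centered = vals - grand
    # Order class axes by projected variance, descending.
    proj_var = np.var(centered @ class_axes.T, axis=0, ddof=1)
    class_axes = class_axes[np.argsort(proj_var)[::-1]]
    q = min(rank, k)
    comp_axes = _complement_pca(centered, class_axes, k - q)
    axes = np.vstack([class_axes[:q], comp_axes])
    return _finalize_linear(
        "CCPCA",
        fm,
        axes,
        supervised=True,
        meta={"n_class_axes": int(q), "classes": classes.tolist()},
    )


def fit_lda_hybrid(X, labels=None, k: int = 2, *, ridge: float = 0.0) -> ReducerModel:
    """Fisher discriminant axis + complement PCA.

    Axis 1 solves S_w w = (μ₁ − μ₀); a ridge is added automatically (and
    logged in ``meta``) when the pooled within-class scatter is singular.
    """
    fm = _as_matrix(X, labels)
    if fm.labels is None:
        raise ValueError("fit_lda_hybrid requires labels")
    n, p = fm.shape
    _check_k(k, n, p)
    vals = fm.values
    classes, centroids, counts = _class_stats(vals, fm.labels)
    if len(classes) != 2:
        raise ValueError(f"fit_lda_hybrid requires exactly 2 classes, got {len(classes)}")
    if np.any(counts < 2):
        raise ValueError("each class needs at least 2 members")
    sw = np.zeros((p, p))
    for c, mu in zip(classes, centroids):
        d = vals[fm.labels == c] - mu
        sw += d.T @ d
    sw /= n - 2
    diff = centroids[1] - centroids[0]
    used_ridge = ridge
    if used_ridge == 0.0 and (
        np.linalg.cond(sw) > 1e10 or not np.all(np.isfinite(np.linalg.cond(sw)))
    ):
        used_ridge = 1e-8 * np.trace(sw) / p
    try:
        w = np.linalg.solve(sw + used_ridge * np.eye(p), diff)
    except np.linalg.LinAlgError:
        used_ridge = max(used_ridge, 1e-6 * np.trace(sw) / p)
        w = np.linalg.solve(sw + used_ridge * np.eye(p), diff)
    w /= np.linalg.norm(w)
    centered = vals - vals.mean(axis=0)
    comp_axes = _complement_pca(centered, w[None, :], k - 1)
    axes = np.vstack([w[None, :], comp_axes])
    return _finalize_linear(
        "LDA_hybrid",
        fm,
        axes,
        supervised=True,
        meta={"n_class_axes": 1, "ridge": float(used_ridge), "classes": classes.tolist()},
    )


# ---------------------------------------------------------------------------
# Variance reporting, ranking, assignment
# ---------------------------------------------------------------------------


def variance_explained_k(model: ReducerModel, k: int) -> float:
    """Percent of total variance explained by the first ``k`` components."""
    if not (1 <= k <= model.k):
        raise ValueError(f"k must be in 1..{model.k}, got {k}")
    return round(100.0 * float(np.sum(model.variance_explained[:k])), 2)


def rank_discriminant_power(model: ReducerModel):
    """Rank features by loading-weighted contribution to the components.

    Each feature scores Σᵢ |loadingᵢ| · variance_explainedᵢ, accumulated
    separately over the class-oriented components and over the remaining
    components.  Ranking is lexicographic — class-oriented score first,
    residual score second, feature name as a deterministic tie-break — so
    features that carry the between-class structure always outrank features
    that merely carry variance.  Requires a supervised model.
    """
    import pandas as pd

    if not model.supervised:
        raise ValueError(
            "discriminant-power ranking needs a supervised model (CCPCA or LDA_hybrid)"
        )
    q = int(model.meta.get("n_class_axes", 0))
    absload = np.abs(model.loadings)
    ve = model.variance_explained
    class_score = absload[:, :q] @ ve[:q] if q else np.zeros(len(model.feature_names))
    resid_score = absload[:, q:] @ ve[q:] if model.k > q else np.zeros_like(class_score)
    df = pd.DataFrame(
        {
            "feature": model.feature_names,
            "class_score": class_score,
            "residual_score": resid_score,
        }
    )
    df = df.sort_values(
        by=["class_score", "residual_score", "feature"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    df.index = df.index + 1
    df.index.name = "rank"
    return df


@dataclass
class FeatureAssignment:
    """Component → features whose |loading| strictly exceeds the threshold."""

    assignments: dict[int, list[str]]
    threshold: float

    def all_features(self) -> list[str]:
        seen: list[str] = []
        for feats in self.assignments.values():
            for f in feats:
                if f not in seen:
                    seen.append(f)
        return seen


def assign_features(model: ReducerModel, threshold: float = 0.7) -> FeatureAssignment:
    """Assign each feature to at most one component by loading threshold.

    A feature qualifies for a component when |loading| > threshold
    (strictly); a feature qualifying for several components is claimed only
    by the component where its |loading| is maximal (ties go to the
    earlier component).
    """
    absload = np.abs(model.loadings)
    assignments: dict[int, list[str]] = {j: [] for j in range(model.k)}
    for i, name in enumerate(model.feature_names):
        qualifying = np.flatnonzero(absload[i] > threshold)
        if qualifying.size == 0:
            continue
        best = int(qualifying[np.argmax(absload[i, qualifying])])
        assignments[best].append(name)
    return FeatureAssignment(assignments=assignments, threshold=threshold)
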