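"""Multivariate chemical profiling of sample x feature intensity matrices.

The workflow mirrors standard untargeted-metabolomics practice: Pareto
scaling of the intensity matrix, unsupervised PCA with cumulative fitted
variance (R2) and leave-one-out predictive ability (Q2), supervised
(sparse) PLS-DA with variable-importance-in-projection (VIP) scores,
hierarchical cluster analysis of the samples, and an ANOVA-selected
heatmap of the most group-discriminating features.

Estimators follow the scikit-learn API (``fit`` / ``transform`` /
``get_params``); module-level functions are thin wrappers over them.
All fitting is deterministic: PCA/PLS component signs follow the
largest-|loading|-positive convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .peaks import FeatureMatrix

__all__ = [
    "ParetoScaler",
    "PrincipalComponentModel",
    "PLSDiscriminantAnalysis",
    "HCATree",
    "HeatmapData",
    "pareto_scale",
    "fit_pca",
    "q2_crossval",
    "fit_plsda",
    "vip_scores",
    "hca",
    "top_features_anova",
    "fisher_lsd",
    "heatmap_data",
    "impute_missing",
]


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, FeatureMatrix):
        return X.values.astype(float)
    if isinstance(X, pd.DataFrame):
        return X.astype(float)
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D samples x features matrix")
    return pd.DataFrame(arr)


def impute_missing(X) -> pd.DataFrame:
    """Replace NaN/zero-missing entries by half the minimum positive value.

    Common metabolomics practice for left-censored missingness ahead of
    log-free scaling; a no-op when the matrix has no missing entries.
    """
    df = _as_frame(X).copy()
    arr = df.to_numpy()
    pos = arr[np.isfinite(arr) & (arr > 0)]
    fill = 0.5 * pos.min() if pos.size else 0.0
    df = df.fillna(fill)
    return df


class ParetoScaler(TransformerMixin, BaseEstimator):
    """Mean-center and divide each feature by the square root of its s.d.

    Pareto scaling damps the dominance of high-intensity features without
    inflating near-constant ones as much as unit-variance scaling would.
    Standard deviations use ddof=1.  Zero-variance features are mapped to
    all-zero columns and flagged in ``zero_variance_mask_``.
    """

    def fit(self, X, y=None):
        df = _as_frame(X)
        if df.shape[0] < 2:
            raise ValueError("Pareto scaling needs at least 2 samples")
        self.feature_names_in_ = np.asarray(df.columns, dtype=object)
        self.mean_ = df.mean(axis=0).to_numpy()
        sd = df.std(axis=0, ddof=1).to_numpy()
        self.zero_variance_mask_ = sd == 0
        with np.errstate(invalid="ignore"):
            self.scale_ = np.sqrt(sd)
        self.scale_[self.zero_variance_mask_] = 1.0
        self.n_features_in_ = df.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "scale_")
        df = _as_frame(X)
        out = (df - self.mean_) / self.scale_
        out.loc[:, self.zero_variance_mask_] = 0.0
        return out


def pareto_scale(matrix) -> pd.DataFrame:
    """Fit-and-apply Pareto scaling (see :class:`ParetoScaler`)."""
    return ParetoScaler().fit_transform(matrix)


def _fix_signs(loadings: np.ndarray, *covectors: np.ndarray) -> tuple[np.ndarray, ...]:
    """Flip component signs so the largest-|value| loading entry is positive."""
    loadings = loadings.copy()
    covectors = tuple(c.copy() for c in covectors)
    for a in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, a])))
        if loadings[j, a] < 0:
            loadings[:, a] *= -1
            for c in covectors:
                c[:, a] *= -1
    return (loadings, *covectors)


class PrincipalComponentModel(BaseEstimator):
    """PCA via SVD with explained-variance (R2) and LOO-Q2 diagnostics.

    Fitted attributes
    -----------------
    scores_ : (n_samples, n_components) component scores
    loadings_ : (n_features, n_components) orthonormal loadings
    explained_variance_pct_ : per-component % of total variance
    r2_cum_ : cumulative fitted-variance fraction per component
    q2_cum_ : cumulative leave-one-out predictive ability, set by
        :meth:`crossval_q2` (or by ``fit`` when ``compute_q2=True``)
    """

    def __init__(self, n_components: int = 2, compute_q2: bool = False):
        self.n_components = n_components
        self.compute_q2 = compute_q2

    def fit(self, X, y=None):
        df = _as_frame(X)
        n, p = df.shape
        max_rank = min(n - 1, p)
        if self.n_components > max_rank:
            raise ValueError(
                f"n_components={self.n_components} exceeds max rank {max_rank}"
            )
        arr = df.to_numpy()
        self.mean_ = arr.mean(axis=0)
        xc = arr - self.mean_
        if not np.any(xc):
            raise ValueError("matrix is constant (all-zero after centering)")
        u, s, vt = np.linalg.svd(xc, full_matrices=False)
        k = self.n_components
        self.loadings_ = vt[:k].T
        self.scores_ = u[:, :k] * s[:k]
        self.loadings_, self.scores_ = _fix_signs(self.loadings_, self.scores_)
        total_var = float((s**2).sum())
        self.singular_values_ = s[:k]
        self.explained_variance_pct_ = 100.0 * (s[:k] ** 2) / total_var
        self.r2_cum_ = np.cumsum(self.explained_variance_pct_) / 100.0
        self.feature_names_in_ = np.asarray(df.columns, dtype=object)
        self.sample_ids_ = np.asarray(df.index, dtype=object)
        self.n_features_in_ = p
        if self.compute_q2:
            self.crossval_q2(df)
        return self

    def transform(self, X):
        check_is_fitted(self, "loadings_")
        return (_as_frame(X).to_numpy() - self.mean_) @ self.loadings_

    def crossval_q2(self, X) -> np.ndarray:
        """Leave-one-out Q2 per cumulative component count.

        Each sample is held out in turn; a PCA refit on the remainder
        predicts it by projection onto the refit loadings.  Q2_a =
        1 - PRESS_a / TSS with TSS the total centered sum of squares of
        the held-out samples.
        """
        check_is_fitted(self, "loadings_")
        df = _as_frame(X)
        n = df.shape[0]
        if n < 3:
            raise ValueError("leave-one-out Q2 needs at least 3 samples")
        k = self.n_components
        if k > min(n - 2, df.shape[1]):
            raise ValueError(f"n_components={k} exceeds leave-one-out refit rank")
        arr = df.to_numpy()
        press = np.zeros(k)
        tss = 0.0
        for i in range(n):
            train = np.delete(arr, i, axis=0)
            mu = train.mean(axis=0)
            xc = train - mu
            _, _, vt = np.linalg.svd(xc, full_matrices=False)
            held = arr[i] - mu
            tss += float(held @ held)
            for a in range(1, k + 1):
                v = vt[:a].T
                resid = held - (held @ v) @ v.T
                press[a - 1] += float(resid @ resid)
        self.q2_cum_ = 1.0 - press / tss
        return self.q2_cum_


def fit_pca(scaled, n_components: int) -> PrincipalComponentModel:
    """Fit a :class:`PrincipalComponentModel` on an (already scaled) matrix."""
    return PrincipalComponentModel(n_components=n_components).fit(scaled)


def q2_crossval(scaled, n_components: int) -> np.ndarray:
    """Leave-one-out Q2 for 1..n_components PCA components."""
    model = PrincipalComponentModel(n_components=n_components).fit(scaled)
    return model.crossval_q2(scaled)


class PLSDiscriminantAnalysis(ClassifierMixin, BaseEstimator):
    """(Sparse) PLS-DA via NIPALS on a one-hot class response.

    Latent components are extracted iteratively with deflation of both
    blocks.  When ``keep_per_component`` is set, each X-weight vector is
    truncated to its largest-|w| entries before the scores are formed
    (the sparse variant); by default all features are kept (plain PLS-DA).

    Fitted attributes include ``x_weights_``, ``x_scores_``,
    ``x_loadings_``, ``y_loadings_``, ``explained_variance_pct_`` (on the
    feature block), ``y_variance_explained_`` (per-component explained
    class variance, the VIP weights), ``vip_`` and ``selected_features_``.
    """

    def __init__(
        self,
        n_components: int = 2,
        keep_per_component: int | None = None,
        max_iter: int = 500,
        tol: float = 1e-10,
    ):
        self.n_components = n_components
        self.keep_per_component = keep_per_component
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y):
        df = _as_frame(X)
        n, p = df.shape
        y = np.asarray(y)
        if y.shape[0] != n:
            raise ValueError("label length must match sample count")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("PLS-DA needs at least 2 classes")
        counts = np.bincount(y_idx)
        if (counts == 1).any():
            warnings.warn(
                "some classes have a single sample; leave-one-out validation "
                "downstream will be unreliable",
                stacklevel=2,
            )
        if self.n_components > n - 1:
            raise ValueError("n_components must be <= n_samples - 1")

        Y = np.zeros((n, len(self.classes_)))
        Y[np.arange(n), y_idx] = 1.0
        arr = df.to_numpy()
        self.x_mean_ = arr.mean(axis=0)
        self.y_mean_ = Y.mean(axis=0)
        Xd = arr - self.x_mean_
        Yd = Y - self.y_mean_
        ssx_total = float((Xd**2).sum())
        ssy_total = float((Yd**2).sum())

        W, T, P, Q = [], [], [], []
        ssx, ssy = [], []
        selected: list[np.ndarray] = []
        for _ in range(self.n_components):
            w, t, q = self._nipals_component(Xd, Yd)
            tt = float(t @ t)
            if tt <= 0:
                break
            pvec = Xd.T @ t / tt
            W.append(w)
            T.append(t)
            P.append(pvec)
            Q.append(q)
            selected.append(np.flatnonzero(w))
            ssx.append(tt * float(pvec @ pvec))
            ssy.append(tt * float(q @ q))
            Xd = Xd - np.outer(t, pvec)
            Yd = Yd - np.outer(t, q)

        self.x_weights_ = np.column_stack(W)
        self.x_scores_ = np.column_stack(T)
        self.x_loadings_ = np.column_stack(P)
        self.y_loadings_ = np.column_stack(Q)
        (self.x_weights_, self.x_scores_, self.x_loadings_, self.y_loadings_) = _fix_signs(
            self.x_weights_, self.x_scores_, self.x_loadings_, self.y_loadings_
        )
        self.explained_variance_pct_ = 100.0 * np.asarray(ssx) / ssx_total
        self.y_variance_explained_ = np.asarray(ssy) / ssy_total
        self.selected_features_ = selected
        self.feature_names_in_ = np.asarray(df.columns, dtype=object)
        self.n_features_in_ = p
        self.vip_ = self._vip()
        # regression coefficients for prediction
        pw = self.x_loadings_.T @ self.x_weights_
        self.coef_ = self.x_weights_ @ np.linalg.solve(pw, self.y_loadings_.T)
        return self

    def _nipals_component(self, Xd, Yd):
        # start from the Y column with the largest residual variance
        u = Yd[:, int(np.argmax(Yd.var(axis=0)))].copy()
        if not np.any(u):
            u = Yd[:, 0].copy()
        t_old = None
        w = np.zeros(Xd.shape[1])
        t = np.zeros(Xd.shape[0])
        q = np.zeros(Yd.shape[1])
        for _ in range(self.max_iter):
            w = Xd.T @ u
            norm = np.linalg.norm(w)
            if norm == 0:
                break
            w = w / norm
            if self.keep_per_component is not None and self.keep_per_component < w.size:
                keep = np.argsort(np.abs(w))[::-1][: self.keep_per_component]
                mask = np.zeros_like(w, dtype=bool)
                mask[keep] = True
                w = np.where(mask, w, 0.0)
                w = w / np.linalg.norm(w)
            t = Xd @ w
            tt = float(t @ t)
            if tt == 0:
                break
            q = Yd.T @ t / tt
            qq = float(q @ q)
            if qq == 0:
                break
            u = Yd @ q / qq
            if t_old is not None and float((t - t_old) @ (t - t_old)) < self.tol * tt:
                break
            t_old = t.copy()
        return w, t, q

    def _vip(self) -> np.ndarray:
        """VIP_j = sqrt(p * sum_a SSY_a w_ja^2 / sum_a SSY_a)."""
        w2 = self.x_weights_**2
        ssy = self.y_variance_explained_
        p = self.n_features_in_
        denom = float(ssy.sum())
        if denom == 0:
            return np.zeros(p)
        return np.sqrt(p * (w2 @ ssy) / denom)

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        return (_as_frame(X).to_numpy() - self.x_mean_) @ self.coef_ + self.y_mean_

    def predict(self, X):
        scores = self.decision_function(X)
        return self.classes_[np.argmax(scores, axis=1)]

    def transform(self, X):
        check_is_fitted(self, "x_weights_")
        # scores for new samples via the weight rotation
        pw = self.x_loadings_.T @ self.x_weights_
        rot = self.x_weights_ @ np.linalg.inv(pw)
        return (_as_frame(X).to_numpy() - self.x_mean_) @ rot


def fit_plsda(
    scaled, labels, n_components: int = 2, keep_per_component: int | None = None
) -> PLSDiscriminantAnalysis:
    """Fit a :class:`PLSDiscriminantAnalysis` on a scaled matrix."""
    return PLSDiscriminantAnalysis(
        n_components=n_components, keep_per_component=keep_per_component
    ).fit(scaled, labels)


def vip_scores(model: PLSDiscriminantAnalysis) -> pd.Series:
    """Per-feature VIP scores of a fitted PLS-DA model (mean VIP^2 = 1)."""
    check_is_fitted(model, "vip_")
    return pd.Series(model.vip_, index=model.feature_names_in_, name="VIP")


@dataclass
class HCATree:
    """Agglomerative clustering result over the samples (or features)."""

    merges: np.ndarray  # scipy linkage matrix, (n-1, 4)
    leaf_order: list[int]
    labels: list[str]
    metric: str
    linkage: str

    @property
    def ordered_labels(self) -> list[str]:
        return [self.labels[i] for i in self.leaf_order]

    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def to_newick(self) -> str:
        """Dendrogram as a Newick string with merge heights as branch lengths."""
        n = len(self.labels)
        node: dict[int, str] = {}
        height: dict[int, float] = {i: 0.0 for i in range(n)}
        for k, (a, b, h, _) in enumerate(self.merges):
            a, b = int(a), int(b)
            la = node.get(a, self.labels[a] if a < n else "")
            lb = node.get(b, self.labels[b] if b < n else "")
            ba = h - height[a]
            bb = h - height[b]
            node[n + k] = f"({la}:{ba:.6g},{lb}:{bb:.6g})"
            height[n + k] = h
        return node[n + len(self.merges) - 1] + ";" if len(self.merges) else f"({self.labels[0]});"


def hca(matrix, metric: str = "euclidean", linkage: str = "ward") -> HCATree:
    """Hierarchical cluster analysis of the samples of a (scaled) matrix."""
    df = _as_frame(matrix)
    if df.isna().any().any():
        raise ValueError("matrix contains NaN; impute before clustering")
    if df.shape[0] < 2:
        raise ValueError("clustering needs at least 2 samples")
    if linkage not in ("ward", "average", "complete", "single"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    dist = pdist(df.to_numpy(), metric=metric)
    Z = sch.linkage(dist, method=linkage)
    order = sch.leaves_list(Z).tolist()
    return HCATree(
        merges=Z,
        leaf_order=order,
        labels=[str(i) for i in df.index],
        metric=metric,
        linkage=linkage,
    )


def top_features_anova(matrix, labels, n: int) -> pd.DataFrame:
    """Rank features by one-way ANOVA across groups and return the top ``n``.

    Returns a DataFrame indexed by feature id with columns ``F`` and ``p``,
    sorted by p ascending (ties by F descending).  When any group has
    fewer than 2 samples the F test is undefined and ranking falls back to
    between-sample variance, with a warning.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    df = _as_frame(matrix)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    counts = {g: int((labels == g).sum()) for g in groups}
    if len(groups) < 2 or min(counts.values()) < 2:
        warnings.warn(
            "ANOVA undefined (need >=2 groups with >=2 samples each); "
            "falling back to variance ranking",
            stacklevel=2,
        )
        var = df.var(axis=0, ddof=1).sort_values(ascending=False)
        out = pd.DataFrame({"F": np.nan, "p": np.nan}, index=var.index)
        return out.head(n)
    F = np.empty(df.shape[1])
    p = np.empty(df.shape[1])
    arrays_by_group = [df.to_numpy()[labels == g] for g in groups]
    for j in range(df.shape[1]):
        samples = [a[:, j] for a in arrays_by_group]
        if all(np.ptp(s) == 0 for s in samples) and len({s[0] for s in samples}) == 1:
            F[j], p[j] = 0.0, 1.0
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            F[j], p[j] = sps.f_oneway(*samples)
        if np.isnan(F[j]):
            F[j], p[j] = 0.0, 1.0
    out = pd.DataFrame({"F": F, "p": p}, index=df.columns)
    out = out.sort_values(["p", "F"], ascending=[True, False], kind="mergesort")
    return out.head(n)


def fisher_lsd(matrix, labels, feature) -> pd.DataFrame:
    """Fisher's least-significant-difference post hoc test for one feature.

    Pairwise group comparisons using the pooled within-group variance from
    the one-way ANOVA; reported alongside the ANOVA ranking, not used for
    selection.
    """
    df = _as_frame(matrix)
    labels = np.asarray(labels)
    x = df[feature].to_numpy()
    groups = np.unique(labels)
    k = len(groups)
    n = len(x)
    if n - k <= 0:
        raise ValueError("no residual degrees of freedom for LSD")
    means = {g: x[labels == g].mean() for g in groups}
    sse = sum(((x[labels == g] - means[g]) ** 2).sum() for g in groups)
    mse = sse / (n - k)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = groups[i], groups[j]
            na, nb = (labels == a).sum(), (labels == b).sum()
            se = np.sqrt(mse * (1 / na + 1 / nb))
            t = (means[a] - means[b]) / se if se > 0 else 0.0
            pval = 2 * sps.t.sf(abs(t), n - k) if se > 0 else 1.0
            rows.append({"group_a": a, "group_b": b, "diff": means[a] - means[b],
                         "t": t, "p": pval})
    return pd.DataFrame(rows)


@dataclass
class HeatmapData:
    """Top-feature z-scored matrix with HCA orderings for display."""

    values: pd.DataFrame  # features x samples, ordered
    feature_order: list[str]
    sample_order: list[str]
    feature_tree: HCATree
    sample_tree: HCATree


def heatmap_data(matrix, labels, n_top: int = 50, linkage: str = "ward") -> HeatmapData:
    """ANOVA-selected, z-scored, doubly HCA-ordered heatmap matrix.

    The matrix is restricted to the top ``n_top`` ANOVA features, each
    feature autoscaled to zero mean / unit variance for display, and both
    axes ordered by hierarchical clustering.
    """
    df = _as_frame(matrix)
    top = top_features_anova(df, labels, min(n_top, df.shape[1]))
    sub = df[top.index]
    sd = sub.std(axis=0, ddof=1).replace(0, 1.0)
    z = (sub - sub.mean(axis=0)) / sd
    sample_tree = hca(z, linkage=linkage)
    feature_tree = hca(z.T, linkage=linkage)
    sample_order = [z.index[i] for i in sample_tree.leaf_order]
    feature_order = [z.columns[i] for i in feature_tree.leaf_order]
    values = z.T.loc[feature_order, sample_order]
    return HeatmapData(
        values=values,
        feature_order=[str(f) for f in feature_order],
        sample_order=[str(s) for s in sample_order],
        feature_tree=feature_tree,
        sample_tree=sample_tree,
    )
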