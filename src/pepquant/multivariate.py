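"""Multivariate class modelling: PCA and PLS-DA with Q2, VIP and diagnostics.

Observations are LC-MS runs, variables are peptides.  Both models center the
variables and (by default) scale them to unit variance, the convention of the
chemometric software of the label-free era.  Model quality is summarised by
R2X / R2Y (fraction of predictor / response variance captured) and Q2, the
cross-validated predictive ability estimated by leaving whole observations
out fold by fold.  Per-observation diagnostics are Hotelling's T-squared
(distance within the model plane, F-referenced 95% tolerance limit) and
DModX (orthogonal distance to the model plane, chi-squared-referenced
critical limit at significance 0.05).

PLS-DA regresses the predictors on a class-indicator dummy matrix via the
iterative two-block NIPALS algorithm; the variable importance in the
projection (VIP) summarises each variable's contribution to the class
separation, with mean squared VIP equal to 1, so VIP > 1 marks influential
variables.  Jackknife (leave-one-observation-out) confidence intervals for
VIP use the standard-error form with n-1 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "CrossValidatedPCA", "PLSDA", "VipResult",
    "fit_pca", "fit_plsda", "compute_vip", "jackknife_vip",
    "group_median_transform", "hierarchical_cluster", "linkage_to_newick",
]


def _preprocess_fit(X: np.ndarray, scale: bool):
    mean = X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            raise ValueError(f"zero-variance variable(s) at index {zero.tolist()}; "
                             "unit-variance scaling undefined")
    else:
        sd = np.ones(X.shape[1])
    return mean, sd


def _fold_indices(n: int, k: int):
    """Deterministic round-robin ('venetian blinds') fold assignment."""
    return [np.arange(n)[np.arange(n) % k == f] for f in range(min(k, n))]


class CrossValidatedPCA(BaseEstimator, TransformerMixin):
    """Principal component analysis with row-wise cross-validated Q2.

    Components are extracted on the centered (and optionally unit-variance
    scaled) matrix in order of explained variance.  Attributes follow the
    scikit-learn convention; scores are ``scores_`` (n x A), loadings
    ``loadings_`` (p x A), per-component explained fraction ``r2x_``.

    Q2 per component a is 1 - PRESS_a / SS_{a-1}: per fold the model is refit
    on the training rows and held-out rows are projected component by
    component; PRESS accumulates their squared residuals.
    """

    def __init__(self, n_components: int = 2, scale: bool = True,
                 cv: int = 7, alpha_t2: float = 0.05, alpha_dmodx: float = 0.05):
        self.n_components = n_components
        self.scale = scale
        self.cv = cv
        self.alpha_t2 = alpha_t2
        self.alpha_dmodx = alpha_dmodx

    # -- core decomposition ------------------------------------------------
    @staticmethod
    def _decompose(Xc: np.ndarray, A: int):
        """Sequential rank-1 extraction via SVD; returns scores, loadings."""
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        # deterministic sign: largest-|.| loading coefficient positive
        T = U[:, :A] * s[:A]
        P = Vt[:A].T
        for a in range(A):
            j = np.argmax(np.abs(P[:, a]))
            if P[j, a] < 0:
                P[:, a] = -P[:, a]
                T[:, a] = -T[:, a]
        return T, P

    def fit(self, X, y=None):
        X = np.asarray(X, float)
        if np.isnan(X).any():
            raise ValueError("PCA requires a complete matrix; filter missing values upstream")
        n, p = X.shape
        A = self.n_components
        if A > min(n, p):
            raise ValueError(f"n_components={A} exceeds min(n, p)={min(n, p)}")
        self.mean_, self.scale_ = _preprocess_fit(X, self.scale)
        Xc = (X - self.mean_) / self.scale_
        ss_total = np.sum(Xc**2)

        T, P = self._decompose(Xc, A)
        self.scores_ = T
        self.loadings_ = P
        # eigenvalue convention: (n-1) * variance of each score vector,
        # i.e. the component sum of squares
        self.eigenvalues_ = np.sum(T**2, axis=0) / 1.0
        comp_ss = np.sum(T**2, axis=0)
        self.r2x_ = comp_ss / ss_total
        self.r2x_cum_ = np.cumsum(self.r2x_)

        # residuals and diagnostics
        resid = Xc - T @ P.T
        self.t2_ = np.sum(T**2 / np.var(T, axis=0, ddof=1), axis=1)
        if n > A:
            f = stats.f.ppf(1 - self.alpha_t2, A, n - A)
            self.t2_limit_ = A * (n - 1) / (n - A) * f
        else:
            self.t2_limit_ = np.inf
        dof = p - A
        if dof > 0 and n - A - 1 > 0:
            s_i = np.sqrt(np.sum(resid**2, axis=1) / dof)
            s0 = np.sqrt(np.sum(resid**2) / ((n - A - 1) * dof))
            # a numerically exact fit has no meaningful pooled residual scale;
            # report the (zero) absolute residual distance instead of 0/0
            self.dmodx_ = s_i / s0 if s0 > 1e-10 else s_i
            self.dmodx_crit_ = np.sqrt(stats.chi2.ppf(1 - self.alpha_dmodx, dof) / dof)
        else:
            self.dmodx_ = np.zeros(n)
            self.dmodx_crit_ = np.inf

        self.q2_, self.q2_cum_ = self._cross_validate(X, ss_total, Xc)
        self.n_features_in_ = p
        return self

    def _cross_validate(self, X, ss_total, Xc):
        n, p = X.shape
        A = self.n_components
        folds = _fold_indices(n, self.cv)
        if len(folds) < 2:
            return np.full(A, np.nan), np.full(A, np.nan)
        press = np.zeros(A)
        for held in folds:
            train = np.setdiff1d(np.arange(n), held)
            mean, sd = _preprocess_fit(X[train], self.scale)
            Xt = (X[train] - mean) / sd
            Xh = (X[held] - mean) / sd
            a_max = min(A, min(Xt.shape) )
            Tt, Pt = self._decompose(Xt, a_max)
            res = Xh.copy()
            for a in range(A):
                if a < a_max:
                    t = res @ Pt[:, a]
                    res = res - np.outer(t, Pt[:, a])
                press[a] += np.sum(res**2)
        # SS after a-1 components on the full fit
        ss_prev = np.empty(A)
        res_full = Xc.copy()
        for a in range(A):
            ss_prev[a] = np.sum(res_full**2)
            t = self.scores_[:, a]
            res_full = res_full - np.outer(t, self.loadings_[:, a])
        q2 = 1 - press / ss_prev
        q2_cum = 1 - np.cumprod(press / ss_prev)
        return q2, q2_cum

    def transform(self, X):
        check_is_fitted(self, "loadings_")
        X = np.asarray(X, float)
        return (X - self.mean_) / self.scale_ @ self.loadings_


class PLSDA(BaseEstimator, ClassifierMixin):
    """Partial least squares discriminant analysis (two-block NIPALS).

    The response is the K-column class-indicator matrix (dummy variables,
    one per class).  Components are extracted iteratively: the X-weight
    vector converges to the dominant eigenvector of X'Y Y'X.  Class
    prediction is the argmax over predicted dummy columns.
    """

    def __init__(self, n_components: int = 2, scale: bool = True, cv: int = 7,
                 max_iter: int = 500, tol: float = 1e-10):
        self.n_components = n_components
        self.scale = scale
        self.cv = cv
        self.max_iter = max_iter
        self.tol = tol

    def _encode(self, y):
        classes = np.unique(y)
        Y = (np.asarray(y)[:, None] == classes[None, :]).astype(float)
        return classes, Y

    def _nipals(self, X0, Y0, A):
        """Returns W, T, P, C on already-preprocessed blocks (deflating copies)."""
        X = X0.copy()
        Y = Y0.copy()
        n, p = X.shape
        W = np.zeros((p, A))
        T = np.zeros((n, A))
        P = np.zeros((p, A))
        C = np.zeros((Y.shape[1], A))
        for a in range(A):
            u = Y[:, np.argmax(Y.var(axis=0))]
            if np.allclose(u, 0):
                u = Y[:, 0]
            t_old = np.zeros(n)
            for _ in range(self.max_iter):
                w = X.T @ u
                norm = np.linalg.norm(w)
                if norm == 0:
                    raise ValueError("zero X-weight vector; no explainable Y variance left")
                w /= norm
                t = X @ w
                c = Y.T @ t / (t @ t)
                u = Y @ c / (c @ c)
                if np.linalg.norm(t - t_old) < self.tol * max(1.0, np.linalg.norm(t)):
                    break
                t_old = t
            # deterministic sign
            j = np.argmax(np.abs(w))
            if w[j] < 0:
                w, t, c = -w, -t, -c
            pvec = X.T @ t / (t @ t)
            X = X - np.outer(t, pvec)
            Y = Y - np.outer(t, c)
            W[:, a], T[:, a], P[:, a], C[:, a] = w, t, pvec, c
        return W, T, P, C

    def fit(self, X, y):
        X = np.asarray(X, float)
        if np.isnan(X).any():
            raise ValueError("PLS-DA requires a complete matrix")
        self.classes_, Y = self._encode(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        n, p = X.shape
        A = self.n_components
        self.mean_, self.scale_ = _preprocess_fit(X, self.scale)
        self.y_mean_ = Y.mean(axis=0)
        X0 = (X - self.mean_) / self.scale_
        Y0 = Y - self.y_mean_
        ssx = np.sum(X0**2)
        ssy = np.sum(Y0**2)

        W, T, P, C = self._nipals(X0, Y0, A)
        self.x_weights_ = W
        self.x_scores_ = T
        self.x_loadings_ = P
        self.y_loadings_ = C
        # W* = W (P'W)^-1 : weights applicable to undeflated X
        self.x_rotations_ = W @ np.linalg.inv(P.T @ W)
        self.wstarc_ = self.x_rotations_ @ C.T  # combined weight-loading map
        self.coef_ = self.x_rotations_ @ C.T

        comp_ssx = np.sum(T**2, axis=0) * np.sum(P**2, axis=0)
        comp_ssy = np.sum(T**2, axis=0) * np.sum(C**2, axis=0)
        self.r2x_ = comp_ssx / ssx
        self.r2x_cum_ = np.cumsum(self.r2x_)
        self.r2y_ = comp_ssy / ssy
        self.r2y_cum_ = np.cumsum(self.r2y_)
        self.eigenvalues_ = np.var(T, axis=0, ddof=1)
        self.ssy_explained_ = comp_ssy

        self.q2_, self.q2_cum_ = self._cross_validate(X, np.asarray(y), Y, ssy)
        self.vip_ = compute_vip(self)
        self.n_features_in_ = p
        return self

    def _cross_validate(self, X, y, Y, ssy):
        n = len(y)
        A = self.n_components
        folds = _fold_indices(n, self.cv)
        if len(folds) < 2:
            return np.full(A, np.nan), np.full(A, np.nan)
        for held in folds:
            train = np.setdiff1d(np.arange(n), held)
            if len(np.unique(y[train])) < len(self.classes_):
                raise ValueError(
                    "a class disappears entirely from a cross-validation "
                    "training fold; use fewer folds or more observations")
        press = np.zeros(A)
        for held in folds:
            train = np.setdiff1d(np.arange(n), held)
            mean, sd = _preprocess_fit(X[train], self.scale)
            ymean = Y[train].mean(axis=0)
            Xt = (X[train] - mean) / sd
            Yt = Y[train] - ymean
            W, T, P, C = self._nipals(Xt, Yt, A)
            res = (X[held] - mean) / sd
            pred = np.tile(ymean, (len(held), 1))
            for a in range(A):
                t = res @ W[:, a]
                res = res - np.outer(t, P[:, a])
                pred = pred + np.outer(t, C[:, a])
                press[a] += np.sum((Y[held] - pred) ** 2)
        ss_prev = np.empty(A)
        Yres = Y - Y.mean(axis=0)
        for a in range(A):
            ss_prev[a] = np.sum(Yres**2)
            Yres = Yres - np.outer(self.x_scores_[:, a], self.y_loadings_[:, a])
        q2 = 1 - press / ss_prev
        q2_cum = 1 - np.cumprod(press / ss_prev)
        return q2, q2_cum

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, float)
        X0 = (X - self.mean_) / self.scale_
        return X0 @ self.coef_ + self.y_mean_

    def predict(self, X):
        scores = self.decision_function(X)
        return self.classes_[np.argmax(scores, axis=1)]

    def transform(self, X):
        check_is_fitted(self, "x_rotations_")
        X0 = (np.asarray(X, float) - self.mean_) / self.scale_
        return X0 @ self.x_rotations_


@dataclass
class VipResult:
    vip: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    se: np.ndarray


def compute_vip(model: PLSDA) -> np.ndarray:
    """VIP_j = sqrt(p * sum_a SSY_a (w_aj/|w_a|)^2 / sum_a SSY_a)."""
    check_is_fitted(model, "x_weights_")
    W = model.x_weights_
    ssy = model.ssy_explained_
    total = ssy.sum()
    if total <= 0:
        raise ValueError("model explains no Y variance; VIP undefined")
    p = W.shape[0]
    wnorm2 = (W / np.linalg.norm(W, axis=0)) ** 2
    return np.sqrt(p * (wnorm2 @ ssy) / total)


def jackknife_vip(X, y, n_components: int = 2, scale: bool = True,
                  alpha: float = 0.05, cv: int = 0) -> VipResult:
    """Leave-one-observation-out confidence intervals for VIP.

    Interval = point estimate +/- t(1-alpha/2, n-1) * jackknife SE, where
    SE^2 = (n-1)/n * sum_i (VIP_i - mean VIP)^2 over the n LOO refits.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    n = X.shape[0]
    if n < 3:
        raise ValueError("jackknife needs at least 3 observations")
    point = PLSDA(n_components=n_components, scale=scale, cv=0).fit(X, y).vip_
    reps = np.empty((n, X.shape[1]))
    for i in range(n):
        keep = np.delete(np.arange(n), i)
        try:
            reps[i] = PLSDA(n_components=n_components, scale=scale,
                            cv=0).fit(X[keep], y[keep]).vip_
        except Exception as exc:
            raise RuntimeError(f"jackknife refit failed leaving out observation {i}: {exc}")
    mean = reps.mean(axis=0)
    se = np.sqrt((n - 1) / n * np.sum((reps - mean) ** 2, axis=0))
    tval = stats.t.ppf(1 - alpha / 2, n - 1)
    return VipResult(vip=point, lower=point - tval * se,
                     upper=point + tval * se, se=se)


def fit_pca(X, n_components: int = 2, cv_folds: int = 7,
            scale: bool = True) -> CrossValidatedPCA:
    return CrossValidatedPCA(n_components=n_components, cv=cv_folds,
                             scale=scale).fit(np.asarray(X, float))


def fit_plsda(X, class_labels, n_components: int = 2, cv_folds: int = 7,
              scale: bool = True) -> PLSDA:
    return PLSDA(n_components=n_components, cv=cv_folds, scale=scale).fit(
        np.asarray(X, float), np.asarray(class_labels))


def group_median_transform(values: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Per peptide: group median minus overall median (Xclass - Xtot).

    ``values`` is peptides x runs; a group with no observed value for a
    peptide yields a missing entry.
    """
    groups = groups.loc[values.columns]
    xtot = values.median(axis=1, skipna=True)
    out = {}
    for g in sorted(groups.unique()):
        cols = groups.index[groups == g]
        out[g] = values[cols].median(axis=1, skipna=True) - xtot
    return pd.DataFrame(out, index=values.index)


def hierarchical_cluster(values: pd.DataFrame, axis: str = "rows"):
    """Complete-linkage agglomeration on Euclidean distances.

    Returns a scipy linkage matrix for 'rows' or 'columns', or a dict with
    both for 'both' (the two-way clustering used for heatmap displays).
    """
    if axis == "both":
        return {"rows": hierarchical_cluster(values, "rows"),
                "columns": hierarchical_cluster(values, "columns")}
    data = values.to_numpy() if axis == "rows" else values.to_numpy().T
    if np.isnan(data).any():
        raise ValueError("clustered grid must not contain missing entries")
    if data.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    return hierarchy.linkage(data, method="complete", metric="euclidean")


def linkage_to_newick(Z: np.ndarray, labels) -> str:
    """Serialize a linkage matrix as a Newick tree (branch lengths = heights)."""
    from skbio import TreeNode

    tree = TreeNode.from_linkage_matrix(Z, list(labels))
    return str(tree)
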