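"""PLS regression (SIMPLS), PCA, venetian-blinds CV, and error metrics.

The latent-variable regression is single-response SIMPLS: both the spectral
matrix and the response are mean-centered at fit time, successive weight
vectors maximise covariance with the response under orthogonality of the
loading space, and the regression vector collects the weights times the
response loadings. At full rank the predictions coincide with ordinary
least squares. The fit is fully deterministic.

Cross-validation uses venetian blinds: sample ``i`` (in acquisition order)
joins validation fold ``i mod n_splits``, so every fold interleaves early
and late process states of a kinetic series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.decomposition import PCA as _SKPCA
from sklearn.utils.validation import check_is_fitted

from .errors import InputDataError, ParameterError

__all__ = [
    "SIMPLSRegression",
    "fit_pls",
    "predict_pls",
    "VenetianBlinds",
    "venetian_blinds_cv",
    "PCAResult",
    "fit_pca",
    "EvaluationResult",
    "evaluate",
]


# ---------------------------------------------------------------------------
# evaluation metrics
# ---------------------------------------------------------------------------

@dataclass
class EvaluationResult:
    """RMSE (prediction or cross-validation) plus R² and residuals."""

    rmse: float
    r2: float
    residuals: np.ndarray
    metric: str = "rmsep"  # "rmsep" | "rmsecv" | "rmse"

    def to_dict(self) -> dict:
        return {"metric": self.metric, "rmse": self.rmse, "r2": self.r2}


def evaluate(y_true, y_pred, metric: str = "rmse") -> EvaluationResult:
    """RMSE = sqrt(mean squared residual); R² = 1 − SS_res/SS_tot."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size != y_pred.size:
        raise InputDataError("y_true and y_pred must have equal length")
    if y_true.size < 1:
        raise InputDataError("evaluation requires at least one sample")
    residuals = y_true - y_pred
    rmse = float(np.sqrt(np.mean(residuals**2)))
    ss_res = float(np.sum(residuals**2))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0.0 else float("nan"))
    return EvaluationResult(rmse=rmse, r2=r2, residuals=residuals, metric=metric)


# ---------------------------------------------------------------------------
# SIMPLS
# ---------------------------------------------------------------------------

class SIMPLSRegression(RegressorMixin, BaseEstimator):
    """Single-response PLS regression via the SIMPLS algorithm.

    Parameters
    ----------
    n_components : int
        Number of latent variables; must satisfy
        ``1 <= n_components <= min(n_samples - 1, n_channels)``.

    Attributes
    ----------
    x_weights_ : ndarray (n_channels, n_components)
        Weight vectors R mapping centered spectra to scores.
    x_loadings_ : ndarray (n_channels, n_components)
    y_loadings_ : ndarray (n_components,)
    coef_ : ndarray (n_channels,)
        Regression vector on centered data.
    x_mean_, y_mean_ : training means (the response offset is restored at
        prediction time).
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2:
            raise InputDataError("X must be a 2-D matrix")
        n, p = X.shape
        if y.size != n:
            raise InputDataError("X and y must have the same number of rows")
        a = int(self.n_components)
        if a < 1 or a > min(n - 1, p):
            raise ParameterError(
                f"n_components must lie in [1, min(n-1, p)] = [1, {min(n - 1, p)}]"
            )

        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = float(y.mean())
        Xc = X - self.x_mean_
        yc = y - self.y_mean_

        R = np.zeros((p, a))  # weights
        P = np.zeros((p, a))  # X loadings
        q = np.zeros(a)  # y loadings
        V = np.zeros((p, a))  # orthonormal basis of the loading space
        s = Xc.T @ yc  # covariance vector, deflated each round

        for i in range(a):
            r = s.copy()
            t = Xc @ r
            norm_t = np.linalg.norm(t)
            if norm_t <= np.finfo(float).eps * 100:
                raise ParameterError(
                    f"rank of the centered data exhausted at component {i + 1}; "
                    "reduce n_components"
                )
            t /= norm_t
            r /= norm_t
            pvec = Xc.T @ t
            q[i] = float(yc @ t)
            v = pvec.copy()
            if i > 0:
                v -= V[:, :i] @ (V[:, :i].T @ pvec)
            v /= np.linalg.norm(v)
            s -= v * (v @ s)
            R[:, i], P[:, i], V[:, i] = r, pvec, v

        self.x_weights_ = R
        self.x_loadings_ = P
        self.y_loadings_ = q
        self.coef_ = R @ q
        self.n_features_in_ = p
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != self.n_features_in_:
            raise InputDataError(
                f"expected {self.n_features_in_} channels, got {X.shape[-1]}"
            )
        return (X - self.x_mean_) @ self.coef_ + self.y_mean_

    # ---- persistence ----------------------------------------------------
    def to_dict(self) -> dict:
        check_is_fitted(self, "coef_")
        return {
            "n_components": int(self.n_components),
            "x_weights": self.x_weights_.tolist(),
            "x_loadings": self.x_loadings_.tolist(),
            "y_loadings": self.y_loadings_.tolist(),
            "coef": self.coef_.tolist(),
            "x_mean": self.x_mean_.tolist(),
            "y_mean": self.y_mean_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SIMPLSRegression":
        obj = cls(n_components=d["n_components"])
        obj.x_weights_ = np.asarray(d["x_weights"], dtype=float)
        obj.x_loadings_ = np.asarray(d["x_loadings"], dtype=float)
        obj.y_loadings_ = np.asarray(d["y_loadings"], dtype=float)
        obj.coef_ = np.asarray(d["coef"], dtype=float)
        obj.x_mean_ = np.asarray(d["x_mean"], dtype=float)
        obj.y_mean_ = float(d["y_mean"])
        obj.n_features_in_ = obj.coef_.size
        return obj


def fit_pls(X, y, n_lv: int) -> SIMPLSRegression:
    """Fit a single-response SIMPLS model with ``n_lv`` latent variables."""
    return SIMPLSRegression(n_components=n_lv).fit(X, y)


def predict_pls(model: SIMPLSRegression, X_new) -> np.ndarray:
    """Raw (unclipped) predicted mass fractions, one per row of ``X_new``."""
    return model.predict(X_new)


# ---------------------------------------------------------------------------
# venetian blinds cross-validation
# ---------------------------------------------------------------------------

class VenetianBlinds:
    """Interleaved CV splitter: sample ``i`` validates in fold ``i mod n_splits``.

    Compatible with scikit-learn's splitter protocol (``split`` /
    ``get_n_splits``).
    """

    def __init__(self, n_splits: int = 10):
        if n_splits < 2:
            raise ParameterError("venetian blinds requires n_splits >= 2")
        self.n_splits = int(n_splits)

    def get_n_splits(self, X=None, y=None, groups=None) -> int:
        return self.n_splits

    def split(self, X, y=None, groups=None):
        n = len(X)
        if n < self.n_splits:
            raise ParameterError("need at least n_splits samples")
        indices = np.arange(n)
        for fold in range(self.n_splits):
            test = indices[indices % self.n_splits == fold]
            train = indices[indices % self.n_splits != fold]
            yield train, test


def venetian_blinds_cv(X, y, n_splits: int, n_lv: int) -> EvaluationResult:
    """RMSECV from venetian-blinds CV with a fixed latent-variable count.

    Each fold's model is fitted on the remaining samples; left-out
    predictions are pooled over all folds before computing the RMSE.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    y_pred = np.empty_like(y)
    for train, test in VenetianBlinds(n_splits).split(X):
        model = SIMPLSRegression(n_components=n_lv).fit(X[train], y[train])
        y_pred[test] = model.predict(X[test])
    result = evaluate(y, y_pred, metric="rmsecv")
    return result


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    """Loadings, scores and explained-variance fractions of a PCA fit."""

    loadings: np.ndarray  # (n_pc, n_channels), orthonormal rows
    scores: np.ndarray  # (n_samples, n_pc)
    explained_variance_ratio: np.ndarray
    mean: np.ndarray

    def to_dict(self) -> dict:
        return {
            "loadings": self.loadings.tolist(),
            "scores": self.scores.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
            "mean": self.mean.tolist(),
        }


def fit_pca(X, n_pc: int) -> PCAResult:
    """PCA with components ordered by decreasing explained variance.

    Sign convention: in every loading vector the element of largest
    magnitude is made positive, so repeated fits are bit-identical.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise InputDataError("PCA requires a 2-D matrix with >= 2 rows")
    if n_pc < 1 or n_pc > min(X.shape):
        raise ParameterError(f"n_pc must lie in [1, {min(X.shape)}]")
    pca = _SKPCA(n_components=n_pc, svd_solver="full").fit(X)
    loadings = pca.components_.copy()
    scores = pca.transform(X)
    for i in range(loadings.shape[0]):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] *= -1.0
            scores[:, i] *= -1.0
    return PCAResult(
        loadings=loadings,
        scores=scores,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        mean=pca.mean_.copy(),
    )
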