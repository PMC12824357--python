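"""PLS regression from subject-level gradient maps to scalar dopaminergic
measures, with leave-one-out cross-validation and cross-condition transfer.

Predictors are the full parcel-wise gradient map (one column per parcel).
X columns and y are z-scored with statistics of the training set only;
inside leave-one-out, each fold standardizes on its own training subjects
(no leakage).  The fit is the NIPALS deflation algorithm (via
scikit-learn); predictions with fewer components than fitted use the
standard reduced-rank coefficient ``B_k = W_k (P_k' W_k)^{-1} q_k'``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.cross_decomposition import PLSRegression

from .errors import ConfigError, DegenerateDataError, ModelError, ShapeError


@dataclass(frozen=True)
class PLSModel:
    n_components: int
    x_weights: np.ndarray     # (N, k)
    x_loadings: np.ndarray    # (N, k)
    y_loadings: np.ndarray    # (1, k)
    scores: np.ndarray        # (subjects, k)
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float
    explained_y_variance: np.ndarray  # % of y variance per component (cumulative increments)
    explained_x_variance: np.ndarray  # % of X variance per component

    def coef(self, k: int | None = None) -> np.ndarray:
        """Regression coefficients (standardized space) using the first k
        components."""
        k = self.n_components if k is None else k
        if not (1 <= k <= self.n_components):
            raise ConfigError(f"k must be in 1..{self.n_components}")
        W, P, Q = self.x_weights[:, :k], self.x_loadings[:, :k], self.y_loadings[:, :k]
        return W @ np.linalg.solve(P.T @ W, Q.T[:k].reshape(k, 1)).ravel()


def _standardize_train(X: np.ndarray, y: np.ndarray):
    x_mean, x_sd = X.mean(axis=0), X.std(axis=0, ddof=0)
    x_sd = np.where(x_sd > 0, x_sd, 1.0)   # constant predictor contributes 0
    y_mean, y_sd = float(y.mean()), float(y.std(ddof=0))
    if y_sd == 0:
        raise DegenerateDataError("zero-variance target")
    return (X - x_mean) / x_sd, (y - y_mean) / y_sd, x_mean, x_sd, y_mean, y_sd


def fit_pls(X: np.ndarray, y: np.ndarray, k: int = 2) -> PLSModel:
    """Fit a k-component PLS regression of y on X (both z-scored here)."""
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n, _ = X.shape
    if len(y) != n:
        raise ShapeError("X and y disagree on the number of subjects")
    if n < k + 2:
        raise ConfigError(f"need at least k+2={k + 2} subjects, got {n}")
    Xz, yz, x_mean, x_sd, y_mean, y_sd = _standardize_train(X, y)
    rank = np.linalg.matrix_rank(Xz)
    if k > rank:
        raise ModelError(f"k={k} exceeds rank(X)={rank}")
    pls = PLSRegression(n_components=k, scale=False)
    pls.fit(Xz, yz)
    W = pls.x_weights_
    P = pls.x_loadings_
    Q = pls.y_loadings_.reshape(1, -1)
    T = pls.x_scores_

    total_x = float((Xz**2).sum())
    ex_x = 100.0 * np.array(
        [float((np.outer(T[:, j], P[:, j]) ** 2).sum()) / total_x for j in range(k)]
    )
    total_y = float((yz**2).sum())
    ex_y = np.empty(k)
    model = PLSModel(
        n_components=k, x_weights=W, x_loadings=P, y_loadings=Q, scores=T,
        x_mean=x_mean, x_sd=x_sd, y_mean=y_mean, y_sd=y_sd,
        explained_y_variance=ex_y, explained_x_variance=ex_x,
    )
    prev = 0.0
    for j in range(1, k + 1):
        fit_j = Xz @ model.coef(j)
        r2 = 100.0 * (1.0 - float(((yz - fit_j) ** 2).sum()) / total_y)
        ex_y[j - 1] = r2 - prev
        prev = r2
    return model


def predict(model: PLSModel, X: np.ndarray, k: int | None = None) -> np.ndarray:
    """Predict targets for new subjects using training standardization."""
    X = np.asarray(X, float)
    if X.shape[1] != model.x_mean.shape[0]:
        raise ShapeError(
            f"X has {X.shape[1]} parcels, model was trained on "
            f"{model.x_mean.shape[0]}"
        )
    Xz = (X - model.x_mean) / model.x_sd
    return model.y_mean + model.y_sd * (Xz @ model.coef(k))


@dataclass(frozen=True)
class CVReport:
    """Leave-one-out performance per component count."""

    k_values: np.ndarray
    rmse: np.ndarray
    r: np.ndarray
    k_opt: int
    predictions: np.ndarray  # (k_max, subjects) LOO predictions
    training_r2: float       # final model (k_opt) fit on all subjects


def loo_cv(X: np.ndarray, y: np.ndarray, k_max: int = 5) -> CVReport:
    """Leave-one-out CV over component counts 1..k_max.

    Standardization and fitting use the training fold only; the left-out
    subject is predicted for every k from a single k_max fit per fold.
    ``k_opt`` minimizes LOO RMSE with ties broken toward smaller k.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n = len(y)
    if n < 5:
        raise ConfigError(f"LOO-CV needs at least 5 subjects, got {n}")
    preds = np.empty((k_max, n))
    for i in range(n):
        tr = np.ones(n, bool)
        tr[i] = False
        model = fit_pls(X[tr], y[tr], k=k_max)
        for k in range(1, k_max + 1):
            preds[k - 1, i] = predict(model, X[i : i + 1], k=k)[0]
    rmse = np.sqrt(((preds - y) ** 2).mean(axis=1))
    r = np.array([np.corrcoef(preds[k], y)[0, 1] if preds[k].std() > 0 else 0.0
                  for k in range(k_max)])
    k_opt = int(np.argmin(rmse)) + 1   # argmin returns first (smallest k) on ties
    final = fit_pls(X, y, k=k_opt)
    Xz = (X - final.x_mean) / final.x_sd
    yz = (y - final.y_mean) / final.y_sd
    resid = yz - Xz @ final.coef()
    training_r2 = 1.0 - float((resid**2).sum()) / float((yz**2).sum())
    return CVReport(
        k_values=np.arange(1, k_max + 1), rmse=rmse, r=r, k_opt=k_opt,
        predictions=preds, training_r2=training_r2,
    )


@dataclass(frozen=True)
class TransferReport:
    predicted: np.ndarray
    r: float
    p: float


def transfer_predict(model: PLSModel, X_other: np.ndarray,
                     y_observed: np.ndarray) -> TransferReport:
    """Cross-condition transfer: predict the other condition's targets with
    a model trained on this condition (training standardization reused)."""
    y_observed = np.asarray(y_observed, float).ravel()
    pred = predict(model, X_other)
    if len(pred) != len(y_observed):
        raise ShapeError("prediction/observation length mismatch")
    r, p = stats.pearsonr(pred, y_observed)
    return TransferReport(predicted=pred, r=float(r), p=float(p))


def subject_mean_gradients(values: np.ndarray, subject_ids) -> tuple[np.ndarray, list]:
    """Average scan-level gradient maps to one row per subject (sorted by
    subject id) — the per-subject PLS predictor."""
    values = np.asarray(values, float)
    subject_ids = np.asarray([str(s) for s in subject_ids], object)
    subjects = sorted(set(subject_ids.tolist()))
    out = np.vstack([values[subject_ids == s].mean(axis=0) for s in subjects])
    return out, subjects
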