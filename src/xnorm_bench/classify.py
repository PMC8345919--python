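"""Two-group classifiers: nearest shrunken centroids and L1 logistic regression.

Nearest shrunken centroids (NSC, the "Prediction Analysis for Microarrays"
method) standardizes each marker's class-centroid deviation from the overall
centroid,

    d_ik = (xbar_ik - xbar_i) / (m_k * (s_i + s0)),   m_k = sqrt(1/n_k - 1/n),

soft-thresholds it, d'_ik = sign(d_ik) * (|d_ik| - Delta)_+, rebuilds the
shrunken centroid xbar'_ik = xbar_i + m_k * (s_i + s0) * d'_ik, and assigns a
test profile x* to the class minimizing the penalized distance

    delta_k(x*) = sum_i (x*_i - xbar'_ik)^2 / (s_i + s0)^2 - 2 log pi_k.

Here s_i is the pooled within-class standard deviation of marker i, s0 the
median of the s_i, and pi_k the empirical class priors.  The shrinkage Delta
is tuned by stratified five-fold cross-validation over an equally spaced grid
from 0 to max|d_ik|, breaking ties toward the largest (sparsest) Delta.

The L1-penalized logistic regression alternative is backed by scikit-learn's
liblinear solver; this module owns the lambda grid, the CV-tuning protocol
and the standardization, not the solver internals.  Both classifiers consume
marker-level (post-summarization) data, markers x samples.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .data_model import DataError


# ---------------------------------------------------------------------------
# nearest shrunken centroids
# ---------------------------------------------------------------------------


@dataclass
class NSCModel:
    classes: list
    overall_centroid: np.ndarray  # per marker
    centroids: np.ndarray  # markers x classes (unshrunken)
    s: np.ndarray  # pooled within-class SD per marker
    s0: float
    priors: np.ndarray
    m_k: np.ndarray
    delta: float
    marker_ids: list = field(default_factory=list)
    cv_errors: np.ndarray | None = None
    delta_grid: np.ndarray | None = None

    @property
    def d_ik(self) -> np.ndarray:
        denom = np.outer(self.s + self.s0, self.m_k)
        return (self.centroids - self.overall_centroid[:, None]) / denom

    @property
    def d_shrunk(self) -> np.ndarray:
        d = self.d_ik
        return np.sign(d) * np.maximum(np.abs(d) - self.delta, 0.0)

    @property
    def shrunken_centroids(self) -> np.ndarray:
        denom = np.outer(self.s + self.s0, self.m_k)
        return self.overall_centroid[:, None] + denom * self.d_shrunk

    @property
    def n_active(self) -> int:
        """Markers whose shrunken deviation is nonzero for some class."""
        return int(np.any(self.d_shrunk != 0.0, axis=1).sum())

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "classes": list(map(str, self.classes)),
            "overall_centroid": self.overall_centroid.tolist(),
            "centroids": self.centroids.tolist(),
            "s": self.s.tolist(),
            "s0": self.s0,
            "priors": self.priors.tolist(),
            "m_k": self.m_k.tolist(),
            "delta": self.delta,
            "marker_ids": list(map(str, self.marker_ids)),
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text


def _nsc_statistics(X: np.ndarray, y: np.ndarray, classes: list) -> dict:
    """Centroids, pooled within-class SD, s0, priors, m_k for markers x samples X."""
    n = X.shape[1]
    k = len(classes)
    centroids = np.empty((X.shape[0], k))
    n_k = np.empty(k, dtype=int)
    ss = np.zeros(X.shape[0])
    for j, cls in enumerate(classes):
        mask = y == cls
        n_k[j] = mask.sum()
        centroids[:, j] = X[:, mask].mean(axis=1)
        ss += ((X[:, mask] - centroids[:, [j]]) ** 2).sum(axis=1)
    s = np.sqrt(ss / (n - k))
    s0 = float(np.median(s))
    m_k = np.sqrt(1.0 / n_k - 1.0 / n)
    return {
        "overall": X.mean(axis=1),
        "centroids": centroids,
        "s": s,
        "s0": s0,
        "priors": n_k / n,
        "m_k": m_k,
        "n_k": n_k,
    }


def _nsc_model_at(stats: dict, delta: float, classes: list, marker_ids: list) -> NSCModel:
    return NSCModel(
        classes=classes,
        overall_centroid=stats["overall"],
        centroids=stats["centroids"],
        s=stats["s"],
        s0=stats["s0"],
        priors=stats["priors"],
        m_k=stats["m_k"],
        delta=float(delta),
        marker_ids=marker_ids,
    )


def predict_nsc(model: NSCModel, X) -> np.ndarray:
    """Assign each sample (column) to the class minimizing the discriminant.

    Ties break deterministically toward the first class in label order.
    """
    marker_ids = list(X.index) if isinstance(X, pd.DataFrame) else None
    arr = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    if arr.shape[0] != len(model.overall_centroid):
        raise DataError(
            f"marker count {arr.shape[0]} does not match model ({len(model.overall_centroid)})"
        )
    if marker_ids is not None and model.marker_ids and marker_ids != list(model.marker_ids):
        raise DataError("marker ids/order do not match the fitted model")
    sc = model.shrunken_centroids
    w = (model.s + model.s0) ** 2
    scores = np.empty((arr.shape[1], len(model.classes)))
    for j in range(len(model.classes)):
        diff = arr - sc[:, [j]]
        scores[:, j] = (diff**2 / w[:, None]).sum(axis=0) - 2.0 * np.log(model.priors[j])
    idx = np.argmin(scores, axis=1)  # argmin takes the first minimum: tie -> first class
    return np.asarray([model.classes[i] for i in idx], dtype=object)


def default_delta_grid(stats: dict, n_points: int = 30) -> np.ndarray:
    dmax = float(np.abs(
        (stats["centroids"] - stats["overall"][:, None])
        / np.outer(stats["s"] + stats["s0"], stats["m_k"])
    ).max())
    return np.linspace(0.0, dmax, n_points)


def fit_nsc(
    X,
    y,
    delta_grid: np.ndarray | None = None,
    cv_folds: int = 5,
    seed: int = 0,
    n_grid: int = 30,
) -> NSCModel:
    """Fit NSC with Delta tuned by stratified cross-validated misclassification.

    ``X`` is marker-level, markers x samples.  Ties in CV error prefer the
    largest Delta (the sparsest model).  The final model is refit on all
    training data at the chosen Delta.
    """
    marker_ids = list(X.index) if isinstance(X, pd.DataFrame) else []
    arr = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    y = np.asarray(pd.Series(y).to_numpy())
    classes = sorted(pd.unique(y).tolist())
    if len(classes) != 2:
        raise DataError(f"exactly 2 classes required, got {classes}")

    full_stats = _nsc_statistics(arr, y, classes)
    if delta_grid is None:
        delta_grid = default_delta_grid(full_stats, n_grid)
    delta_grid = np.asarray(delta_grid, dtype=float)

    counts = pd.Series(y).value_counts()
    folds = min(cv_folds, int(counts.min()))
    if folds < 2:
        raise DataError("too few samples per class for cross-validation")

    errors = np.zeros(len(delta_grid))
    for attempt in range(5):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + attempt)
        ok = True
        errors[:] = 0.0
        for tr_idx, te_idx in skf.split(arr.T, y):
            if len(np.unique(y[tr_idx])) < 2:
                ok = False
                break
            st = _nsc_statistics(arr[:, tr_idx], y[tr_idx], classes)
            for gi, delta in enumerate(delta_grid):
                m = _nsc_model_at(st, delta, classes, [])
                pred = predict_nsc(m, arr[:, te_idx])
                errors[gi] += int((pred != y[te_idx]).sum())
        if ok:
            break
    else:
        raise DataError("could not form cross-validation folds with both classes")
    errors /= len(y)

    best = np.flatnonzero(errors == errors.min())[-1]  # tie -> largest Delta
    model = _nsc_model_at(full_stats, delta_grid[best], classes, marker_ids)
    model.cv_errors = errors
    model.delta_grid = delta_grid
    return model


# ---------------------------------------------------------------------------
# L1-penalized logistic regression
# ---------------------------------------------------------------------------


@dataclass
class PenalizedLogisticModel:
    classes: list
    coef: np.ndarray
    intercept: float
    lam: float
    center: np.ndarray
    scale: np.ndarray
    marker_ids: list = field(default_factory=list)
    cv_errors: np.ndarray | None = None
    lambda_grid: np.ndarray | None = None

    @property
    def n_active(self) -> int:
        return int((self.coef != 0.0).sum())

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "classes": list(map(str, self.classes)),
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "lambda": self.lam,
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "marker_ids": list(map(str, self.marker_ids)),
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text


def default_lambda_grid(
    X: np.ndarray, y01: np.ndarray, n_points: int = 100, ratio: float = 1e-4
) -> np.ndarray:
    """Log-spaced grid from the smallest lambda zeroing all coefficients."""
    n = len(y01)
    lam_max = float(np.abs(X @ (y01 - y01.mean())).max()) / n
    lam_max = max(lam_max, 1e-6)
    return np.geomspace(lam_max, lam_max * ratio, n_points)


def _fit_l1_at(Xs: np.ndarray, y01: np.ndarray, lam: float) -> LogisticRegression | None:
    # liblinear minimizes sum(loss) + (1/C)*|beta|_1; glmnet-style lambda is per-sample
    C = 1.0 / (lam * len(y01))
    clf = LogisticRegression(
        l1_ratio=1.0, C=C, solver="liblinear", max_iter=200, tol=1e-6, random_state=0
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            clf.fit(Xs, y01)
    except ConvergenceWarning:
        warnings.warn(f"skipping lambda={lam:.4g}: solver did not converge")
        return None
    return clf


def fit_penalized_logistic(
    X,
    y,
    lambda_grid: np.ndarray | None = None,
    cv_folds: int = 5,
    seed: int = 0,
) -> PenalizedLogisticModel:
    """L1 logistic regression with lambda tuned by stratified 5-fold CV.

    Features are standardized with training means/SDs.  Ties in CV error
    prefer the largest lambda (sparsest model).  Refit on all data at the
    chosen lambda.
    """
    marker_ids = list(X.index) if isinstance(X, pd.DataFrame) else []
    arr = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    y = np.asarray(pd.Series(y).to_numpy())
    classes = sorted(pd.unique(y).tolist())
    if len(classes) != 2:
        raise DataError(f"exactly 2 classes required, got {classes}")
    y01 = (y == classes[1]).astype(float)

    center = arr.mean(axis=1)
    scale = arr.std(axis=1, ddof=0)
    scale[scale == 0.0] = 1.0
    Xs = ((arr - center[:, None]) / scale[:, None]).T  # samples x markers

    if lambda_grid is None:
        lambda_grid = default_lambda_grid(Xs.T, y01)
    lambda_grid = np.asarray(lambda_grid, dtype=float)

    counts = pd.Series(y).value_counts()
    folds = min(cv_folds, int(counts.min()))
    if folds < 2:
        raise DataError("too few samples per class for cross-validation")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)

    errors = np.full(len(lambda_grid), np.nan)
    miss = np.zeros(len(lambda_grid))
    valid = np.ones(len(lambda_grid), dtype=bool)
    for tr_idx, te_idx in skf.split(Xs, y01):
        for gi, lam in enumerate(lambda_grid):
            if not valid[gi]:
                continue
            clf = _fit_l1_at(Xs[tr_idx], y01[tr_idx], lam)
            if clf is None:
                valid[gi] = False
                continue
            pred = clf.predict(Xs[te_idx])
            miss[gi] += int((pred != y01[te_idx]).sum())
    errors[valid] = miss[valid] / len(y)
    if not valid.any():
        raise DataError("no lambda grid point converged")

    best_err = np.nanmin(errors)
    best = np.flatnonzero(errors == best_err)[0]  # grid descends: first -> largest lambda
    final = _fit_l1_at(Xs, y01, lambda_grid[best])
    if final is None:
        raise DataError("final fit did not converge at the selected lambda")
    model = PenalizedLogisticModel(
        classes=classes,
        coef=final.coef_.ravel().copy(),
        intercept=float(final.intercept_[0]),
        lam=float(lambda_grid[best]),
        center=center,
        scale=scale,
        marker_ids=marker_ids,
    )
    model.cv_errors = errors
    model.lambda_grid = lambda_grid
    return model


def predict_penalized_logistic(model: PenalizedLogisticModel, X) -> np.ndarray:
    """Predict with threshold 0.5 on the logistic probability."""
    arr = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    Xs = ((arr - model.center[:, None]) / model.scale[:, None]).T
    eta = Xs @ model.coef + model.intercept
    return np.where(eta > 0.0, model.classes[1], model.classes[0]).astype(object)


def misclassification_error(predicted, truth) -> float:
    """Proportion of mismatching labels."""
    predicted = np.asarray(pd.Series(predicted).to_numpy())
    truth = np.asarray(pd.Series(truth).to_numpy())
    if len(predicted) == 0:
        raise DataError("empty label vectors")
    if len(predicted) != len(truth):
        raise DataError("label vectors differ in length")
    return float((predicted != truth).mean())
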