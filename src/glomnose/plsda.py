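"""Partial Least Squares Discriminant Analysis (PLS2 on one-hot indicators).

Class labels are coded as one-hot indicator columns, a PLS2 regression is fit
from the (mean-centered, optionally autoscaled) predictors to the indicators,
and a sample is assigned to the class with the largest predicted score
(ties break to the lowest class index).

Each component's predictor weight vector is the dominant left singular vector
of X_res' Y_res — the direction of maximal covariance with the remaining
response — followed by the usual rank-one deflation of X.  This is the SVD
formulation of PLS2: deterministic, with no iterative convergence tolerance.
When the response residual is numerically exhausted before the requested
number of components (possible at full rank), remaining directions fall back
to the dominant principal component of the predictor residual so that the
score basis still spans the predictor column space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PLSModel",
    "ClassificationReport",
    "fit_plsda",
    "classify",
    "confusion",
    "select_ncomp",
]


@dataclass
class PLSModel:
    n_components: int
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: np.ndarray
    x_weights: np.ndarray    # predictors x A
    x_loadings: np.ndarray   # predictors x A
    y_loadings: np.ndarray   # classes x A
    coefficients: np.ndarray  # predictors x classes
    class_labels: np.ndarray

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.x_mean.size:
            raise ValueError(
                f"expected {self.x_mean.size} predictor columns, got {X.shape}")
        Xc = (X - self.x_mean) / self.x_scale
        return Xc @ self.coefficients + self.y_mean


@dataclass
class ClassificationReport:
    """Confusion counts (rows true, columns predicted), correct-classification
    rate, and per-class error rates."""

    confusion: np.ndarray
    ccr: float
    per_class_error: np.ndarray
    class_labels: np.ndarray = field(default=None)


def _one_hot(labels: np.ndarray, classes: np.ndarray) -> np.ndarray:
    return (labels[:, None] == classes[None, :]).astype(float)


def fit_plsda(X: np.ndarray, labels, n_components: int,
              autoscale: bool = False) -> PLSModel:
    """Fit a PLS2 discriminant model with ``n_components`` latent variables."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != labels.size:
        raise ValueError("X must be samples x predictors matching labels")
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("need at least two classes to fit a discriminant model")
    n, p = X.shape
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(
            f"n_components must lie in [1, {min(n - 1, p)}] for this data")
    x_mean = X.mean(axis=0)
    Xc = X - x_mean
    sd = Xc.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0).tolist()
        raise ValueError(f"zero-variance predictor columns: {bad}")
    x_scale = sd if autoscale else np.ones(p)
    Xc = Xc / x_scale
    Y = _one_hot(labels, classes)
    y_mean = Y.mean(axis=0)
    Yc = Y - y_mean

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros((classes.size, n_components))
    Xr, Yr = Xc.copy(), Yc.copy()
    x_norm0 = np.linalg.norm(Xc)
    for a in range(n_components):
        S = Xr.T @ Yr
        if np.linalg.norm(S) > 1e-12 * max(x_norm0, 1.0):
            u, _, _ = np.linalg.svd(S, full_matrices=False)
            w = u[:, 0]
        else:
            # response exhausted: keep spanning the predictor space
            _, _, vt = np.linalg.svd(Xr, full_matrices=False)
            w = vt[0]
        # deterministic sign: largest-magnitude coordinate positive
        w = w * np.sign(w[np.argmax(np.abs(w))] or 1.0)
        t = Xr @ w
        tt = t @ t
        if tt <= 1e-300:
            # predictor residual exhausted; truncate silently
            W, P, Q = W[:, :a], P[:, :a], Q[:, :a]
            n_components = a
            break
        pl = Xr.T @ t / tt
        ql = Yr.T @ t / tt
        Xr = Xr - np.outer(t, pl)
        Yr = Yr - np.outer(t, ql)
        W[:, a], P[:, a], Q[:, a] = w, pl, ql

    # B = W (P'W)^-1 Q'
    PtW = P.T @ W
    B = W @ np.linalg.solve(PtW, Q.T)
    return PLSModel(n_components, x_mean, x_scale, y_mean, W, P, Q, B,
                    classes)


def classify(model: PLSModel, X: np.ndarray) -> np.ndarray:
    """Assign each row to the class with the highest predicted indicator
    score; exact ties go to the lowest class index."""
    scores = model.predict_scores(X)
    return model.class_labels[np.argmax(scores, axis=1)]


def confusion(true_labels, predicted_labels, n_classes: int) -> ClassificationReport:
    """Count matrix, CCR = trace/total, per-class error = 1 - diag/rowsum."""
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if t.size != p.size:
        raise ValueError("label vectors differ in length")
    if t.size == 0:
        raise ValueError("empty label vectors")
    for arr, name in ((t, "true"), (p, "predicted")):
        if arr.min() < 1 or arr.max() > n_classes:
            raise ValueError(f"{name} labels must lie in [1, {n_classes}]")
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (t - 1, p - 1), 1)
    ccr = np.trace(cm) / t.size
    rowsum = cm.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_class_error = np.where(rowsum > 0, 1.0 - np.diag(cm) / rowsum, np.nan)
    return ClassificationReport(cm, float(ccr), per_class_error,
                                np.arange(1, n_classes + 1))


def _stratified_folds(labels: np.ndarray, n_folds: int, rng: np.random.Generator):
    """Fold assignment preserving class proportions."""
    fold = np.empty(labels.size, dtype=int)
    for cls in np.unique(labels):
        idx = rng.permutation(np.flatnonzero(labels == cls))
        fold[idx] = np.arange(idx.size) % n_folds
    return fold


def select_ncomp(X: np.ndarray, labels, max_components: int,
                 n_folds: int = 5, seed: int = 0,
                 autoscale: bool = False) -> int:
    """Cross-validated component count with a one-standard-error rule.

    Returns the smallest number of components whose mean CV accuracy is within
    one standard error of the best candidate.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < n_folds:
        warnings.warn(
            f"smallest class has {counts.min()} members; reducing folds",
            stacklevel=2)
        n_folds = int(counts.min())
        if n_folds < 2:
            raise ValueError("a class has fewer than 2 members; cannot cross-validate")
    rng = np.random.default_rng(seed)
    fold = _stratified_folds(labels, n_folds, rng)
    accs = np.zeros((max_components, n_folds))
    for k in range(n_folds):
        tr, te = fold != k, fold == k
        a_max = min(max_components, int(tr.sum()) - 1, X.shape[1])
        for a in range(1, max_components + 1):
            if a > a_max:
                accs[a - 1, k] = accs[a_max - 1, k]
                continue
            model = fit_plsda(X[tr], labels[tr], a, autoscale=autoscale)
            pred = classify(model, X[te])
            accs[a - 1, k] = np.mean(pred == labels[te])
    mean = accs.mean(axis=1)
    se = accs.std(axis=1, ddof=1) / np.sqrt(n_folds)
    best = int(np.argmax(mean))
    threshold = mean[best] - se[best]
    return int(np.flatnonzero(mean >= threshold)[0]) + 1
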