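"""Orthogonal projections to latent structures discriminant analysis.

OPLS-DA splits the variation of a (centered, scaled) data matrix X into a
single component predictive of a two-class response and components
orthogonal to it, following the Trygg-Wold orthogonal-signal-correction
NIPALS scheme.  For a single response column the NIPALS weight vector has
a closed form (w = X'y/||X'y||), so the fit is fully deterministic.

Model quality is summarised by R2X/R2Y (explained fractions of X and of
the class dummy) and Q2 (1 - PRESS/SS over k-fold cross-validation with
per-fold re-scaling), and validated by a label-permutation test whose
R2/Q2-vs-label-correlation regression intercepts diagnose overfitting
(a Q2 intercept below 0.05 indicates a valid model).  Variable influence
is scored by VIP over the predictive component; variables with VIP > 1
are flagged as discriminating.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scaling import pareto_scale

__all__ = [
    "OplsModel",
    "PermutationSummary",
    "fit_oplsda",
    "cross_validate",
    "permutation_test",
    "vip",
    "class_folds",
]


def _dummy(y) -> tuple[np.ndarray, dict]:
    """Centered single-column dummy coding of a two-class label vector."""
    y = np.asarray(y)
    classes = sorted(map(str, np.unique(y.astype(str))))
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, got {classes}")
    d = (np.asarray(y, dtype=str) == classes[1]).astype(float)
    return d - d.mean(), {classes[0]: 0.0, classes[1]: 1.0}


@dataclass
class OplsModel:
    """Fitted OPLS-DA model (one predictive component, two classes)."""

    w: np.ndarray                  # predictive weights, unit norm
    p: np.ndarray                  # predictive loadings
    t: np.ndarray                  # predictive scores
    c: float                       # y-loading
    W_o: np.ndarray                # (n_vars, n_orth) orthogonal weights
    P_o: np.ndarray                # orthogonal loadings
    T_o: np.ndarray                # (n_samples, n_orth) orthogonal scores
    n_orthogonal: int
    R2X_cum: float
    R2Y_cum: float
    class_map: dict
    y_mean: float                  # mean of the raw dummy (for prediction)
    Q2_cum: float | None = None
    n_predictive: int = 1
    columns: list[str] | None = None
    scaling: object = None         # optional ScalingModel reference

    def filter(self, X: np.ndarray) -> np.ndarray:
        """Remove the orthogonal variation from new (scaled) data."""
        X = np.asarray(X, dtype=float).copy()
        for a in range(self.n_orthogonal):
            t_o = X @ self.W_o[:, a]
            X -= np.outer(t_o, self.P_o[:, a])
        return X

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        return self.filter(X) @ self.w

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted dummy value (on the raw 0/1 scale)."""
        return self.predict_scores(X) * self.c + self.y_mean

    def predict_class(self, X: np.ndarray) -> np.ndarray:
        yhat = self.predict(X)
        inv = {v: k for k, v in self.class_map.items()}
        return np.array([inv[1.0] if v >= 0.5 else inv[0.0] for v in yhat])


def fit_oplsda(X, y, n_orthogonal: int = 1, columns=None,
               scaling=None) -> OplsModel:
    """Fit OPLS-DA on a centered (scaled) matrix and two-class labels.

    ``n_orthogonal`` orthogonal components are estimated and deflated from
    X by the orthogonal-projection iteration, then one predictive PLS
    component is fitted on the filtered matrix.  Requires at least three
    samples per class.
    """
    X = np.asarray(X, dtype=float)
    yd, class_map = _dummy(y)
    counts = np.unique(np.asarray(y, dtype=str), return_counts=True)[1]
    if counts.min() < 3:
        raise ValueError("each class needs at least 3 samples")
    if np.allclose(yd, 0):
        raise ValueError("constant class vector")
    ss_x = float(np.sum(X * X))
    ss_y = float(np.sum(yd * yd))
    if ss_x == 0:
        raise ValueError("X has no variation")

    Xf = X.copy()
    W_o, P_o, T_o = [], [], []
    for _ in range(n_orthogonal):
        w = Xf.T @ yd
        nw = np.linalg.norm(w)
        if nw == 0:
            raise ValueError("y is orthogonal to X; cannot extract component")
        w /= nw
        t = Xf @ w
        p = Xf.T @ t / float(t @ t)
        w_o = p - float(w @ p) * w
        n_wo = np.linalg.norm(w_o)
        if n_wo < 1e-12:
            break  # no orthogonal variation left
        w_o /= n_wo
        t_o = Xf @ w_o
        p_o = Xf.T @ t_o / float(t_o @ t_o)
        Xf = Xf - np.outer(t_o, p_o)
        W_o.append(w_o)
        P_o.append(p_o)
        T_o.append(t_o)

    w = Xf.T @ yd
    w /= np.linalg.norm(w)
    t = Xf @ w
    p = Xf.T @ t / float(t @ t)
    c = float(yd @ t / (t @ t))

    n_o = len(W_o)
    W_o = np.column_stack(W_o) if n_o else np.zeros((X.shape[1], 0))
    P_o = np.column_stack(P_o) if n_o else np.zeros((X.shape[1], 0))
    T_o = np.column_stack(T_o) if n_o else np.zeros((X.shape[0], 0))

    explained_x = float(t @ t) * float(p @ p)
    for a in range(n_o):
        explained_x += float(T_o[:, a] @ T_o[:, a]) * float(P_o[:, a] @ P_o[:, a])
    r2x = explained_x / ss_x
    r2y = (c * c) * float(t @ t) / ss_y

    d_raw = (np.asarray(y, dtype=str) ==
             sorted(class_map, key=class_map.get)[1]).astype(float)
    return OplsModel(w=w, p=p, t=t, c=c, W_o=W_o, P_o=P_o, T_o=T_o,
                     n_orthogonal=n_o, R2X_cum=r2x, R2Y_cum=r2y,
                     class_map=class_map, y_mean=float(d_raw.mean()),
                     columns=list(columns) if columns is not None else None,
                     scaling=scaling)


def class_folds(y, folds: int) -> np.ndarray:
    """Deterministic round-robin fold assignment within each class, by
    input order."""
    y = np.asarray(y, dtype=str)
    assign = np.empty(y.size, dtype=int)
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        assign[idx] = np.arange(idx.size) % folds
    return assign


def cross_validate(X, y, n_orthogonal: int = 1, folds: int = 7,
                   scaling: str = "pareto") -> float:
    """Q2 = 1 - PRESS/SS over k-fold held-out predictions.

    ``X`` is the raw (unscaled) matrix: each training fold is re-centered
    and re-scaled, and its model applied to the held-out fold.  Folds are
    assigned round-robin within class by input order, so the split is
    reproducible.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=str)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    assign = class_folds(y, folds)
    press = 0.0
    ss = 0.0
    for k in np.unique(assign):
        test = assign == k
        train = ~test
        classes, counts = np.unique(y[train], return_counts=True)
        if len(classes) < 2 or counts.min() < 3:
            raise ValueError(
                f"fold {k} leaves too few samples of one class in "
                "training; use fewer folds")
        Xtr, model_s = pareto_scale(X[train], method=scaling)
        model = fit_oplsda(Xtr, y[train], n_orthogonal=n_orthogonal)
        Xte = model_s.transform(X[test])
        d_test = (y[test] == sorted(model.class_map,
                                    key=model.class_map.get)[1]).astype(float)
        yhat = model.predict(Xte)
        press += float(np.sum((d_test - yhat) ** 2))
        ss += float(np.sum((d_test - model.y_mean) ** 2))
    return 1.0 - press / ss


@dataclass
class PermutationSummary:
    """Label-permutation diagnostics for an OPLS-DA model.

    Contains the unpermuted model at correlation 1, per-permutation
    (|corr|, R2Y, Q2) triples, the least-squares regression lines through
    all points, and their intercepts at correlation 0.
    """

    correlations: np.ndarray
    r2y: np.ndarray
    q2: np.ndarray
    R2_intercept: float
    Q2_intercept: float
    R2_slope: float
    Q2_slope: float
    n_permutations: int
    n_failed: int = 0
    original_R2Y: float = float("nan")
    original_Q2: float = float("nan")

    def empirical_p(self) -> float:
        """Fraction of permuted Q2 at least as large as the original."""
        perm = self.q2[1:]
        return float((1 + np.sum(perm >= self.original_Q2)) / (perm.size + 1))


def permutation_test(X, y, n_orthogonal: int = 1, folds: int = 7,
                     n_perm: int = 500, seed: int = 0,
                     scaling: str = "pareto") -> PermutationSummary:
    """Refit model + CV under label permutation; report R2/Q2 intercepts.

    The regression of R2Y (and Q2) on the absolute correlation between the
    permuted and original class dummy is fitted through all points
    including the unpermuted model at correlation 1; the intercepts at
    correlation 0 measure overfit.
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=str)
    rng = np.random.default_rng(seed)
    yd, _ = _dummy(y)
    denom = float(yd @ yd)

    def fit_stats(labels):
        Xs, _ = pareto_scale(X, method=scaling)
        model = fit_oplsda(Xs, labels, n_orthogonal=n_orthogonal)
        q2 = cross_validate(X, labels, n_orthogonal=n_orthogonal,
                            folds=folds, scaling=scaling)
        return model.R2Y_cum, q2

    r2_0, q2_0 = fit_stats(y)
    corrs, r2s, q2s = [1.0], [r2_0], [q2_0]
    failed = 0
    for _ in range(n_perm):
        yp = rng.permutation(y)
        dp, _ = _dummy(yp)
        corr = abs(float(dp @ yd) / denom)  # both dummies share the scale
        try:
            r2, q2 = fit_stats(yp)
        except Exception as exc:  # degenerate permutation; record and skip
            failed += 1
            warnings.warn(f"permutation refit failed: {exc}")
            continue
        corrs.append(corr)
        r2s.append(r2)
        q2s.append(q2)

    corrs = np.asarray(corrs)
    r2s = np.asarray(r2s)
    q2s = np.asarray(q2s)
    A = np.column_stack([np.ones_like(corrs), corrs])
    (b0_r2, b1_r2), *_ = np.linalg.lstsq(A, r2s, rcond=None)
    (b0_q2, b1_q2), *_ = np.linalg.lstsq(A, q2s, rcond=None)
    return PermutationSummary(correlations=corrs, r2y=r2s, q2=q2s,
                              R2_intercept=float(b0_r2),
                              Q2_intercept=float(b0_q2),
                              R2_slope=float(b1_r2), Q2_slope=float(b1_q2),
                              n_permutations=n_perm, n_failed=failed,
                              original_R2Y=r2_0, original_Q2=q2_0)


def vip(model: OplsModel) -> pd.DataFrame:
    """Variable influence on projection over the predictive component.

    With a single predictive component the standard PLS VIP reduces to
    sqrt(p_vars) * |w_j| / ||w||, so the mean squared VIP equals 1.
    Variables with VIP > 1 are flagged as discriminating.  The variant
    (predictive-component VIP, not total-model VIP) is recorded in the
    output attributes.
    """
    if model.w is None:
        raise ValueError("model is not fitted")
    p_vars = model.w.size
    scores = np.sqrt(p_vars) * np.abs(model.w) / np.linalg.norm(model.w)
    names = model.columns if model.columns is not None else \
        [f"var{j}" for j in range(p_vars)]
    out = pd.DataFrame({"vip": scores, "selected": scores > 1.0}, index=names)
    out.attrs["variant"] = "predictive-component VIP"
    return out
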