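"""Multi-metabolite logistic biomarker panels and ROC evaluation.

A panel is a logistic regression P(y=1|x) over selected metabolite
concentrations.  The module provides maximum-likelihood fitting (IRLS with
a tiny ridge for numerical stability at small n, with complete-separation
detection), ROC/AUC with a DeLong 95% CI, Monte-Carlo cross-validation
with a label-permutation guard, Youden threshold selection, and a
fixed-coefficient scorer that ships the published nine-metabolite serum
panel (intercept -61.645, decision cutoff P = 0.38, positive class =
healthy controls — the coding implied by the published coefficient signs).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "PanelModel",
    "RocCurve",
    "FixedPanel",
    "fit_logistic",
    "score_fixed_panel",
    "load_fixed_panel",
    "roc_curve",
    "auc_ci",
    "cv_and_permute",
    "youden_threshold",
]


@dataclass
class RocCurve:
    """ROC points ordered from (0,0) to (1,1), with trapezoidal AUC.

    Ties in the scores are handled through the threshold sweep so the AUC
    equals the midrank Mann-Whitney statistic U/(n1*n2) exactly.
    """

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_curve(scores, labels, positive) -> RocCurve:
    """ROC over all unique score thresholds; AUC by trapezoid."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=str)
    ybin = (labels == str(positive)).astype(int)
    if ybin.min() == ybin.max():
        raise ValueError("both classes must be present")
    fpr, tpr, thr = _sk_roc_curve(ybin, scores, drop_intermediate=False)
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr,
                    auc=float(np.trapezoid(tpr, fpr)))


def youden_threshold(curve: RocCurve) -> float:
    """Score threshold maximizing TPR - FPR (Youden's J)."""
    j = curve.tpr - curve.fpr
    return float(curve.thresholds[int(np.argmax(j))])


def _delong_variance(scores, ybin):
    """DeLong placement-value variance of the AUC (midrank form)."""
    pos = scores[ybin == 1]
    neg = scores[ybin == 0]
    m, n = pos.size, neg.size

    def placements(a, b):
        # fraction of b below each a, ties counted half
        order = np.sort(b)
        lo = np.searchsorted(order, a, side="left")
        hi = np.searchsorted(order, a, side="right")
        return (lo + hi) / (2.0 * b.size)

    v10 = placements(pos, neg)   # per-positive placement values
    v01 = 1.0 - placements(neg, pos)
    auc = v10.mean()
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return auc, s10 / m + s01 / n


def auc_ci(scores, labels, positive, level: float = 0.95,
           method: str = "delong", n_boot: int = 2000,
           seed: int = 0) -> tuple[float, float]:
    """95% CI for the AUC by DeLong variance (default) or stratified
    percentile bootstrap.  Degenerate AUC in {0, 1} falls back to the
    bootstrap with a warning."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=str)
    ybin = (labels == str(positive)).astype(int)
    if min(ybin.sum(), (1 - ybin).sum()) < 5:
        raise ValueError("need at least 5 samples per class for a CI")
    auc, var = _delong_variance(scores, ybin)
    z = stats.norm.ppf(0.5 + level / 2.0)
    if method == "delong" and 0.0 < auc < 1.0 and var > 0:
        se = np.sqrt(var)
        return (max(0.0, auc - z * se), min(1.0, auc + z * se))
    if method == "delong":
        warnings.warn("degenerate AUC; falling back to bootstrap CI")
    rng = np.random.default_rng(seed)
    pos = np.nonzero(ybin == 1)[0]
    neg = np.nonzero(ybin == 0)[0]
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate([rng.choice(pos, pos.size),
                              rng.choice(neg, neg.size)])
        a, _ = _delong_variance(scores[idx], ybin[idx])
        aucs[b] = a
    lo, hi = np.quantile(aucs, [0.5 - level / 2.0, 0.5 + level / 2.0])
    return float(lo), float(hi)


@dataclass
class PanelModel:
    """Fitted logistic biomarker panel."""

    intercept: float
    coefficients: pd.Series
    positive_class: str
    threshold: float
    auc: float
    auc_ci: tuple[float, float]
    separation: bool = False
    cv_auc: np.ndarray | None = None
    permutation_p: float | None = None

    def predict_proba(self, conc: pd.DataFrame) -> np.ndarray:
        X = conc[list(self.coefficients.index)].to_numpy(float)
        logit = self.intercept + X @ self.coefficients.to_numpy()
        return 1.0 / (1.0 + np.exp(-np.clip(logit, -700, 700)))

    def predict(self, conc: pd.DataFrame) -> np.ndarray:
        return self.predict_proba(conc) >= self.threshold


def _irls_logistic(X: np.ndarray, ybin: np.ndarray, ridge: float = 1e-8,
                   max_iter: int = 100, tol: float = 1e-10):
    """Maximum-likelihood logistic fit by IRLS with a tiny ridge.

    Returns (beta with intercept first, separation flag).  Complete
    separation is reported when every fitted probability is within 1e-6 of
    its label (the ridge keeps the coefficients finite).
    """
    n, p = X.shape
    A = np.column_stack([np.ones(n), X])
    beta = np.zeros(p + 1)
    pen = ridge * np.eye(p + 1)
    pen[0, 0] = 0.0  # do not penalize the intercept
    for _ in range(max_iter):
        eta = np.clip(A @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-12)
        z = eta + (ybin - mu) / w
        H = A.T @ (A * w[:, None]) + pen
        beta_new = np.linalg.solve(H, A.T @ (w * z))
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
    mu = 1.0 / (1.0 + np.exp(-np.clip(A @ beta, -30, 30)))
    separated = bool(np.all(np.abs(ybin - mu) < 1e-6))
    return beta, separated


def fit_logistic(conc: pd.DataFrame, labels, positive_class: str = "HC",
                 threshold: str | float = "youden",
                 ci_method: str = "delong") -> PanelModel:
    """Fit a logistic panel on the given metabolite columns.

    ``positive_class`` is the label coded y=1 (healthy controls by
    default, matching the published panel's coding).  The decision
    threshold is Youden's J on the training ROC unless a number is given.
    Raises on constant predictors, naming them.
    """
    labels = np.asarray(labels, dtype=str)
    classes = sorted(np.unique(labels))
    if len(classes) != 2:
        raise ValueError("exactly two classes required")
    if str(positive_class) not in classes:
        raise ValueError(f"positive_class {positive_class!r} not in {classes}")
    X = conc.to_numpy(float)
    if min((labels == c).sum() for c in classes) < 2:
        raise ValueError("need at least 2 samples per class")
    const = [c for c, s in zip(conc.columns, X.std(axis=0)) if s == 0]
    if const:
        raise ValueError(f"constant predictor(s): {const}")
    ybin = (labels == str(positive_class)).astype(float)
    beta, separated = _irls_logistic(X, ybin)
    if separated:
        warnings.warn("complete separation detected; coefficients are "
                      "ridge-stabilized and should be interpreted with care")
    probs = 1.0 / (1.0 + np.exp(-np.clip(
        beta[0] + X @ beta[1:], -700, 700)))
    curve = roc_curve(probs, labels, positive_class)
    counts = [(labels == c).sum() for c in classes]
    if ci_method == "none" or min(counts) < 5:
        ci = (float("nan"), float("nan"))
    else:
        ci = auc_ci(probs, labels, positive_class, method=ci_method)
    thr = youden_threshold(curve) if threshold == "youden" else float(threshold)
    thr = float(np.clip(thr, 1e-9, 1 - 1e-9))
    return PanelModel(intercept=float(beta[0]),
                      coefficients=pd.Series(beta[1:], index=conc.columns),
                      positive_class=str(positive_class), threshold=thr,
                      auc=curve.auc, auc_ci=ci, separation=separated)


@dataclass
class FixedPanel:
    """A frozen published panel: names, coefficients, intercept, cutoff."""

    name: str
    intercept: float
    coefficients: dict[str, float]
    threshold: float
    positive_class: str
    description: str = ""


def load_fixed_panel(name: str = "psa_serum") -> FixedPanel:
    """Load a shipped fixed-coefficient panel by name."""
    text = resources.files("psametab.data").joinpath(
        f"panel_{name}.json").read_text()
    d = json.loads(text)
    return FixedPanel(name=d["name"], intercept=d["intercept"],
                      coefficients=d["coefficients"], threshold=d["threshold"],
                      positive_class=d["positive_class"],
                      description=d.get("description", ""))


def score_fixed_panel(conc: pd.DataFrame, panel: FixedPanel | None = None,
                      threshold: float | None = None) -> pd.DataFrame:
    """Score samples with a fixed panel (default: the published one).

    Pure function of the inputs: P = 1/(1+exp(-(b0 + sum b_j x_j)));
    positive call when P >= threshold.  Raises listing the required
    metabolites if any column is missing.
    """
    panel = panel or load_fixed_panel()
    thr = panel.threshold if threshold is None else float(threshold)
    names = list(panel.coefficients)
    missing = [m for m in names if m not in conc.columns]
    if missing:
        raise ValueError(
            f"missing metabolite column(s) {missing}; the panel requires "
            f"exactly these metabolites: {names}")
    X = conc[names].to_numpy(float)
    beta = np.array([panel.coefficients[m] for m in names])
    logit = panel.intercept + X @ beta
    P = 1.0 / (1.0 + np.exp(-np.clip(logit, -700, 700)))
    return pd.DataFrame({"P": P, "call": np.where(P >= thr,
                                                  panel.positive_class,
                                                  "other")},
                        index=conc.index)


def cv_and_permute(conc: pd.DataFrame, labels, positive_class: str = "HC",
                   n_cv: int = 100, n_perm: int = 1000,
                   test_fraction: float = 1 / 3, seed: int = 0):
    """Monte-Carlo cross-validation plus a label-permutation guard.

    ``n_cv`` stratified random 2:1 train/test splits, held-out AUC each
    time; the permutation p is (1 + #{permuted resubstitution AUC >=
    observed}) / (n_perm + 1), refitting on permuted labels each time.
    Returns (cv_aucs, permutation_p, observed_auc).
    """
    if n_cv < 10:
        raise ValueError("n_cv must be >= 10")
    labels = np.asarray(labels, dtype=str)
    rng = np.random.default_rng(seed)
    X = conc.to_numpy(float)
    ybin = (labels == str(positive_class)).astype(float)

    def resub_auc(yb):
        beta, _ = _irls_logistic(X, yb)
        probs = beta[0] + X @ beta[1:]
        a, _ = _delong_variance(probs, yb.astype(int))
        return a

    observed = resub_auc(ybin)

    classes = np.unique(labels)
    idx_by_class = {c: np.nonzero(labels == c)[0] for c in classes}
    cv_aucs = np.empty(n_cv)
    for r in range(n_cv):
        while True:
            test = []
            for c in classes:
                idx = rng.permutation(idx_by_class[c])
                n_test = max(1, int(round(test_fraction * idx.size)))
                test.append(idx[:n_test])
            test = np.concatenate(test)
            train = np.setdiff1d(np.arange(labels.size), test)
            if len(np.unique(labels[train])) == 2 and \
                    len(np.unique(labels[test])) == 2:
                break
        beta, _ = _irls_logistic(X[train], ybin[train])
        scores = beta[0] + X[test] @ beta[1:]
        a, _ = _delong_variance(scores, ybin[test].astype(int))
        cv_aucs[r] = a

    hits = 0
    for _ in range(n_perm):
        if resub_auc(rng.permutation(ybin)) >= observed:
            hits += 1
    perm_p = (1 + hits) / (n_perm + 1)
    return cv_aucs, float(perm_p), float(observed)
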