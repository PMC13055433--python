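"""Benchmark metrics: support-recovery ROC/AUC and DA confusion metrics.

Also hosts the thin comparator adapter running the graphical lasso on
CLR-transformed data, whose sparse inverse-covariance support serves as a
(misspecified) proxy for the interaction matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import matthews_corrcoef

__all__ = [
    "RecoveryROC",
    "DAMetrics",
    "support_recovery_roc",
    "mean_roc",
    "da_metrics",
    "clr_transform",
    "clr_glasso_supports",
    "log_ttest_baseline",
]


@dataclass
class RecoveryROC:
    fpr: np.ndarray          # monotone curve points (with (0,0)/(1,1) anchors)
    tpr: np.ndarray
    auc: float
    raw_points: np.ndarray   # per-lambda (fpr, tpr) pairs, path order


@dataclass
class DAMetrics:
    fdr: float
    tpr: float
    mcc: float
    n_called: int


def _offdiag_support(K: np.ndarray, tol: float = 0.0) -> np.ndarray:
    """Upper-triangle boolean support of the symmetrized off-diagonal."""
    Ks = (K + K.T) / 2.0
    iu = np.triu_indices_from(Ks, k=1)
    return np.abs(Ks[iu]) > tol


def support_recovery_roc(path, K_true: np.ndarray) -> RecoveryROC:
    """ROC of off-diagonal support recovery along a regularization path.

    ``path`` is a FitPath or an iterable of p x p estimated matrices.  Each
    path point contributes one (FPR, TPR) pair; the curve is the monotone
    upper envelope of the sorted points with (0,0) and (1,1) anchors, and the
    AUC is its trapezoid integral.
    """
    truth = _offdiag_support(np.asarray(K_true, dtype=np.float64))
    P = int(truth.sum())
    N = int((~truth).sum())
    if P == 0 or N == 0:
        raise ValueError("true off-diagonal support must be nonempty and non-full")
    mats = [f.K_hat for f in path.fits] if hasattr(path, "fits") else list(path)
    pts = np.empty((len(mats), 2))
    for i, K in enumerate(mats):
        est = _offdiag_support(np.asarray(K, dtype=np.float64))
        tp = int(np.sum(est & truth))
        fp = int(np.sum(est & ~truth))
        pts[i] = (fp / N, tp / P)
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    fpr = np.concatenate([[0.0], pts[order, 0], [1.0]])
    tpr = np.concatenate([[0.0], np.maximum.accumulate(pts[order, 1]), [1.0]])
    auc = float(np.trapezoid(tpr, fpr))
    return RecoveryROC(fpr, tpr, auc, pts)


def mean_roc(rocs, fpr_grid=None):
    """Vertically average replicate ROC curves on a common FPR grid.

    Returns (fpr_grid, mean_tpr, se_tpr, mean_auc); the mean AUC is the mean
    of the per-replicate AUCs.
    """
    if fpr_grid is None:
        fpr_grid = np.linspace(0, 1, 101)
    curves = np.array([np.interp(fpr_grid, r.fpr, r.tpr) for r in rocs])
    mean_tpr = curves.mean(axis=0)
    se_tpr = curves.std(axis=0, ddof=1) / np.sqrt(len(rocs)) if len(rocs) > 1 \
        else np.zeros_like(mean_tpr)
    mean_auc = float(np.mean([r.auc for r in rocs]))
    return fpr_grid, mean_tpr, se_tpr, mean_auc


def da_metrics(p_adj, truth, alpha: float = 0.05) -> DAMetrics:
    """Confusion metrics of DA calls (p_adj < alpha) against ground truth.

    FDR = FP/(FP+TP) with the 0/0 -> 0 convention (nothing called); when
    FP > 0 the raw ratio is reported even without true positives.  MCC uses
    the 0-on-degenerate-margin convention.
    """
    p_adj = np.asarray(p_adj, dtype=np.float64)
    truth = np.asarray(truth, dtype=bool)
    if p_adj.shape != truth.shape:
        raise ValueError("p_adj and truth must have equal lengths")
    calls = p_adj < alpha
    tp = int(np.sum(calls & truth))
    fp = int(np.sum(calls & ~truth))
    fdr = fp / (fp + tp) if (fp + tp) > 0 else 0.0
    tpr = tp / truth.sum() if truth.any() else 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mcc = float(matthews_corrcoef(truth, calls)) if truth.size else 0.0
    return DAMetrics(float(fdr), float(tpr), mcc, int(calls.sum()))


def log_ttest_baseline(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Interaction-blind DA baseline: per-feature Welch t-tests on log proportions.

    Two-sample tests of log-abundance between the y=0 and y=1 groups with
    Benjamini-Hochberg adjustment; returns adjusted p-values per feature.
    Secondary (correlation-induced) abundance shifts are indistinguishable
    from primary effects for this baseline.
    """
    from scipy import stats
    from statsmodels.stats.multitest import multipletests

    X = np.asarray(X, dtype=np.float64)
    if np.any(X <= 0):
        raise ValueError("log baseline requires strictly positive proportions")
    L = np.log(X)
    g0 = L[np.asarray(y) == 0]
    g1 = L[np.asarray(y) == 1]
    p_raw = stats.ttest_ind(g0, g1, equal_var=False).pvalue
    return multipletests(p_raw, method="fdr_bh")[1]


def clr_transform(X: np.ndarray) -> np.ndarray:
    """Centered log-ratio transform (rows must be strictly positive)."""
    X = np.asarray(X, dtype=np.float64)
    if np.any(X <= 0):
        raise ValueError("CLR requires strictly positive data")
    L = np.log(X)
    return L - L.mean(axis=1, keepdims=True)


def clr_glasso_supports(X: np.ndarray, lambdas, tol: float = 1e-8,
                        max_iter: int = 200):
    """Graphical-lasso precision supports of CLR data along a penalty path.

    Thin benchmark adapter: returns one p x p precision matrix per lambda
    (decreasing order internally); non-converged or failed solves reuse the
    previous path point.  The support of the result is the comparator's
    estimate of the interaction structure.
    """
    from sklearn.covariance import graphical_lasso

    Z = clr_transform(X)
    emp = np.cov(Z, rowvar=False, bias=True)
    emp = emp + 1e-10 * np.eye(emp.shape[0])
    lambdas = np.sort(np.asarray(lambdas, dtype=np.float64))[::-1]
    precisions = []
    prev = None
    for lam in lambdas:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, prec = graphical_lasso(emp, alpha=float(lam), max_iter=max_iter,
                                          tol=1e-6, enet_tol=1e-6)
            prev = prec
        except Exception:
            prec = prev if prev is not None else np.diag(1.0 / np.diag(emp))
        P = np.array(prec, copy=True)
        P[np.abs(P) <= tol] = 0.0
        precisions.append(P)
    return lambdas, precisions
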