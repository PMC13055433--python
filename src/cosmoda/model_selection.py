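"""Regularization-strength selection: k-fold CV with the 1SE rule, and eBIC."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .optimizer import FitPath, FitResult, default_lambda_grid, fit_path
from .power_model import CompositionDataset
from .score_system import WeightSpec, build_score_system

__all__ = ["SelectionResult", "cross_validate", "ebic_score", "ebic_path"]


@dataclass
class SelectionResult:
    lambda_selected: float
    rule: str
    lambdas: np.ndarray
    cv_mean: np.ndarray = None
    cv_se: np.ndarray = None
    ebic_values: np.ndarray = None
    fold_seed: int = 0

    @property
    def selected_index(self) -> int:
        return int(np.argmin(np.abs(self.lambdas - self.lambda_selected)))


def _fold_assignment(n: int, k: int, rng, y=None, stratify: bool = False):
    """Uniformly random fold labels; optional stratification on binary y."""
    folds = np.empty(n, dtype=np.int64)
    if stratify and y is not None:
        for level in np.unique(y):
            ii = np.flatnonzero(y == level)
            perm = rng.permutation(ii)
            folds[perm] = np.arange(perm.size) % k
    else:
        folds[rng.permutation(n)] = np.arange(n) % k
    return folds


def cross_validate(dataset: CompositionDataset, a: float, b: float,
                   lambdas=None, k: int = 5, rule: str = "cv-1se",
                   seed: int = 0, lambda2: float = 0.0,
                   spec: WeightSpec | None = None, delta="auto",
                   stratify: bool = False, eps: float = 1e-4,
                   tmax: int = 1000) -> SelectionResult:
    """Select lambda1 by k-fold CV on the unpenalized validation loss.

    Per fold, the path is fitted on the training samples and scored with the
    quadratic loss 1/2 th' Gamma_val th - g_val' th assembled from the held-out
    samples (no delta scaling: the multiplier is an estimation device, not
    part of the divergence).  ``cv-1se`` picks the largest lambda whose mean
    loss is within one standard error of the minimizer; ``cv-min`` picks the
    minimizer itself.
    """
    if rule not in ("cv-1se", "cv-min"):
        raise ValueError(f"unknown rule {rule!r}")
    if not 2 <= k <= dataset.n:
        raise ValueError("need n >= k >= 2")
    if lambdas is None:
        lambdas = default_lambda_grid()
    lambdas = np.sort(np.asarray(lambdas, dtype=np.float64))[::-1]
    rng = np.random.default_rng(seed)
    folds = _fold_assignment(dataset.n, k, rng, dataset.y, stratify)
    if np.min(np.bincount(folds, minlength=k)) < 2:
        raise ValueError("a fold has fewer than 2 samples; reduce k")
    losses = np.empty((k, lambdas.size))
    for f in range(k):
        tr = folds != f
        va = ~tr
        ds_tr = CompositionDataset(dataset.X[tr], dataset.y[tr],
                                   list(dataset.feature_names), dataset.reference_index)
        ds_va = CompositionDataset(dataset.X[va], dataset.y[va],
                                   list(dataset.feature_names), dataset.reference_index)
        sys_tr = build_score_system(ds_tr, a, b, spec, delta)
        sys_va = build_score_system(ds_va, a, b, spec, delta)
        path = fit_path(sys_tr, lambdas, lambda2, eps=eps, tmax=tmax)
        for li, fit in enumerate(path.fits):
            losses[f, li] = sys_va.loss(fit.theta_hat, use_delta=False)
    cv_mean = losses.mean(axis=0)
    cv_se = losses.std(axis=0, ddof=1) / np.sqrt(k)
    imin = int(np.argmin(cv_mean))
    if rule == "cv-min":
        sel = lambdas[imin]
    else:
        thresh = cv_mean[imin] + cv_se[imin]
        sel = lambdas[np.flatnonzero(cv_mean <= thresh)[0]]  # largest qualifying
    return SelectionResult(float(sel), rule, lambdas, cv_mean, cv_se,
                           fold_seed=seed)


def ebic_score(fit: FitResult, n: int, gamma: float = 0.5,
               loss_shift: float = 0.0, use_penalized: bool = False) -> float:
    """Extended BIC for one fitted model.

    S * log(n) - 2 * log(loss + shift) + 2 * gamma * ||vec(K_off)||_1, where
    S is the off-diagonal support size of the symmetrized K-hat and the loss
    slot holds the score-matching loss (the model has no tractable
    likelihood).  The quadratic loss can be negative, hence the shift
    convention; ``use_penalized`` swaps in the raw penalized objective.
    """
    Koff = fit.K_hat.copy()
    np.fill_diagonal(Koff, 0.0)
    S = int(np.count_nonzero(Koff))
    loss = fit.objective if use_penalized else fit.quad_loss
    shifted = loss + loss_shift
    if shifted <= 0:
        raise ValueError("shifted loss must be positive to take its log; "
                         "increase loss_shift (see ebic_path)")
    return float(S * np.log(n) - 2.0 * np.log(shifted)
                 + 2.0 * gamma * np.abs(Koff).sum())


def ebic_path(path: FitPath, n: int, gamma: float = 0.5) -> SelectionResult:
    """eBIC over a fitted path, shifting losses positive by the path minimum."""
    losses = np.array([f.quad_loss for f in path.fits])
    shift = max(0.0, -losses.min()) + 1.0
    values = np.array([ebic_score(f, n, gamma, loss_shift=shift) for f in path.fits])
    sel = path.lambdas[int(np.argmin(values))]
    return SelectionResult(float(sel), "ebic", path.lambdas, ebic_values=values)
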