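"""L1-penalized quadratic solver: proximal coordinate descent with warm starts.

The objective is

    1/2 theta' Gamma_delta theta - g' theta
        + lambda1 ||vec(K_off)||_1 + lambda2 (||eta0||_1 + ||eta1||_1),

where the K-diagonal coordinates are unpenalized.  Each coordinate update is
the exact minimizer of the objective in that coordinate (a soft-thresholded
Newton step), so the objective is monotone non-increasing across sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .score_system import ScoreSystem

__all__ = [
    "FitResult",
    "FitPath",
    "soft_threshold",
    "prox_coordinate_descent",
    "fit_path",
    "default_lambda_grid",
    "lambda_max",
]


def soft_threshold(z: float, t: float) -> float:
    """Proximal map of t*|.|: sign(z) * max(|z| - t, 0)."""
    if t < 0:
        raise ValueError("threshold must be nonnegative")
    return float(np.sign(z) * max(abs(z) - t, 0.0))


def _lambda_vector(p: int, lambda1: float, lambda2: float) -> np.ndarray:
    lam = np.full(p * p + 2 * p, lambda2, dtype=np.float64)
    Kblock = np.full((p, p), lambda1)
    np.fill_diagonal(Kblock, 0.0)  # the K diagonal is unpenalized
    lam[: p * p] = Kblock.ravel()
    return lam


@dataclass
class FitResult:
    theta_hat: np.ndarray
    lambda1: float
    lambda2: float
    n_iter: int
    converged: bool
    objective: float
    quad_loss: float
    kkt_residual: float
    p: int
    a: float
    b: float

    @property
    def K_hat(self) -> np.ndarray:
        """Symmetrized interaction matrix estimate."""
        K = self.theta_hat[: self.p * self.p].reshape(self.p, self.p)
        return (K + K.T) / 2.0

    @property
    def eta0_hat(self) -> np.ndarray:
        return self.theta_hat[self.p * self.p: self.p * self.p + self.p]

    @property
    def eta1_hat(self) -> np.ndarray:
        return self.theta_hat[self.p * self.p + self.p:]

    @property
    def support_size(self) -> int:
        """Number of nonzero off-diagonal entries of the symmetrized K-hat."""
        K = self.K_hat.copy()
        np.fill_diagonal(K, 0.0)
        return int(np.count_nonzero(K))


@dataclass
class FitPath:
    lambdas: np.ndarray
    fits: list[FitResult]
    support_sizes: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.support_sizes is None:
            self.support_sizes = np.array([f.support_size for f in self.fits])

    def __iter__(self):
        return iter(self.fits)

    def __len__(self):
        return len(self.fits)


def _kkt_residual(system: ScoreSystem, theta: np.ndarray, lam: np.ndarray) -> float:
    grad = system.GammaDelta @ theta - system.g
    active = theta != 0
    res = np.where(active,
                   np.abs(grad + lam * np.sign(theta)),
                   np.maximum(np.abs(grad) - lam, 0.0))
    return float(res.max())


def prox_coordinate_descent(system: ScoreSystem, lambda1: float,
                            lambda2: float = 0.0, theta_init=None,
                            eps: float = 1e-6, tmax: int = 1000,
                            compute_kkt: bool = True) -> FitResult:
    """Solve the penalized problem by cyclic soft-thresholded coordinate updates.

    ``eps`` bounds the largest coordinate move per sweep relative to
    max(1, ||theta||_inf); the default is deliberately tight so that
    stand-alone fits are accurate enough for downstream inference.
    """
    if lambda1 < 0 or lambda2 < 0:
        raise ValueError("penalties must be nonnegative")
    p = system.p
    diag = system.diag_delta
    if np.any(diag <= 0):
        s = int(np.argmax(diag <= 0))
        raise ArithmeticError(
            f"Gamma_delta has a nonpositive diagonal entry at coordinate {s}; "
            "the delta multiplier is insufficient for this dataset")
    theta = (np.zeros(system.r) if theta_init is None
             else np.array(theta_init, dtype=np.float64, copy=True))
    lam = _lambda_vector(p, lambda1, lambda2)[: system.r]
    n_iter, converged = _kernels.prox_cd(system.Gamma, system.g, diag, lam,
                                         theta, float(eps), int(tmax))
    quad = system.loss(theta, use_delta=True)
    Koff = theta[: p * p].reshape(p, p).copy()
    np.fill_diagonal(Koff, 0.0)
    obj = (quad + lambda1 * np.abs(Koff).sum()
           + lambda2 * (np.abs(theta[p * p: p * p + p]).sum()
                        + np.abs(theta[p * p + p:]).sum()))
    kkt = _kkt_residual(system, theta, lam) if compute_kkt else np.nan
    return FitResult(theta, float(lambda1), float(lambda2), n_iter, converged,
                     float(obj), float(quad), kkt, p, system.a, system.b)


def default_lambda_grid(num: int = 100, lo: float = 1e-6, hi: float = 1.0) -> np.ndarray:
    """Log-linearly spaced penalty grid, decreasing."""
    return np.geomspace(hi, lo, num)


def fit_path(system: ScoreSystem, lambdas=None, lambda2: float = 0.0,
             eps: float = 1e-4, tmax: int = 1000,
             compute_kkt: bool = False) -> FitPath:
    """Fit the lambda1 path with warm starts from large to small penalties."""
    if lambdas is None:
        lambdas = default_lambda_grid()
    lambdas = np.sort(np.asarray(lambdas, dtype=np.float64))[::-1]
    if np.any(lambdas <= 0):
        raise ValueError("path lambdas must be positive")
    fits = []
    theta = np.zeros(system.r)
    for lam in lambdas:
        try:
            fit = prox_coordinate_descent(system, lam, lambda2, theta_init=theta,
                                          eps=eps, tmax=tmax, compute_kkt=compute_kkt)
        except ArithmeticError as err:
            raise ArithmeticError(f"solver failure at lambda1={lam:.3g}: {err}") from err
        theta = fit.theta_hat
        fits.append(fit)
    return FitPath(lambdas, fits)


def lambda_max(system: ScoreSystem, lambda2: float = 0.0) -> float:
    """Smallest lambda1 that fully sparsifies the off-diagonal of K-hat.

    With the off-diagonals pinned at zero, the unpenalized coordinates solve
    their subsystem; the KKT bound is the max absolute gradient over the
    off-diagonal K coordinates at that restricted solution.
    """
    big = 1e12 * max(1.0, np.abs(system.g).max())
    fit = prox_coordinate_descent(system, big, lambda2, eps=1e-10, tmax=2000,
                                  compute_kkt=False)
    grad = system.GammaDelta @ fit.theta_hat - system.g
    p = system.p
    mask = ~np.eye(p, dtype=bool)
    return float(np.abs(grad[: p * p].reshape(p, p)[mask]).max())
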