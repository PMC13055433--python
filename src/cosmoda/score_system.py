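"""Generalized score matching system for the covariate-extended power model.

Estimation minimizes the empirical weighted Hyvarinen divergence, which for
an exponential-family kernel collapses to the quadratic form

    L(theta) = 1/2 theta' Gamma theta - g' theta + const,

with ``Gamma`` and ``g`` sample averages of sufficient-statistic derivative
products.  The last (reference) coordinate is profiled out, and the boundary
weight h_j(x) = min{x_j, x_p, C_j}^c makes the divergence well-defined on the
closed simplex.  ``loss_direct`` evaluates the divergence by brute force and
serves as the independent oracle for the quadratic construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

from . import _kernels
from .power_model import CompositionDataset, ModelParams, boxcox_transform

__all__ = [
    "WeightSpec",
    "ScoreSystem",
    "weight_function",
    "weight_derivative",
    "log_density_partials",
    "loss_direct",
    "build_score_system",
    "default_delta",
]


@dataclass
class WeightSpec:
    """Boundary weight h_j(x) = min{x_j, x_p, Cj}^c; defaults give min{x_j, x_p}^2."""

    c: float = 2.0
    Cj: float = 1.0

    def __post_init__(self):
        if self.c < 0:
            raise ValueError("weight exponent c must be >= 0")
        if self.Cj <= 0:
            raise ValueError("weight truncation Cj must be > 0")


def default_delta(n: int, p: int) -> float:
    """Diagonal multiplier keeping the penalized problem strictly convex.

    delta = 2 - 1 / (1 + 4e * max(sqrt(6 log p / n), 6 log p / n)).
    """
    t = 6.0 * np.log(p) / n
    return 2.0 - 1.0 / (1.0 + 4.0 * np.e * max(np.sqrt(t), t))


def weight_function(x, j: int, spec: WeightSpec | None = None) -> float:
    """h_j applied to one simplex point; coordinate p-1 (profiled) is excluded."""
    spec = spec or WeightSpec()
    x = np.asarray(x, dtype=np.float64)
    p = x.shape[0]
    if not 0 <= j < p - 1:
        raise IndexError("j must index a non-profiled coordinate")
    return float(min(x[j], x[p - 1], spec.Cj) ** spec.c)


def weight_derivative(x, j: int, spec: WeightSpec | None = None) -> float:
    """d/dx_j of h_j along the profiled simplex (x_p = 1 - sum x_{-p}).

    At the kink x_j = x_p the x_j branch is taken (measure-zero tie).
    """
    spec = spec or WeightSpec()
    x = np.asarray(x, dtype=np.float64)
    p = x.shape[0]
    xj, xq = x[j], x[p - 1]
    phi = min(xj, xq, spec.Cj)
    if xj <= xq and xj <= spec.Cj:
        dphi = 1.0
    elif xq < xj and xq <= spec.Cj:
        dphi = -1.0
    else:
        dphi = 0.0
    if phi == 0.0:
        return 0.0
    return float(spec.c * phi ** (spec.c - 1.0) * dphi)


def _power_vec(x, e):
    # x^e with the convention x^0/x handled upstream; zeros give inf for e<0
    with np.errstate(divide="ignore"):
        return np.power(x, e)


def log_density_partials(x, y: float, params: ModelParams):
    """First and second partials of log p w.r.t. x_1..x_{p-1} (profiled model).

    Matrix-expression evaluation, independent of the sparse coefficient
    assembly; covariate terms enter through eta = eta0 + y*eta1.
    """
    x = np.asarray(x, dtype=np.float64)
    p = x.shape[0]
    a, b = params.a, params.b
    if (a == 0 or b == 0) and np.any(x <= 0):
        raise ValueError("strictly positive x required when a=0 or b=0")
    M = (params.K + params.K.T) / 2.0
    z = boxcox_transform(x, a)
    u = _power_vec(x, a - 1.0)
    u2 = _power_vec(x, a - 2.0)
    v = _power_vec(x, b - 1.0)
    v2 = _power_vec(x, b - 2.0)
    eta = params.eta(y)
    Mz = M @ z
    q = p - 1
    j = np.arange(q)
    first = -Mz[j] * u[j] + Mz[q] * u[q] + eta[j] * v[j] - eta[q] * v[q]
    second = (-(a - 1.0) * (Mz[j] * u2[j] + Mz[q] * u2[q])
              - (M[j, j] * u[j] ** 2 + M[q, q] * u[q] ** 2 - 2.0 * M[j, q] * u[j] * u[q])
              + (b - 1.0) * (eta[j] * v2[j] + eta[q] * v2[q]))
    return first, second


def loss_direct(dataset: CompositionDataset, params: ModelParams,
                spec: WeightSpec | None = None) -> float:
    """Brute-force empirical score matching loss (the oracle).

    Mean over samples of sum_j [ 1/2 h_j (d_j log p)^2 + h_j d_jj log p
    + (d_j h_j) (d_j log p) ]; equals 1/2 th'Gamma th - g'th up to a
    theta-independent constant (here exactly, the constant is zero).
    """
    spec = spec or WeightSpec()
    ds = dataset if dataset.reference_index == dataset.p - 1 else dataset.with_reference_last()[0]
    total = 0.0
    for i in range(ds.n):
        x = ds.X[i]
        first, second = log_density_partials(x, ds.y[i], params)
        for j in range(ds.p - 1):
            h = weight_function(x, j, spec)
            if h == 0.0:
                continue
            dh = weight_derivative(x, j, spec)
            total += 0.5 * h * first[j] ** 2 + h * second[j] + dh * first[j]
    return total / ds.n


@dataclass
class ScoreSystem:
    """Quadratic system (Gamma, g) plus everything needed downstream.

    The data are stored in reference-last order; per-sample components (for
    the sandwich covariance) are recomputed on demand from the stored data
    rather than materialized, since a dense per-sample Gamma is O(r^2) each.
    """

    Gamma: np.ndarray
    g: np.ndarray
    a: float
    b: float
    n: int
    p: int
    delta: float
    weight: WeightSpec
    X: np.ndarray
    y: np.ndarray
    feature_names: list[str] = field(default=None)
    covariate: bool = True

    @property
    def r(self) -> int:
        """Problem dimension: p^2 + 2p with a covariate block, p^2 + p without."""
        return self.p * self.p + (2 if self.covariate else 1) * self.p

    @property
    def k_diag_index(self) -> np.ndarray:
        """Indices of theta holding vec(K) (the delta-scaled Gamma diagonal)."""
        return np.arange(self.p * self.p)

    @cached_property
    def GammaDelta(self) -> np.ndarray:
        G = self.Gamma.copy()
        kk = self.k_diag_index
        G[kk, kk] *= self.delta
        return G

    @property
    def diag_delta(self) -> np.ndarray:
        d = np.diag(self.Gamma).copy()
        d[: self.p * self.p] *= self.delta
        return d

    def per_sample(self, i: int):
        """Dense (Gamma_delta^(i), g^(i)) for sample i (mean over i = aggregate)."""
        Gi, gi = _kernels.build_gamma_g(self.X[i: i + 1], self.y[i: i + 1],
                                        self.a, self.b, self.weight.c, self.weight.Cj)
        Gi, gi = Gi[: self.r, : self.r], gi[: self.r]
        kk = self.k_diag_index
        Gi[kk, kk] *= self.delta
        return Gi, gi

    def residuals(self, theta: np.ndarray) -> np.ndarray:
        """n x r matrix with rows Gamma_delta^(i) theta - g^(i)."""
        full = np.zeros(self.p * self.p + 2 * self.p)
        full[: self.r] = theta
        R = _kernels.residual_matrix(self.X, self.y, self.a, self.b,
                                     self.weight.c, self.weight.Cj,
                                     np.ascontiguousarray(full), self.delta)
        return R[:, : self.r]

    def loss(self, theta: np.ndarray, use_delta: bool = False) -> float:
        """Unpenalized quadratic loss 1/2 th'G th - g'th (G = Gamma or Gamma_delta)."""
        theta = np.asarray(theta, dtype=np.float64)
        Gt = self.Gamma @ theta
        val = 0.5 * theta @ Gt - self.g @ theta
        if use_delta:
            kk = self.k_diag_index
            val += 0.5 * (self.delta - 1.0) * np.sum(
                np.diag(self.Gamma)[kk] * theta[kk] ** 2)
        return float(val)


def build_score_system(dataset: CompositionDataset, a: float, b: float,
                       spec: WeightSpec | None = None,
                       delta="auto", covariate: bool | None = None,
                       max_p: int = 150) -> ScoreSystem:
    """Assemble Gamma, Gamma_delta and g for a dataset.

    Zeros in the data are admissible only when a > 0 and b > 0; otherwise an
    error directs the caller to the pseudocount option.  ``delta="auto"``
    uses the (n, p)-dependent default multiplier.  ``covariate=None`` keeps
    the eta1 block only when y actually varies (a constant covariate leaves
    eta1 unidentified, so the covariate-less model is fitted instead).
    """
    spec = spec or WeightSpec()
    ds = dataset if dataset.reference_index == dataset.p - 1 else dataset.with_reference_last()[0]
    n, p = ds.n, ds.p
    if p > max_p:
        raise MemoryError(
            f"dense Gamma for p={p} needs ~{(p * p + 2 * p) ** 2 * 8 / 1e9:.1f} GB; "
            "filter features below the guard (max_p) or raise it explicitly")
    if (a == 0 or b == 0) and np.any(ds.X == 0):
        raise ValueError(
            "data contain zeros but a=0 or b=0 requires positivity; "
            "replace zeros (pseudocount option) or use a, b > 0")
    X = np.ascontiguousarray(ds.X, dtype=np.float64)
    yv = np.ascontiguousarray(ds.y, dtype=np.float64)
    if covariate is None:
        covariate = bool(np.ptp(yv) > 0)
    Gamma, g = _kernels.build_gamma_g(X, yv, float(a), float(b), spec.c, spec.Cj)
    if not covariate:
        r = p * p + p
        Gamma, g = np.ascontiguousarray(Gamma[:r, :r]), g[:r]
    if not (np.all(np.isfinite(Gamma)) and np.all(np.isfinite(g))):
        bad = np.unique(np.where(~np.isfinite(Gamma))[0] % p)
        names = [ds.feature_names[int(t)] for t in bad[:5]]
        raise FloatingPointError(
            f"non-finite score system entries (extreme powers?); features involved: {names}")
    d = default_delta(n, p) if delta == "auto" else float(delta)
    if d <= 1.0:
        raise ValueError("delta must exceed 1")
    return ScoreSystem(Gamma, g, float(a), float(b), n, p, d, spec, X, yv,
                       list(ds.feature_names), covariate)
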