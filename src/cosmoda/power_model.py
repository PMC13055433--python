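"""Model family: the covariate-extended a-b power interaction model on the simplex.

The unnormalized density for a sample ``x`` on the (p-1)-simplex with
covariate value ``y`` is

    log p(x) = -1/2 * t_a(x)' K t_a(x) + (eta0 + y*eta1)' t_b(x) + const,

where ``t_a(x) = (x^a - 1)/a`` elementwise (``log x`` at ``a = 0``), ``K`` is a
symmetric p x p interaction matrix with zero row sums (for ground-truth
parameters), and ``eta0``, ``eta1`` are location vectors.  At ``a = b = 0``
with ``K = 0`` the kernel is the Dirichlet log-kernel; the Box-Cox-centered
transform makes the family continuous in ``a`` at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CompositionDataset",
    "ModelParams",
    "ValidityReport",
    "power_transform",
    "boxcox_transform",
    "unnorm_logdensity",
    "validate_params",
]


@dataclass
class CompositionDataset:
    """n x p relative-abundance matrix with a per-sample covariate.

    Rows of ``X`` live on the probability simplex.  ``y`` is a binary {0,1}
    or continuous covariate.  ``reference_index`` names the feature that is
    profiled out during estimation (default: last column).
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str] = field(default=None)
    reference_index: int = -1

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D samples x features matrix")
        n, p = self.X.shape
        if p < 3:
            raise ValueError(f"need at least 3 features, got p={p}")
        if n < 1:
            raise ValueError("need at least one sample")
        if np.any(self.X < 0):
            raise ValueError("abundances must be nonnegative")
        self.y = np.zeros(n) if self.y is None else np.asarray(self.y, dtype=np.float64)
        if self.y.shape != (n,):
            raise ValueError(f"covariate length {self.y.shape} does not match n={n}")
        if self.feature_names is None:
            self.feature_names = [f"feature_{j}" for j in range(p)]
        if len(self.feature_names) != p:
            raise ValueError("feature_names length must equal p")
        if self.reference_index < 0:
            self.reference_index += p
        if not 0 <= self.reference_index < p:
            raise ValueError(f"reference_index out of range [0, {p})")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @classmethod
    def from_counts(cls, counts, y=None, feature_names=None, reference_index=-1,
                    pseudocount: float | None = None):
        """Normalize a count (or unnormalized abundance) table to proportions.

        ``pseudocount`` (count scale) optionally replaces zeros before
        normalization; by default zeros are kept (the power model with a, b > 0
        handles them without replacement).
        """
        counts = np.asarray(counts, dtype=np.float64)
        if pseudocount is not None:
            counts = np.where(counts == 0, float(pseudocount), counts)
        sums = counts.sum(axis=1, keepdims=True)
        if np.any(sums <= 0):
            raise ValueError("every sample must have positive total abundance")
        return cls(counts / sums, y, feature_names, reference_index)

    def normalized(self) -> "CompositionDataset":
        """Return a copy with rows renormalized to sum to one."""
        return CompositionDataset(
            self.X / self.X.sum(axis=1, keepdims=True),
            self.y, list(self.feature_names), self.reference_index)

    def with_reference_last(self) -> tuple["CompositionDataset", np.ndarray]:
        """Reorder columns so the reference feature is last.

        Returns the reordered dataset and the permutation applied (such that
        ``X_new = X[:, perm]``).  Model internals profile out the *last*
        coordinate.
        """
        p = self.p
        r = self.reference_index
        perm = np.array([j for j in range(p) if j != r] + [r])
        ds = CompositionDataset(
            self.X[:, perm], self.y,
            [self.feature_names[j] for j in perm], p - 1)
        return ds, perm


@dataclass
class ModelParams:
    """Parameters of the covariate-extended a-b power interaction model."""

    a: float
    b: float
    K: np.ndarray
    eta0: np.ndarray
    eta1: np.ndarray = None

    def __post_init__(self):
        self.K = np.asarray(self.K, dtype=np.float64)
        self.eta0 = np.asarray(self.eta0, dtype=np.float64)
        p = self.K.shape[0]
        if self.K.shape != (p, p):
            raise ValueError("K must be square")
        if self.eta1 is None:
            self.eta1 = np.zeros(p)
        self.eta1 = np.asarray(self.eta1, dtype=np.float64)
        if self.eta0.shape != (p,) or self.eta1.shape != (p,):
            raise ValueError("eta0/eta1 must have length p")
        if self.a < 0 or self.b < 0:
            raise ValueError("powers a, b must be nonnegative")

    @property
    def p(self) -> int:
        return self.K.shape[0]

    def eta(self, y: float) -> np.ndarray:
        return self.eta0 + y * self.eta1

    def theta(self) -> np.ndarray:
        """Flatten to theta = (vec(K), eta0, eta1), row-major vec."""
        return np.concatenate([self.K.ravel(), self.eta0, self.eta1])

    @classmethod
    def from_theta(cls, theta: np.ndarray, p: int, a: float, b: float,
                   symmetrize: bool = True) -> "ModelParams":
        theta = np.asarray(theta, dtype=np.float64)
        K = theta[: p * p].reshape(p, p)
        if symmetrize:
            K = (K + K.T) / 2.0
        return cls(a, b, K, theta[p * p: p * p + p], theta[p * p + p:])


@dataclass
class ValidityReport:
    is_valid: bool
    case_label: str
    violated_conditions: list[str]


def power_transform(x, a: float):
    """Elementwise power transform ``x^a`` (``log x`` at a=0).

    Returns ``(x^a, scale)`` where the companion scalar ``scale = 1/a``
    (``1`` at a=0) multiplies the transform inside the density.  Zeros are
    permitted only for ``a > 0``.
    """
    x = np.asarray(x, dtype=np.float64)
    if a == 0:
        if np.any(x <= 0):
            raise ValueError(
                "log transform (a=0) requires strictly positive entries; "
                "replace zeros (pseudocount) or use a > 0")
        return np.log(x), 1.0
    if np.any(x < 0):
        raise ValueError("power transform requires nonnegative entries")
    return np.power(x, a), 1.0 / a


def boxcox_transform(x, a: float) -> np.ndarray:
    """Centered (Box-Cox) transform ``(x^a - 1)/a``, ``log x`` at a=0.

    This is the sufficient-statistic transform used throughout estimation;
    it converges to the logarithm as a -> 0.
    """
    x = np.asarray(x, dtype=np.float64)
    if a == 0:
        if np.any(x <= 0):
            raise ValueError(
                "log transform (a=0) requires strictly positive entries; "
                "replace zeros (pseudocount) or use a > 0")
        return np.log(x)
    if np.any(x < 0):
        raise ValueError("power transform requires nonnegative entries")
    return (np.power(x, a) - 1.0) / a


def unnorm_logdensity(x, y: float, params: ModelParams) -> float:
    """Unnormalized log-density of one simplex point under the model.

    The cumulant (normalizing constant) is never computed.  Zeros in ``x``
    are admissible only when both a > 0 and b > 0.
    """
    z = boxcox_transform(x, params.a)
    w = z if params.b == params.a else boxcox_transform(x, params.b)
    eta = params.eta(y)
    return float(-0.5 * z @ params.K @ z + eta @ w)


def _simplex_grid(p: int, m: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    g = rng.dirichlet(np.ones(p), size=m)
    return np.clip(g, 1e-12, None)


def validate_params(params: ModelParams, y_range=(0.0, 1.0), grid=None,
                    grid_size: int = 1000, seed: int = 0) -> ValidityReport:
    """Check the four propriety cases of the model.

    The location vector is evaluated at both extremes of ``y_range`` (it is
    linear in y, so extremes suffice).  For the a=0 cases the quadratic-form
    condition ``log(x)' K log(x) > 0`` for all simplex x cannot be certified
    numerically; it is checked on a grid of random simplex points and is a
    *necessary-condition* check only.
    """
    a, b, K = params.a, params.b, params.K
    violated: list[str] = []
    etas = [params.eta(y_range[0]), params.eta(y_range[1])]
    if not np.allclose(K, K.T, atol=1e-8):
        violated.append("K != K^T")
    if a > 0 and b > 0:
        label = "a>0&b>0"
    elif a > 0 and b == 0:
        label = "a>0&b=0"
        for eta in etas:
            if np.any(eta <= -1):
                violated.append("eta_j > -1 for all j (eta = eta0 + y*eta1)")
                break
    else:
        label = "a=0&b=0" if b == 0 else "a=0&b>0"
        if np.max(np.abs(K)) < 1e-14:
            # vanishing interactions: Dirichlet-type propriety via the location
            if b == 0:
                for eta in etas:
                    if np.any(eta <= -1):
                        violated.append("eta_j > -1 for all j (K = 0, Dirichlet case)")
                        break
        else:
            if grid is None:
                grid = _simplex_grid(params.p, grid_size, seed)
            L = np.log(grid)
            q = np.einsum("ij,jk,ik->i", L, K, L)
            strict = b == 0
            if (strict and np.any(q <= 0)) or (not strict and np.any(q < -1e-12)):
                op = ">" if strict else ">="
                violated.append(f"log(x)' K log(x) {op} 0 on simplex grid (necessary check)")
    return ValidityReport(len(violated) == 0, label, violated)
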