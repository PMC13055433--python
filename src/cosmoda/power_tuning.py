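"""Data-driven selection of the power phi = a = b.

The power is chosen so that the geometry of the Box-Cox-like transformed
data (which needs no zero replacement) matches the additive log-ratio
geometry of zero-replaced data as closely as possible, measured by the
Procrustes correlation r_phi over a grid phi in (0, 1).  Selecting the
argmax keeps the raw zeros in the data while staying close to the log-ratio
analysis a practitioner would otherwise run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ProcrustesResult",
    "boxcox_compositional_transform",
    "alr_with_zero_column",
    "procrustes_correlation",
    "select_power",
]


@dataclass
class ProcrustesResult:
    phi_grid: np.ndarray
    correlations: np.ndarray
    phi_star: float
    pseudocount: float


def boxcox_compositional_transform(X, phi: float) -> np.ndarray:
    """Row-wise compositional Box-Cox transform.

    X_out[i, j] = (1/phi) * (p * X[i,j]^phi / sum_k X[i,k]^phi - 1); rows sum
    to zero exactly, and as phi -> 0 the transform converges to the centered
    log-ratio.  Zeros are permitted (phi > 0).
    """
    X = np.asarray(X, dtype=np.float64)
    if phi <= 0:
        raise ValueError("phi must be positive (use the CLR for the log limit)")
    if np.any(X < 0):
        raise ValueError("X must be nonnegative")
    Xp = np.power(X, phi)
    sums = Xp.sum(axis=1, keepdims=True)
    if np.any(sums <= 0):
        raise ValueError("all-zero row encountered")
    p = X.shape[1]
    return (p * Xp / sums - 1.0) / phi


def _replace_zeros(X: np.ndarray, pseudocount: float, library_sizes=None) -> np.ndarray:
    """Zero replacement on the count scale when possible.

    Count tables get ``pseudocount`` counts in place of zeros.  Proportion
    tables use ``pseudocount / library_size`` when library sizes are known,
    otherwise ``pseudocount * (smallest nonzero proportion)`` — the standard
    multiplicative-replacement heuristic.  Rows are renormalized afterwards.
    """
    X = np.array(X, dtype=np.float64, copy=True)
    looks_like_counts = np.any(X.sum(axis=1) > 1.5)
    zero = X == 0
    if looks_like_counts:
        X[zero] = pseudocount
    elif library_sizes is not None:
        ls = np.asarray(library_sizes, dtype=np.float64).reshape(-1, 1)
        X = np.where(zero, pseudocount / ls, X)
    else:
        pos_min = X[X > 0].min()
        X[zero] = pseudocount * pos_min
    return X / X.sum(axis=1, keepdims=True)


def alr_with_zero_column(X, reference_index: int = -1, pseudocount: float = 0.5,
                         library_sizes=None) -> np.ndarray:
    """ALR transform with zeros replaced, keeping p columns.

    log(X_j / X_ref) for every feature; the reference column itself maps to
    log(X_ref/X_ref) = 0 and is kept in place so the matrix shape matches the
    power transform.
    """
    X = np.asarray(X, dtype=np.float64)
    p = X.shape[1]
    ref = reference_index % p
    Xr = _replace_zeros(X, pseudocount, library_sizes)
    if np.any(Xr[:, ref] <= 0):
        raise ValueError("reference column must be positive after zero replacement")
    out = np.log(Xr / Xr[:, [ref]])
    out[:, ref] = 0.0
    return out


def procrustes_correlation(A, B) -> float:
    """Procrustes correlation between two equally-shaped matrices.

    Both are normalized to unit Frobenius norm; B is rotated onto A by the
    orthogonal map from the SVD of the cross-product; the correlation is one
    minus the residual sum of squares.
    """
    A = np.asarray(A, dtype=np.float64)
    B = np.asarray(B, dtype=np.float64)
    if A.shape != B.shape:
        raise ValueError("matrices must have identical shapes")
    na = np.sqrt(np.trace(A.T @ A))
    nb = np.sqrt(np.trace(B.T @ B))
    if na == 0 or nb == 0:
        raise ValueError("zero-norm input")
    As = A / na
    Bs = B / nb
    U, sv, Vt = np.linalg.svd(As.T @ Bs)
    Q = Vt.T @ U.T
    D = As - Bs @ Q
    E = np.trace(D.T @ D)
    return float(1.0 - E)


def select_power(X, reference_index: int = -1, grid=None, pseudocount: float = 0.5,
                 library_sizes=None, center: bool = True,
                 n_components: int | None = None) -> ProcrustesResult:
    """Grid-search the power phi maximizing Procrustes alignment with the ALR.

    Both matrices are column-centered before alignment; Procrustes over
    full-dimensional rotations is invariant to an orthogonal change of basis,
    so this is equivalent to aligning complete PC-score embeddings.
    ``n_components`` optionally runs an explicit truncated PCA instead.
    Ties in the argmax resolve to the smallest phi.
    """
    X = np.asarray(X, dtype=np.float64)
    X = X / X.sum(axis=1, keepdims=True)
    if grid is None:
        grid = np.round(np.arange(0.01, 1.0, 0.01), 10)
    grid = np.asarray(grid, dtype=np.float64)
    if np.any((grid <= 0) | (grid >= 1)):
        raise ValueError("phi grid must lie in (0, 1)")
    alr = alr_with_zero_column(X, reference_index, pseudocount, library_sizes)
    alr_c = alr - alr.mean(axis=0) if center else alr

    def embed(M):
        if n_components is None:
            return M
        U, sv, _ = np.linalg.svd(M, full_matrices=False)
        return U[:, :n_components] * sv[:n_components]

    alr_e = embed(alr_c)
    corrs = np.empty(grid.size)
    for gi, phi in enumerate(grid):
        Bc = boxcox_compositional_transform(X, phi)
        if center:
            Bc = Bc - Bc.mean(axis=0)
        corrs[gi] = procrustes_correlation(embed(Bc), alr_e)
    best = int(np.argmax(corrs))  # argmax returns the first (smallest phi) tie
    return ProcrustesResult(grid, corrs, float(grid[best]), pseudocount)
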