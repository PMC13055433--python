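"""Differential abundance testing on the covariate coefficients eta1.

The fitted theta-hat is an M-estimator solving a penalized quadratic
program; its variance is estimated by the sandwich

    Var(theta-hat) ~= Gamma^{-1} Sigma0 Gamma^{-1} / n,
    Sigma0 = 1/n sum_i r_i r_i',   r_i = Gamma_delta^(i) theta-hat - g^(i),

the empirical covariance of the per-sample score residuals bread-and-meat
construction.  Per feature j the studentized statistic T_j = eta1_j / se_j is
referred to a t-distribution with n - 3 degrees of freedom, and raw p-values
are Benjamini-Hochberg adjusted.  The profiled-out reference feature carries
no test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .score_system import ScoreSystem

__all__ = ["sandwich_covariance", "da_test", "bh_adjust"]


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must be finite and in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def sandwich_covariance(system: ScoreSystem, theta_hat: np.ndarray,
                        use_delta_gamma: bool = False,
                        cond_threshold: float = 1e12,
                        jitter_scale: float = 1e-8) -> np.ndarray:
    """Sandwich covariance estimate of theta-hat.

    The bread uses the un-delta-scaled Gamma by default (the diagonal
    multiplier is an optimization device); ``use_delta_gamma`` switches to
    Gamma_delta for parity experiments.  When Gamma is ill-conditioned
    (condition number above ``cond_threshold``) a ridge jitter of
    ``jitter_scale * trace(Gamma)/r`` is added to its diagonal; if that still
    fails, an error recommends stronger regularization or more samples.
    """
    theta_hat = np.asarray(theta_hat, dtype=np.float64)
    R = system.residuals(theta_hat)
    G = system.GammaDelta if use_delta_gamma else system.Gamma
    G = G.copy()
    r = G.shape[0]
    ev = np.linalg.eigvalsh(G)
    if ev[0] <= 0 or ev[-1] / max(ev[0], 1e-300) > cond_threshold:
        G[np.diag_indices_from(G)] += jitter_scale * np.trace(G) / r
        ev = np.linalg.eigvalsh(G)
        if ev[0] <= 0:
            raise np.linalg.LinAlgError(
                "Gamma is numerically singular even after ridge jitter; "
                "use stronger regularization or more samples")
    # S = G^{-1} (R'R/n) G^{-1} / n written as a Gram product, PSD by construction
    B = np.linalg.solve(G, R.T)
    return (B @ B.T) / (system.n ** 2)


def da_test(theta_hat: np.ndarray, S_hat: np.ndarray, n: int,
            feature_names=None, alpha: float = 0.05) -> pd.DataFrame:
    """Per-feature test of H0: eta1_j = 0 from a fitted system.

    ``theta_hat`` and ``S_hat`` are in reference-last order; the last feature
    is the profiled reference and is flagged instead of tested.  Returns the
    results table with columns feature, eta1_hat, se, t, p_raw, p_adj,
    is_reference.
    """
    if n <= 3:
        raise ValueError("the t(n-3) reference requires n > 3")
    r = theta_hat.shape[0]
    p = int(round((-1 + np.sqrt(1 + r))))  # r = p^2 + 2p
    if p * p + 2 * p != r:
        raise ValueError("theta length is not of the form p^2 + 2p")
    if feature_names is None:
        feature_names = [f"feature_{j}" for j in range(p)]
    eta1 = theta_hat[p * p + p:]
    var = np.diag(S_hat)[p * p + p:]
    tested = np.arange(p - 1)
    if np.any(var[tested] <= 0):
        bad = [feature_names[int(j)] for j in tested[var[tested] <= 0]]
        raise ValueError(f"nonpositive sandwich variance for {bad}; "
                         "the covariance estimate failed")
    se = np.sqrt(np.where(var > 0, var, np.nan))
    tstat = eta1 / se
    p_raw = 2.0 * stats.t.cdf(-np.abs(tstat), df=n - 3)
    p_adj = np.full(p, np.nan)
    p_adj[tested] = bh_adjust(p_raw[tested])
    table = pd.DataFrame({
        "feature": feature_names,
        "eta1_hat": eta1,
        "se": se,
        "t": tstat,
        "p_raw": p_raw,
        "p_adj": p_adj,
        "is_reference": [j == p - 1 for j in range(p)],
    })
    table.loc[p - 1, ["se", "t", "p_raw", "p_adj"]] = np.nan
    return table
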