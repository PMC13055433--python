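"""Numba kernels for the score-matching system, the solver, and the sampler.

Everything here operates in "reference-last" column order: the last
coordinate is profiled out (x_p = 1 - sum of the others) and the parameter
vector is laid out as theta = (vec(K) row-major, eta0, eta1) of length
r = p^2 + 2p.

The per-(sample, feature) coefficient vectors b_j and c_j are the gradients
with respect to theta of the first and second partial derivatives of the
log-density; they are sparse with ~4p nonzeros, which keeps the Gamma
assembly at O(n * p * (4p)^2) flops.
"""

import numpy as np
from numba import njit

_F = "float64"


@njit(cache=True, fastmath=False)
def _fill_coeffs(x, yi, a, b, z, u, u2, v, v2, j, q, idx, bv, cv):
    """Fill sparse index/value arrays for b_j (bv) and c_j (cv).

    Returns the number of entries written.  K-part support: rows j and q,
    columns j and q of the p x p coefficient matrices; eta parts have two
    entries each.
    """
    p = x.shape[0]
    am1 = a - 1.0
    bm1 = b - 1.0
    count = 0
    uj = u[j]
    uq = u[q]
    zj = z[j]
    zq = z[q]
    e2j = u2[j]
    e2q = u2[q]
    # row j of the K coefficient matrices
    for w in range(p):
        dc = uj if w == j else (-uq if w == q else 0.0)
        e2c = e2j if w == j else (e2q if w == q else 0.0)
        idx[count] = j * p + w
        bv[count] = -0.5 * (uj * z[w] + zj * dc)
        cv[count] = -0.5 * am1 * (e2j * z[w] + zj * e2c) - uj * dc
        count += 1
    # row q
    for w in range(p):
        dc = uj if w == j else (-uq if w == q else 0.0)
        e2c = e2j if w == j else (e2q if w == q else 0.0)
        idx[count] = q * p + w
        bv[count] = -0.5 * (-uq * z[w] + zq * dc)
        cv[count] = -0.5 * am1 * (e2q * z[w] + zq * e2c) + uq * dc
        count += 1
    # columns j and q, remaining rows
    for w in range(p):
        if w == j or w == q:
            continue
        idx[count] = w * p + j
        bv[count] = -0.5 * (z[w] * uj)
        cv[count] = -0.5 * am1 * (z[w] * e2j)
        count += 1
        idx[count] = w * p + q
        bv[count] = -0.5 * (z[w] * (-uq))
        cv[count] = -0.5 * am1 * (z[w] * e2q)
        count += 1
    # eta0 block
    idx[count] = p * p + j
    bv[count] = v[j]
    cv[count] = bm1 * v2[j]
    count += 1
    idx[count] = p * p + q
    bv[count] = -v[q]
    cv[count] = bm1 * v2[q]
    count += 1
    # eta1 block
    idx[count] = p * p + p + j
    bv[count] = yi * v[j]
    cv[count] = yi * bm1 * v2[j]
    count += 1
    idx[count] = p * p + p + q
    bv[count] = -yi * v[q]
    cv[count] = yi * bm1 * v2[q]
    count += 1
    return count


@njit(cache=True)
def _transforms(x, a, b, z, u, u2, v, v2):
    p = x.shape[0]
    for k in range(p):
        xk = x[k]
        if xk > 0.0:
            if a == 0.0:
                z[k] = np.log(xk)
                u[k] = 1.0 / xk
                u2[k] = 1.0 / (xk * xk)
            else:
                z[k] = (xk ** a - 1.0) / a
                u[k] = xk ** (a - 1.0)
                u2[k] = xk ** (a - 2.0)
            if b == 0.0:
                v[k] = 1.0 / xk
                v2[k] = 1.0 / (xk * xk)
            else:
                v[k] = xk ** (b - 1.0)
                v2[k] = xk ** (b - 2.0)
        else:
            # only reachable for a,b > 0; the vanishing boundary weight
            # removes any term where these singular powers would enter
            z[k] = (-1.0 / a) if a > 0.0 else 0.0
            u[k] = 0.0 if a >= 1.0 else np.inf
            u2[k] = 0.0 if a >= 2.0 else np.inf
            v[k] = 0.0 if b >= 1.0 else np.inf
            v2[k] = 0.0 if b >= 2.0 else np.inf


@njit(cache=True)
def _weight(xj, xq, Cj, c):
    phi = xj
    if xq < phi:
        phi = xq
    if Cj < phi:
        phi = Cj
    h = phi ** c
    # subgradient convention at ties: the x_j branch wins
    if xj <= xq and xj <= Cj:
        dphi = 1.0
    elif xq < xj and xq <= Cj:
        dphi = -1.0
    else:
        dphi = 0.0
    dh = c * phi ** (c - 1.0) * dphi if phi > 0.0 else 0.0
    return phi, h, dh


@njit(cache=True)
def build_gamma_g(X, y, a, b, c, Cj):
    """Aggregate Gamma (r x r) and g (r) as sample averages.

    Loops feature-outer / sample-inner: for a fixed feature j the sparse
    coefficient support (rows/cols j and p of the K block plus the eta
    entries) is the same for every sample, so contributions accumulate in a
    small dense (4p x 4p) scratch matrix that stays in cache and is
    scattered into the big Gamma once per feature.
    """
    n, p = X.shape
    r = p * p + 2 * p
    m = 4 * p
    Gamma = np.zeros((r, r))
    g = np.zeros(r)
    idx = np.empty(m, dtype=np.int64)
    bv = np.empty(m)
    cv = np.empty(m)
    Z = np.empty((n, p))
    U = np.empty((n, p))
    U2 = np.empty((n, p))
    V = np.empty((n, p))
    V2 = np.empty((n, p))
    for i in range(n):
        _transforms(X[i], a, b, Z[i], U[i], U2[i], V[i], V2[i])
    q = p - 1
    L = np.empty((m, m))
    gl = np.empty(m)
    for j in range(p - 1):
        L[:, :] = 0.0
        gl[:] = 0.0
        touched = False
        for i in range(n):
            x = X[i]
            phi, h, dh = _weight(x[j], x[q], Cj, c)
            if phi <= 0.0:
                continue
            touched = True
            _fill_coeffs(x, y[i], a, b, Z[i], U[i], U2[i], V[i], V2[i],
                         j, q, idx, bv, cv)
            for s in range(m):
                gl[s] -= h * cv[s] + dh * bv[s]
                hb = h * bv[s]
                Ls = L[s]
                for t in range(m):
                    Ls[t] += hb * bv[t]
        if not touched:
            continue
        for s in range(m):
            gi = idx[s]
            g[gi] += gl[s]
            Gi = Gamma[gi]
            Ls = L[s]
            for t in range(m):
                Gi[idx[t]] += Ls[t]
    inv_n = 1.0 / n
    for s in range(r):
        g[s] *= inv_n
        for t in range(r):
            Gamma[s, t] *= inv_n
    return Gamma, g


@njit(cache=True)
def residual_matrix(X, y, a, b, c, Cj, theta, delta):
    """Per-sample score residuals R[i] = Gamma_delta^(i) theta - g^(i).

    Gamma^(i), g^(i) are the single-sample contributions (so that their mean
    over i equals the aggregate system); the K-diagonal of each Gamma^(i) is
    scaled by delta.
    """
    n, p = X.shape
    r = p * p + 2 * p
    R = np.zeros((n, r))
    idx = np.empty(4 * p, dtype=np.int64)
    bv = np.empty(4 * p)
    cv = np.empty(4 * p)
    z = np.empty(p)
    u = np.empty(p)
    u2 = np.empty(p)
    v = np.empty(p)
    v2 = np.empty(p)
    q = p - 1
    dm1 = delta - 1.0
    for i in range(n):
        x = X[i]
        _transforms(x, a, b, z, u, u2, v, v2)
        xq = x[q]
        for j in range(p - 1):
            phi, h, dh = _weight(x[j], xq, Cj, c)
            if phi <= 0.0:
                continue
            cnt = _fill_coeffs(x, y[i], a, b, z, u, u2, v, v2, j, q, idx, bv, cv)
            dot = 0.0
            for s in range(cnt):
                dot += bv[s] * theta[idx[s]]
            for s in range(cnt):
                gi = idx[s]
                # Gamma^(i) theta  (+ delta excess on the K diagonal)
                R[i, gi] += h * bv[s] * dot
                if gi < p * p:
                    R[i, gi] += dm1 * h * bv[s] * bv[s] * theta[gi]
                # minus g^(i)
                R[i, gi] += h * cv[s] + dh * bv[s]
    return R


@njit(cache=True)
def prox_cd(Gamma, g, diag_delta, lam, theta, eps, tmax):
    """Cyclic proximal coordinate descent on 1/2 th'Gd th - g'th + sum lam|th|.

    ``Gamma`` holds the unscaled matrix; ``diag_delta`` its delta-scaled
    diagonal (off-diagonals of Gamma_delta equal Gamma's).  ``theta`` is
    updated in place.  Convergence: max coordinate change per sweep below
    eps * max(1, ||theta||_inf).
    """
    r = g.shape[0]
    q = Gamma @ theta
    converged = False
    it = 0
    scale = 1.0
    for it in range(1, tmax + 1):
        maxd = 0.0
        maxth = 0.0
        # moves below half the convergence tolerance are not applied at all:
        # the coordinate is already optimal to within tolerance, and skipping
        # the O(r) gradient update keeps theta/q bookkeeping exact
        skip = 0.5 * eps * scale
        for s in range(r):
            ths = theta[s]
            num = g[s] - (q[s] - Gamma[s, s] * ths)
            den = diag_delta[s]
            zval = num / den
            thr = lam[s] / den
            if zval > thr:
                new = zval - thr
            elif zval < -thr:
                new = zval + thr
            else:
                new = 0.0
            d = new - ths
            ad = abs(d)
            if ad > skip:
                theta[s] = new
                row = Gamma[s]
                for t in range(r):
                    q[t] += row[t] * d
                if ad > maxd:
                    maxd = ad
                at = abs(new)
            else:
                at = abs(ths)
            if at > maxth:
                maxth = at
        scale = 1.0 if maxth < 1.0 else maxth
        if maxd <= eps * scale:
            converged = True
            break
    return it, converged


@njit(cache=True, inline="always")
def _bc(xv, a):
    if a == 0.0:
        return np.log(xv)
    return (xv ** a - 1.0) / a


@njit(cache=True)
def gibbs_independent(K, eta, a, b, n_draws, burn_in, grid_size, seed):
    """One independent pairwise-Gibbs chain per draw.

    Every sample starts from a fresh uniform-Dirichlet point and runs
    ``burn_in`` sweeps; the final state is the draw.  Samples are therefore
    exactly independent, mirroring generation by repeated sampler runs.
    """
    p = K.shape[0]
    np.random.seed(seed)
    out = np.empty((n_draws, p))
    for d in range(n_draws):
        x0 = np.empty(p)
        tot = 0.0
        for t in range(p):
            x0[t] = np.random.exponential(1.0)
            tot += x0[t]
        for t in range(p):
            x0[t] /= tot
        chain_seed = np.random.randint(0, 2**31 - 1)
        draw = gibbs_chain(K, eta, a, b, 1, burn_in, 1, grid_size,
                           chain_seed, x0)
        out[d] = draw[0]
    return out


@njit(cache=True)
def gibbs_chain(K, eta, a, b, n_draws, burn_in, thin, grid_size, seed, x0):
    """Pairwise Gibbs sampler on the simplex for the a-b power model.

    Each step redistributes the joint mass of a random coordinate pair,
    drawing the split fraction from a griddy inverse-CDF approximation of
    the 1-D conditional kernel (piecewise-constant over grid_size bins,
    uniform within the chosen bin).  One sweep = p pair updates.
    """
    p = K.shape[0]
    np.random.seed(seed)
    x = x0.copy()
    z = np.empty(p)
    for t in range(p):
        z[t] = _bc(x[t], a)
    Kz = K @ z
    logk = np.empty(grid_size)
    out = np.empty((n_draws, p))
    # grid transforms depend on the split fraction t only; precompute
    # t^a (or log t) so each kernel evaluation is a handful of flops
    ta_t = np.empty(grid_size)
    ta_1t = np.empty(grid_size)
    tb_t = np.empty(grid_size)
    tb_1t = np.empty(grid_size)
    for gidx in range(grid_size):
        tt = (gidx + 0.5) / grid_size
        if a == 0.0:
            ta_t[gidx] = np.log(tt)
            ta_1t[gidx] = np.log(1.0 - tt)
        else:
            ta_t[gidx] = tt ** a
            ta_1t[gidx] = (1.0 - tt) ** a
        if b == 0.0:
            tb_t[gidx] = np.log(tt)
            tb_1t[gidx] = np.log(1.0 - tt)
        else:
            tb_t[gidx] = tt ** b
            tb_1t[gidx] = (1.0 - tt) ** b
    draw = 0
    total = burn_in + thin * n_draws
    for sweep in range(total):
        for j in range(p):
            k = np.random.randint(0, p - 1)
            if k >= j:
                k += 1
            m = x[j] + x[k]
            if m <= 0.0:
                continue
            Sj = Kz[j] - K[j, j] * z[j] - K[j, k] * z[k]
            Sk = Kz[k] - K[k, j] * z[j] - K[k, k] * z[k]
            Kjj = K[j, j]
            Kkk = K[k, k]
            Kjk = K[j, k]
            ej = eta[j]
            ek = eta[k]
            if a == 0.0:
                lma = np.log(m)
                ma = 0.0
            else:
                lma = 0.0
                ma = m ** a
            if b == a:
                lmb = lma
                mb = ma
            elif b == 0.0:
                lmb = np.log(m)
                mb = 0.0
            else:
                lmb = 0.0
                mb = m ** b
            mx = -1e300
            for gidx in range(grid_size):
                if a == 0.0:
                    zj = lma + ta_t[gidx]
                    zk = lma + ta_1t[gidx]
                else:
                    zj = (ma * ta_t[gidx] - 1.0) / a
                    zk = (ma * ta_1t[gidx] - 1.0) / a
                if b == a:
                    wj = zj
                    wk = zk
                elif b == 0.0:
                    wj = lmb + tb_t[gidx]
                    wk = lmb + tb_1t[gidx]
                else:
                    wj = (mb * tb_t[gidx] - 1.0) / b
                    wk = (mb * tb_1t[gidx] - 1.0) / b
                val = (-(Sj * zj + Sk * zk)
                       - 0.5 * (Kjj * zj * zj + Kkk * zk * zk + 2.0 * Kjk * zj * zk)
                       + ej * wj + ek * wk)
                logk[gidx] = val
                if val > mx:
                    mx = val
            csum = 0.0
            for gidx in range(grid_size):
                v = logk[gidx] - mx
                if v > -34.0:   # exp underflows to ~1e-15 of the peak: skip
                    csum += np.exp(v)
                logk[gidx] = csum
            uu = np.random.random() * csum
            lo = 0
            hi = grid_size - 1
            while lo < hi:
                mid = (lo + hi) // 2
                if logk[mid] < uu:
                    lo = mid + 1
                else:
                    hi = mid
            tt = (lo + np.random.random()) / grid_size
            if tt <= 0.0:
                tt = 0.5 / grid_size
            if tt >= 1.0:
                tt = 1.0 - 0.5 / grid_size
            xj = m * tt
            xk = m - xj
            zj = _bc(xj, a)
            zk = _bc(xk, a)
            dzj = zj - z[j]
            dzk = zk - z[k]
            rowj = K[j]
            rowk = K[k]
            # K is symmetric, so the j/k columns equal the (contiguous) rows
            for t in range(p):
                Kz[t] += rowj[t] * dzj + rowk[t] * dzk
            x[j] = xj
            x[k] = xk
            z[j] = zj
            z[k] = zk
        if sweep >= burn_in and (sweep - burn_in) % thin == thin - 1:
            out[draw] = x
            draw += 1
            if draw == n_draws:
                break
    return out
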