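"""Numba kernels for EM fitting of 1-D / 2-D Gaussian mixtures.

The kernels are deliberately free of RNG state: k-means++ seeding consumes a
pre-drawn vector of uniforms, so a fit is a pure function of (data, uniforms,
config scalars) and bit-identical across runs and platforms with the same
BLAS-free arithmetic.
"""
from __future__ import annotations

import numpy as np
from numba import njit

_LOG2PI = np.log(2.0 * np.pi)


@njit(cache=True)
def _floor_cov2(a, b, c, floor):
    """Clamp the eigenvalues of the symmetric 2x2 matrix [[a,b],[b,c]] at `floor`."""
    half = 0.5 * (a - c)
    rad = np.sqrt(half * half + b * b)
    mid = 0.5 * (a + c)
    l1 = mid + rad
    l2 = mid - rad
    if l2 >= floor:
        return a, b, c
    l1c = l1 if l1 >= floor else floor
    l2c = floor
    # eigenvector for l1
    vx = l1 - c
    vy = b
    norm = np.sqrt(vx * vx + vy * vy)
    if norm < 1e-300:
        # matrix is (numerically) a*I: just clamp the diagonal
        an = a if a >= floor else floor
        cn = c if c >= floor else floor
        return an, b, cn
    vx /= norm
    vy /= norm
    an = l1c * vx * vx + l2c * vy * vy
    bn = (l1c - l2c) * vx * vy
    cn = l1c * vy * vy + l2c * vx * vx
    return an, bn, cn


@njit(cache=True)
def _log_density_ll(X, weights, means, covs, logdens):
    """Fill logdens[i,g] = log w_g + log N(X_i | mu_g, Sigma_g); return total loglik."""
    n, d = X.shape
    G = weights.shape[0]
    for g in range(G):
        lw = np.log(weights[g])
        if d == 1:
            v = covs[g, 0, 0]
            cst = lw - 0.5 * (_LOG2PI + np.log(v))
            inv = 0.5 / v
            for i in range(n):
                diff = X[i, 0] - means[g, 0]
                logdens[i, g] = cst - diff * diff * inv
        else:
            a = covs[g, 0, 0]
            b = covs[g, 0, 1]
            c = covs[g, 1, 1]
            det = a * c - b * b
            cst = lw - _LOG2PI - 0.5 * np.log(det)
            ia = c / det
            ib = -b / det
            ic = a / det
            for i in range(n):
                dx = X[i, 0] - means[g, 0]
                dy = X[i, 1] - means[g, 1]
                q = ia * dx * dx + 2.0 * ib * dx * dy + ic * dy * dy
                logdens[i, g] = cst - 0.5 * q
    ll = 0.0
    for i in range(n):
        m = logdens[i, 0]
        for g in range(1, G):
            if logdens[i, g] > m:
                m = logdens[i, g]
        s = 0.0
        for g in range(G):
            s += np.exp(logdens[i, g] - m)
        ll += m + np.log(s)
    return ll


@njit(cache=True)
def fit_once(X, G, u, tol, max_iter, floor):
    """One complete EM run: k-means++ seeding, hard-assignment init, EM to convergence.

    Parameters
    ----------
    X : (n, d) float64, d in {1, 2}
    G : number of components
    u : (G,) uniforms in [0,1) consumed by the k-means++ seeding
    tol : relative log-likelihood convergence tolerance
    max_iter : EM iteration cap
    floor : covariance eigenvalue floor (> 0)

    Returns
    -------
    weights, means, covs, loglik, n_iter, converged, max_decrease
    where max_decrease is the largest per-iteration log-likelihood decrease
    observed (0.0 for a healthy run).
    """
    n, d = X.shape

    # ---- k-means++ seeding ----
    centers = np.empty((G, d))
    idx0 = int(u[0] * n)
    if idx0 >= n:
        idx0 = n - 1
    for j in range(d):
        centers[0, j] = X[idx0, j]
    d2 = np.empty(n)
    for i in range(n):
        s = 0.0
        for j in range(d):
            diff = X[i, j] - centers[0, j]
            s += diff * diff
        d2[i] = s
    for g in range(1, G):
        tot = 0.0
        for i in range(n):
            tot += d2[i]
        if tot <= 0.0:
            pick = int(u[g] * n)
            if pick >= n:
                pick = n - 1
        else:
            r = u[g] * tot
            pick = n - 1
            acc = 0.0
            for i in range(n):
                acc += d2[i]
                if acc >= r:
                    pick = i
                    break
        for j in range(d):
            centers[g, j] = X[pick, j]
        for i in range(n):
            s = 0.0
            for j in range(d):
                diff = X[i, j] - centers[g, j]
                s += diff * diff
            if s < d2[i]:
                d2[i] = s

    # ---- initial parameters from hard assignment ----
    gmean = np.zeros(d)
    for j in range(d):
        s = 0.0
        for i in range(n):
            s += X[i, j]
        gmean[j] = s / n
    gcov = np.zeros((d, d))
    for i in range(n):
        for j in range(d):
            for j2 in range(d):
                gcov[j, j2] += (X[i, j] - gmean[j]) * (X[i, j2] - gmean[j2])
    for j in range(d):
        for j2 in range(d):
            gcov[j, j2] /= n
    if d == 1:
        if gcov[0, 0] < floor:
            gcov[0, 0] = floor
    else:
        a, b, c = _floor_cov2(gcov[0, 0], gcov[0, 1], gcov[1, 1], floor)
        gcov[0, 0] = a
        gcov[0, 1] = b
        gcov[1, 0] = b
        gcov[1, 1] = c

    assign = np.empty(n, np.int64)
    counts = np.zeros(G)
    for i in range(n):
        best = 0
        bd = 1e300
        for g in range(G):
            s = 0.0
            for j in range(d):
                diff = X[i, j] - centers[g, j]
                s += diff * diff
            if s < bd:
                bd = s
                best = g
        assign[i] = best
        counts[best] += 1.0

    weights = np.empty(G)
    means = centers.copy()
    covs = np.empty((G, d, d))
    for g in range(G):
        if counts[g] >= 1.0:
            weights[g] = counts[g] / n
            for j in range(d):
                s = 0.0
                for i in range(n):
                    if assign[i] == g:
                        s += X[i, j]
                means[g, j] = s / counts[g]
        else:
            weights[g] = 1.0 / n
        if counts[g] >= 2.0 * d:
            for j in range(d):
                for j2 in range(d):
                    s = 0.0
                    for i in range(n):
                        if assign[i] == g:
                            s += (X[i, j] - means[g, j]) * (X[i, j2] - means[g, j2])
                    covs[g, j, j2] = s / counts[g]
            if d == 1:
                if covs[g, 0, 0] < floor:
                    covs[g, 0, 0] = floor
            else:
                a, b, c = _floor_cov2(covs[g, 0, 0], covs[g, 0, 1], covs[g, 1, 1], floor)
                covs[g, 0, 0] = a
                covs[g, 0, 1] = b
                covs[g, 1, 0] = b
                covs[g, 1, 1] = c
        else:
            for j in range(d):
                for j2 in range(d):
                    covs[g, j, j2] = gcov[j, j2]
    wsum = 0.0
    for g in range(G):
        wsum += weights[g]
    for g in range(G):
        weights[g] /= wsum

    # ---- EM iterations ----
    logdens = np.empty((n, G))
    prev_ll = 0.0
    have_prev = False
    max_dec = 0.0
    converged = False
    n_iter = 0
    for it in range(max_iter):
        ll = _log_density_ll(X, weights, means, covs, logdens)
        if have_prev:
            if ll < prev_ll:
                dec = prev_ll - ll
                if dec > max_dec:
                    max_dec = dec
            scale = abs(ll)
            if scale < 1.0:
                scale = 1.0
            if abs(ll - prev_ll) <= tol * scale:
                converged = True
                break
        prev_ll = ll
        have_prev = True
        n_iter = it + 1
        # responsibilities in place
        for i in range(n):
            m = logdens[i, 0]
            for g in range(1, G):
                if logdens[i, g] > m:
                    m = logdens[i, g]
            s = 0.0
            for g in range(G):
                s += np.exp(logdens[i, g] - m)
            lse = m + np.log(s)
            for g in range(G):
                logdens[i, g] = np.exp(logdens[i, g] - lse)
        # M-step
        for g in range(G):
            nk = 0.0
            for i in range(n):
                nk += logdens[i, g]
            if nk < 1e-10:
                nk = 1e-10
            weights[g] = nk / n
            for j in range(d):
                s = 0.0
                for i in range(n):
                    s += logdens[i, g] * X[i, j]
                means[g, j] = s / nk
            if d == 1:
                s = 0.0
                for i in range(n):
                    diff = X[i, 0] - means[g, 0]
                    s += logdens[i, g] * diff * diff
                v = s / nk
                if v < floor:
                    v = floor
                covs[g, 0, 0] = v
            else:
                sxx = 0.0
                syy = 0.0
                sxy = 0.0
                for i in range(n):
                    dx = X[i, 0] - means[g, 0]
                    dy = X[i, 1] - means[g, 1]
                    r = logdens[i, g]
                    sxx += r * dx * dx
                    syy += r * dy * dy
                    sxy += r * dx * dy
                a, b, c = _floor_cov2(sxx / nk, sxy / nk, syy / nk, floor)
                covs[g, 0, 0] = a
                covs[g, 0, 1] = b
                covs[g, 1, 0] = b
                covs[g, 1, 1] = c
        wsum = 0.0
        for g in range(G):
            wsum += weights[g]
        for g in range(G):
            weights[g] /= wsum

    # log-likelihood of the parameters actually returned
    final_ll = _log_density_ll(X, weights, means, covs, logdens)
    if final_ll < prev_ll:
        dec = prev_ll - final_ll
        if dec > max_dec:
            max_dec = dec
    return weights, means, covs, final_ll, n_iter, converged, max_dec


@njit(cache=True)
def log_responsibilities(X, weights, means, covs):
    """Posterior component responsibilities for points X under a fitted mixture."""
    n = X.shape[0]
    G = weights.shape[0]
    logdens = np.empty((n, G))
    _log_density_ll(X, weights, means, covs, logdens)
    resp = np.empty((n, G))
    for i in range(n):
        m = logdens[i, 0]
        for g in range(1, G):
            if logdens[i, g] > m:
                m = logdens[i, g]
        s = 0.0
        for g in range(G):
            s += np.exp(logdens[i, g] - m)
        lse = m + np.log(s)
        for g in range(G):
            resp[i, g] = np.exp(logdens[i, g] - lse)
    return resp
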