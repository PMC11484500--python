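"""Jitted coordinate-descent kernels for penalized logistic regression.

The solver minimizes

    (1/n) * NLL(b0, beta; X, y)  +  lambda * P(beta)

over a column-standardized design (each column has zero mean and unit
population SD, so sum(x_j^2) == n).  Each coordinate step minimizes an
exact quadratic majorizer of the loss with curvature L = 1/4 (the global
bound on the logistic second derivative times sum(x^2)/n), so the
penalized objective is non-increasing across sweeps for both the convex
LASSO penalty and the non-convex SCAD penalty, whose one-dimensional
proximal problem is solved exactly by candidate enumeration.

Penalty codes: 0 = LASSO, 1 = SCAD.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: Curvature bound used by the majorization step (standardized columns).
_L = 0.25


@njit(cache=True)
def _soft(z, t):
    if z > t:
        return z - t
    if z < -t:
        return z + t
    return 0.0


@njit(cache=True)
def _scad_pen_1d(b, lam, a):
    ab = abs(b)
    if ab <= lam:
        return lam * ab
    if ab <= a * lam:
        return (2.0 * a * lam * ab - ab * ab - lam * lam) / (2.0 * (a - 1.0))
    return (a + 1.0) * lam * lam / 2.0


@njit(cache=True)
def _scad_prox(z, v, lam, a):
    """argmin_b v/2 (b - z)^2 + SCAD(b; lam, a), exact for any v > 0.

    For v < 1/(a-1) the subproblem is non-convex; the stationary point of
    the middle piece may be a local maximum, so all region stationary
    points and region boundaries are enumerated and compared.
    """
    if lam == 0.0:
        return z
    s = 1.0 if z >= 0.0 else -1.0
    az = abs(z)
    # candidate: b = 0
    best_b = 0.0
    best_f = 0.5 * v * az * az
    # region |b| <= lam: soft-threshold stationary point, clamped
    b1 = _soft(v * az, lam) / v
    if b1 > lam:
        b1 = lam
    f1 = 0.5 * v * (b1 - az) ** 2 + lam * b1
    if f1 < best_f:
        best_f = f1
        best_b = b1
    # region lam < b <= a*lam: stationary point of the quadratic piece
    denom = v * (a - 1.0) - 1.0
    if denom != 0.0:
        b2 = (v * az * (a - 1.0) - a * lam) / denom
        if b2 < lam:
            b2 = lam
        elif b2 > a * lam:
            b2 = a * lam
        f2 = 0.5 * v * (b2 - az) ** 2 + _scad_pen_1d(b2, lam, a)
        if f2 < best_f:
            best_f = f2
            best_b = b2
    # region boundaries (minima when the middle piece is concave)
    fb = 0.5 * v * (lam - az) ** 2 + _scad_pen_1d(lam, lam, a)
    if fb < best_f:
        best_f = fb
        best_b = lam
    fb = 0.5 * v * (a * lam - az) ** 2 + _scad_pen_1d(a * lam, lam, a)
    if fb < best_f:
        best_f = fb
        best_b = a * lam
    # region b > a*lam: flat penalty, stationary at z
    b3 = az
    if b3 < a * lam:
        b3 = a * lam
    f3 = 0.5 * v * (b3 - az) ** 2 + (a + 1.0) * lam * lam / 2.0
    if f3 < best_f:
        best_f = f3
        best_b = b3
    return s * best_b


@njit(cache=True)
def _objective(y, eta, beta, lam, pen_kind, a):
    n = eta.shape[0]
    nll = 0.0
    for i in range(n):
        e = eta[i]
        # log(1 + exp(e)) - y*e, computed stably
        if e > 0.0:
            nll += e + np.log1p(np.exp(-e)) - y[i] * e
        else:
            nll += np.log1p(np.exp(e)) - y[i] * e
    obj = nll / n
    for j in range(beta.shape[0]):
        if beta[j] != 0.0:
            if pen_kind == 0:
                obj += lam * abs(beta[j])
            else:
                obj += _scad_pen_1d(beta[j], lam, a)
    return obj


@njit(cache=True)
def _sweep(X, y, eta, mu, beta, b0, lam, pen_kind, a, use_active, active):
    """One coordinate-descent sweep (intercept + features); returns
    (max abs change, new intercept)."""
    n, p = X.shape
    maxd = 0.0
    # unpenalized intercept step
    g0 = 0.0
    for i in range(n):
        g0 += mu[i] - y[i]
    g0 /= n
    d0 = -g0 / _L
    if d0 != 0.0:
        b0 += d0
        for i in range(n):
            eta[i] += d0
            mu[i] = 1.0 / (1.0 + np.exp(-eta[i]))
        ad = abs(d0)
        if ad > maxd:
            maxd = ad
    for j in range(p):
        if use_active and active[j] == 0:
            continue
        g = 0.0
        for i in range(n):
            g += X[i, j] * (mu[i] - y[i])
        g /= n
        z = beta[j] - g / _L
        if pen_kind == 0:
            bnew = _soft(z, lam / _L)
        else:
            bnew = _scad_prox(z, _L, lam, a)
        d = bnew - beta[j]
        if d != 0.0:
            beta[j] = bnew
            for i in range(n):
                eta[i] += d * X[i, j]
                mu[i] = 1.0 / (1.0 + np.exp(-eta[i]))
            ad = abs(d)
            if ad > maxd:
                maxd = ad
        if bnew != 0.0:
            active[j] = 1
    return maxd, b0


@njit(cache=True)
def cd_solve(X, y, lam, pen_kind, a, tol, max_iter, b0_init, beta_init,
             track_objective):
    """Coordinate descent at a single lambda on standardized X.

    Returns (b0, beta, n_sweeps, converged, objective_history) where the
    history holds the penalized objective after each sweep (length
    n_sweeps + 1, leading entry = objective at the initial point) when
    ``track_objective``; otherwise a length-1 array with the final value.
    """
    n, p = X.shape
    beta = beta_init.copy()
    b0 = b0_init
    eta = np.empty(n)
    mu = np.empty(n)
    for i in range(n):
        e = b0
        for j in range(p):
            if beta[j] != 0.0:
                e += X[i, j] * beta[j]
        eta[i] = e
        mu[i] = 1.0 / (1.0 + np.exp(-eta[i]))
    active = np.zeros(p, dtype=np.uint8)
    for j in range(p):
        if beta[j] != 0.0:
            active[j] = 1
    hist = np.empty(max_iter + 1 if track_objective else 1)
    nh = 0
    if track_objective:
        hist[0] = _objective(y, eta, beta, lam, pen_kind, a)
        nh = 1
    n_sweeps = 0
    converged = False
    while n_sweeps < max_iter:
        # full sweep over all coordinates (also refreshes the active set)
        maxd, b0 = _sweep(X, y, eta, mu, beta, b0, lam, pen_kind, a,
                          False, active)
        n_sweeps += 1
        if track_objective:
            hist[nh] = _objective(y, eta, beta, lam, pen_kind, a)
            nh += 1
        if maxd < tol:
            converged = True
            break
        # cycle the active set until stable, then re-check with a full sweep
        while n_sweeps < max_iter:
            maxd, b0 = _sweep(X, y, eta, mu, beta, b0, lam, pen_kind, a,
                              True, active)
            n_sweeps += 1
            if track_objective:
                hist[nh] = _objective(y, eta, beta, lam, pen_kind, a)
                nh += 1
            if maxd < tol:
                break
    if not track_objective:
        hist[0] = _objective(y, eta, beta, lam, pen_kind, a)
        nh = 1
    return b0, beta, n_sweeps, converged, hist[:nh]


@njit(cache=True)
def scad_multistart(X, y, lam, a, tol, max_iter, b0_a, beta_a, b0_b, beta_b):
    """Descend the (non-convex) SCAD objective from two starts and keep
    the stationary point with the lower penalized objective."""
    b0_1, be1, it1, cv1, h1 = cd_solve(X, y, lam, 1, a, tol, max_iter,
                                       b0_a, beta_a, False)
    b0_2, be2, it2, cv2, h2 = cd_solve(X, y, lam, 1, a, tol, max_iter,
                                       b0_b, beta_b, False)
    if h2[0] < h1[0]:
        return b0_2, be2, it1 + it2, cv2
    return b0_1, be1, it1 + it2, cv1


@njit(cache=True)
def cd_path(X, y, lambdas, pen_kind, a, tol, max_iter, dev_max=0.999):
    """Warm-started pathwise fit over a decreasing lambda grid.

    For SCAD, a LASSO path is maintained alongside and the SCAD solve at
    each lambda is initialized from the LASSO solution at that lambda
    (one-step local-linear-approximation flavor, then descended to a
    stationary point of the SCAD objective).

    The path is truncated once the fitted deviance ratio
    1 - NLL/NLL_null exceeds ``dev_max`` (the saturated, typically
    separable regime); remaining grid entries repeat the last solution.

    Returns (intercepts, coefficient matrix n_lambda x p, sweep counts,
    convergence flags), all on the standardized scale.
    """
    n, p = X.shape
    nl = lambdas.shape[0]
    B = np.zeros((nl, p))
    b0s = np.zeros(nl)
    iters = np.zeros(nl, dtype=np.int64)
    conv = np.zeros(nl, dtype=np.uint8)
    ybar = 0.0
    for i in range(n):
        ybar += y[i]
    ybar /= n
    b0_start = np.log(ybar / (1.0 - ybar))
    null_nll = _objective(y, np.full(n, b0_start), np.zeros(1), 0.0, 0, a)
    beta_lasso = np.zeros(p)
    b0_lasso = b0_start
    beta = np.zeros(p)
    b0 = b0_start
    for k in range(nl):
        lam = lambdas[k]
        if pen_kind == 1:
            b0_lasso, beta_lasso, _, _, _ = cd_solve(
                X, y, lam, 0, a, tol, max_iter, b0_lasso, beta_lasso, False)
            # two starts: LLA-style (lasso at this lambda) and the warm
            # previous-lambda SCAD solution; keep the better minimum
            b0, beta, it, cv = scad_multistart(
                X, y, lam, a, tol, max_iter, b0_lasso, beta_lasso, b0, beta)
        else:
            b0, beta, it, cv, _ = cd_solve(
                X, y, lam, 0, a, tol, max_iter, b0, beta, False)
        b0s[k] = b0
        B[k, :] = beta
        iters[k] = it
        conv[k] = cv
        nll = _objective(y, b0 + X @ beta, np.zeros(1), 0.0, 0, a)
        if null_nll > 0.0 and 1.0 - nll / null_nll > dev_max:
            for kk in range(k + 1, nl):
                b0s[kk] = b0
                B[kk, :] = beta
                conv[kk] = cv
            break
    return b0s, B, iters, conv
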