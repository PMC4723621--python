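"""Compiled numerical core for PLS-DA and nested cross-validation.

All kernels operate on plain float64 arrays and are numba-compiled because
the permutation test re-runs the full double cross-validation (n outer folds,
each with an n-1 fold inner leave-one-out) for every label permutation —
tens of thousands of PLS fits per analysis.

Conventions fixed here so results are reproducible across backends:
- column scaling uses the sample SD (n-1 denominator); zero-variance columns
  get SD 1, i.e. they center to all-zero and carry no weight;
- NIPALS PLS2 deflates X only (Y is not deflated);
- class assignment is argmax of the predicted indicators, ties going to the
  lowest class index.
"""

import numpy as np
from numba import njit

NIPALS_TOL = 1e-12
NIPALS_MAX_ITER = 500


@njit(cache=True)
def scale_columns(X):
    """Column means and sample SDs (ddof=1); SD 0 is replaced by 1."""
    n, p = X.shape
    mean = np.empty(p)
    sd = np.empty(p)
    for j in range(p):
        m = 0.0
        for i in range(n):
            m += X[i, j]
        m /= n
        v = 0.0
        for i in range(n):
            d = X[i, j] - m
            v += d * d
        s = np.sqrt(v / (n - 1)) if n > 1 else 0.0
        if s <= 0.0:
            s = 1.0
        mean[j] = m
        sd[j] = s
    return mean, sd


@njit(cache=True)
def nipals_pls2(X, Y, n_components, tol, max_iter):
    """NIPALS PLS2 on pre-scaled X and pre-centered Y, X-deflation only.

    Returns (W, P, Q, T) truncated to the number of components actually
    extracted (the iteration stops early when X or Y is exhausted).
    """
    n, p = X.shape
    K = Y.shape[1]
    Xd = X.copy()
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros((K, n_components))
    T = np.zeros((n, n_components))
    a_used = 0
    for a in range(n_components):
        # start u from the Y column with the largest sum of squares
        best = 0
        best_ss = -1.0
        for k in range(K):
            ss = 0.0
            for i in range(n):
                ss += Y[i, k] * Y[i, k]
            if ss > best_ss:
                best_ss = ss
                best = k
        if best_ss <= 1e-30:
            break
        u = Y[:, best].copy()
        t = np.zeros(n)
        t_old = np.zeros(n)
        w = np.zeros(p)
        ok = False
        for _ in range(max_iter):
            w = np.dot(u, Xd)  # X^T u
            wn = np.sqrt(np.dot(w, w))
            if wn <= 1e-30:
                break
            w = w / wn
            t = np.dot(Xd, w)
            tt = np.dot(t, t)
            if tt <= 1e-30:
                break
            q = np.dot(t, Y) / tt  # Y^T t / t^T t
            qq = np.dot(q, q)
            if qq <= 1e-30:
                break
            u = np.dot(Y, q) / qq
            ok = True
            diff = 0.0
            for i in range(n):
                d = t[i] - t_old[i]
                diff += d * d
            if np.sqrt(diff) <= tol * np.sqrt(tt):
                break
            for i in range(n):
                t_old[i] = t[i]
        if not ok:
            break
        tt = np.dot(t, t)
        if tt <= 1e-30:
            break
        q = np.dot(t, Y) / tt
        pvec = np.dot(t, Xd) / tt
        Xd -= np.outer(t, pvec)
        W[:, a] = w
        P[:, a] = pvec
        Q[:, a] = q
        T[:, a] = t
        a_used = a + 1
    return (
        np.ascontiguousarray(W[:, :a_used]),
        np.ascontiguousarray(P[:, :a_used]),
        np.ascontiguousarray(Q[:, :a_used]),
        np.ascontiguousarray(T[:, :a_used]),
    )


@njit(cache=True)
def pls_coefficients(W, P, Q):
    """Closed-form regression coefficients B = W (P^T W)^-1 Q^T."""
    p, A = W.shape
    K = Q.shape[0]
    if A == 0:
        return np.zeros((p, K))
    M = np.dot(P.T.copy(), W)  # A x A
    R = np.dot(W, np.linalg.inv(M))
    return np.dot(R, Q.T.copy())


@njit(cache=True)
def predict_path(W, P, Q, x):
    """Cumulative predictions for one scaled sample after 1..A components.

    Uses the deflation sequence (no matrix inversion); row a-1 of the result
    equals x @ B_a on the centered-Y scale.
    """
    p, A = W.shape
    K = Q.shape[0]
    out = np.zeros((A, K))
    xd = x.copy()
    acc = np.zeros(K)
    for a in range(A):
        t = 0.0
        for j in range(p):
            t += xd[j] * W[j, a]
        for j in range(p):
            xd[j] -= t * P[j, a]
        for k in range(K):
            acc[k] += t * Q[k, a]
            out[a, k] = acc[k]
    return out


@njit(cache=True)
def _drop_row(X, Y, skip):
    n, p = X.shape
    K = Y.shape[1]
    Xt = np.empty((n - 1, p))
    Yt = np.empty((n - 1, K))
    r = 0
    for i in range(n):
        if i == skip:
            continue
        for j in range(p):
            Xt[r, j] = X[i, j]
        for k in range(K):
            Yt[r, k] = Y[i, k]
        r += 1
    return Xt, Yt


@njit(cache=True)
def _fit_scaled(Xt, Yt, n_components):
    """Scale Xt / center Yt, fit PLS; returns model + scaling parameters."""
    mean, sd = scale_columns(Xt)
    Xs = (Xt - mean) / sd
    K = Yt.shape[1]
    ym = np.empty(K)
    for k in range(K):
        ym[k] = Yt[:, k].mean()
    Yc = Yt - ym
    W, P, Q, T = nipals_pls2(Xs, Yc, n_components, NIPALS_TOL, NIPALS_MAX_ITER)
    return W, P, Q, mean, sd, ym


@njit(cache=True)
def inner_loo_select(X, Y, a_max):
    """Inner leave-one-out selection of the latent-variable count.

    X, Y are the outer training fold (raw X, 0/1 indicator Y). Each inner
    fold rescales on its own n-2 training rows. Returns the component count
    in 1..a_max with the fewest inner misclassifications, ties broken toward
    fewer components.
    """
    n, p = X.shape
    err = np.zeros(a_max, dtype=np.int64)
    for j in range(n):
        Xt, Yt = _drop_row(X, Y, j)
        a_eff = min(a_max, min(n - 2, p))
        W, P, Q, mean, sd, ym = _fit_scaled(Xt, Yt, a_eff)
        a_used = W.shape[1]
        xs = (X[j] - mean) / sd
        path = predict_path(W, P, Q, xs)
        true_k = np.argmax(Y[j])
        for a in range(a_max):
            if a_used == 0:
                pred = np.argmax(ym)
            else:
                ai = a if a < a_used else a_used - 1
                yhat = path[ai] + ym
                pred = np.argmax(yhat)
            if pred != true_k:
                err[a] += 1
    best = 0
    for a in range(1, a_max):
        if err[a] < err[best]:
            best = a
    return best + 1


@njit(cache=True)
def double_cv_kernel(X, Y, a_max, compute_b):
    """Two-nested leave-one-out PLS-DA.

    For each sample: set it aside, select the component count by inner LOO on
    the remaining n-1 samples, refit on those n-1 samples (with their own
    scaling), and predict the left-out sample.

    Returns (predicted class index per sample, selected component count per
    sample, coefficient matrices (n, p, K), continuous predictions (n, K)).
    """
    n, p = X.shape
    K = Y.shape[1]
    pred = np.empty(n, dtype=np.int64)
    sel = np.empty(n, dtype=np.int64)
    B_all = np.zeros((n, p, K))
    yhat_all = np.zeros((n, K))
    for i in range(n):
        Xt, Yt = _drop_row(X, Y, i)
        n_train = n - 1
        a_cap = min(a_max, min(n_train - 2, p))
        if a_cap < 1:
            a_cap = 1
        a_sel = inner_loo_select(Xt, Yt, a_cap)
        W, P, Q, mean, sd, ym = _fit_scaled(Xt, Yt, a_sel)
        a_used = W.shape[1]
        xs = (X[i] - mean) / sd
        if a_used == 0:
            yhat = ym.copy()
        else:
            path = predict_path(W, P, Q, xs)
            yhat = path[a_used - 1] + ym
        pred[i] = np.argmax(yhat)
        sel[i] = a_sel
        yhat_all[i] = yhat
        if compute_b:
            B_all[i] = pls_coefficients(W, P, Q)
    return pred, sel, B_all, yhat_all
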