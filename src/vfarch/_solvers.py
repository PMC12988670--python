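"""Compiled kernels for simplex-constrained least squares.

The public contract lives in :mod:`vfarch.archetypal`; this module only
holds the numba-compiled inner loops.  The route is: non-negative least
squares on the sum-constraint-augmented normal equations (penalty row of
magnitude ``M``), exact renormalization, then an exact KKT active-set
polish of the detected support so the result matches the true constrained
optimum to solver precision rather than to O(1/M^2).
"""

from __future__ import annotations

import numpy as np
from numba import njit

_NNLS_TOL_SCALE = 1e-11


@njit(cache=True)
def _gauss_solve(A, b):
    """In-place Gaussian elimination with partial pivoting; returns (x, ok).

    A and b are scratch copies owned by the caller.  Singular (to machine
    tolerance) systems report ok=False.
    """
    n = A.shape[0]
    x = np.zeros(n)
    for col in range(n):
        piv = col
        best = abs(A[col, col])
        for r in range(col + 1, n):
            v = abs(A[r, col])
            if v > best:
                best = v
                piv = r
        if best < 1e-13:
            return x, False
        if piv != col:
            for c in range(col, n):
                tmp = A[col, c]
                A[col, c] = A[piv, c]
                A[piv, c] = tmp
            tmp = b[col]
            b[col] = b[piv]
            b[piv] = tmp
        inv = 1.0 / A[col, col]
        for r in range(col + 1, n):
            f = A[r, col] * inv
            if f != 0.0:
                for c in range(col, n):
                    A[r, c] -= f * A[col, c]
                b[r] -= f * b[col]
    for r in range(n - 1, -1, -1):
        s = b[r]
        for c in range(r + 1, n):
            s -= A[r, c] * x[c]
        x[r] = s / A[r, r]
    return x, True


@njit(cache=True)
def _solve_sub(G, h, idx):
    """Solve G[idx, idx] s = h[idx]; tiny ridge retry on rank deficiency."""
    k = idx.size
    Gs = np.empty((k, k))
    hs = np.empty(k)
    for a in range(k):
        hs[a] = h[idx[a]]
        for b in range(k):
            Gs[a, b] = G[idx[a], idx[b]]
    s, ok = _gauss_solve(Gs.copy(), hs.copy())
    if not ok:
        ridge = 1e-10 * (np.trace(Gs) / k + 1.0)
        for a in range(k):
            Gs[a, a] += ridge
        s, ok = _gauss_solve(Gs, hs)
    return s


@njit(cache=True)
def _sparse_grad(G, h, w, idx):
    """h - G[:, idx] @ w[idx] without touching zero weights."""
    m = h.size
    grad = h.copy()
    for a in range(idx.size):
        j = idx[a]
        wj = w[j]
        if wj != 0.0:
            for r in range(m):
                grad[r] -= G[r, j] * wj
    return grad


@njit(cache=True)
def _fnnls(G, h):
    """NNLS in normal-equation form (Bro & de Jong): min ||Aw-b||^2, w >= 0,
    given G = A'A and h = A'b."""
    m = G.shape[0]
    w = np.zeros(m)
    passive = np.zeros(m, np.bool_)
    grad = h.copy()
    tol = _NNLS_TOL_SCALE * max(1.0, np.abs(h).max())
    outer = 0
    while outer < 3 * m + 30:
        outer += 1
        jbest = -1
        gbest = tol
        for j in range(m):
            if not passive[j] and grad[j] > gbest:
                gbest = grad[j]
                jbest = j
        if jbest < 0:
            break
        passive[jbest] = True
        inner = 0
        while inner < 3 * m + 30:
            inner += 1
            idx = np.where(passive)[0]
            s = _solve_sub(G, h, idx)
            if s.min() > 0.0:
                w[:] = 0.0
                for a in range(idx.size):
                    w[idx[a]] = s[a]
                break
            # step towards s until the first coordinate hits zero
            alpha = 1.0
            for a in range(idx.size):
                if s[a] <= 0.0:
                    wj = w[idx[a]]
                    denom = wj - s[a]
                    if denom > 0.0:
                        step = wj / denom
                        if step < alpha:
                            alpha = step
            for a in range(idx.size):
                j = idx[a]
                w[j] = w[j] + alpha * (s[a] - w[j])
                if w[j] <= 1e-14:
                    w[j] = 0.0
                    passive[j] = False
        idx = np.where(passive)[0]
        grad = _sparse_grad(G, h, w, idx)
    return w


@njit(cache=True)
def _kkt_polish(G, h, w0):
    """Exact active-set solve of min w'Gw - 2h'w s.t. sum(w)=1, w>=0.

    Warm-started from the support of ``w0``.  KKT stationarity on the
    support S: 2 G_SS w_S - lam * 1 = 2 h_S, sum(w_S) = 1; a variable j
    outside S violates optimality when 2 (Gw - h)_j < lam.
    """
    m = w0.size
    active = w0 > 1e-9
    if not np.any(active):
        active[np.argmax(h)] = True
    w = np.zeros(m)
    for _ in range(6 * m + 40):
        idx = np.where(active)[0]
        k = idx.size
        K = np.zeros((k + 1, k + 1))
        rhs = np.zeros(k + 1)
        for a in range(k):
            rhs[a] = 2.0 * h[idx[a]]
            K[a, k] = -1.0
            K[k, a] = 1.0
            for b in range(k):
                K[a, b] = 2.0 * G[idx[a], idx[b]]
        rhs[k] = 1.0
        sol, ok = _gauss_solve(K, rhs)
        if not ok:
            # rank-deficient support: fall back to the warm start
            return w0
        wS = sol[:k]
        lam = sol[k]
        if k > 1 and wS.min() < -1e-12:
            drop = idx[np.argmin(wS)]
            active[drop] = False
            continue
        w[:] = 0.0
        for a in range(k):
            w[idx[a]] = wS[a] if wS[a] > 0.0 else 0.0
        ssum = w.sum()
        if ssum > 0.0:
            w /= ssum
        grad = _sparse_grad(G, h, w, idx)  # = h - Gw; optimality: 2(Gw-h)_j >= lam
        jadd = -1
        worst = -1e-9 * max(1.0, abs(lam))
        for j in range(m):
            if not active[j]:
                v = -2.0 * grad[j] - lam
                if v < worst:
                    worst = v
                    jadd = j
        if jadd < 0:
            break
        active[jadd] = True
    return w


@njit(cache=True)
def simplex_ls_gram(G0, H0T, tt, penalty):
    """Batched simplex-constrained least squares from Gram-form inputs.

    Parameters
    ----------
    G0 : (m, m) basis Gram matrix ``B @ B.T`` (no penalty term).
    H0T : (p, m) cross products ``T @ B.T`` for the p targets.
    tt : (p,) squared norms of the targets.
    penalty : augmented-row magnitude M.

    Returns ``(W, R)`` with W of shape (p, m) simplex rows and R the squared
    residuals of the renormalized, polished solutions.
    """
    p, m = H0T.shape
    M2 = penalty * penalty
    Ga = G0 + M2
    W = np.zeros((p, m))
    R = np.empty(p)
    for j in range(p):
        h0 = H0T[j]
        w = _fnnls(Ga, h0 + M2)
        s = w.sum()
        if s > 0.0:
            w = w / s
        else:  # pathological; fall back to the nearest single basis row
            w = np.zeros(m)
            w[np.argmax(h0)] = 1.0
        w = _kkt_polish(G0, h0, w)
        r = tt[j] - 2.0 * (w @ h0) + w @ (G0 @ w)
        W[j] = w
        R[j] = r if r > 0.0 else 0.0
    return W, R


def simplex_ls_batch(targets: np.ndarray, basis: np.ndarray, penalty: float):
    """Convenience wrapper computing the Gram-form inputs from dense arrays."""
    B = np.ascontiguousarray(basis, dtype=np.float64)
    T = np.ascontiguousarray(targets, dtype=np.float64)
    G0 = B @ B.T
    H0T = np.ascontiguousarray(T @ B.T)
    tt = np.einsum("ij,ij->i", T, T)
    return simplex_ls_gram(np.ascontiguousarray(G0), H0T, tt, float(penalty))
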