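"""Small dense linear C-SVM used inside the nested cross-validation loops.

Solves the standard C-SVC dual (the same optimization problem libsvm
solves) with an SMO working-set scheme, JIT-compiled with numba so that
the tens of thousands of tiny fits performed by the inner LOO loops and
the permutation test stay cheap.  Agreement of the resulting hyperplane
with ``sklearn.svm.SVC(kernel='linear')`` is asserted in the test suite.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return deco


@njit(cache=True)
def _smo(K, y, C, tol, max_iter):  # pragma: no cover - numba kernel
    n = K.shape[0]
    eps = 1e-9 * C
    alpha = np.zeros(n)
    # u_i = sum_j alpha_j y_j K_ij (decision values without bias)
    u = np.zeros(n)
    it = 0
    while it < max_iter:
        it += 1
        # maximal-violating pair on E_t = y_t - u_t
        i = -1
        j = -1
        gmax = -1e300
        gmin = 1e300
        for t in range(n):
            e = y[t] - u[t]
            up = (y[t] > 0 and alpha[t] < C - eps) or (y[t] < 0 and alpha[t] > eps)
            lo = (y[t] < 0 and alpha[t] < C - eps) or (y[t] > 0 and alpha[t] > eps)
            if up and e > gmax:
                gmax = e
                i = t
            if lo and e < gmin:
                gmin = e
                j = t
        if i < 0 or j < 0 or gmax - gmin < tol:
            break
        eta = K[i, i] + K[j, j] - 2.0 * K[i, j]
        if eta <= 1e-12:
            eta = 1e-12
        ai_old = alpha[i]
        aj_old = alpha[j]
        ei = u[i] - y[i]
        ej = u[j] - y[j]
        aj_new = aj_old + y[j] * (ei - ej) / eta
        if y[i] != y[j]:
            L = max(0.0, aj_old - ai_old)
            H = min(C, C + aj_old - ai_old)
        else:
            L = max(0.0, ai_old + aj_old - C)
            H = min(C, ai_old + aj_old)
        if aj_new < L:
            aj_new = L
        elif aj_new > H:
            aj_new = H
        if abs(aj_new - aj_old) < 1e-14:
            break  # maximal violating pair blocked at machine precision
        ai_new = ai_old + y[i] * y[j] * (aj_old - aj_new)
        # snap to the box to keep bound-membership tests exact
        if aj_new < eps:
            aj_new = 0.0
        elif aj_new > C - eps:
            aj_new = C
        if ai_new < eps:
            ai_new = 0.0
        elif ai_new > C - eps:
            ai_new = C
        alpha[i] = ai_new
        alpha[j] = aj_new
        di = (ai_new - ai_old) * y[i]
        dj = (aj_new - aj_old) * y[j]
        for t in range(n):
            u[t] += di * K[i, t] + dj * K[j, t]
    # bias: average y - u over free support vectors, else midpoint of bounds
    nfree = 0
    bsum = 0.0
    for t in range(n):
        if eps < alpha[t] < C - eps:
            bsum += y[t] - u[t]
            nfree += 1
    if nfree > 0:
        b = bsum / nfree
    else:
        gmax = -1e300
        gmin = 1e300
        for t in range(n):
            e = y[t] - u[t]
            up = (y[t] > 0 and alpha[t] < C - eps) or (y[t] < 0 and alpha[t] > eps)
            lo = (y[t] < 0 and alpha[t] < C - eps) or (y[t] > 0 and alpha[t] > eps)
            if up and e > gmax:
                gmax = e
            if lo and e < gmin:
                gmin = e
        b = (gmax + gmin) / 2.0
    return alpha, b


def linear_svm_fit(X: np.ndarray, y_signed: np.ndarray, C: float = 1.0,
                   tol: float = 1e-4, max_iter: int = 20000):
    """Fit a linear C-SVM; returns (weights, bias).

    ``y_signed`` must contain both -1 and +1.  Deterministic for fixed
    input (SMO with maximal-violating-pair selection has no randomness).
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y_signed = np.ascontiguousarray(y_signed, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    if not (np.any(y_signed > 0) and np.any(y_signed < 0)):
        raise ValueError("training set contains a single class")
    K = X @ X.T
    alpha, b = _smo(K, y_signed, float(C), float(tol), int(max_iter))
    w = (alpha * y_signed) @ X
    return w, float(b)
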