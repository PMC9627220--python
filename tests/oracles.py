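"""Independent reference implementations used only as test oracles."""

import numpy as np


def svd_pls1(X, y, n_components):
    """PLS1 via explicit SVD of the residual cross-covariance per component.

    Independent of the package's NIPALS loop: each weight vector is the
    dominant left singular vector of X_a^T y_a (sign-fixed to positive
    covariance), with explicit deflation.  Autoscaling matches the
    documented convention (ddof=1).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    ys = (y - y.mean()) / y.std(ddof=1)
    n, p = Xs.shape
    Xa, ya = Xs.copy(), ys.copy()
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros(n_components)
    T = np.zeros((n, n_components))
    for a in range(n_components):
        c = (Xa.T @ ya)[:, None]  # p x 1 cross-covariance
        U, s, Vt = np.linalg.svd(c, full_matrices=False)
        w = U[:, 0]
        if w @ (Xa.T @ ya) < 0:
            w = -w
        t = Xa @ w
        tt = t @ t
        pa = Xa.T @ t / tt
        qa = (ya @ t) / tt
        Xa = Xa - np.outer(t, pa)
        ya = ya - qa * t
        W[:, a], P[:, a], Q[a], T[:, a] = w, pa, qa, t
    coef = W @ np.linalg.solve(P.T @ W, Q)
    return {"W": W, "P": P, "Q": Q, "T": T, "coef": coef}


def naive_grey_degree(x0, X, rho=0.5):
    """Deng's relational coefficients by direct double loops over s and t."""
    x0 = np.asarray(x0, float)
    X = np.asarray(X, float)
    N, p = X.shape
    deltas = [[abs(x0[t] - X[t, s]) for t in range(N)] for s in range(p)]
    dmin = min(min(row) for row in deltas)
    dmax = max(max(row) for row in deltas)
    coeff = np.empty((N, p))
    for s in range(p):
        for k in range(N):
            coeff[k, s] = (dmin + rho * dmax) / (deltas[s][k] + rho * dmax)
    return coeff, coeff.mean(axis=0)


def grid_search_ic50(conc, resp, n_grid=400):
    """Brute-force 4PL least squares on a (logIC50, hill) grid with the
    floor/ceiling profiled out by OLS for each grid point."""
    conc = np.asarray(conc, float)
    resp = np.asarray(resp, float)
    logc = np.log10(conc)
    best = (None, np.inf)
    for logic50 in np.linspace(logc.min() - 1, logc.max() + 1, n_grid):
        for hill in np.linspace(0.2, 4.0, 60):
            f = 1.0 / (1.0 + 10 ** ((logic50 - logc) * hill))
            # resp ~ floor + (ceiling - floor) * f  -> linear in (floor, span)
            A = np.column_stack([np.ones_like(f), f])
            beta, *_ = np.linalg.lstsq(A, resp, rcond=None)
            rss = float(((A @ beta - resp) ** 2).sum())
            if rss < best[1]:
                best = (10 ** logic50, rss)
    return best
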