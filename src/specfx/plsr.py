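"""NIPALS PLS1 regression, VIP scores, cross-validated Q2 and peak selection.

Activities are regressed on autoscaled peak areas by NIPALS partial least
squares with a single response.  Variable importance follows Wold's VIP,

    VIP_j = sqrt( p * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a ),

where SSY_a is the response sum of squares explained by component a, so
that sum_j VIP_j^2 = p.  Predictive ability is the leave-one-out Q2 =
1 - PRESS/TSS with full refitting per fold; the component count A is the
smallest whose Q2 sits within 0.01 of the maximum over A <= 5.  A peak is
selected when VIP > 1 *and* its regression coefficient is positive
(screening for positive correlation with activity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SpecfxError


def _autoscale(M: np.ndarray):
    mean = M.mean(axis=0)
    std = M.std(axis=0, ddof=1)
    return mean, std


@dataclass
class PLSModel:
    """A fitted NIPALS PLS1 decomposition on autoscaled data."""

    n_components: int
    feature_names: list[str]
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    y_std: float
    weights: np.ndarray    # p x A, unit columns
    x_loadings: np.ndarray  # p x A
    y_loadings: np.ndarray  # A
    scores: np.ndarray     # n x A
    coef_scaled: np.ndarray  # p, on autoscaled predictors
    ssy: np.ndarray        # A, explained response SS per component (scaled units)
    r2x: float
    r2y: float

    @property
    def coefficients(self) -> pd.Series:
        return pd.Series(self.coef_scaled, index=self.feature_names,
                         name="coef_autoscaled")

    def predict(self, X) -> np.ndarray:
        Xs = (np.asarray(X, float) - self.x_mean) / self.x_std
        return self.y_mean + self.y_std * (Xs @ self.coef_scaled)


def pls_fit(X, y, n_components: int) -> PLSModel:
    """Fit PLS1 by NIPALS on internally autoscaled X and y."""
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [f"x{j}" for j in
                                                                 range(np.shape(X)[1])]
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.shape[0] != n:
        raise SpecfxError("X and y have different numbers of samples")
    std = X.std(axis=0, ddof=1)
    keep = std > 0
    if not keep.all():
        dropped = [names[j] for j in range(p) if not keep[j]]
        warnings.warn(f"dropping zero-variance predictor(s): {dropped}")
        X = X[:, keep]
        names = [nm for nm, k in zip(names, keep) if k]
        n, p = X.shape
    if p == 0:
        raise SpecfxError("no predictors with nonzero variance")
    if not 1 <= n_components <= min(n - 1, p):
        raise SpecfxError(
            f"n_components must be in [1, min(n-1, p)] = [1, {min(n - 1, p)}]")
    if y.std(ddof=1) == 0:
        raise SpecfxError("response has zero variance")

    x_mean, x_std = _autoscale(X)
    y_mean, y_std = float(y.mean()), float(y.std(ddof=1))
    Xs = (X - x_mean) / x_std
    ys = (y - y_mean) / y_std
    ssx_total = float((Xs ** 2).sum())
    ssy_total = float((ys ** 2).sum())

    A = n_components
    W = np.zeros((p, A))
    P = np.zeros((p, A))
    Q = np.zeros(A)
    T = np.zeros((n, A))
    ssy = np.zeros(A)
    Xa, ya = Xs.copy(), ys.copy()
    for a in range(A):
        w = Xa.T @ ya
        norm = np.linalg.norm(w)
        if norm == 0:
            # residual response orthogonal to X: truncate
            A = a
            break
        w /= norm
        t = Xa @ w
        tt = float(t @ t)
        if tt == 0:
            A = a
            break
        pa = Xa.T @ t / tt
        qa = float(ya @ t) / tt
        Xa = Xa - np.outer(t, pa)
        ya = ya - qa * t
        W[:, a], P[:, a], Q[a], T[:, a] = w, pa, qa, t
        ssy[a] = qa ** 2 * tt
    if A == 0:
        raise SpecfxError("response is orthogonal to all predictors")
    W, P, Q, T, ssy = W[:, :A], P[:, :A], Q[:A], T[:, :A], ssy[:A]
    coef = W @ np.linalg.solve(P.T @ W, Q)
    r2x = 1.0 - float((Xa ** 2).sum()) / ssx_total
    r2y = float(ssy.sum()) / ssy_total
    return PLSModel(n_components=A, feature_names=names, x_mean=x_mean, x_std=x_std,
                    y_mean=y_mean, y_std=y_std, weights=W, x_loadings=P,
                    y_loadings=Q, scores=T, coef_scaled=coef, ssy=ssy,
                    r2x=r2x, r2y=r2y)


def vip_scores(model: PLSModel) -> pd.Series:
    """Wold VIP per predictor; satisfies sum(VIP^2) = p."""
    ssy_sum = model.ssy.sum()
    if ssy_sum <= 0:
        raise SpecfxError("model explains no response variance; VIP undefined")
    p = len(model.feature_names)
    wnorm2 = (model.weights ** 2).sum(axis=0)  # = 1 per component, kept explicit
    contrib = (model.weights ** 2 / wnorm2) @ model.ssy
    vip = np.sqrt(p * contrib / ssy_sum)
    return pd.Series(vip, index=model.feature_names, name="VIP")


@dataclass
class Q2Result:
    q2_by_components: pd.Series
    n_components: int
    q2: float


def cv_q2(X, y, max_components: int = 5, tol: float = 0.01) -> Q2Result:
    """Leave-one-out Q2 = 1 - PRESS/TSS with per-fold refitting.

    The chosen component count is the smallest A whose Q2 is within ``tol``
    of the maximum over A <= ``max_components`` (plateau rule).
    """
    Xarr = np.asarray(X, dtype=float)
    yarr = np.asarray(y, dtype=float).ravel()
    n, p = Xarr.shape
    if n < 3:
        raise SpecfxError("need at least 3 samples for cross-validation")
    amax = min(max_components, n - 2, p)
    press = np.zeros(amax)
    for i in range(n):
        mask = np.arange(n) != i
        Xtr, ytr = Xarr[mask], yarr[mask]
        if ytr.std(ddof=1) == 0:
            raise SpecfxError("a cross-validation fold has zero response variance")
        model = pls_fit(pd.DataFrame(Xtr, columns=list(pd.Index(range(p)).astype(str))),
                        ytr, n_components=min(amax, Xtr.shape[0] - 1))
        # per-component predictions from the same NIPALS pass
        keepnames = model.feature_names
        cols = [int(nm) for nm in keepnames]
        xs = (Xarr[i, cols] - model.x_mean) / model.x_std
        for a in range(amax):
            aa = min(a + 1, model.n_components)
            Wa = model.weights[:, :aa]
            Pa = model.x_loadings[:, :aa]
            Qa = model.y_loadings[:aa]
            coef = Wa @ np.linalg.solve(Pa.T @ Wa, Qa)
            pred = model.y_mean + model.y_std * (xs @ coef)
            press[a] += (yarr[i] - pred) ** 2
    tss = float(((yarr - yarr.mean()) ** 2).sum())
    q2 = 1.0 - press / tss
    series = pd.Series(q2, index=pd.RangeIndex(1, amax + 1, name="A"), name="Q2")
    best = float(series.max())
    chosen = int(series.index[series >= best - tol][0])
    return Q2Result(q2_by_components=series, n_components=chosen,
                    q2=float(series.loc[chosen]))


def pls_select(model: PLSModel, vip: pd.Series, vip_threshold: float = 1.0,
               require_positive: bool = True) -> set[str]:
    """Peaks with VIP above threshold and (by default) positive coefficient."""
    coef = model.coefficients
    mask = vip > vip_threshold
    if require_positive:
        mask &= coef > 0
    return {str(p) for p in vip.index[mask]}


@dataclass
class PLSScreenResult:
    model: PLSModel
    vip: pd.Series
    q2: Q2Result
    selected: set[str]


def pls_screen(areas: pd.DataFrame, activity: pd.Series, max_components: int = 5,
               vip_threshold: float = 1.0, require_positive: bool = True) -> PLSScreenResult:
    """Full PLSR screen for one endpoint: choose A by LOO Q2, fit, VIP-select."""
    areas = areas.loc[activity.index]
    q2 = cv_q2(areas.to_numpy(float), activity.to_numpy(float),
               max_components=max_components)
    model = pls_fit(areas, activity.to_numpy(float), n_components=q2.n_components)
    vip = vip_scores(model)
    selected = pls_select(model, vip, vip_threshold=vip_threshold,
                          require_positive=require_positive)
    return PLSScreenResult(model=model, vip=vip, q2=q2, selected=selected)
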