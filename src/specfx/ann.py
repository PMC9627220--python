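"""Backpropagation neural network screening via mean impact values.

A small single-hidden-layer feedforward regressor (default p-3-1: sigmoid
hidden units, linear output) is trained per endpoint on min-max-scaled
inputs and output.  Variable screening uses the mean impact value (MIV):
each input column of the *original* data is multiplied by 1 + delta and
1 - delta (delta = 0.10), the two perturbed matrices are pushed through the
network, and the per-sample prediction difference is the impact value; its
mean over samples (and over an ensemble of seeded restarts, to tame
initialization noise at n = 10 batches) is the MIV.  MIV > 0 marks a peak
as positively correlated with the effect.

For an exactly linear predictor y = sum_j w_j x_j the construction gives
MIV_j = 2 * delta * w_j * mean(x_j) (= 0.2 w_j mean(x_j) at delta 0.1),
which anchors the implementation's unit tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import r2_score
from sklearn.neural_network import MLPRegressor

from .errors import SpecfxError


@dataclass
class ANNConfig:
    """Architecture and training settings for the per-endpoint network."""

    hidden: int = 3
    train_fraction: float = 0.8
    max_iter: int = 5000
    tol: float = 1e-8
    ensemble: int = 20
    alpha: float = 1e-4  # L2 penalty, sklearn default scale

    def validate(self) -> None:
        if self.hidden < 1:
            raise SpecfxError("hidden must be >= 1")
        if not 0 < self.train_fraction <= 1:
            raise SpecfxError("train_fraction must be in (0, 1]")
        if self.ensemble < 1:
            raise SpecfxError("ensemble must be >= 1")


class ANNModel:
    """Min-max scaling wrapper around a fitted single-hidden-layer regressor.

    ``predict`` accepts data on the original scale; scaling to [0, 1] (fit
    on the training data) and inverse scaling of the output are internal,
    so impact-value perturbations can be applied to the original data as
    the MIV algorithm prescribes.
    """

    def __init__(self, net: MLPRegressor, x_min, x_span, y_min, y_span, feature_names):
        self._net = net
        self.x_min = np.asarray(x_min, float)
        self.x_span = np.asarray(x_span, float)
        self.y_min = float(y_min)
        self.y_span = float(y_span)
        self.feature_names = list(feature_names)

    def predict(self, X) -> np.ndarray:
        Xs = (np.asarray(X, float) - self.x_min) / self.x_span
        return self.y_min + self.y_span * self._net.predict(Xs)


def _split(n: int, train_fraction: float, rng: np.random.Generator):
    perm = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    n_train = min(max(n_train, 1), n)
    return perm[:n_train], perm[n_train:]


def train_ann(X, y, config: ANNConfig | None = None, seed: int = 0):
    """Train one network; returns ``(ANNModel, fit_report)``.

    The fit report carries R2 on the training split, the held-out split
    (NaN when the split is empty) and the whole set.  Identical data and
    seed give identical weights and predictions.
    """
    config = config or ANNConfig()
    config.validate()
    names = list(X.columns) if isinstance(X, pd.DataFrame) else \
        [f"x{j}" for j in range(np.shape(X)[1])]
    Xarr = np.asarray(X, dtype=float)
    yarr = np.asarray(y, dtype=float).ravel()
    if not np.isfinite(Xarr).all() or not np.isfinite(yarr).all():
        raise SpecfxError("X and y must be finite")
    if yarr.std() == 0:
        raise SpecfxError("response has zero variance")
    n = len(yarr)
    rng = np.random.default_rng(seed)
    train_idx, test_idx = _split(n, config.train_fraction, rng)

    x_min = Xarr[train_idx].min(axis=0)
    x_span = Xarr[train_idx].max(axis=0) - x_min
    x_span[x_span == 0] = 1.0
    y_min = yarr[train_idx].min()
    y_span = yarr[train_idx].max() - y_min
    if y_span == 0:
        raise SpecfxError("training split has constant response")

    Xs = (Xarr - x_min) / x_span
    ys = (yarr - y_min) / y_span
    net = MLPRegressor(hidden_layer_sizes=(config.hidden,), activation="logistic",
                       solver="lbfgs", alpha=config.alpha, max_iter=config.max_iter,
                       tol=config.tol, random_state=int(seed) % (2 ** 31))
    net.fit(Xs[train_idx], ys[train_idx])
    model = ANNModel(net, x_min, x_span, y_min, y_span, names)
    pred = model.predict(Xarr)
    report = {
        "r2_train": float(r2_score(yarr[train_idx], pred[train_idx])),
        "r2_test": float(r2_score(yarr[test_idx], pred[test_idx]))
        if len(test_idx) >= 2 else float("nan"),
        "r2_whole": float(r2_score(yarr, pred)),
        "n_train": int(len(train_idx)),
        "n_test": int(len(test_idx)),
        "seed": int(seed),
    }
    return model, report


def train_ensemble(X, y, config: ANNConfig | None = None, seed: int = 0):
    """Train ``config.ensemble`` seeded restarts (init and split both vary)."""
    config = config or ANNConfig()
    config.validate()
    seeds = np.random.default_rng(seed).integers(0, 2 ** 31 - 1, size=config.ensemble)
    models, reports = [], []
    for s in seeds:
        m, r = train_ann(X, y, config, seed=int(s))
        models.append(m)
        reports.append(r)
    return models, reports


@dataclass
class MIVResult:
    """Ensemble-averaged mean impact values with per-model fit reports."""

    miv: pd.Series                 # per input, ensemble mean
    per_model: pd.DataFrame        # models x inputs
    delta: float
    reports: list[dict] = field(default_factory=list)


def miv_scores(models, X, delta: float = 0.10, reports=None) -> MIVResult:
    """Mean impact value per input for an ensemble of fitted predictors.

    Each predictor only needs a ``predict(X)`` method on original-scale
    data.  Column j of the original X is multiplied by (1 + delta) and
    (1 - delta); MIV_j is the mean over samples of the prediction
    difference, averaged over the ensemble.
    """
    if not 0 < delta < 1:
        raise SpecfxError("delta must be in (0, 1)")
    if not isinstance(models, (list, tuple)):
        models = [models]
    names = list(X.columns) if isinstance(X, pd.DataFrame) else \
        [f"x{j}" for j in range(np.shape(X)[1])]
    Xarr = np.asarray(X, dtype=float)
    p = Xarr.shape[1]
    per_model = np.zeros((len(models), p))
    for mi, model in enumerate(models):
        for j in range(p):
            Xp = Xarr.copy()
            Xm = Xarr.copy()
            Xp[:, j] *= (1.0 + delta)
            Xm[:, j] *= (1.0 - delta)
            iv = np.asarray(model.predict(Xp), float) - np.asarray(model.predict(Xm), float)
            per_model[mi, j] = iv.mean()
    miv = pd.Series(per_model.mean(axis=0), index=names, name="MIV")
    return MIVResult(miv=miv, per_model=pd.DataFrame(per_model, columns=names),
                     delta=delta, reports=list(reports) if reports else [])


def miv_select(result: MIVResult) -> set[str]:
    """Peaks with strictly positive mean impact value."""
    return {str(p) for p in result.miv.index[result.miv > 0]}


@dataclass
class ANNScreenResult:
    miv_result: MIVResult
    selected: set[str]
    reports: list[dict]


def ann_screen(areas: pd.DataFrame, activity: pd.Series,
               config: ANNConfig | None = None, seed: int = 0,
               delta: float = 0.10) -> ANNScreenResult:
    """Full BP-ANN + MIV screen for one endpoint."""
    config = config or ANNConfig()
    areas = areas.loc[activity.index]
    models, reports = train_ensemble(areas, activity.to_numpy(float), config, seed=seed)
    miv = miv_scores(models, areas, delta=delta, reports=reports)
    return ANNScreenResult(miv_result=miv, selected=miv_select(miv), reports=reports)
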