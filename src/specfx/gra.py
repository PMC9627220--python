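"""Deng's grey relational analysis between peak areas and activities.

For a reference sequence x0(k) (one endpoint's activity across batches,
k = 1..N) and comparison sequences xi(k) (peak areas), the relational
coefficient is

    xi_i(k) = (d_min + rho * d_max) / (|x0(k) - xi(k)| + rho * d_max)

with d_min / d_max the global minimum / maximum of |x0(t) - xs(t)| over all
comparison sequences s and all positions t, and rho the resolution
coefficient (0.5 by convention).  The grey relational degree r_i is the
mean of xi_i(k) over k; peaks with r_i above a threshold (0.8) count as
closely related to the effect.

Because the deltas are scale-sensitive while raw peak areas span orders of
magnitude, all sequences are normalized first (division by their own mean
by default; ``none`` and ``minmax`` modes are offered).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SpecfxError


def gra_normalize(sequences, mode: str = "mean"):
    """Normalize sequences (columns of a 2-D array / DataFrame, or one 1-D).

    ``mean``: divide each sequence by its own mean (scale-free, positive
    for positive data, idempotent on mean-1 sequences).  ``minmax``: map to
    [0, 1].  ``none``: pass through.
    """
    arr = np.asarray(sequences, dtype=float)
    one_d = arr.ndim == 1
    if one_d:
        arr = arr[:, None]
    if mode == "none":
        out = arr.copy()
    elif mode == "mean":
        means = arr.mean(axis=0)
        if np.any(means == 0):
            raise SpecfxError("cannot mean-normalize a zero-mean sequence")
        out = arr / means
    elif mode == "minmax":
        span = arr.max(axis=0) - arr.min(axis=0)
        if np.any(span == 0):
            raise SpecfxError("cannot min-max normalize a constant sequence")
        out = (arr - arr.min(axis=0)) / span
    else:
        raise SpecfxError(f"unknown normalization mode {mode!r}")
    if isinstance(sequences, pd.DataFrame):
        return pd.DataFrame(out, index=sequences.index, columns=sequences.columns)
    if isinstance(sequences, pd.Series):
        return pd.Series(out[:, 0], index=sequences.index, name=sequences.name)
    return out[:, 0] if one_d else out


def grey_degree(x0, xi, rho: float = 0.5, scope: str = "global"):
    """Relational coefficients and degree(s) of comparison sequences vs x0.

    ``xi`` may be one sequence (1-D) or several as columns of a 2-D array;
    with ``scope='global'`` (default) the min/max deltas are taken jointly
    over all comparison sequences, with ``scope='per-sequence'`` each
    sequence uses its own extrema.  Returns ``(coefficients, degrees)``
    with shapes (N, p) and (p,) (scalars collapse for a single sequence).
    """
    if not 0 < rho <= 1:
        raise SpecfxError("resolution coefficient rho must be in (0, 1]")
    x0 = np.asarray(x0, dtype=float)
    X = np.asarray(xi, dtype=float)
    one_d = X.ndim == 1
    if one_d:
        X = X[:, None]
    if X.shape[0] != x0.shape[0]:
        raise SpecfxError(f"length mismatch: x0 has {x0.shape[0]} points, "
                          f"comparison sequences have {X.shape[0]}")
    if x0.shape[0] < 2:
        raise SpecfxError("sequences must have at least 2 points")
    delta = np.abs(x0[:, None] - X)
    if scope == "global":
        dmin, dmax = delta.min(), delta.max()
        dmin = np.full(X.shape[1], dmin)
        dmax = np.full(X.shape[1], dmax)
    elif scope == "per-sequence":
        dmin, dmax = delta.min(axis=0), delta.max(axis=0)
    else:
        raise SpecfxError(f"unknown delta scope {scope!r}")
    with np.errstate(invalid="ignore"):
        coeff = (dmin + rho * dmax) / (delta + rho * dmax)
    # all sequences identical to x0: 0/0 -> coefficient 1 by continuity
    coeff = np.where(np.isnan(coeff), 1.0, coeff)
    degrees = coeff.mean(axis=0)
    if one_d:
        return coeff[:, 0], float(degrees[0])
    return coeff, degrees


@dataclass
class GreyResult:
    """Per-peak relational coefficients, degrees and the selected peak set."""

    coefficients: pd.DataFrame  # batches x peaks
    degrees: pd.Series          # peaks
    threshold: float
    selected: set[str]
    rho: float
    normalization: str


def gra_select(areas: pd.DataFrame, activity: pd.Series, rho: float = 0.5,
               threshold: float = 0.8, normalization: str = "mean",
               scope: str = "global") -> GreyResult:
    """Screen peaks whose grey relational degree with one activity exceeds
    the threshold (strict inequality, 'over 0.8')."""
    if not 0 < threshold <= 1:
        raise SpecfxError("threshold must be in (0, 1]")
    areas = areas.loc[activity.index]
    x0 = gra_normalize(activity.to_numpy(float), normalization)
    X = gra_normalize(areas, normalization)
    coeff, degrees = grey_degree(x0, X.to_numpy(float), rho=rho, scope=scope)
    coeff = pd.DataFrame(coeff, index=areas.index, columns=areas.columns)
    degrees = pd.Series(degrees, index=areas.columns, name="grey_degree")
    selected = {str(p) for p in degrees.index[degrees > threshold]}
    return GreyResult(coefficients=coeff, degrees=degrees, threshold=threshold,
                      selected=selected, rho=rho, normalization=normalization)
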