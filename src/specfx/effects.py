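"""Bioassay readouts -> per-batch effect endpoints -> oriented activities.

Six endpoints drive the spectrum-effect screen: DPPH IC50 (mg/mL), FRAP
(µmol/L Fe2+), A549 cell viability (%), relative wound-healing rate (%),
and transwell migrated / invaded cell counts.  For four of the six a
*smaller* raw value means a *more* active batch, so raw endpoints carry an
orientation flag and are mapped to an activity scale that increases with
potency before any correlation method sees them:

=============  =========================  =====================
endpoint kind  raw -> activity transform  examples
=============  =========================  =====================
ic50           1 / raw                    DPPH IC50
percent        100 - raw                  viability, healing
count          (max + min) - raw          migration, invasion
identity       raw                        FRAP
=============  =========================  =====================

All transforms are strictly monotone, keep activities positive (required by
the grey-relational mean normalization) and exactly reverse or preserve the
batch ranking according to the flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import FitError, SpecfxError

#: canonical endpoint order
ENDPOINTS = ("dpph_ic50", "frap", "viability", "healing", "migration", "invasion")

#: endpoint -> (kind, larger raw value means more active?)
ENDPOINT_KINDS: dict[str, tuple[str, bool]] = {
    "dpph_ic50": ("ic50", False),
    "frap": ("identity", True),
    "viability": ("percent", False),
    "healing": ("percent", False),
    "migration": ("count", False),
    "invasion": ("count", False),
}


# ---------------------------------------------------------------------------
# Assay formulas
# ---------------------------------------------------------------------------

def dpph_rate(od_sample, od_blank, od_control) -> float:
    """DPPH scavenging rate (%) = [1 - (OD_sample - OD_blank)/OD_control] x 100.

    Values outside [0, 100] are possible on pathological inputs and are
    returned as-is (never clamped).
    """
    od_control = np.asarray(od_control, dtype=float)
    if np.any(od_control <= 0):
        raise SpecfxError("od_control must be positive")
    rate = (1.0 - (np.asarray(od_sample, float) - np.asarray(od_blank, float)) / od_control) * 100.0
    return float(rate) if np.ndim(rate) == 0 else rate


def healing_rate(area_0h, area_24h) -> float:
    """Relative wound-healing rate (%) = 100 x (area_0h - area_24h) / area_0h."""
    a0 = np.asarray(area_0h, dtype=float)
    a24 = np.asarray(area_24h, dtype=float)
    if np.any(a0 <= 0):
        raise SpecfxError("initial wound area must be positive")
    if np.any(a24 < 0) or np.any(a24 > a0):
        warnings.warn("wound area at 24 h outside [0, area_0h]; rate may leave [0, 100]")
    rate = 100.0 * (a0 - a24) / a0
    return float(rate) if np.ndim(rate) == 0 else rate


# ---------------------------------------------------------------------------
# Four-parameter logistic dose-response / IC50
# ---------------------------------------------------------------------------

@dataclass
class IC50Fit:
    ic50: float
    hill: float
    floor: float
    ceiling: float
    residual_norm: float
    r2: float


def four_param_logistic(conc, ic50, hill, floor, ceiling):
    """4PL response: floor + (ceiling - floor) / (1 + (ic50 / c)^hill).

    At ``c == ic50`` the response is exactly midway between floor and
    ceiling for any Hill slope.
    """
    conc = np.asarray(conc, dtype=float)
    return floor + (ceiling - floor) / (1.0 + (ic50 / conc) ** hill)


def fit_ic50(concentrations, responses) -> IC50Fit:
    """Fit a 4PL on log-concentration and return the half-maximal concentration.

    Mirrors the log(dose)-vs-response variable-slope workflow of standard
    dose-response software: the fitted IC50 is the concentration at the
    midpoint between the fitted floor and ceiling.
    """
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if len(np.unique(c)) < 4:
        raise SpecfxError("need at least 4 distinct concentrations")
    if np.any(c <= 0):
        raise SpecfxError("concentrations must be positive")
    if np.ptp(y) < 1e-10 * max(1.0, abs(np.mean(y))):
        raise FitError("no dose dependence: responses are flat")

    rho = stats.spearmanr(c, y).statistic
    hill0 = 1.0 if (rho is None or rho >= 0) else -1.0
    lo, hi = float(y.min()), float(y.max())
    mid = 0.5 * (lo + hi)
    c0 = float(c[np.argmin(np.abs(y - mid))])

    def model(logc, logic50, hill, floor, ceiling):
        return floor + (ceiling - floor) / (1.0 + 10 ** ((logic50 - logc) * hill))

    logc = np.log10(c)
    try:
        popt, _ = optimize.curve_fit(
            model, logc, y, p0=[np.log10(c0), hill0, lo, hi], maxfev=20000
        )
    except RuntimeError as exc:
        resid = float(np.linalg.norm(y - model(logc, np.log10(c0), hill0, lo, hi)))
        raise FitError(f"4PL fit did not converge: {exc}", residual_norm=resid)
    logic50, hill, floor, ceiling = popt
    resid = y - model(logc, *popt)
    if abs(ceiling - floor) < 1e-9 * max(1.0, abs(ceiling)):
        raise FitError("no dose dependence: fitted span is zero",
                       residual_norm=float(np.linalg.norm(resid)))
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid ** 2).sum()) / tss if tss > 0 else np.nan
    return IC50Fit(ic50=float(10 ** logic50), hill=float(hill), floor=float(floor),
                   ceiling=float(ceiling), residual_norm=float(np.linalg.norm(resid)),
                   r2=r2)


# ---------------------------------------------------------------------------
# FRAP calibration
# ---------------------------------------------------------------------------

@dataclass
class LinearCalibration:
    """Absorbance-on-concentration OLS line for the Fe2+ standard series."""

    slope: float
    intercept: float
    r2: float

    def __post_init__(self):
        if self.slope == 0:
            raise SpecfxError("calibration slope must be nonzero")


def frap_calibrate(standard_concentrations, absorbances) -> LinearCalibration:
    """OLS calibration of absorbance (593 nm) against Fe2+ concentration (µmol/L)."""
    x = np.asarray(standard_concentrations, dtype=float)
    y = np.asarray(absorbances, dtype=float)
    if len(x) < 3:
        raise SpecfxError("need at least 3 calibration standards")
    fit = stats.linregress(x, y)
    return LinearCalibration(slope=float(fit.slope), intercept=float(fit.intercept),
                             r2=float(fit.rvalue ** 2))


def frap_value(absorbance, calibration: LinearCalibration):
    """Invert the calibration: FRAP value in µmol/L Fe2+ equivalents."""
    a = np.asarray(absorbance, dtype=float)
    val = (a - calibration.intercept) / calibration.slope
    return float(val) if np.ndim(val) == 0 else val


# ---------------------------------------------------------------------------
# Effect table assembly
# ---------------------------------------------------------------------------

@dataclass
class EffectTable:
    """Raw endpoints, orientation flags and derived oriented activities."""

    raw: pd.DataFrame       # batches x endpoints
    orientation: dict[str, bool]   # endpoint -> larger raw means more active
    activity: pd.DataFrame  # batches x endpoints, increases with potency
    transforms: dict[str, str]

    @property
    def batches(self) -> list[str]:
        return list(self.raw.index)

    @property
    def endpoints(self) -> list[str]:
        return list(self.raw.columns)

    def to_json_dict(self) -> dict:
        return {
            "raw": self.raw.to_dict(orient="index"),
            "activity": self.activity.to_dict(orient="index"),
            "orientation": self.orientation,
            "transforms": self.transforms,
        }


def assemble_effects(raw: pd.DataFrame,
                     kinds: dict[str, tuple[str, bool]] | None = None) -> EffectTable:
    """Build an :class:`EffectTable` from per-batch raw endpoint means.

    ``kinds`` maps endpoint -> (kind, larger_raw_is_more_active); the six
    standard endpoints default to :data:`ENDPOINT_KINDS`.  Missing cells are
    rejected; endpoints whose larger raw value already means more active are
    passed through unchanged.
    """
    if raw.isna().any().any():
        cell = raw.stack(future_stack=True)
        cell = cell[cell.isna()].index[0]
        raise SpecfxError(f"missing endpoint value at {cell}")
    kinds = dict(kinds) if kinds is not None else {}
    activity = {}
    transforms = {}
    orientation = {}
    for ep in raw.columns:
        kind, larger_better = kinds.get(ep, ENDPOINT_KINDS.get(ep, ("identity", True)))
        orientation[ep] = larger_better
        v = raw[ep].astype(float)
        if larger_better:
            activity[ep] = v
            transforms[ep] = "identity"
        elif kind == "ic50":
            if (v <= 0).any():
                raise SpecfxError(f"non-positive IC50 in endpoint {ep!r}")
            activity[ep] = 1.0 / v
            transforms[ep] = "reciprocal"
        elif kind == "percent":
            activity[ep] = 100.0 - v
            transforms[ep] = "100-x"
        elif kind == "count":
            activity[ep] = (v.max() + v.min()) - v
            transforms[ep] = "(max+min)-x"
        else:  # identity kind but lower-is-better
            activity[ep] = -v
            transforms[ep] = "negate"
    return EffectTable(raw=raw.astype(float), orientation=orientation,
                       activity=pd.DataFrame(activity, index=raw.index),
                       transforms=transforms)
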