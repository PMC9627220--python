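"""Seeded synthetic fingerprint + bioassay data with known ground truth.

The generator emulates the study design this package targets: ten batches
of a herbal decoction, ~70 common LC-MS peaks with heavy-tailed positive
areas (log-normal per peak), six effect endpoints (DPPH IC50, FRAP,
viability, wound healing, transwell migration and invasion) driven by a
planted subset of "active" peaks through a linear or saturating link, plus
assay-level multiplicative noise and QC dilution series for linearity
testing.  Raw endpoint values are mapped onto the scales a wet lab would
report (an IC50-like endpoint *decreases* with activity, viability and
counts decrease, FRAP increases), so orientation handling downstream is
exercised rather than bypassed.  Everything is reproducible bit-for-bit
from ``(spec, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .effects import ENDPOINT_KINDS, ENDPOINTS, EffectTable, assemble_effects
from .errors import SpecfxError
from .peaks import CommonPeakMatrix, PeakTable, assign_peak_ids

#: raw-scale ranges the default generator maps endpoint values onto,
#: mirroring the reported ranges of the ten-batch decoction study
RAW_RANGES: dict[str, tuple[float, float]] = {
    "dpph_ic50": (1.59, 5.50),
    "frap": (143.83, 873.83),
    "viability": (21.73, 85.71),
    "healing": (21.50, 44.46),
    "migration": (12.00, 68.67),
    "invasion": (7.67, 27.00),
}

_DEFAULT_DILUTIONS = (2.0, 4.0, 8.0, 16.0, 32.0, 64.0)
_DEFAULT_CONCS = (0.3125, 0.625, 1.25, 2.5, 5.0, 10.0, 20.0)


@dataclass
class SyntheticSpec:
    """Study-shaped generator settings; defaults are the study conditions."""

    n_batches: int = 10
    n_peaks: int = 70
    n_active: int = 8
    active_sets: dict[str, frozenset] | None = None  # endpoint -> 0-based indices
    link: str = "linear"  # linear | saturating
    coefficients: dict[str, np.ndarray] | None = None
    area_log_loc: np.ndarray | None = None   # per-peak log-area location
    #: per-peak log-area sd; a (lo, hi) pair draws one value per peak so the
    #: area CVs span the range reported for relative peak areas (~9-153%),
    #: a scalar applies to every peak
    area_log_scale: float | tuple = (0.2, 0.65)
    noise_sd: float = 0.05                   # relative assay noise per endpoint
    #: sd of the multiplicative per-batch strength factor; the batches of the
    #: emulated study were produced under an orthogonal design of extraction
    #: conditions, so overall strength varies mildly across batches by default
    batch_effect_sd: float = 0.05
    #: within-module correlation of planted-peak log-areas: the active
    #: constituents behind one endpoint co-vary across extraction batches
    #: (compounds co-released from the same source herbs), which is what
    #: makes each of them individually trackable by the screens
    module_rho: float = 0.85
    endpoints: tuple = ENDPOINTS
    raw_scale: str = "study"                 # study | identity
    rt_jitter_sd: float = 0.02               # min, per-batch RT scatter
    seed: int = 0

    def validate(self) -> None:
        if self.n_batches < 3:
            raise SpecfxError(f"n_batches must be >= 3, got {self.n_batches}")
        if self.n_peaks < 1:
            raise SpecfxError(f"n_peaks must be >= 1, got {self.n_peaks}")
        if self.n_active < 1 or self.n_active > self.n_peaks:
            raise SpecfxError(f"n_active out of range: {self.n_active}")
        if self.active_sets is not None:
            for ep, idx in self.active_sets.items():
                bad = [i for i in idx if not 0 <= int(i) < self.n_peaks]
                if bad:
                    raise SpecfxError(
                        f"active_sets[{ep!r}] has out-of-range peak indices {bad}")
        if self.noise_sd < 0:
            raise SpecfxError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.link not in ("linear", "saturating"):
            raise SpecfxError(f"unknown link {self.link!r}")
        if self.raw_scale not in ("study", "identity"):
            raise SpecfxError(f"unknown raw_scale {self.raw_scale!r}")
        scale = np.atleast_1d(np.asarray(self.area_log_scale, dtype=float))
        if np.any(scale < 0):
            raise SpecfxError(f"area_log_scale must be >= 0, got {self.area_log_scale}")
        if not 0 <= self.module_rho < 1:
            raise SpecfxError(f"module_rho must be in [0, 1), got {self.module_rho}")


@dataclass
class SyntheticTruth:
    """Planted active peaks and link parameters, for grading recovery."""

    active_sets: dict[str, frozenset]          # endpoint -> 0-based indices
    active_peak_ids: dict[str, frozenset]      # endpoint -> P-number ids
    coefficients: dict[str, np.ndarray]
    link: str
    #: per-endpoint population mean and sd of each planted peak's area; the
    #: link acts on standardized abundances so each planted peak contributes
    #: with a comparable, coefficient-controlled effect size regardless of
    #: its absolute ionization response or dispersion
    normalizers: dict[str, dict] = field(default_factory=dict)
    raw_transforms: dict[str, dict] = field(default_factory=dict)

    def combo(self, areas: pd.DataFrame, endpoint: str) -> np.ndarray:
        """Re-evaluate the noiseless link from a peak-area matrix."""
        ids = sorted(self.active_peak_ids[endpoint], key=lambda s: int(s[1:]))
        norm = self.normalizers[endpoint]
        Z = (areas[ids].to_numpy(float) - np.asarray(norm["mu"])) / np.asarray(norm["sd"])
        coef = self.coefficients[endpoint]
        if self.link == "linear":
            return Z @ coef
        return (coef * np.tanh(Z)).sum(axis=1)

    def expected_raw(self, areas: pd.DataFrame, endpoint: str) -> np.ndarray:
        """Noiseless raw endpoint values implied by a peak-area matrix."""
        return _apply_raw_transform(self.combo(areas, endpoint),
                                    self.raw_transforms[endpoint])

    def to_json_dict(self) -> dict:
        return {
            "link": self.link,
            "active_peak_ids": {ep: sorted(ids, key=lambda s: int(s[1:]))
                                for ep, ids in self.active_peak_ids.items()},
            "active_indices": {ep: sorted(int(i) for i in s)
                               for ep, s in self.active_sets.items()},
            "coefficients": {ep: list(map(float, c))
                             for ep, c in self.coefficients.items()},
            "normalizers": self.normalizers,
            "raw_transforms": self.raw_transforms,
        }


def _apply_raw_transform(combo: np.ndarray, params: dict) -> np.ndarray:
    kind = params["kind"]
    if kind == "identity":
        return combo.copy()
    if kind == "reciprocal":
        return params["scale"] / combo
    if kind == "affine":
        return params["intercept"] + params["slope"] * combo
    raise SpecfxError(f"unknown raw transform {kind!r}")


def _raw_transform_params(endpoint: str, combo: np.ndarray, raw_scale: str) -> dict:
    if raw_scale == "identity":
        return {"kind": "identity"}
    kind, larger_better = ENDPOINT_KINDS.get(endpoint, ("identity", True))
    cmin, cmax = float(combo.min()), float(combo.max())
    lo, hi = RAW_RANGES.get(endpoint, (float(cmin), float(cmax)))
    if cmax == cmin:
        return {"kind": "affine", "intercept": 0.5 * (lo + hi), "slope": 0.0}
    slope = (hi - lo) / (cmax - cmin)
    if larger_better:
        return {"kind": "affine", "intercept": lo - slope * cmin, "slope": slope}
    return {"kind": "affine", "intercept": hi + slope * cmin, "slope": -slope}


def gen_spectrum_effect(spec: SyntheticSpec):
    """Generate ``(CommonPeakMatrix, EffectTable, SyntheticTruth)`` from a spec."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_batches, spec.n_peaks

    # peak metadata: ion mode split roughly in half, retention times 2-48 min
    n_pos = max(1, int(round(0.5 * p))) if p > 1 else 1
    modes = ["positive"] * n_pos + ["negative"] * (p - n_pos)

    def _resolved_rts(m: int) -> np.ndarray:
        # chromatographically resolved peaks: grid over the gradient window
        # with jitter well below the grid spacing
        if m == 0:
            return np.zeros(0)
        base = np.linspace(2.0, 48.0, m)
        gap = 46.0 / max(m - 1, 1)
        return base + rng.uniform(-0.25, 0.25, m) * gap

    rts = np.concatenate([_resolved_rts(n_pos), _resolved_rts(p - n_pos)])
    meta = pd.DataFrame({"rt_min": rts, "mode": modes})
    ids = assign_peak_ids(meta)
    meta.index = pd.Index(ids, name="peak_id")

    # planted active peaks per endpoint (drawn before the IS is designated)
    endpoints = tuple(spec.active_sets) if spec.active_sets is not None else spec.endpoints
    if spec.active_sets is not None:
        active = {ep: frozenset(int(i) for i in s) for ep, s in spec.active_sets.items()}
    else:
        active = {ep: frozenset(int(i) for i in
                                rng.choice(p, size=spec.n_active, replace=False))
                  for ep in endpoints}
    all_active = set().union(*active.values()) if active else set()
    is_candidates = [i for i in range(p) if i not in all_active]
    if not is_candidates:
        raise SpecfxError("no peak left to serve as internal standard: "
                          "active_sets cover every peak")
    is_index = is_candidates[0]

    coefs = {}
    for ep in endpoints:
        k = len(active[ep])
        if spec.coefficients is not None and ep in spec.coefficients:
            c = np.asarray(spec.coefficients[ep], dtype=float)
            if c.shape != (k,):
                raise SpecfxError(f"coefficients[{ep!r}] must have length {k}")
        else:
            c = rng.uniform(0.5, 1.5, size=k)
        coefs[ep] = c

    # heavy-tailed positive areas: log-normal per peak, dispersion spanning
    # the reported relative-peak-area CV range; multiplicative per-batch
    # strength factor (mean 1) emulating orthogonal extraction variation
    loc = (np.asarray(spec.area_log_loc, float) if spec.area_log_loc is not None
           else rng.uniform(np.log(1e4), np.log(1e6), size=p))
    if loc.shape != (p,):
        raise SpecfxError(f"area_log_loc must have length n_peaks={p}")
    if np.ndim(spec.area_log_scale) == 0:
        sigma = np.full(p, float(spec.area_log_scale))
    else:
        lo_s, hi_s = (float(v) for v in spec.area_log_scale)
        sigma = rng.uniform(lo_s, hi_s, size=p)
    noise = rng.standard_normal((n, p))
    if spec.module_rho > 0 and active:
        # variance-preserving blend: planted peaks share per-endpoint module
        # factors (equal split when a peak belongs to several modules), so
        # each marginal stays log-normal(loc_j, sigma_j)
        factors = {ep: rng.standard_normal(n) for ep in endpoints}
        fsum = np.zeros((n, p))
        count = np.zeros(p)
        for ep in endpoints:
            for i in active[ep]:
                fsum[:, i] += factors[ep]
                count[i] += 1
        member = count > 0
        noise[:, member] = (np.sqrt(1 - spec.module_rho) * noise[:, member]
                            + np.sqrt(spec.module_rho)
                            * fsum[:, member] / np.sqrt(count[member]))
    areas = np.exp(loc + sigma * noise)
    if spec.batch_effect_sd > 0:
        g = spec.batch_effect_sd
        areas *= np.exp(g * rng.standard_normal((n, 1)) - g ** 2 / 2.0)

    batch_ids = [f"S{i + 1}" for i in range(n)]
    areas_df = pd.DataFrame(areas, index=pd.Index(batch_ids, name="batch"),
                            columns=meta.index)
    # order columns by P number
    order = sorted(meta.index, key=lambda s: int(s[1:]))
    areas_df = areas_df[order]
    meta = meta.loc[order]
    rt_df = pd.DataFrame(
        np.clip(meta["rt_min"].to_numpy(float)[None, :]
                + spec.rt_jitter_sd * rng.standard_normal((n, p)), 0.01, None),
        index=areas_df.index, columns=areas_df.columns)

    # expected (population-mean) area per peak: exp(loc + sigma^2/2); the
    # batch factor has mean 1 by construction
    # population moments of each peak's area (batch factor has mean 1):
    # ln(area) ~ N(loc - g^2/2, sqrt(sigma^2 + g^2)) with g the batch sd
    g2 = spec.batch_effect_sd ** 2
    s2 = sigma ** 2 + g2
    mu = np.exp(loc + sigma ** 2 / 2.0)
    sd = mu * np.sqrt(np.expm1(s2))
    normalizers = {}
    coefs_by_pid = {}
    for ep in endpoints:
        # the drawn/supplied coefficient vector aligns with sorted 0-based
        # indices; reorder to P-number order, which truth.combo uses
        sorted_idx = sorted(active[ep])
        perm = np.argsort([int(ids[i][1:]) for i in sorted_idx])
        coefs_by_pid[ep] = coefs[ep][perm]
        normalizers[ep] = {"mu": [float(mu[sorted_idx[j]]) for j in perm],
                           "sd": [float(sd[sorted_idx[j]]) for j in perm]}
    truth = SyntheticTruth(
        active_sets={ep: frozenset(active[ep]) for ep in endpoints},
        active_peak_ids={ep: frozenset(ids[i] for i in active[ep]) for ep in endpoints},
        coefficients=coefs_by_pid, link=spec.link, normalizers=normalizers)

    raw = {}
    for ep in endpoints:
        combo = truth.combo(areas_df, ep)
        params = _raw_transform_params(ep, combo, spec.raw_scale)
        truth.raw_transforms[ep] = params
        values = _apply_raw_transform(combo, params)
        if spec.noise_sd > 0:
            values = values * (1.0 + spec.noise_sd * rng.standard_normal(n))
        raw[ep] = values
    raw_df = pd.DataFrame(raw, index=areas_df.index)
    kinds = None
    if spec.raw_scale == "identity":
        kinds = {ep: ("identity", True) for ep in endpoints}
    effect_table = assemble_effects(raw_df, kinds=kinds)

    matrix = CommonPeakMatrix(areas=areas_df, peak_meta=meta,
                              is_peak=ids[is_index], rt=rt_df)
    return matrix, effect_table, truth


def gen_peak_tables(matrix: CommonPeakMatrix, seed: int = 0,
                    rt_jitter_sd: float = 0.02) -> list[PeakTable]:
    """Degrade a matrix into per-batch peak tables with RT scatter (for the
    peak-matching path)."""
    rng = np.random.default_rng(seed)
    tables = []
    base_rt = matrix.peak_meta["rt_min"].to_numpy(float)
    for batch in matrix.batches:
        rt = base_rt + rt_jitter_sd * rng.standard_normal(len(base_rt))
        df = pd.DataFrame({
            "peak_id": matrix.peak_ids,
            "rt_min": rt,
            "area": matrix.areas.loc[batch].to_numpy(float),
            "mode": matrix.peak_meta["mode"].to_numpy(),
        }).sort_values("rt_min", kind="stable")
        tables.append(PeakTable(sample=batch, peaks=df))
    return tables


def gen_calibration(matrix: CommonPeakMatrix,
                    dilution_factors=_DEFAULT_DILUTIONS,
                    failing_peaks=frozenset(), seed: int = 0,
                    rel_noise: float = 0.0,
                    r2_threshold: float = 0.99) -> pd.DataFrame:
    """QC-dilution calibration table (rows: dilution factor, cols: peaks).

    Values are analyte/IS area ratios.  Non-failing peaks respond linearly
    in 1/dilution (exactly, at zero noise); peaks in ``failing_peaks`` get
    progressively stronger power-law curvature until their OLS R2 falls
    below ``r2_threshold``, so a downstream linearity screen removes them
    by construction.  ``failing_peaks`` accepts P-number ids or 0-based
    column indices.
    """
    dil = np.asarray(list(dilution_factors), dtype=float)
    if dil.size == 0:
        raise SpecfxError("dilution factor list is empty")
    if np.any(dil < 1):
        raise SpecfxError("dilution factors must be >= 1")
    if len(np.unique(dil)) != len(dil):
        raise SpecfxError("dilution factors must be distinct")
    if matrix.is_peak is None:
        raise SpecfxError("matrix has no internal standard for area ratios")
    failing_ids = set()
    for f in failing_peaks:
        failing_ids.add(matrix.peak_ids[int(f)] if isinstance(f, (int, np.integer)) else str(f))
    unknown = failing_ids - set(matrix.peak_ids)
    if unknown:
        raise SpecfxError(f"failing_peaks not in matrix: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    mean_area = matrix.areas.mean(axis=0)
    base_ratio = mean_area / mean_area[matrix.is_peak]
    x = 1.0 / dil
    out = {}
    from scipy import stats as _stats
    for pid in matrix.peak_ids:
        if pid in failing_ids:
            y = None
            for gamma in np.arange(0.55, 0.04, -0.05):
                cand = float(base_ratio[pid]) * x ** gamma
                r2 = _stats.linregress(x, cand).rvalue ** 2
                if r2 < r2_threshold - 0.003:
                    y = cand
                    break
            if y is None:  # strongest curvature regardless
                y = float(base_ratio[pid]) * x ** 0.05
        else:
            y = float(base_ratio[pid]) * x
        if rel_noise > 0:
            y = y * (1.0 + rel_noise * rng.standard_normal(len(x)))
        out[pid] = y
    return pd.DataFrame(out, index=pd.Index(dil, name="dilution_factor"))


def gen_dose_response(ic50: float, hill: float = 1.0,
                      concentrations=_DEFAULT_CONCS, noise_sd: float = 0.0,
                      seed: int = 0, floor: float = 0.0,
                      ceiling: float = 100.0) -> pd.DataFrame:
    """Four-parameter-logistic dose-response table (scavenging-style: the
    response rises with concentration and is exactly midway between floor
    and ceiling at ``c == ic50``)."""
    if ic50 <= 0:
        raise SpecfxError(f"ic50 must be positive, got {ic50}")
    c = np.asarray(list(concentrations), dtype=float)
    if len(c) < 4:
        raise SpecfxError("need at least 4 concentrations")
    if np.any(c <= 0):
        raise SpecfxError("concentrations must be positive")
    resp = floor + (ceiling - floor) / (1.0 + (ic50 / c) ** hill)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        resp = resp + noise_sd * (ceiling - floor) * rng.standard_normal(len(c))
    return pd.DataFrame({"concentration": c, "response": resp})


def recovery_metrics(selected, truth: SyntheticTruth, endpoint: str) -> dict:
    """Precision/recall of a selected peak-id set against the planted truth.

    ``precision`` is reported as ``None`` when nothing was selected.
    """
    if endpoint not in truth.active_peak_ids:
        raise SpecfxError(f"unknown endpoint {endpoint!r}; truth has "
                          f"{sorted(truth.active_peak_ids)}")
    selected = {str(s) for s in selected}
    planted = set(truth.active_peak_ids[endpoint])
    tp = len(selected & planted)
    return {
        "endpoint": endpoint,
        "n_selected": len(selected),
        "n_planted": len(planted),
        "true_positives": tp,
        "recall": tp / len(planted) if planted else None,
        "precision": tp / len(selected) if selected else None,
    }
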