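"""Model/Results facade over the three-method spectrum-effect screen.

``SpectrumEffectModel`` binds a common-peak matrix (the "spectrum") to an
effect table (the "effects"); ``fit`` runs grey relational analysis, PLSR
with VIP selection and the BP-ANN/MIV screen for every endpoint and
returns a ``SpectrumEffectResults`` carrying per-method scores, the
consensus (three-way intersection) sets, cross-endpoint overlaps, and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import consensus as cns
from .ann import ANNConfig, ANNScreenResult, ann_screen
from .effects import EffectTable
from .errors import SpecfxError
from .gra import GreyResult, gra_select
from .peaks import CommonPeakMatrix
from .plsr import PLSScreenResult, pls_screen
from .synthetic import SyntheticTruth, recovery_metrics


@dataclass
class ScreenConfig:
    """Thresholds and settings for the three screening methods."""

    gra_rho: float = 0.5
    gra_threshold: float = 0.8
    gra_normalization: str = "mean"
    vip_threshold: float = 1.0
    pls_max_components: int = 5
    pls_require_positive: bool = True
    miv_delta: float = 0.10
    ann: ANNConfig = field(default_factory=ANNConfig)


@dataclass
class SpectrumEffectResults:
    """Fitted screen: per-endpoint method results and consensus sets."""

    gra: dict[str, GreyResult]
    pls: dict[str, PLSScreenResult]
    miv: dict[str, ANNScreenResult]
    consensus: dict[str, set]
    overlaps: dict
    config: ScreenConfig
    seed: int
    peak_ids: list[str]

    def summary(self) -> str:
        lines = ["Spectrum-effect screening summary",
                 "=" * 50,
                 f"{'endpoint':<12}{'GRA':>5}{'PLSR':>6}{'MIV':>5}{'consensus':>11}  Q2"]
        for ep in self.gra:
            q2 = self.pls[ep].q2.q2
            lines.append(f"{ep:<12}{len(self.gra[ep].selected):>5}"
                         f"{len(self.pls[ep].selected):>6}"
                         f"{len(self.miv[ep].selected):>5}"
                         f"{len(self.consensus[ep]):>11}  {q2:.3f}")
        lines.append("-" * 50)
        for ep, cons in self.consensus.items():
            members = ", ".join(sorted(cons, key=cns._peak_key)) or "(none)"
            lines.append(f"{ep}: {members}")
        return "\n".join(lines)

    def scores_frame(self, endpoint: str) -> pd.DataFrame:
        """Per-peak score table (grey degree, VIP, coefficient, MIV) for one endpoint."""
        return pd.DataFrame({
            "grey_degree": self.gra[endpoint].degrees,
            "vip": self.pls[endpoint].vip,
            "coef": self.pls[endpoint].model.coefficients,
            "miv": self.miv[endpoint].miv_result.miv,
        })

    def report(self, provenance: dict | None = None) -> dict:
        method_sets = {ep: {"gra": self.gra[ep].selected,
                            "plsr": self.pls[ep].selected,
                            "miv": self.miv[ep].selected}
                       for ep in self.gra}
        scores = {ep: {"grey_degree": {k: float(v) for k, v in
                                       self.gra[ep].degrees.items()},
                       "vip": {k: float(v) for k, v in self.pls[ep].vip.items()},
                       "coef": {k: float(v) for k, v in
                                self.pls[ep].model.coefficients.items()},
                       "miv": {k: float(v) for k, v in
                               self.miv[ep].miv_result.miv.items()},
                       "q2": float(self.pls[ep].q2.q2),
                       "n_components": int(self.pls[ep].q2.n_components)}
                  for ep in self.gra}
        prov = {"seed": self.seed,
                "gra_threshold": self.config.gra_threshold,
                "gra_rho": self.config.gra_rho,
                "vip_threshold": self.config.vip_threshold,
                "miv_delta": self.config.miv_delta,
                "ann_hidden": self.config.ann.hidden,
                "ann_ensemble": self.config.ann.ensemble}
        prov.update(provenance or {})
        return cns.screening_report(method_sets, scores=scores, provenance=prov)

    def recovery(self, truth: SyntheticTruth) -> pd.DataFrame:
        """Grade the consensus sets against planted synthetic truth."""
        rows = [recovery_metrics(self.consensus[ep], truth, ep)
                for ep in self.consensus if ep in truth.active_peak_ids]
        return pd.DataFrame(rows).set_index("endpoint")


class SpectrumEffectModel:
    """Three-method spectrum-effect relationship model for one dataset.

    Parameters
    ----------
    matrix : CommonPeakMatrix
        Common-peak areas, typically restricted to linearity-retained peaks
        (``retain`` lists them; default all columns).
    effects : EffectTable
        Oriented per-batch activities for one or more endpoints.
    config : ScreenConfig, optional
    retain : list of peak ids, optional
    """

    def __init__(self, matrix: CommonPeakMatrix, effects: EffectTable,
                 config: ScreenConfig | None = None, retain: list[str] | None = None):
        if set(effects.batches) != set(matrix.batches):
            raise SpecfxError("matrix and effect table cover different batches")
        self.matrix = matrix
        self.effects = effects
        self.config = config or ScreenConfig()
        cols = list(retain) if retain is not None else list(matrix.peak_ids)
        unknown = set(cols) - set(matrix.peak_ids)
        if unknown:
            raise SpecfxError(f"retain lists unknown peaks: {sorted(unknown)}")
        self.areas = matrix.areas.loc[effects.batches, cols]

    @classmethod
    def from_dataframes(cls, areas: pd.DataFrame, raw_effects: pd.DataFrame,
                        **kwargs) -> "SpectrumEffectModel":
        """Build directly from a batches x peaks area frame and raw endpoint
        values (orientation applied via the standard endpoint kinds)."""
        from .effects import assemble_effects
        from .peaks import CommonPeakMatrix
        meta = pd.DataFrame({"rt_min": range(1, len(areas.columns) + 1),
                             "mode": "positive"}, index=areas.columns)
        matrix = CommonPeakMatrix(areas=areas, peak_meta=meta)
        return cls(matrix, assemble_effects(raw_effects), **kwargs)

    def fit(self, seed: int = 0) -> SpectrumEffectResults:
        cfg = self.config
        gra_res, pls_res, miv_res, consensus = {}, {}, {}, {}
        for k, ep in enumerate(self.effects.endpoints):
            activity = self.effects.activity[ep]
            gra_res[ep] = gra_select(self.areas, activity, rho=cfg.gra_rho,
                                     threshold=cfg.gra_threshold,
                                     normalization=cfg.gra_normalization)
            pls_res[ep] = pls_screen(self.areas, activity,
                                     max_components=cfg.pls_max_components,
                                     vip_threshold=cfg.vip_threshold,
                                     require_positive=cfg.pls_require_positive)
            miv_res[ep] = ann_screen(self.areas, activity, config=cfg.ann,
                                     seed=(int(seed) * 1000003 + k) % (2 ** 31),
                                     delta=cfg.miv_delta)
            consensus[ep] = cns.intersect_per_effect(
                gra_res[ep].selected, pls_res[ep].selected, miv_res[ep].selected,
                universe=self.areas.columns)
        overlaps = (cns.shared_across_effects(consensus)
                    if len(consensus) >= 2 else {})
        return SpectrumEffectResults(gra=gra_res, pls=pls_res, miv=miv_res,
                                     consensus=consensus, overlaps=overlaps,
                                     config=cfg, seed=int(seed),
                                     peak_ids=list(self.areas.columns))
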