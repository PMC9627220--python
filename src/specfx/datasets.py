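"""Published reference values for the ten-batch QYSLD screening study.

These are the printed result lists and tables of the original ten-batch
Qi-Yu-San-Long decoction (QYSLD) spectrum-effect study: the per-endpoint
consensus peak sets obtained by intersecting GRA, PLSR-VIP and BP-ANN/MIV
selections; the antioxidant endpoint values per batch; and the eleven
peaks dropped by the calibration linearity screen.  They serve as inputs
for the pure set-algebra operations (cross-endpoint overlaps) and for
orientation/ranking checks — the study's raw peak-area and assay tables
are not publicly deposited, so nothing here can stand in for them.
"""

from __future__ import annotations

import pandas as pd

#: consensus (three-method intersection) active peaks per endpoint
QYSLD_CONSENSUS_SETS: dict[str, frozenset] = {
    "dpph_ic50": frozenset({"P1", "P4", "P24", "P28", "P34", "P62", "P68", "P70"}),
    "frap": frozenset({"P4", "P7", "P10", "P17", "P37", "P39", "P46", "P50", "P67"}),
    "viability": frozenset({"P1", "P4", "P28", "P37", "P44", "P62"}),
    "healing": frozenset({"P2", "P7", "P8", "P13", "P20", "P21", "P23", "P24",
                          "P28", "P30", "P34", "P35", "P36", "P42", "P44", "P48",
                          "P49", "P51", "P60", "P62", "P68", "P70"}),
    "migration": frozenset({"P24", "P28", "P44", "P62", "P70"}),
    "invasion": frozenset({"P1", "P5", "P7", "P10", "P16", "P21", "P23", "P24",
                           "P28", "P34", "P35", "P70"}),
}

#: peaks that failed the QC-dilution calibration linearity standard (R2 < 0.99)
QYSLD_LINEARITY_DROPPED: frozenset = frozenset(
    {"P3", "P11", "P27", "P31", "P33", "P40", "P41", "P45", "P53", "P57", "P69"})

#: PLSR positive-contribution order for the DPPH endpoint (VIP > 1, coef > 0)
QYSLD_PLSR_DPPH_ORDER = ("P28", "P24", "P32", "P62", "P70", "P39", "P68",
                         "P1", "P4", "P61", "P34")


def qysld_antioxidant_table() -> pd.DataFrame:
    """Reported antioxidant endpoints per batch: DPPH IC50 (mg/mL) and FRAP
    (µmol/L Fe2+ equivalents), means over three replicates."""
    data = {
        "S1": (1.71, 463.83), "S2": (5.50, 143.83), "S3": (1.59, 873.83),
        "S4": (3.19, 327.58), "S5": (3.24, 251.33), "S6": (2.65, 372.58),
        "S7": (3.41, 390.92), "S8": (2.43, 382.33), "S9": (3.51, 208.42),
        "S10": (3.40, 352.17),
    }
    df = pd.DataFrame(data, index=["dpph_ic50", "frap"]).T
    df.index.name = "batch"
    return df
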