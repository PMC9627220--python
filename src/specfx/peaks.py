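"""Common-peak fingerprint matrix construction and quality control.

Batches of an LC-MS fingerprint are delivered as per-sample peak tables
(peak id, retention time, integrated area, ion mode).  This module matches
peaks across batches into a common-peak matrix, computes internal-standard
relative metrics (RRT/RPA), dispersion statistics (RSD/CV%), screens peaks
for calibration linearity against a QC dilution series, evaluates per-batch
fingerprint similarity against a reference fingerprint, and round-trips the
legacy two-block TXT exchange format used by fingerprint similarity software.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AmbiguousMatchError, PeakTableParseError, SpecfxError

PEAK_TABLE_COLUMNS = ["sample", "peak_id", "rt_min", "area", "mode"]
ION_MODES = ("positive", "negative")


# ---------------------------------------------------------------------------
# Peak tables
# ---------------------------------------------------------------------------

@dataclass
class PeakTable:
    """One sample's peak list: id, retention time (min), area, ion mode."""

    sample: str
    peaks: pd.DataFrame  # columns: peak_id, rt_min, area, mode

    def __post_init__(self):
        self.peaks = self.peaks.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        required = {"peak_id", "rt_min", "area", "mode"}
        missing = required - set(self.peaks.columns)
        if missing:
            raise SpecfxError(f"peak table {self.sample!r} missing columns {sorted(missing)}")
        if (self.peaks["area"] < 0).any():
            bad = self.peaks.index[self.peaks["area"] < 0][0]
            raise SpecfxError(f"peak table {self.sample!r}: negative area at row {bad}")
        bad_mode = ~self.peaks["mode"].isin(ION_MODES)
        if bad_mode.any():
            raise SpecfxError(
                f"peak table {self.sample!r}: unknown ion mode "
                f"{self.peaks['mode'][bad_mode].iloc[0]!r}"
            )
        for mode, sub in self.peaks.groupby("mode"):
            rt = np.sort(sub["rt_min"].to_numpy(float))
            if len(rt) > 1 and (np.diff(rt) <= 0).any():
                raise SpecfxError(
                    f"peak table {self.sample!r}: duplicate retention time in {mode} mode"
                )

    def __len__(self) -> int:
        return len(self.peaks)


def read_peak_table(path) -> PeakTable:
    """Read one delimited peak table (header: sample,peak_id,rt_min,area,mode)."""
    try:
        df = pd.read_csv(path, dtype={"sample": str, "peak_id": str, "mode": str})
    except Exception as exc:  # malformed CSV
        raise PeakTableParseError(f"cannot parse peak table: {exc}", path=path) from exc
    missing = set(PEAK_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise PeakTableParseError(f"missing column(s) {sorted(missing)}", path=path)
    for col in ("rt_min", "area"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            row = int((numeric.isna()).idxmax())
            # +2: header line plus 1-based indexing
            raise PeakTableParseError(f"non-numeric {col}", path=path, line=row + 2)
        df[col] = numeric
    neg = df.index[df["area"] < 0]
    if len(neg):
        raise PeakTableParseError("negative area", path=path, line=int(neg[0]) + 2)
    samples = df["sample"].unique()
    if len(samples) != 1:
        raise PeakTableParseError(f"expected one sample per file, found {list(samples)}", path=path)
    return PeakTable(sample=samples[0], peaks=df[["peak_id", "rt_min", "area", "mode"]])


def read_peak_tables(paths) -> list[PeakTable]:
    return [read_peak_table(p) for p in paths]


def write_peak_table(table: PeakTable, path) -> None:
    out = table.peaks.copy()
    out.insert(0, "sample", table.sample)
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Common-peak matrix
# ---------------------------------------------------------------------------

@dataclass
class CommonPeakMatrix:
    """Batches x common peaks of integrated areas with peak metadata.

    ``areas`` is indexed by batch id with common-peak ids (P1..Pn) as
    columns.  ``peak_meta`` carries the consensus retention time and ion
    mode per peak; ``rt`` optionally carries per-batch retention times (used
    for RRT); ``is_peak`` names the internal-standard column.
    """

    areas: pd.DataFrame
    peak_meta: pd.DataFrame  # index: peak ids; columns: rt_min, mode
    is_peak: str | None = None
    rt: pd.DataFrame | None = None
    match_report: dict = field(default_factory=dict)

    def __post_init__(self):
        if list(self.areas.columns) != list(self.peak_meta.index):
            raise SpecfxError("areas columns and peak_meta index disagree")
        if self.areas.isna().any().any():
            raise SpecfxError("common-peak matrix has missing cells")
        if self.is_peak is not None and self.is_peak not in self.areas.columns:
            raise SpecfxError(f"internal standard {self.is_peak!r} is not a matrix column")

    @property
    def batches(self) -> list[str]:
        return list(self.areas.index)

    @property
    def peak_ids(self) -> list[str]:
        return list(self.areas.columns)

    def to_csv(self, area_path, meta_path) -> None:
        self.areas.to_csv(area_path, index_label="batch")
        meta = self.peak_meta.copy()
        meta["is_peak"] = [pid == self.is_peak for pid in meta.index]
        meta.to_csv(meta_path, index_label="peak_id")

    @classmethod
    def from_csv(cls, area_path, meta_path) -> "CommonPeakMatrix":
        areas = pd.read_csv(area_path, index_col="batch")
        meta = pd.read_csv(meta_path, index_col="peak_id")
        is_flags = meta.pop("is_peak")
        is_peak = is_flags.index[is_flags.astype(bool)]
        return cls(areas=areas, peak_meta=meta,
                   is_peak=is_peak[0] if len(is_peak) else None)


def assign_peak_ids(meta: pd.DataFrame) -> list[str]:
    """Order peaks positive-mode block first, by consensus RT, and name P1..Pn."""
    mode_rank = {"positive": 0, "negative": 1}
    order = sorted(range(len(meta)),
                   key=lambda i: (mode_rank[meta["mode"].iloc[i]], meta["rt_min"].iloc[i]))
    ids = [""] * len(meta)
    for rank, i in enumerate(order):
        ids[i] = f"P{rank + 1}"
    return ids


def match_common_peaks(tables: list[PeakTable], rt_tolerance: float = 0.2,
                       is_peak_id: str | None = None) -> CommonPeakMatrix:
    """Match peaks across batches into a common-peak matrix.

    A common peak exists iff every batch contributes exactly one peak within
    ``rt_tolerance`` minutes of the consensus (median) retention time of the
    cluster, matched within ion mode.  Peaks absent from any batch are
    excluded and reported in ``match_report``; two peaks of one batch inside
    the tolerance raise :class:`AmbiguousMatchError`.  Columns are named
    P1..Pn ordered by ion mode block then consensus RT, so peak identity is
    stable across reruns.  The result is invariant to the order of the input
    tables (clusters are built from the pooled, RT-sorted peak list).
    """
    if len(tables) < 2:
        raise SpecfxError("need at least 2 peak tables to match")
    if rt_tolerance <= 0:
        raise SpecfxError("rt_tolerance must be positive")
    samples = [t.sample for t in tables]
    if len(set(samples)) != len(samples):
        raise SpecfxError("duplicate sample ids among peak tables")

    pooled = []
    for t in tables:
        for _, row in t.peaks.iterrows():
            pooled.append((row["mode"], float(row["rt_min"]), t.sample,
                           str(row["peak_id"]), float(row["area"])))
    kept, excluded = [], []
    for mode in ION_MODES:
        peaks = sorted((p for p in pooled if p[0] == mode), key=lambda p: (p[1], p[2]))
        cluster: list[tuple] = []
        clusters = []
        for p in peaks:
            if cluster and p[1] - float(np.median([q[1] for q in cluster])) > rt_tolerance:
                clusters.append(cluster)
                cluster = []
            cluster.append(p)
        if cluster:
            clusters.append(cluster)
        for cl in clusters:
            med = float(np.median([q[1] for q in cl]))
            by_batch: dict[str, list] = {}
            for q in cl:
                by_batch.setdefault(q[2], []).append(q)
            for batch, members in by_batch.items():
                if len(members) > 1:
                    rts = [m[1] for m in members]
                    raise AmbiguousMatchError(
                        f"batch {batch!r} has {len(members)} peaks within "
                        f"{rt_tolerance} min of consensus RT {med:.3f} ({mode}): {rts}"
                    )
            if set(by_batch) == set(samples) and all(
                abs(q[1] - med) <= rt_tolerance for q in cl
            ):
                kept.append((mode, med, {b: m[0] for b, m in by_batch.items()}))
            else:
                excluded.append({"mode": mode, "rt_min": med,
                                 "present_in": sorted(by_batch)})

    if not kept:
        raise SpecfxError("no common peaks found")
    meta = pd.DataFrame({"rt_min": [k[1] for k in kept], "mode": [k[0] for k in kept]})
    ids = assign_peak_ids(meta)
    meta.index = pd.Index(ids, name="peak_id")
    order = sorted(range(len(kept)), key=lambda i: int(ids[i][1:]))

    areas = pd.DataFrame(index=pd.Index(samples, name="batch"))
    rts = pd.DataFrame(index=pd.Index(samples, name="batch"))
    source_ids: dict[str, set] = {}
    for i in order:
        mode, med, by_batch = kept[i]
        pid = ids[i]
        areas[pid] = [by_batch[s][4] for s in samples]
        rts[pid] = [by_batch[s][1] for s in samples]
        source_ids[pid] = {by_batch[s][3] for s in samples}
    meta = meta.loc[list(areas.columns)]

    is_peak = None
    if is_peak_id is not None:
        hits = [pid for pid, src in source_ids.items() if is_peak_id in src]
        if not hits:
            raise SpecfxError(f"internal standard id {is_peak_id!r} not found in any common peak")
        is_peak = hits[0]
    return CommonPeakMatrix(areas=areas, peak_meta=meta, is_peak=is_peak, rt=rts,
                            match_report={"excluded": excluded,
                                          "n_common": len(areas.columns)})


# ---------------------------------------------------------------------------
# Internal-standard relative metrics
# ---------------------------------------------------------------------------

@dataclass
class RelativeMetrics:
    """RRT and RPA per batch per peak, relative to the internal standard."""

    rrt: pd.DataFrame
    rpa: pd.DataFrame


def relative_to_is(matrix: CommonPeakMatrix) -> RelativeMetrics:
    """Relative retention time and relative peak area against the IS peak."""
    if matrix.is_peak is None:
        raise SpecfxError("no internal standard designated")
    is_area = matrix.areas[matrix.is_peak]
    zero = is_area.index[is_area <= 0]
    if len(zero):
        raise SpecfxError(f"internal standard area is not positive in batch {zero[0]!r}")
    rpa = matrix.areas.div(is_area, axis=0)
    if matrix.rt is not None:
        rrt = matrix.rt.div(matrix.rt[matrix.is_peak], axis=0)
    else:  # consensus RT only: RRT constant across batches
        ref = matrix.peak_meta.loc[matrix.is_peak, "rt_min"]
        row = matrix.peak_meta["rt_min"] / ref
        rrt = pd.DataFrame([row] * len(matrix.areas), index=matrix.areas.index)
    return RelativeMetrics(rrt=rrt, rpa=rpa)


def dispersion_stats(values, mode: str = "rsd") -> float:
    """RSD/CV% = 100 * sample standard deviation / mean (mode only labels)."""
    if mode not in ("rsd", "cv"):
        raise SpecfxError(f"unknown dispersion mode {mode!r}")
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise SpecfxError("need at least 2 values for a dispersion statistic")
    mean = x.mean()
    if mean == 0:
        raise SpecfxError("dispersion undefined for zero mean")
    return float(100.0 * x.std(ddof=1) / mean)


# ---------------------------------------------------------------------------
# Linearity screen
# ---------------------------------------------------------------------------

@dataclass
class LinearityReport:
    """Per-peak calibration OLS fit and the retained/dropped partition."""

    stats: pd.DataFrame  # index: peak ids; columns: slope, intercept, r2
    retained: list[str]
    dropped: list[str]
    threshold: float


def linearity_screen(calibrations: pd.DataFrame, r2_threshold: float = 0.99) -> LinearityReport:
    """OLS of area ratio on relative concentration (1/dilution) per peak.

    ``calibrations`` rows are indexed by dilution factor, columns are peak
    ids, values are analyte/IS area ratios.  Peaks whose coefficient of
    determination falls below ``r2_threshold`` are dropped.
    """
    dil = np.asarray(calibrations.index, dtype=float)
    if len(dil) < 3:
        raise SpecfxError("need at least 3 dilution points")
    x = 1.0 / dil
    if np.ptp(x) == 0:
        raise SpecfxError("degenerate calibration: all concentrations equal")
    rows = {}
    for pid in calibrations.columns:
        y = calibrations[pid].to_numpy(float)
        fit = stats.linregress(x, y)
        rows[pid] = {"slope": fit.slope, "intercept": fit.intercept,
                     "r2": fit.rvalue ** 2}
    table = pd.DataFrame(rows).T
    retained = [p for p in calibrations.columns if table.loc[p, "r2"] >= r2_threshold]
    dropped = [p for p in calibrations.columns if p not in retained]
    return LinearityReport(stats=table, retained=retained, dropped=dropped,
                           threshold=r2_threshold)


# ---------------------------------------------------------------------------
# Fingerprint similarity
# ---------------------------------------------------------------------------

def _cosine(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise SpecfxError("cosine similarity undefined for a zero-norm fingerprint")
    return float(u @ v / (nu * nv))


def fingerprint_similarity(matrix: CommonPeakMatrix, reference: str = "mean") -> pd.Series:
    """Uncentered cosine of each batch fingerprint against the reference.

    The reference fingerprint is the mean (or median) common-peak area
    vector across batches, the documented default of fingerprint similarity
    software for herbal medicines.
    """
    if len(matrix.areas) < 2:
        raise SpecfxError("need at least 2 batches for similarity evaluation")
    X = matrix.areas.to_numpy(float)
    if reference == "mean":
        ref = X.mean(axis=0)
    elif reference == "median":
        ref = np.median(X, axis=0)
    else:
        raise SpecfxError(f"unknown reference {reference!r}")
    sims = [_cosine(row, ref) for row in X]
    return pd.Series(sims, index=matrix.areas.index, name=f"similarity_vs_{reference}")


def pairwise_similarity(matrix: CommonPeakMatrix) -> pd.DataFrame:
    """Uncentered cosine similarity between every pair of batch fingerprints."""
    X = matrix.areas.to_numpy(float)
    n = len(X)
    out = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = _cosine(X[i], X[j])
    return pd.DataFrame(out, index=matrix.areas.index, columns=matrix.areas.index)


# ---------------------------------------------------------------------------
# Legacy two-block TXT exchange format
# ---------------------------------------------------------------------------

_B1_HEADER = "DATASET1\trt_min\tintensity"
_B2_HEADER = "DATASET2\trt_min\theight\tarea"


def write_legacy_fingerprint(matrix: CommonPeakMatrix, traces: pd.DataFrame | None,
                             path, encoding: str = "latin-1") -> None:
    """Write the two-block single-byte-encoded TXT exchange layout.

    Block 1 holds retention time and peak intensity in peak (column) order;
    block 2 holds retention time, peak height and integrated area ordered by
    retention time ascending.  ``traces`` may supply chromatogram points
    (columns rt_min, intensity) for block 1; otherwise the consensus RT and
    mean area per common peak stand in.  The layout is a documented
    reconstruction of the prose description of the legacy dialect.
    """
    if matrix.areas.empty or not len(matrix.areas.columns):
        raise SpecfxError("refusing to write legacy fingerprint for an empty matrix")
    mean_area = matrix.areas.mean(axis=0)
    if traces is None:
        traces = pd.DataFrame({"rt_min": matrix.peak_meta["rt_min"].to_numpy(float),
                               "intensity": mean_area.to_numpy(float)})
    buf = io.StringIO()
    buf.write(_B1_HEADER + "\n")
    for _, row in traces.iterrows():
        buf.write(f"{float(row['rt_min'])!r}\t{float(row['intensity'])!r}\n")
    buf.write(_B2_HEADER + "\n")
    block2 = pd.DataFrame({"rt_min": matrix.peak_meta["rt_min"].to_numpy(float),
                           "height": mean_area.to_numpy(float),
                           "area": mean_area.to_numpy(float)})
    block2 = block2.sort_values("rt_min", kind="stable")
    for _, row in block2.iterrows():
        buf.write(f"{float(row['rt_min'])!r}\t{float(row['height'])!r}\t{float(row['area'])!r}\n")
    data = buf.getvalue()
    try:
        data.encode(encoding)
    except UnicodeEncodeError as exc:
        raise SpecfxError(f"content not representable in single-byte encoding: {exc}")
    with open(path, "w", encoding=encoding, newline="\n") as fh:
        fh.write(data)


def read_legacy_fingerprint(path, encoding: str = "latin-1"):
    """Read back the two blocks written by :func:`write_legacy_fingerprint`."""
    with open(path, encoding=encoding) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines or lines[0] != _B1_HEADER:
        raise SpecfxError("not a legacy fingerprint file (missing DATASET1 header)")
    try:
        split = lines.index(_B2_HEADER)
    except ValueError:
        raise SpecfxError("missing DATASET2 header")
    b1 = pd.DataFrame([[float(v) for v in ln.split("\t")] for ln in lines[1:split]],
                      columns=["rt_min", "intensity"])
    b2 = pd.DataFrame([[float(v) for v in ln.split("\t")] for ln in lines[split + 1:]],
                      columns=["rt_min", "height", "area"])
    return b1, b2
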