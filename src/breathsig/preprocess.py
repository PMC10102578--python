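"""Raw recordings -> breath-profile matrix.

Pipeline: resample each scan onto a fixed 0.0005 Th grid over 50-500 Th,
detect exhalation windows on the TIC trace, average the exhalation spectra,
pick peaks against a rolling median + MAD baseline, integrate them by the
trapezoid rule, align apexes across samples, TIC-normalize and log2.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MZ_MAX, MZ_MIN, ScanSeries

__all__ = [
    "MZ_GRID_STEP",
    "mz_grid",
    "resample_spectrum",
    "ExhalationSegments",
    "detect_exhalations",
    "average_exhalation_spectrum",
    "PeakTable",
    "pick_peaks",
    "align_features",
    "normalize_and_log",
    "BreathProfileMatrix",
    "recalibrate_mz",
    "process_sample",
    "build_matrix",
]

log = logging.getLogger(__name__)

MZ_GRID_STEP = 0.0005
_N_GRID = int(round((MZ_MAX - MZ_MIN) / MZ_GRID_STEP)) + 1


def mz_grid() -> np.ndarray:
    """The standard uniform m/z axis: 0.0005 Th steps over [50, 500]."""
    return MZ_MIN + np.arange(_N_GRID) * MZ_GRID_STEP


def resample_spectrum(mz: np.ndarray, intensity: np.ndarray) -> np.ndarray:
    """Linear interpolation of one scan onto the standard grid.

    Returns zero outside the scan's m/z support.
    """
    mz = np.asarray(mz, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if len(mz) > 1 and not np.all(np.diff(mz) > 0):
        raise ValueError("mz array must be strictly ascending")
    if len(mz) == 0:
        return np.zeros(_N_GRID)
    grid = mz_grid()
    out = np.interp(grid, mz, intensity, left=0.0, right=0.0)
    out[(grid < mz[0]) | (grid > mz[-1])] = 0.0
    return out


@dataclass
class ExhalationSegments:
    """Half-open scan-index intervals classified as exhalation."""

    segments: list[tuple[int, int]]
    tic_trace: np.ndarray
    warning: bool = False  # fewer than 3 exhalations found

    def __len__(self) -> int:
        return len(self.segments)

    def scan_indices(self) -> np.ndarray:
        idx = [np.arange(a, b) for a, b in self.segments]
        return np.concatenate(idx) if idx else np.array([], dtype=int)


def detect_exhalations(
    tic_trace: np.ndarray,
    scan_period: float,
    min_duration_s: float = 3.0,
    k_mad: float = 3.0,
    merge_gap_scans: int = 2,
) -> ExhalationSegments:
    """Threshold the TIC at median + k_mad x MAD and keep long plateaus.

    Above-threshold runs separated by gaps of <= ``merge_gap_scans`` scans
    are merged; runs shorter than ``min_duration_s`` are dropped. A warning
    flag is set when fewer than three segments remain.
    """
    tic = np.asarray(tic_trace, dtype=float)
    if len(tic) < 20:
        raise ValueError("need at least 20 scans to detect exhalations")
    med = np.median(tic)
    mad = np.median(np.abs(tic - med))
    mask = tic > med + k_mad * mad

    segments: list[tuple[int, int]] = []
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            segments.append((start, i))
            start = None
    if start is not None:
        segments.append((start, len(mask)))

    merged: list[tuple[int, int]] = []
    for seg in segments:
        if merged and seg[0] - merged[-1][1] <= merge_gap_scans:
            merged[-1] = (merged[-1][0], seg[1])
        else:
            merged.append(seg)

    min_scans = max(1, int(np.ceil(min_duration_s / scan_period)))
    kept = [s for s in merged if s[1] - s[0] >= min_scans]
    warning = len(kept) < 3
    if warning:
        log.warning("only %d exhalation segment(s) detected", len(kept))
    return ExhalationSegments(segments=kept, tic_trace=tic, warning=warning)


def average_exhalation_spectrum(
    series: ScanSeries, segments: ExhalationSegments
) -> np.ndarray:
    """Pointwise mean of the resampled scans inside exhalation segments."""
    idx = segments.scan_indices()
    if len(idx) == 0:
        raise ValueError("no exhalation segments to average")
    acc = np.zeros(_N_GRID)
    for i in idx:
        acc += resample_spectrum(series.mz_arrays[i], series.intensity_arrays[i])
    return acc / len(idx)


@dataclass
class PeakTable:
    """Picked peaks on the standard grid: apex, bounds, trapezoid area."""

    table: pd.DataFrame  # apex_mz, left_mz, right_mz, area, apex_intensity

    def __len__(self) -> int:
        return len(self.table)


def _block_baseline(y: np.ndarray, window_pts: int) -> tuple[np.ndarray, np.ndarray]:
    """Blockwise median and MAD, linearly interpolated back to the grid."""
    n = len(y)
    edges = np.arange(0, n, window_pts)
    centers, meds, mads = [], [], []
    for a in edges:
        b = min(a + window_pts, n)
        block = y[a:b]
        m = np.median(block)
        centers.append((a + b - 1) / 2.0)
        meds.append(m)
        mads.append(np.median(np.abs(block - m)))
    x = np.arange(n)
    return np.interp(x, centers, meds), np.interp(x, centers, mads)


def pick_peaks(
    avg_spectrum: np.ndarray, snr_k: float = 5.0, window_Th: float = 1.0
) -> PeakTable:
    """Local maxima above a rolling median + snr_k x MAD baseline.

    Peak bounds are the nearest flanking local minima; areas are trapezoid
    integrals of the grid between the bounds.
    """
    y = np.asarray(avg_spectrum, dtype=float)
    if len(y) != _N_GRID:
        raise ValueError("spectrum must be on the standard grid")
    grid = mz_grid()
    window_pts = max(3, int(round(window_Th / MZ_GRID_STEP)))
    base_med, base_mad = _block_baseline(y, window_pts)
    thresh = base_med + snr_k * np.maximum(base_mad, 1e-12)

    interior = np.arange(1, len(y) - 1)
    is_max = (y[interior] > y[interior - 1]) & (y[interior] >= y[interior + 1])
    apexes = interior[is_max & (y[interior] > thresh[interior])]

    is_min = (y[interior] <= y[interior - 1]) & (y[interior] <= y[interior + 1])
    minima = np.concatenate([[0], interior[is_min], [len(y) - 1]])

    rows = []
    last_right = -1
    for apex in apexes:
        li = minima[np.searchsorted(minima, apex) - 1]
        ri = minima[np.searchsorted(minima, apex, side="right")]
        if li <= last_right:  # keep peaks non-overlapping
            li = last_right
        if ri <= li + 1:
            continue
        area = float(np.trapezoid(y[li : ri + 1], grid[li : ri + 1]))
        if area <= 0:
            continue
        rows.append(
            {
                "apex_mz": grid[apex],
                "left_mz": grid[li],
                "right_mz": grid[ri],
                "area": area,
                "apex_intensity": y[apex],
            }
        )
        last_right = ri
    return PeakTable(pd.DataFrame(rows, columns=["apex_mz", "left_mz", "right_mz", "area", "apex_intensity"]))


def align_features(
    peak_tables: list[PeakTable],
    tol_ppm: float = 10.0,
    presence_fraction: float = 0.7,
) -> tuple[np.ndarray, np.ndarray]:
    """Bin apex m/z values across samples into consensus features.

    Single-linkage binning on the sorted pooled apex list with a cluster
    diameter of <= ``tol_ppm``; the consensus m/z is the intensity-weighted
    mean of the member apexes. Features present in fewer than
    ``presence_fraction`` of the samples are dropped; absent cells are zero
    (imputed at the normalization step).

    Returns (areas matrix samples x features, consensus feature m/z).
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be > 0")
    if len(peak_tables) < 2:
        raise ValueError("need >= 2 samples to align")
    pooled = []
    for si, pt in enumerate(peak_tables):
        for _, r in pt.table.iterrows():
            pooled.append((r["apex_mz"], r["area"], si))
    if not pooled:
        return np.zeros((len(peak_tables), 0)), np.array([])
    pooled.sort()

    clusters: list[list[tuple[float, float, int]]] = [[pooled[0]]]
    for item in pooled[1:]:
        start_mz = clusters[-1][0][0]
        if (item[0] - start_mz) / start_mz * 1e6 <= tol_ppm:
            clusters[-1].append(item)
        else:
            clusters.append([item])

    n_samples = len(peak_tables)
    feature_mz, columns = [], []
    for cl in clusters:
        present = {si for _, _, si in cl}
        if len(present) / n_samples < presence_fraction:
            continue
        mzs = np.array([m for m, _, _ in cl])
        areas = np.array([a for _, a, _ in cl])
        feature_mz.append(float(np.average(mzs, weights=areas)))
        col = np.zeros(n_samples)
        for m, a, si in cl:
            col[si] += a
        columns.append(col)
    if not columns:
        return np.zeros((n_samples, 0)), np.array([])
    matrix = np.column_stack(columns)
    order = np.argsort(feature_mz)
    return matrix[:, order], np.asarray(feature_mz)[order]


@dataclass
class BreathProfileMatrix:
    """Samples x features log2 TIC-normalized breath profiles."""

    values: np.ndarray
    feature_mz: np.ndarray
    sample_ids: list[str]
    polarity: str = "positive"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_mz = np.asarray(self.feature_mz, dtype=float)
        if np.any(np.isnan(self.values)):
            raise ValueError("breath profile matrix must be complete")
        if len(self.feature_mz) > 1 and not np.all(np.diff(self.feature_mz) > 0):
            raise ValueError("feature m/z must be sorted ascending")
        if self.values.shape[1] != len(self.feature_mz):
            raise ValueError("column count must equal feature count")


def normalize_and_log(
    areas: np.ndarray, feature_mz, sample_ids, polarity: str = "positive"
) -> BreathProfileMatrix:
    """TIC-normalize each sample, impute zeros at half-minimum, then log2."""
    A = np.asarray(areas, dtype=float)
    if np.any(A < 0):
        raise ValueError("areas must be >= 0")
    tic = A.sum(axis=1, keepdims=True)
    if np.any(tic <= 0):
        raise ValueError("every sample needs positive total area")
    norm = A / tic
    out = norm.copy()
    for i in range(out.shape[0]):
        row = out[i]
        pos = row[row > 0]
        if len(pos) == 0:
            raise ValueError(f"sample {i} has no positive areas")
        row[row == 0] = pos.min() / 2.0
    return BreathProfileMatrix(
        values=np.log2(out),
        feature_mz=np.asarray(feature_mz, dtype=float),
        sample_ids=list(sample_ids),
        polarity=polarity,
    )


def recalibrate_mz(
    mz: np.ndarray,
    point1: tuple[float, float],
    point2: tuple[float, float],
) -> np.ndarray:
    """Linear two-point recalibration: (observed, reference) pairs."""
    (o1, r1), (o2, r2) = point1, point2
    if o1 == o2:
        raise ValueError("calibration points must have distinct observed m/z")
    slope = (r2 - r1) / (o2 - o1)
    return r1 + (np.asarray(mz, dtype=float) - o1) * slope


@dataclass
class SampleQC:
    sample_id: str
    n_scans: int
    n_exhalations: int
    n_peaks: int
    warning: bool


def process_sample(
    series: ScanSeries,
    min_duration_s: float = 3.0,
    k_mad: float = 3.0,
    snr_k: float = 5.0,
    window_Th: float = 1.0,
) -> tuple[PeakTable, SampleQC]:
    """Detect exhalations, average, and pick peaks for one recording."""
    scan_period = float(np.median(np.diff(series.times))) if len(series) > 1 else 0.5
    segments = detect_exhalations(series.tic(), scan_period, min_duration_s, k_mad)
    if len(segments) == 0:
        raise ValueError(f"no exhalation detected in sample {series.sample_id!r}")
    avg = average_exhalation_spectrum(series, segments)
    peaks = pick_peaks(avg, snr_k=snr_k, window_Th=window_Th)
    qc = SampleQC(
        sample_id=series.sample_id,
        n_scans=len(series),
        n_exhalations=len(segments),
        n_peaks=len(peaks),
        warning=segments.warning,
    )
    log.info(
        "sample %s: %d scans, %d exhalations, %d peaks",
        qc.sample_id, qc.n_scans, qc.n_exhalations, qc.n_peaks,
    )
    return peaks, qc


def build_matrix(
    recordings: list[ScanSeries],
    tol_ppm: float = 10.0,
    presence_fraction: float = 0.7,
    **sample_kwargs,
) -> tuple[BreathProfileMatrix, list[SampleQC]]:
    """Full preprocessing of a set of recordings into a breath-profile matrix."""
    tables, qcs = [], []
    for series in recordings:
        pt, qc = process_sample(series, **sample_kwargs)
        tables.append(pt)
        qcs.append(qc)
    areas, feature_mz = align_features(tables, tol_ppm, presence_fraction)
    bpm = normalize_and_log(
        areas,
        feature_mz,
        [s.sample_id for s in recordings],
        polarity=recordings[0].polarity,
    )
    return bpm, qcs
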