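"""ROI time series to functional-connectivity vectors.

The processing order is fixed: band-pass filter the ROI series *and* the
nuisance regressors, regress the filtered regressors out of the filtered
series, then correlate over the frames that survive motion scrubbing.
Filtering always sees the full series; frame exclusion happens only at the
correlation stage, because censoring before filtering would corrupt the
frequency content of the retained frames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "RoiTimeSeries",
    "QualityMetrics",
    "ConnectivityVector",
    "frame_displacement",
    "mean_relative_displacement",
    "scrub_mask",
    "bandpass",
    "nuisance_regress",
    "fc_vector",
    "fc_index_pairs",
    "n_fc_pairs",
    "process_subject",
]

#: Radius (mm) of the sphere used to convert rotational motion parameters
#: (radians) to an arc-length displacement in millimetres before summation
#: into frame displacement. Pass ``rotation_radius_mm=None`` to sum raw
#: radians instead.
DEFAULT_ROTATION_RADIUS_MM = 50.0


@dataclass
class RoiTimeSeries:
    """One subject's extracted ROI signals and nuisance series.

    Parameters
    ----------
    data : ndarray, shape (frames, regions)
        Mean signal per ROI per frame, arbitrary units.
    tr : float
        Repetition time, seconds per frame.
    motion : ndarray, shape (frames, 6)
        Rigid-body motion parameters: three translations (mm) followed by
        three rotations (radians).
    tissue_signals : ndarray, shape (frames, 3)
        White-matter, CSF and whole-brain mean signals.
    """

    data: np.ndarray
    tr: float
    motion: np.ndarray
    tissue_signals: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.motion = np.asarray(self.motion, dtype=float)
        self.tissue_signals = np.asarray(self.tissue_signals, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] < 12:
            raise ValueError("time series needs >= 12 frames")
        if self.motion.shape != (self.data.shape[0], 6):
            raise ValueError("motion must be frames x 6")
        if self.tissue_signals.shape[0] != self.data.shape[0]:
            raise ValueError("tissue signals must match frame count")
        for arr in (self.data, self.motion, self.tissue_signals):
            if not np.all(np.isfinite(arr)):
                raise ValueError("missing or non-finite values")
        if self.tr <= 0:
            raise ValueError("tr must be positive")


@dataclass
class QualityMetrics:
    """Per-subject motion quality summary."""

    fd: np.ndarray
    mean_relative_displacement: np.ndarray
    retained_fraction: float


@dataclass
class ConnectivityVector:
    """Strict-lower-triangle Pearson FC vector.

    ``index_map[k] == (i, j)`` with ``i > j`` gives the 0-based region pair of
    vector position *k*; the order is row-major over the strict lower
    triangle: (1,0), (2,0), (2,1), (3,0), ...
    """

    values: np.ndarray
    index_map: list[tuple[int, int]] = field(repr=False)

    @property
    def n_regions(self) -> int:
        m = len(self.values)
        r = int(round((1 + np.sqrt(1 + 8 * m)) / 2))
        assert r * (r - 1) // 2 == m
        return r


def n_fc_pairs(n_regions: int) -> int:
    """Number of unordered region pairs, R(R-1)/2."""
    return n_regions * (n_regions - 1) // 2


def fc_index_pairs(n_regions: int) -> list[tuple[int, int]]:
    """Region pair per FC-vector position (row-major strict lower triangle)."""
    rows, cols = np.tril_indices(n_regions, k=-1)
    return list(zip(rows.tolist(), cols.tolist()))


def _motion_in_mm(motion: np.ndarray, rotation_radius_mm: float | None) -> np.ndarray:
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion must have exactly 6 columns")
    out = motion.copy()
    if rotation_radius_mm is not None:
        out[:, 3:] *= rotation_radius_mm
    return out


def frame_displacement(
    motion: np.ndarray,
    rotation_radius_mm: float | None = DEFAULT_ROTATION_RADIUS_MM,
) -> np.ndarray:
    """Frame displacement: summed absolute frame-to-frame parameter changes.

    ``fd[0] = 0`` and ``fd[t] = sum_p |p_t - p_{t-1}|`` over the six motion
    parameters, rotations converted to mm as arc length on a sphere of radius
    ``rotation_radius_mm`` (or left in radians if ``None``).
    """
    mm = _motion_in_mm(motion, rotation_radius_mm)
    if mm.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    fd = np.zeros(mm.shape[0])
    fd[1:] = np.abs(np.diff(mm, axis=0)).sum(axis=1)
    return fd

def mean_relative_displacement(
    motion: np.ndarray,
    rotation_radius_mm: float | None = DEFAULT_ROTATION_RADIUS_MM,
) -> np.ndarray:
    """Per-parameter mean absolute frame-to-frame change (6 values)."""
    mm = _motion_in_mm(motion, rotation_radius_mm)
    if mm.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    return np.abs(np.diff(mm, axis=0)).mean(axis=0)


def scrub_mask(fd: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Frame retention mask after motion scrubbing.

    A frame with ``fd > threshold`` is removed together with the previous
    frame and the two subsequent frames (where they exist).
    """
    fd = np.asarray(fd, dtype=float)
    if np.any(fd < 0):
        raise ValueError("fd must be nonnegative")
    n = len(fd)
    keep = np.ones(n, dtype=bool)
    for t in np.flatnonzero(fd > threshold):
        keep[max(t - 1, 0) : min(t + 3, n)] = False
    return keep


def bandpass(
    series: np.ndarray,
    tr: float,
    low: float = 0.008,
    high: float = 0.1,
) -> np.ndarray:
    """Zero-phase band-pass filter (transmission range ``low``–``high`` Hz).

    Realized as a second-order Butterworth band-pass applied forward and
    backward (`filtfilt`), so the effective magnitude response is squared and
    the phase response is identically zero — correlations between filtered
    series are not shifted in time.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    nyq = 0.5 / tr
    if not (0 < low < high < nyq):
        raise ValueError(f"need 0 < low < high < Nyquist ({nyq:g} Hz)")
    series = np.asarray(series, dtype=float)
    squeeze = series.ndim == 1
    if squeeze:
        series = series[:, None]
    b, a = signal.butter(2, [low / nyq, high / nyq], btype="bandpass")
    padlen = min(3 * max(len(a), len(b)), series.shape[0] - 1)
    out = signal.filtfilt(b, a, series, axis=0, padlen=padlen)
    return out[:, 0] if squeeze else out


def nuisance_regress(
    roi_series: np.ndarray,
    regressors: np.ndarray,
    tr: float,
    low: float = 0.008,
    high: float = 0.1,
) -> np.ndarray:
    """Band-pass both blocks, then project the regressors out of the series.

    The regressors (tissue signals and motion parameters) are filtered with
    the same band-pass as the ROI series before the regression, so that
    unfiltered regressors cannot reintroduce out-of-band fluctuations. An
    intercept column is always included. Rank-deficient regressor matrices
    are fit with the pseudo-inverse and flagged with a warning.
    """
    roi_series = np.asarray(roi_series, dtype=float)
    regressors = np.asarray(regressors, dtype=float)
    if regressors.shape[0] != roi_series.shape[0]:
        raise ValueError("regressors and series must have the same frame count")
    y = bandpass(roi_series, tr, low, high)
    x = bandpass(regressors, tr, low, high)
    design = np.column_stack([np.ones(x.shape[0]), x])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        warnings.warn("rank-deficient regressor matrix; using pseudo-inverse")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def fc_vector(series: np.ndarray, mask: np.ndarray | None = None) -> ConnectivityVector:
    """Pairwise Pearson correlations over retained frames.

    Pairs whose series are constant within the mask have an undefined
    correlation; these are stored as 0 and a warning is emitted so vector
    length stays fixed at R(R-1)/2.
    """
    series = np.asarray(series, dtype=float)
    if mask is None:
        mask = np.ones(series.shape[0], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    kept = series[mask]
    if kept.shape[0] < 5:
        raise ValueError("need >= 5 retained frames")
    n_regions = series.shape[1]
    sd = kept.std(axis=0)
    degenerate = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(kept, rowvar=False)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} constant region series; "
            "their correlations stored as 0"
        )
        corr[degenerate, :] = 0.0
        corr[:, degenerate] = 0.0
    rows, cols = np.tril_indices(n_regions, k=-1)
    values = np.clip(corr[rows, cols], -1.0, 1.0)
    return ConnectivityVector(values=values, index_map=fc_index_pairs(n_regions))


def process_subject(
    ts: RoiTimeSeries,
    fd_threshold: float = 0.5,
    rotation_radius_mm: float | None = DEFAULT_ROTATION_RADIUS_MM,
    include_global_signal: bool = True,
) -> tuple[ConnectivityVector, QualityMetrics]:
    """Full per-subject pipeline: filter, regress, scrub, correlate.

    ``include_global_signal=False`` drops the whole-brain column from the
    tissue regressors for datasets where global-signal regression is not
    wanted; the default keeps it.
    """
    fd = frame_displacement(ts.motion, rotation_radius_mm)
    mask = scrub_mask(fd, fd_threshold)
    tissue = ts.tissue_signals if include_global_signal else ts.tissue_signals[:, :2]
    regressors = np.column_stack([tissue, ts.motion])
    residuals = nuisance_regress(ts.data, regressors, ts.tr)
    vec = fc_vector(residuals, mask)
    qm = QualityMetrics(
        fd=fd,
        mean_relative_displacement=mean_relative_displacement(
            ts.motion, rotation_radius_mm
        ),
        retained_fraction=float(mask.mean()),
    )
    return vec, qm


def load_roi_timeseries(
    data_path: str,
    motion_path: str,
    tissue_path: str,
    tr: float,
) -> RoiTimeSeries:
    """Read one subject's TSV files (frames x regions, x 6 motion, x 3 tissue)."""
    return RoiTimeSeries(
        data=np.loadtxt(data_path, delimiter="\t"),
        tr=tr,
        motion=np.loadtxt(motion_path, delimiter="\t"),
        tissue_signals=np.loadtxt(tissue_path, delimiter="\t"),
    )


def write_fc_matrix(path: str, fc_matrix: np.ndarray, n_regions: int) -> None:
    """Write a subjects x pairs FC matrix as TSV with an index-map header.

    The header names each column ``r<i>-r<j>`` for the region pair (i, j),
    i > j, 0-based, in the package's row-major lower-triangle order, so the
    column order of external matrices is unambiguous.
    """
    pairs = fc_index_pairs(n_regions)
    if fc_matrix.shape[1] != len(pairs):
        raise ValueError("matrix width does not match n_regions")
    header = "\t".join(f"r{i}-r{j}" for i, j in pairs)
    np.savetxt(path, fc_matrix, delimiter="\t", header=header, comments="")
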