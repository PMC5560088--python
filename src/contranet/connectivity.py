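"""From ROI time series to Fisher-z connectivity matrices and feature vectors.

The processing chain mirrors a standard resting-state ROI pipeline:
quality control by temporal signal-to-noise ratio (tSNR), nuisance
regression against supplied confound columns, linear detrending, band-pass
filtering by an ideal FFT mask, Pearson correlation between all ROI pairs,
and the Fisher z-transform.  The strict upper triangle of the z-matrix is
the subject's feature vector (990 features for 45 ROIs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: default band edges in Hz; the upper edge is clamped to Nyquist when needed
DEFAULT_LOW_HZ = 0.009
DEFAULT_HIGH_HZ = 0.8

#: subject-level tSNR gate (mean over ROIs of mean/sd of the raw series)
DEFAULT_TSNR_THRESHOLD = 45.0

_R_CLAMP = 1.0 - 1e-7
_SYMMETRY_TOL = 1e-10


@dataclass
class TimeSeriesPanel:
    """One subject's timepoints x ROIs signal matrix with sampling interval."""

    data: np.ndarray
    tr: float
    roi_names: list[str]
    confounds: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    confound_names: list[str] = field(default_factory=list)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a timepoints x ROIs matrix")
        if self.data.shape[0] < 2:
            raise ValueError("need at least 2 timepoints")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if self.data.shape[1] != len(self.roi_names):
            raise ValueError(
                f"{self.data.shape[1]} ROI columns but {len(self.roi_names)} roi_names"
            )
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        self.confounds = np.asarray(self.confounds, dtype=float)
        if self.confounds.size == 0:
            self.confounds = np.empty((self.data.shape[0], 0))
        if self.confounds.shape[0] != self.data.shape[0]:
            raise ValueError("confounds must have the same number of timepoints as data")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray, confounds: np.ndarray | None = None,
                  confound_names: list[str] | None = None) -> "TimeSeriesPanel":
        return TimeSeriesPanel(
            data=data,
            tr=self.tr,
            roi_names=list(self.roi_names),
            confounds=self.confounds if confounds is None else confounds,
            confound_names=list(self.confound_names)
            if confound_names is None
            else confound_names,
            subject_id=self.subject_id,
        )


@dataclass
class ConnectivityMatrix:
    """Symmetric ROI x ROI Fisher-z matrix with zero diagonal."""

    z: np.ndarray
    roi_names: list[str]
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        n = self.z.shape[0]
        if self.z.ndim != 2 or self.z.shape[1] != n:
            raise ValueError("z must be square")
        if n != len(self.roi_names):
            raise ValueError("roi_names length must match matrix size")
        if not np.allclose(self.z, self.z.T, atol=_SYMMETRY_TOL, rtol=0):
            raise ValueError("z must be symmetric")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("z contains non-finite values")
        np.fill_diagonal(self.z, 0.0)

    @property
    def n_rois(self) -> int:
        return self.z.shape[0]


@dataclass
class FeatureVector:
    """Strict upper triangle of a connectivity matrix, row-major order."""

    values: np.ndarray
    index_map: list[tuple[str, str]]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.index_map) != self.values.size:
            raise ValueError("index_map length must match values length")


@dataclass
class TsnrReport:
    per_roi: np.ndarray
    mean: float
    threshold: float
    passed: bool


def tsnr(panel: TimeSeriesPanel, threshold: float = DEFAULT_TSNR_THRESHOLD) -> TsnrReport:
    """Temporal SNR per ROI (mean / sd of the raw series) plus a subject gate.

    The subject fails QC when the ROI-mean tSNR falls below ``threshold``.
    A zero-variance ROI yields +inf (a flat series is noiseless, not noisy)
    and is flagged in the log.
    """
    mean = panel.data.mean(axis=0)
    sd = panel.data.std(axis=0, ddof=1)
    with np.errstate(divide="ignore"):
        values = np.where(sd > 0, np.abs(mean) / np.where(sd > 0, sd, 1.0), np.inf)
    if np.any(sd == 0):
        flat = [panel.roi_names[i] for i in np.where(sd == 0)[0]]
        logger.warning("%s: zero-variance ROI(s) %s; tSNR set to +inf",
                       panel.subject_id, flat)
    finite = values[np.isfinite(values)]
    mean_tsnr = float(finite.mean()) if finite.size else float("inf")
    return TsnrReport(values, mean_tsnr, threshold, mean_tsnr >= threshold)


def regress_confounds(panel: TimeSeriesPanel) -> TimeSeriesPanel:
    """Residualize every ROI series against [intercept | confound columns].

    Ordinary least squares; the output is orthogonal to each confound
    column.  Collinear confound columns are dropped with a warning.  With
    no confounds this reduces to removing the temporal mean.
    """
    t = panel.n_timepoints
    design = np.column_stack([np.ones(t), panel.confounds])
    # drop collinear columns (QR pivots on running rank)
    keep = [0]
    for j in range(1, design.shape[1]):
        cand = design[:, keep + [j]]
        if np.linalg.matrix_rank(cand) > len(keep):
            keep.append(j)
        else:
            name = (panel.confound_names[j - 1]
                    if j - 1 < len(panel.confound_names) else f"col{j - 1}")
            logger.warning("%s: dropping collinear confound %r",
                           panel.subject_id, name)
    x = design[:, keep]
    beta, *_ = np.linalg.lstsq(x, panel.data, rcond=None)
    resid = panel.data - x @ beta
    return panel.with_data(resid, confounds=np.empty((t, 0)), confound_names=[])


def detrend_bandpass(
    panel: TimeSeriesPanel,
    low_hz: float = DEFAULT_LOW_HZ,
    high_hz: float = DEFAULT_HIGH_HZ,
) -> TimeSeriesPanel:
    """Linear detrend then ideal band-pass by zeroing FFT bins outside the band.

    The upper edge is clamped to the Nyquist frequency when the requested
    value exceeds it (logged): at TR = 1.5 s the conventional 0.8 Hz upper
    edge is unreachable and the filter is effectively high-pass.
    """
    if high_hz <= low_hz:
        raise ValueError(f"high_hz ({high_hz}) must exceed low_hz ({low_hz})")
    t = panel.n_timepoints
    time = np.arange(t)
    x = np.column_stack([np.ones(t), time])
    beta, *_ = np.linalg.lstsq(x, panel.data, rcond=None)
    detrended = panel.data - x @ beta

    nyquist = 0.5 / panel.tr
    hi = high_hz
    if hi > nyquist:
        logger.info(
            "band upper edge %.3f Hz exceeds Nyquist %.3f Hz; clamping", hi, nyquist
        )
        hi = nyquist
    freqs = np.fft.rfftfreq(t, d=panel.tr)
    mask = (freqs >= low_hz) & (freqs <= hi)
    spec = np.fft.rfft(detrended, axis=0)
    spec[~mask] = 0.0
    filtered = np.fft.irfft(spec, n=t, axis=0)
    return panel.with_data(filtered)


def correlation_matrix(panel: TimeSeriesPanel) -> ConnectivityMatrix:
    """Pearson correlation between all ROI pairs, Fisher z-transformed.

    |r| = 1 pairs are clamped just inside the pole of atanh with a warning;
    a zero-variance ROI is an error naming the ROI.
    """
    if panel.n_timepoints < 3:
        raise ValueError("need at least 3 timepoints for a correlation matrix")
    sd = panel.data.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [panel.roi_names[i] for i in np.where(sd == 0)[0]]
        raise ValueError(f"zero-variance ROI(s) after denoising: {bad}")
    r = np.corrcoef(panel.data, rowvar=False)
    np.fill_diagonal(r, 0.0)
    if np.any(np.abs(r) >= _R_CLAMP):
        logger.warning("%s: |r| at unity clamped to %.7f", panel.subject_id, _R_CLAMP)
        r = np.clip(r, -_R_CLAMP, _R_CLAMP)
    z = np.arctanh(r)
    z = (z + z.T) / 2.0  # enforce exact symmetry against float noise
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(z, list(panel.roi_names), panel.subject_id)


def vectorize_upper_triangle(matrix: ConnectivityMatrix) -> FeatureVector:
    """Strict upper triangle in row-major order; for 45 ROIs, 990 features."""
    z = matrix.z
    if not np.allclose(z, z.T, atol=_SYMMETRY_TOL, rtol=0):
        raise ValueError("matrix must be symmetric")
    iu = np.triu_indices(matrix.n_rois, k=1)
    names = matrix.roi_names
    index_map = [(names[i], names[j]) for i, j in zip(*iu)]
    return FeatureVector(z[iu], index_map)


def matrix_from_features(fv: FeatureVector, roi_names: Sequence[str],
                         subject_id: str = "") -> ConnectivityMatrix:
    """Rebuild the symmetric z-matrix from a feature vector (inverse of vectorize)."""
    n = len(roi_names)
    if fv.values.size != n * (n - 1) // 2:
        raise ValueError("feature length does not match roi count")
    z = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    z[iu] = fv.values
    z = z + z.T
    return ConnectivityMatrix(z, list(roi_names), subject_id)


def parcellate(voxel_data: np.ndarray, labels: Sequence[int]) -> np.ndarray:
    """Average voxel columns into ROI series given 1-based labels (0 = background)."""
    labels = np.asarray(labels, dtype=int)
    if labels.shape[0] != voxel_data.shape[1]:
        raise ValueError("one label per voxel column required")
    rois = np.unique(labels[labels > 0])
    return np.column_stack([voxel_data[:, labels == r].mean(axis=1) for r in rois])


def subject_connectivity(
    panel: TimeSeriesPanel,
    low_hz: float = DEFAULT_LOW_HZ,
    high_hz: float = DEFAULT_HIGH_HZ,
    tsnr_threshold: float = DEFAULT_TSNR_THRESHOLD,
) -> tuple[ConnectivityMatrix | None, TsnrReport]:
    """Full chain: tSNR gate -> confound regression -> detrend/band-pass -> z-matrix.

    Returns (None, report) when the subject fails the tSNR gate.
    """
    report = tsnr(panel, tsnr_threshold)
    if not report.passed:
        logger.info("%s excluded: mean tSNR %.1f < %.1f",
                    panel.subject_id, report.mean, tsnr_threshold)
        return None, report
    clean = regress_confounds(panel)
    clean = detrend_bandpass(clean, low_hz, high_hz)
    return correlation_matrix(clean), report


# ---------------------------------------------------------------------------
# plain-text I/O


def write_panel_tsv(panel: TimeSeriesPanel, path: str | Path) -> None:
    """TSV with a header row of ROI names, one row per timepoint.

    Confound columns, when present, are appended with a ``confound:`` prefix.
    """
    cols = {name: panel.data[:, i] for i, name in enumerate(panel.roi_names)}
    for j, name in enumerate(panel.confound_names):
        cols[f"confound:{name}"] = panel.confounds[:, j]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_panel_tsv(path: str | Path, tr: float, subject_id: str = "") -> TimeSeriesPanel:
    df = pd.read_csv(path, sep="\t")
    conf_cols = [c for c in df.columns if c.startswith("confound:")]
    roi_cols = [c for c in df.columns if not c.startswith("confound:")]
    return TimeSeriesPanel(
        data=df[roi_cols].to_numpy(),
        tr=tr,
        roi_names=roi_cols,
        confounds=df[conf_cols].to_numpy() if conf_cols else np.empty((len(df), 0)),
        confound_names=[c.split(":", 1)[1] for c in conf_cols],
        subject_id=subject_id or Path(path).stem,
    )


def write_matrix_csv(matrix: ConnectivityMatrix, path: str | Path) -> None:
    """Full symmetric matrix as CSV with ROI names as header and first column."""
    pd.DataFrame(matrix.z, index=matrix.roi_names, columns=matrix.roi_names).to_csv(path)


def read_matrix_csv(path: str | Path, subject_id: str = "") -> ConnectivityMatrix:
    df = pd.read_csv(path, index_col=0)
    return ConnectivityMatrix(
        df.to_numpy(), list(df.columns), subject_id or Path(path).stem
    )


def write_features_csv(fv: FeatureVector, path: str | Path) -> None:
    """Long-format feature table with (roi_i, roi_j, z) columns."""
    pd.DataFrame(
        {
            "roi_i": [a for a, _ in fv.index_map],
            "roi_j": [b for _, b in fv.index_map],
            "z": fv.values,
        }
    ).to_csv(path, index=False)
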