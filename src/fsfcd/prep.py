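"""In-scope tail of the BOLD preprocessing chain.

Covers linear detrending, zero-phase temporal filtering, nuisance regression,
and framewise-displacement (FD) summarization of realignment parameters.
Spatial steps (slice timing, realignment, normalization, segmentation) belong
to registration tooling and are out of scope.

Detrending and nuisance regression are both least-squares projections, so
each is idempotent; the filter is a zero-phase forward-backward Butterworth
(order 4 by default), which preserves correlation structure because it adds
no phase shift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import MaskedBoldSeries

HEAD_RADIUS_MM = 50.0  # sphere radius used to convert rotations to arc length


@dataclass
class NuisanceSet:
    """Per-volume nuisance regressors (n_timepoints x n_regressors)."""

    regressors: np.ndarray
    names: list

    def __post_init__(self):
        self.regressors = np.atleast_2d(np.asarray(self.regressors, dtype=float))
        if self.regressors.shape[1] != len(self.names):
            raise ValueError("number of names must match regressor columns")
        if not np.all(np.isfinite(self.regressors)):
            raise ValueError("nuisance regressors must be finite")


@dataclass
class MotionTrace:
    """Per-volume rigid-body parameters: 3 translations (mm), 3 rotations (rad)."""

    params: np.ndarray

    def __post_init__(self):
        self.params = np.atleast_2d(np.asarray(self.params, dtype=float))
        if self.params.shape[1] != 6:
            raise ValueError(
                f"motion parameters must have 6 columns, got {self.params.shape[1]}"
            )


def read_motion_params(path) -> MotionTrace:
    """Read whitespace-delimited realignment parameters (translations then rotations)."""
    return MotionTrace(np.loadtxt(path, ndmin=2))


def linear_detrend(series: MaskedBoldSeries) -> MaskedBoldSeries:
    """Remove the per-voxel least-squares line (intercept + slope)."""
    if series.n_timepoints < 3:
        raise ValueError("linear detrend needs at least 3 timepoints")
    out = sps.detrend(series.data, axis=1, type="linear")
    return series.with_data(out, "linear_detrend")


def butter_filtfilt(
    data: np.ndarray,
    f_low: float,
    f_high: float,
    fs: float,
    order: int = 4,
    axis: int = -1,
) -> np.ndarray:
    """Zero-phase Butterworth filter of array data along `axis`.

    f_low <= 0 gives a low-pass at f_high; f_high >= Nyquist gives a
    high-pass at f_low; otherwise a band-pass.
    """
    nyq = fs / 2.0
    if not (0 <= f_low < f_high):
        raise ValueError(f"need 0 <= f_low < f_high, got ({f_low}, {f_high})")
    if f_high > nyq + 1e-12:
        raise ValueError(f"f_high={f_high} exceeds Nyquist {nyq}")
    if f_low <= 0:
        sos = sps.butter(order, f_high, btype="lowpass", fs=fs, output="sos")
    elif f_high >= nyq - 1e-12:
        sos = sps.butter(order, f_low, btype="highpass", fs=fs, output="sos")
    else:
        sos = sps.butter(order, [f_low, f_high], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, data, axis=axis)


def temporal_filter(
    series: MaskedBoldSeries, f_low: float, f_high: float, order: int = 4
) -> MaskedBoldSeries:
    """Zero-phase band limiting of every voxel series to (f_low, f_high) Hz."""
    out = butter_filtfilt(
        series.data, f_low, f_high, fs=1.0 / series.tr_s, order=order, axis=1
    )
    return series.with_data(out, f"temporal_filter({f_low},{f_high})")


def _design_matrix(nuisance: NuisanceSet, n_timepoints: int) -> np.ndarray:
    reg = nuisance.regressors
    if reg.shape[0] != n_timepoints:
        raise ValueError(
            f"regressors have {reg.shape[0]} rows, series has {n_timepoints} timepoints"
        )
    return np.column_stack([np.ones(n_timepoints), reg])


def _collinear_columns(X: np.ndarray, names: list) -> list:
    """Names of regressor columns implicated in rank deficiency."""
    bad = []
    base_rank = np.linalg.matrix_rank(X[:, :1])
    kept = X[:, :1]
    for j in range(1, X.shape[1]):
        cand = np.column_stack([kept, X[:, j]])
        if np.linalg.matrix_rank(cand) == base_rank:
            bad.append(names[j - 1])
        else:
            kept = cand
            base_rank += 1
    return bad


def regress_nuisance(series: MaskedBoldSeries, nuisance: NuisanceSet) -> MaskedBoldSeries:
    """OLS residuals of every voxel on [intercept | regressors]."""
    X = _design_matrix(nuisance, series.n_timepoints)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = _collinear_columns(X, list(nuisance.names))
        raise ValueError(f"rank-deficient nuisance design; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(X, series.data.T, rcond=None)
    resid = series.data.T - X @ beta
    return series.with_data(resid.T, f"regress_nuisance({list(nuisance.names)})")


def global_signal_regressor(series: MaskedBoldSeries) -> np.ndarray:
    """Mask-wide mean time series (the global-signal nuisance regressor)."""
    return series.data.mean(axis=0)


def framewise_displacement(
    motion: MotionTrace, head_radius_mm: float = HEAD_RADIUS_MM
) -> tuple[np.ndarray, float]:
    """Power-style FD: sum of absolute backward differences of the 6 parameters.

    Rotations are converted to arc length on a sphere of `head_radius_mm`.
    Returns (per-volume FD in mm with FD_1 = 0, mean FD).
    """
    p = motion.params
    if p.shape[0] < 2:
        raise ValueError("framewise displacement needs at least 2 volumes")
    scaled = p.copy()
    scaled[:, 3:] *= head_radius_mm
    fd = np.zeros(p.shape[0])
    fd[1:] = np.abs(np.diff(scaled, axis=0)).sum(axis=1)
    return fd, float(fd.mean())


def prepare(
    series: MaskedBoldSeries,
    f_low: float = 0.0,
    f_high: float = 0.08,
    nuisance: NuisanceSet | None = None,
    steps: tuple = ("detrend", "filter", "regress"),
    filter_order: int = 4,
) -> MaskedBoldSeries:
    """Run the configured preprocessing steps in order, recording provenance.

    Default order is detrend -> filter (0-0.08 Hz low-pass) -> nuisance
    regression; the order is configurable because conventions differ.
    """
    out = series
    for step in steps:
        if step == "detrend":
            out = linear_detrend(out)
        elif step == "filter":
            out = temporal_filter(out, f_low, f_high, order=filter_order)
        elif step == "regress":
            if nuisance is not None:
                out = regress_nuisance(out, nuisance)
        else:
            raise ValueError(f"unknown preprocessing step: {step!r}")
    return out
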