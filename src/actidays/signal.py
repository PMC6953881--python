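"""Raw tri-axial acceleration to calibrated, wear-flagged ENMO epoch series.

The processing chain mirrors the standard open-source raw-accelerometry
pipeline for wrist-worn devices:

1. autocalibration against local gravity — still windows should have a
   vector magnitude of exactly 1 g, so per-axis offsets and gains are fit
   to push them there;
2. screening of sustained abnormally high values (outside the device's
   dynamic range, nominally +/- 8 g);
3. ENMO (Euclidean Norm Minus One) computation: per sample,
   sqrt(x^2 + y^2 + z^2) - 1 g with negatives truncated to zero, then
   averaged over fixed epochs (default 5 s) and expressed in milli-g (mg);
4. non-wear detection from sustained per-axis stillness in long sliding
   windows.

Acceleration is in gravitational units (g) throughout; ENMO and all
thresholds are in mg (1 mg = 0.001 g).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import InputDataError

logger = logging.getLogger(__name__)

G_TO_MG = 1000.0

__all__ = [
    "RawRecording",
    "CalibrationModel",
    "EpochSeries",
    "AccelerometerCalibrator",
    "autocalibrate",
    "screen_abnormal",
    "compute_enmo",
    "detect_nonwear",
    "detect_nonwear_from_enmo",
]


@dataclass
class RawRecording:
    """Timestamped tri-axial acceleration samples for one subject, in g.

    Axes follow the wrist-device convention: Y vertical, X horizontal
    right-left, Z horizontal front-back. ``start_time`` is timezone-naive
    local time; sample *i* is at ``start_time + i / sample_rate`` seconds.
    """

    subject_id: str
    sample_rate: float
    start_time: pd.Timestamp
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        self.start_time = pd.Timestamp(self.start_time)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if not (len(self.x) == len(self.y) == len(self.z)):
            raise InputDataError("axes x, y, z must have equal length")
        if not self.sample_rate > 0:
            raise InputDataError(f"sample_rate must be > 0, got {self.sample_rate}")
        for name, arr in (("x", self.x), ("y", self.y), ("z", self.z)):
            if arr.size and not np.all(np.isfinite(arr)):
                raise InputDataError(f"axis {name} contains non-finite values")

    @property
    def n_samples(self) -> int:
        return len(self.x)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    def xyz(self) -> np.ndarray:
        """Samples as an (n, 3) array in axis order x, y, z."""
        return np.column_stack([self.x, self.y, self.z])

    def sample_times(self) -> pd.DatetimeIndex:
        offs = np.arange(self.n_samples) / self.sample_rate
        return self.start_time + pd.to_timedelta(offs, unit="s")


@dataclass
class CalibrationModel:
    """Per-axis offset/gain correction fitted from still windows.

    A calibrated sample is ``(v - offset) * gain`` per axis. ``pre_error``
    and ``post_error`` are the mean absolute deviation of still-window
    vector magnitudes from 1 g, in mg. ``converged`` is False when too few
    still windows or poor orientation coverage forced the identity model.
    """

    offset: np.ndarray = field(default_factory=lambda: np.zeros(3))
    gain: np.ndarray = field(default_factory=lambda: np.ones(3))
    n_still_windows: int = 0
    pre_error: float = float("nan")
    post_error: float = float("nan")
    converged: bool = False

    def __post_init__(self) -> None:
        self.offset = np.asarray(self.offset, dtype=float)
        self.gain = np.asarray(self.gain, dtype=float)
        if np.any(self.gain <= 0):
            raise InputDataError("calibration gains must be positive")

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return (np.asarray(xyz, dtype=float) - self.offset) * self.gain

    @property
    def offset_x(self) -> float:  # convenience accessors
        return float(self.offset[0])

    @property
    def offset_y(self) -> float:
        return float(self.offset[1])

    @property
    def offset_z(self) -> float:
        return float(self.offset[2])


@dataclass
class EpochSeries:
    """Per-epoch ENMO (mg) with wear and abnormality flags."""

    subject_id: str
    epoch_len: float
    start_time: pd.Timestamp
    enmo: np.ndarray
    wear: np.ndarray = None  # type: ignore[assignment]
    abnormal: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.start_time = pd.Timestamp(self.start_time)
        self.enmo = np.asarray(self.enmo, dtype=float)
        n = len(self.enmo)
        if self.wear is None:
            self.wear = np.ones(n, dtype=bool)
        if self.abnormal is None:
            self.abnormal = np.zeros(n, dtype=bool)
        self.wear = np.asarray(self.wear, dtype=bool)
        self.abnormal = np.asarray(self.abnormal, dtype=bool)
        if not (len(self.wear) == len(self.abnormal) == n):
            raise InputDataError("enmo, wear, abnormal must have equal length")
        if n and np.nanmin(self.enmo) < 0:
            raise InputDataError("epoch ENMO must be non-negative")
        if not self.epoch_len > 0:
            raise InputDataError("epoch_len must be > 0")

    @property
    def n_epochs(self) -> int:
        return len(self.enmo)

    def epoch_times(self) -> pd.DatetimeIndex:
        offs = np.arange(self.n_epochs) * self.epoch_len
        return self.start_time + pd.to_timedelta(offs, unit="s")


# ---------------------------------------------------------------------------
# autocalibration
# ---------------------------------------------------------------------------


def _still_window_means(
    rec: RawRecording, window_len: float, still_sd_threshold: float
) -> np.ndarray:
    """Mean (x, y, z) of non-overlapping windows whose per-axis SD is below
    the threshold on all three axes. Returns an (m, 3) array in g."""
    spw = int(round(rec.sample_rate * window_len))
    if spw < 2:
        raise InputDataError("calibration window too short for the sample rate")
    n_win = rec.n_samples // spw
    if n_win == 0:
        return np.empty((0, 3))
    v = rec.xyz()[: n_win * spw].reshape(n_win, spw, 3)
    sd = v.std(axis=1)
    still = np.all(sd < still_sd_threshold / G_TO_MG, axis=1)
    return v[still].mean(axis=1)


def autocalibrate(
    rec: RawRecording,
    still_sd_threshold: float = 13.0,
    window_len: float = 10.0,
    max_iter: int = 100,
    tol: float = 0.01,
    min_still_windows: int = 10,
    min_coverage_g: float = 0.1,
) -> CalibrationModel:
    """Fit per-axis offsets and gains so still-window magnitudes approach 1 g.

    Still windows (non-overlapping, ``window_len`` seconds, per-axis SD below
    ``still_sd_threshold`` mg on all axes) give a cloud of quasi-static
    gravity vectors. Offsets and gains are estimated by iterating: project
    each calibrated point onto the unit sphere and refit, per axis, the
    linear map input -> projection by least squares. Iteration stops when
    the mean absolute magnitude error changes by less than ``tol`` mg.

    Falls back to the identity model (``converged=False``) when fewer than
    ``min_still_windows`` still windows are found, or when the still
    orientations do not span both signs (beyond ``min_coverage_g`` g) on
    every axis — without sphere coverage the gains are unidentifiable.

    Raises
    ------
    InputDataError
        If the recording is shorter than one hour.
    """
    if rec.duration_s < 3600.0:
        raise InputDataError(
            f"recording of {rec.duration_s:.0f} s is too short to calibrate (need >= 1 h)"
        )
    pts = _still_window_means(rec, window_len, still_sd_threshold)
    identity = CalibrationModel(n_still_windows=len(pts), converged=False)
    if len(pts) < min_still_windows:
        logger.warning(
            "autocalibrate: only %d still windows (< %d); returning identity model",
            len(pts),
            min_still_windows,
        )
        return identity
    coverage_ok = bool(
        np.all(pts.min(axis=0) < -min_coverage_g) and np.all(pts.max(axis=0) > min_coverage_g)
    )
    if not coverage_ok:
        logger.warning(
            "autocalibrate: still orientations do not span the sphere; identity model"
        )
        return identity

    pre_error = float(np.abs(np.linalg.norm(pts, axis=1) - 1.0).mean()) * G_TO_MG
    offset = np.zeros(3)
    gain = np.ones(3)
    prev = np.inf
    for _ in range(max_iter):
        cal = (pts - offset) * gain
        norms = np.linalg.norm(cal, axis=1)
        err = float(np.abs(norms - 1.0).mean()) * G_TO_MG
        if abs(prev - err) < tol:
            break
        prev = err
        target = cal / norms[:, None]
        design = np.column_stack([np.ones(len(pts)), np.zeros(len(pts))])
        for a in range(3):
            design[:, 1] = pts[:, a]
            coef, *_ = np.linalg.lstsq(design, target[:, a], rcond=None)
            intercept, slope = coef
            if slope <= 0:  # degenerate axis; bail out to identity
                return identity
            gain[a] = slope
            offset[a] = -intercept / slope
    cal = (pts - offset) * gain
    post_error = float(np.abs(np.linalg.norm(cal, axis=1) - 1.0).mean()) * G_TO_MG
    if post_error > pre_error:
        logger.warning("autocalibrate: fit did not improve magnitude error; identity model")
        model = identity
        model.pre_error = pre_error
        model.post_error = pre_error
        return model
    return CalibrationModel(
        offset=offset,
        gain=gain,
        n_still_windows=len(pts),
        pre_error=pre_error,
        post_error=post_error,
        converged=True,
    )


class AccelerometerCalibrator(BaseEstimator):
    """Sklearn-style wrapper around :func:`autocalibrate`.

    ``fit`` estimates the calibration from a recording's still windows;
    ``transform`` returns a new recording with the correction applied.

    Parameters mirror :func:`autocalibrate`. Fitted attributes:
    ``offset_`` (3-vector, g), ``gain_`` (3-vector), ``model_``
    (:class:`CalibrationModel`), ``converged_``.
    """

    def __init__(
        self,
        still_sd_threshold: float = 13.0,
        window_len: float = 10.0,
        max_iter: int = 100,
        tol: float = 0.01,
        min_still_windows: int = 10,
        min_coverage_g: float = 0.1,
    ):
        self.still_sd_threshold = still_sd_threshold
        self.window_len = window_len
        self.max_iter = max_iter
        self.tol = tol
        self.min_still_windows = min_still_windows
        self.min_coverage_g = min_coverage_g

    def fit(self, X: RawRecording, y=None) -> "AccelerometerCalibrator":
        self.model_ = autocalibrate(
            X,
            still_sd_threshold=self.still_sd_threshold,
            window_len=self.window_len,
            max_iter=self.max_iter,
            tol=self.tol,
            min_still_windows=self.min_still_windows,
            min_coverage_g=self.min_coverage_g,
        )
        self.offset_ = self.model_.offset
        self.gain_ = self.model_.gain
        self.converged_ = self.model_.converged
        return self

    def transform(self, X: RawRecording) -> RawRecording:
        if not hasattr(self, "model_"):
            raise InputDataError("AccelerometerCalibrator is not fitted")
        cal = self.model_.apply(X.xyz())
        return replace(X, x=cal[:, 0], y=cal[:, 1], z=cal[:, 2])

    def fit_transform(self, X: RawRecording, y=None) -> RawRecording:
        return self.fit(X).transform(X)


# ---------------------------------------------------------------------------
# abnormal-value screening
# ---------------------------------------------------------------------------


def screen_abnormal(rec: RawRecording, clip: float = 8.0) -> tuple[RawRecording, np.ndarray]:
    """Flag and clip samples outside the device's dynamic range.

    A sample is abnormal when |value| > ``clip`` g on any axis; flagged
    samples are clipped to +/- ``clip``. Returns the clipped recording and
    the per-sample boolean mask. The mask is propagated to epochs by
    :func:`compute_enmo` (epoch abnormal when more than half its samples
    are flagged).
    """
    if not clip > 0:
        raise InputDataError("clip must be > 0")
    v = rec.xyz()
    mask = np.any(np.abs(v) > clip, axis=1)
    if mask.any():
        v = np.clip(v, -clip, clip)
    clipped = replace(rec, x=v[:, 0], y=v[:, 1], z=v[:, 2])
    return clipped, mask


# ---------------------------------------------------------------------------
# ENMO epochs
# ---------------------------------------------------------------------------


def _epoch_index(rec: RawRecording, epoch_len: float) -> tuple[np.ndarray, int]:
    """Epoch index per sample by timestamp, and the count of complete epochs.

    The trailing partial epoch is dropped. Assigning by timestamp keeps
    epochs aligned when ``sample_rate * epoch_len`` is non-integer (e.g.
    85.7 Hz x 5 s = 428.5): epochs then hold 428 or 429 samples with no
    cumulative drift.
    """
    spe = rec.sample_rate * epoch_len
    if abs(spe - round(spe)) > 1.0:
        raise InputDataError(
            f"epoch_len {epoch_len}s does not divide the cadence at "
            f"{rec.sample_rate} Hz within one sample"
        )
    idx = (np.arange(rec.n_samples) / (rec.sample_rate * epoch_len)).astype(np.int64)
    n_full = int(np.floor(rec.duration_s / epoch_len + 1e-9))
    return idx, n_full


def compute_enmo(
    rec: RawRecording,
    calib: CalibrationModel | None = None,
    epoch_len: float = 5.0,
    negatives: str = "truncate",
    abnormal_mask: np.ndarray | None = None,
) -> EpochSeries:
    """Calibrate, compute per-sample ENMO, and average per epoch (mg).

    ENMO = sqrt(x^2 + y^2 + z^2) - 1 g per sample. With
    ``negatives="truncate"`` (the canonical definition) negative values are
    set to zero before averaging; ``negatives="absolute"`` takes the
    absolute value instead, a sensitivity variant.
    """
    if rec.n_samples == 0:
        raise InputDataError("cannot compute ENMO of an empty recording")
    if negatives not in ("truncate", "absolute"):
        raise InputDataError(f"negatives must be 'truncate' or 'absolute', got {negatives!r}")
    idx, n_full = _epoch_index(rec, epoch_len)
    if n_full == 0:
        raise InputDataError("recording shorter than one epoch")
    v = rec.xyz()
    if calib is not None:
        v = calib.apply(v)
    e = np.linalg.norm(v, axis=1) - 1.0
    e = np.maximum(e, 0.0) if negatives == "truncate" else np.abs(e)
    keep = idx < n_full
    counts = np.bincount(idx[keep], minlength=n_full)
    enmo = np.bincount(idx[keep], weights=e[keep], minlength=n_full) / counts * G_TO_MG
    abnormal = np.zeros(n_full, dtype=bool)
    if abnormal_mask is not None:
        abnormal_mask = np.asarray(abnormal_mask, dtype=bool)
        frac = np.bincount(idx[keep], weights=abnormal_mask[keep], minlength=n_full) / counts
        abnormal = frac > 0.5
    return EpochSeries(
        subject_id=rec.subject_id,
        epoch_len=epoch_len,
        start_time=rec.start_time,
        enmo=enmo,
        abnormal=abnormal,
    )


# ---------------------------------------------------------------------------
# non-wear detection
# ---------------------------------------------------------------------------


def _epoch_axis_stats(rec: RawRecording, epoch_len: float):
    """Per-epoch per-axis (sum, sum of squares, min, max, count)."""
    idx, n_full = _epoch_index(rec, epoch_len)
    keep = idx < n_full
    v = rec.xyz()[keep]
    idx = idx[keep]
    bounds = np.searchsorted(idx, np.arange(n_full))
    counts = np.bincount(idx, minlength=n_full).astype(float)
    s = np.empty((n_full, 3))
    ss = np.empty((n_full, 3))
    mn = np.empty((n_full, 3))
    mx = np.empty((n_full, 3))
    for a in range(3):
        col = v[:, a]
        s[:, a] = np.bincount(idx, weights=col, minlength=n_full)
        ss[:, a] = np.bincount(idx, weights=col * col, minlength=n_full)
        mn[:, a] = np.minimum.reduceat(col, bounds)
        mx[:, a] = np.maximum.reduceat(col, bounds)
    return s, ss, mn, mx, counts, n_full


def detect_nonwear(
    rec: RawRecording,
    ep: EpochSeries,
    window_len: float = 60.0,
    step: float = 15.0,
    sd_threshold: float = 13.0,
    range_threshold: float = 50.0,
    axes_required: int = 2,
) -> EpochSeries:
    """Flag non-wear epochs from sustained per-axis stillness in the raw signal.

    A sliding window (``window_len`` minutes, ``step`` minutes) votes
    non-wear when, on at least ``axes_required`` of the 3 axes, the axis SD
    is below ``sd_threshold`` mg AND the axis range is below
    ``range_threshold`` mg. Every epoch covered by a voting window is
    non-wear. Wear = not non-wear and not abnormal.

    A recording shorter than one window is returned fully worn with a
    warning, as no vote is possible.
    """
    win_s, step_s = window_len * 60.0, step * 60.0
    if rec.duration_s < win_s:
        warnings.warn(
            "recording shorter than one non-wear window; all epochs marked wear",
            stacklevel=2,
        )
        return replace(ep, wear=~ep.abnormal)
    s, ss, mn, mx, counts, n_full = _epoch_axis_stats(rec, ep.epoch_len)
    n_full = min(n_full, ep.n_epochs)
    w = int(round(win_s / ep.epoch_len))
    st = max(1, int(round(step_s / ep.epoch_len)))
    nonwear = np.zeros(ep.n_epochs, dtype=bool)
    starts = list(range(0, n_full - w + 1, st))
    if starts and starts[-1] != n_full - w:
        starts.append(n_full - w)  # anchor a final window at the tail
    for i in starts:
        sl = slice(i, i + w)
        n = counts[sl].sum()
        tot = s[sl].sum(axis=0)
        var = ss[sl].sum(axis=0) / n - (tot / n) ** 2
        sd = np.sqrt(np.maximum(var, 0.0)) * G_TO_MG
        rng = (mx[sl].max(axis=0) - mn[sl].min(axis=0)) * G_TO_MG
        votes = int(np.sum((sd < sd_threshold) & (rng < range_threshold)))
        if votes >= axes_required:
            nonwear[sl] = True
    return replace(ep, wear=~nonwear & ~ep.abnormal)


def detect_nonwear_from_enmo(
    ep: EpochSeries,
    window_len: float = 60.0,
    step: float = 15.0,
    sd_threshold: float = 3.0,
    mean_threshold: float = 3.0,
) -> EpochSeries:
    """Non-wear detection when only the ENMO epoch series is available.

    Without per-axis raw data the SD/range criteria cannot be evaluated, so
    a window votes non-wear when its ENMO standard deviation and mean are
    both below tight thresholds (mg) — i.e. the epoch signal is flat at
    zero, as a removed device produces. Thresholds are deliberately strict
    so quiet sleep (small but non-zero, noisy ENMO) is not misflagged.
    """
    w = int(round(window_len * 60.0 / ep.epoch_len))
    st = max(1, int(round(step * 60.0 / ep.epoch_len)))
    if ep.n_epochs < w:
        warnings.warn(
            "series shorter than one non-wear window; all epochs marked wear",
            stacklevel=2,
        )
        return replace(ep, wear=~ep.abnormal)
    nonwear = np.zeros(ep.n_epochs, dtype=bool)
    c = np.concatenate([[0.0], np.cumsum(ep.enmo)])
    c2 = np.concatenate([[0.0], np.cumsum(ep.enmo**2)])
    starts = list(range(0, ep.n_epochs - w + 1, st))
    if starts and starts[-1] != ep.n_epochs - w:
        starts.append(ep.n_epochs - w)
    for i in starts:
        mean = (c[i + w] - c[i]) / w
        var = (c2[i + w] - c2[i]) / w - mean**2
        if mean < mean_threshold and np.sqrt(max(var, 0.0)) < sd_threshold:
            nonwear[i : i + w] = True
    return replace(ep, wear=~nonwear & ~ep.abnormal)
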