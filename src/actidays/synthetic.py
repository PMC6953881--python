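"""Synthetic cohorts with known ground truth.

Three fidelity tiers, cheapest first:

* **construct tier** — subjects x days matrices of one physical-activity
  construct drawn from a variance-components model
  ``value[i, j] = mu + b_i + d_j + w_ij`` with between-subject effects
  ``b_i ~ N(0, sigma_between^2)``, day-to-day noise
  ``w_ij ~ N(0, sigma_within^2)`` and fixed day-of-week/weekend offsets
  ``d_j``. The ground-truth single-day reliability (one-way ICC) is
  ``sigma_between^2 / (sigma_between^2 + sigma_within^2)`` when the fixed
  offsets are removed; thousands of subject-days cost microseconds.
* **epoch tier** — per-epoch ENMO series driven by a minute-resolution
  activity-state Markov chain (sleep / sedentary / light / MVPA) with a
  diurnal sleep trough, subject-level activity multipliers, a weekend
  activity reduction and exact-zero non-wear gaps. Feeds the epoch-onward
  pipeline at cohort scale.
* **raw tier** — tri-axial samples at the device cadence: a slowly varying
  (piecewise-constant) orientation unit vector scaled by (1 + true ENMO),
  per-axis white noise, injectable calibration offset/gain error,
  perfectly still non-wear windows, and out-of-range spike artifacts.
  Hours of signal, for testing calibration / screening / ENMO / non-wear.

Reproducibility: every generator takes one root seed and derives one child
stream per subject (``numpy.random.SeedSequence.spawn``), in subject order,
so regenerating a subset of subjects yields identical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .constructs import ConstructMatrix
from .errors import ConfigurationError
from .signal import EpochSeries, RawRecording

STATES = ("sleep", "sedentary", "light", "mvpa")

#: mean true ENMO per activity state, mg
DEFAULT_STATE_LEVELS: dict[str, float] = {
    "sleep": 3.0,
    "sedentary": 15.0,
    "light": 70.0,
    "mvpa": 180.0,
}

# per-minute transition probabilities, rows/cols in STATES order
_DAY_T = np.array(
    [
        [0.950, 0.050, 0.000, 0.000],
        [0.002, 0.930, 0.060, 0.008],
        [0.002, 0.150, 0.800, 0.048],
        [0.000, 0.060, 0.090, 0.850],
    ]
)
_NIGHT_T = np.array(
    [
        [0.995, 0.005, 0.000, 0.000],
        [0.060, 0.900, 0.040, 0.000],
        [0.050, 0.250, 0.700, 0.000],
        [0.020, 0.180, 0.100, 0.700],
    ]
)
NIGHT_HOURS = (22, 6)  # sleep-trough span: 22:00 to 06:00

__all__ = [
    "CohortSimConfig",
    "SignalSimConfig",
    "EpochCohortConfig",
    "SimulatedConstructMatrix",
    "RawSignalTruth",
    "simulate_construct_matrix",
    "simulate_raw_recording",
    "simulate_epoch_cohort",
    "STATES",
    "DEFAULT_STATE_LEVELS",
]


def _require(cond: bool, fieldname: str, msg: str) -> None:
    if not cond:
        raise ConfigurationError(f"{fieldname}: {msg}")


# ---------------------------------------------------------------------------
# construct tier
# ---------------------------------------------------------------------------


@dataclass
class CohortSimConfig:
    """Configuration of the construct-level variance-components generator.

    ``mu_construct`` and the sigmas are in construct units (mg for overall
    PA, minutes for LPA/MVPA). ``weekend_shift`` is added on Saturdays and
    Sundays; ``dow_profile`` is an optional 7-vector of additive offsets
    indexed Monday..Sunday. ``truncate`` clips negative values at zero —
    off by default so the closed-form ground-truth ICC holds exactly.
    """

    n_subjects: int = 100
    n_days: int = 6
    epoch_len: float = 5.0
    mu_construct: float = 50.0
    sigma_between: float = 1.0
    sigma_within: float = 1.0
    weekend_shift: float = 0.0
    dow_profile: Sequence[float] | None = None
    start_date: str = "2010-03-01"  # a Monday
    construct: str = "overall"
    truncate: bool = False
    seed: int = 0

    def validate(self) -> None:
        _require(self.n_subjects >= 2, "n_subjects", "must be >= 2")
        _require(self.n_days >= 2, "n_days", "must be >= 2")
        _require(self.sigma_between >= 0, "sigma_between", "must be >= 0")
        _require(self.sigma_within > 0, "sigma_within", "must be > 0")
        _require(self.epoch_len > 0, "epoch_len", "must be > 0")
        if self.dow_profile is not None:
            _require(len(self.dow_profile) == 7, "dow_profile", "must have 7 entries")


@dataclass
class SimulatedConstructMatrix:
    """A construct matrix plus its generating ground truth."""

    matrix: ConstructMatrix
    icc_true: float  #: sigma_b^2/(sigma_b^2+sigma_w^2), fixed offsets removed
    icc_true_with_dow: float  #: ditto, with the day-offset variance folded into within
    day_offsets: np.ndarray  #: d_j actually applied, one per design day
    subject_effects: np.ndarray


def simulate_construct_matrix(cfg: CohortSimConfig) -> SimulatedConstructMatrix:
    """Draw a balanced subjects x days construct matrix with known ICC."""
    cfg.validate()
    start = pd.Timestamp(cfg.start_date)
    dates = pd.DatetimeIndex([start + pd.Timedelta(days=j) for j in range(cfg.n_days)])
    dow = np.array([d.isoweekday() for d in dates])
    prof = np.zeros(7) if cfg.dow_profile is None else np.asarray(cfg.dow_profile, float)
    d_j = prof[dow - 1] + np.where(dow >= 6, cfg.weekend_shift, 0.0)

    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n_subjects)
    values = np.empty((cfg.n_subjects, cfg.n_days))
    b = np.empty(cfg.n_subjects)
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        b[i] = rng.normal(0.0, cfg.sigma_between)
        w = rng.normal(0.0, cfg.sigma_within, cfg.n_days)
        values[i] = cfg.mu_construct + b[i] + d_j + w
    if cfg.truncate:
        values = np.maximum(values, 0.0)

    var_b = cfg.sigma_between**2
    var_w = cfg.sigma_within**2
    var_d = float(np.var(d_j))  # population variance over the design days
    icc_true = var_b / (var_b + var_w) if var_b + var_w > 0 else 0.0
    icc_dow = var_b / (var_b + var_w + var_d)
    matrix = ConstructMatrix(
        construct=cfg.construct,
        subject_ids=np.array([f"S{i:04d}" for i in range(cfg.n_subjects)]),
        dates=np.tile(dates.values, (cfg.n_subjects, 1)),
        day_of_week=np.tile(dow, (cfg.n_subjects, 1)),
        values=values,
    )
    return SimulatedConstructMatrix(
        matrix=matrix,
        icc_true=icc_true,
        icc_true_with_dow=icc_dow,
        day_offsets=d_j,
        subject_effects=b,
    )


# ---------------------------------------------------------------------------
# activity-state chain (shared by epoch and raw tiers)
# ---------------------------------------------------------------------------


def _night_mask_minutes(n_minutes: int, start_minute: int = 0) -> np.ndarray:
    mod = (np.arange(n_minutes) + start_minute) % 1440
    lo, hi = NIGHT_HOURS[0] * 60, NIGHT_HOURS[1] * 60
    return (mod >= lo) | (mod < hi)


def _scale_activity(T: np.ndarray, factor: float) -> np.ndarray:
    """Scale transitions into light/MVPA by ``factor`` and renormalise rows."""
    T = T.copy()
    T[:, 2:] *= factor
    T /= T.sum(axis=1, keepdims=True)
    return T


def _minute_states(
    n_minutes: int,
    rng: np.random.Generator,
    day_T: np.ndarray = _DAY_T,
    night_T: np.ndarray = _NIGHT_T,
    weekend_factor_by_minute: np.ndarray | None = None,
    start_minute: int = 0,
) -> np.ndarray:
    """Simulate the minute-resolution activity-state Markov chain."""
    night = _night_mask_minutes(n_minutes, start_minute)
    # pre-computed cumulative rows for the (at most) 4 matrix variants
    variants = {}

    def cum_for(is_night: bool, factor: float) -> np.ndarray:
        key = (is_night, factor)
        if key not in variants:
            T = night_T if is_night else day_T
            if factor != 1.0:
                T = _scale_activity(T, factor)
            variants[key] = np.cumsum(T, axis=1)
        return variants[key]

    states = np.empty(n_minutes, dtype=np.int8)
    state = 0  # start asleep at midnight
    u = rng.random(n_minutes)
    for m in range(n_minutes):
        f = 1.0 if weekend_factor_by_minute is None else weekend_factor_by_minute[m]
        cum = cum_for(bool(night[m]), f)
        state = int(np.searchsorted(cum[state], u[m], side="right"))
        states[m] = state
    return states


# ---------------------------------------------------------------------------
# raw tier
# ---------------------------------------------------------------------------


@dataclass
class SignalSimConfig:
    """Configuration of the raw tri-axial signal generator.

    ``activity_state_rates`` optionally overrides the built-in per-minute
    transition matrices with ``{"day": 4x4, "night": 4x4}`` (rows/cols in
    :data:`STATES` order; rows are renormalised). ``state_enmo_levels`` are
    mean true ENMO per state in mg. ``axis_offsets`` (g) and ``axis_gains``
    are the *miscalibration* injected into the observed signal, i.e. the
    values a downstream autocalibration should recover.
    ``nonwear_windows`` is a list of ``(start_s, duration_s)`` gaps during
    which the device lies perfectly still (frozen orientation, no noise).
    ``spike_rate`` injects that many out-of-range (+/-10 g) single-sample
    artifacts per day on average. ``noise_sd`` is per-axis white noise, mg.
    """

    sample_rate: float = 85.7
    days: float = 1.0
    start_time: str = "2010-03-01 00:00:00"
    epoch_len: float = 5.0
    activity_state_rates: Mapping[str, np.ndarray] | None = None
    state_enmo_levels: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STATE_LEVELS)
    )
    axis_offsets: Sequence[float] = (0.0, 0.0, 0.0)
    axis_gains: Sequence[float] = (1.0, 1.0, 1.0)
    nonwear_windows: Sequence[tuple[float, float]] = ()
    spike_rate: float = 0.0
    noise_sd: float = 10.0
    orientation_hold_min: float = 5.0
    subject_id: str = "SIM"
    seed: int = 0

    def validate(self) -> None:
        _require(self.sample_rate > 0, "sample_rate", "must be > 0")
        _require(self.days > 0, "days", "must be > 0")
        _require(self.epoch_len > 0, "epoch_len", "must be > 0")
        _require(all(g > 0 for g in self.axis_gains), "axis_gains", "must be > 0")
        _require(len(self.axis_offsets) == 3, "axis_offsets", "needs 3 entries")
        _require(len(self.axis_gains) == 3, "axis_gains", "needs 3 entries")
        _require(self.spike_rate >= 0, "spike_rate", "must be >= 0")
        _require(self.noise_sd >= 0, "noise_sd", "must be >= 0")
        _require(self.orientation_hold_min > 0, "orientation_hold_min", "must be > 0")
        for s in STATES:
            _require(s in self.state_enmo_levels, "state_enmo_levels", f"missing state {s!r}")
            _require(self.state_enmo_levels[s] >= 0, "state_enmo_levels", "must be >= 0")
        span = self.days * 86400.0
        for w_start, w_dur in self.nonwear_windows:
            _require(
                0 <= w_start and w_start + w_dur <= span and w_dur > 0,
                "nonwear_windows",
                f"window ({w_start}, {w_dur}) outside the recording span",
            )


@dataclass
class RawSignalTruth:
    """Ground truth accompanying a simulated raw recording."""

    epoch_len: float
    states: np.ndarray  #: per-epoch state index into STATES
    true_enmo: np.ndarray  #: per-epoch true ENMO, mg (0 inside non-wear)
    nonwear_epochs: np.ndarray  #: per-epoch bool, >=50% of samples in a gap
    spike_indices: np.ndarray  #: sample indices of injected spikes
    n_spikes: int


def _random_unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def simulate_raw_recording(cfg: SignalSimConfig) -> tuple[RawRecording, RawSignalTruth]:
    """Simulate device-cadence tri-axial samples with full ground truth.

    The quiescent signal is a unit-gravity vector with piecewise-constant
    orientation (mean hold ``orientation_hold_min`` minutes) plus per-axis
    white noise; activity scales the magnitude to ``1 + level`` so the true
    epoch ENMO equals the state level exactly. Miscalibration is applied as
    ``observed = true / gain + offset`` per axis, the inverse of the
    correction ``(observed - offset) * gain``.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    n_minutes = int(round(cfg.days * 1440))
    n_samples = int(round(cfg.days * 86400 * cfg.sample_rate))
    n_epochs = int(np.floor(cfg.days * 86400 / cfg.epoch_len + 1e-9))

    if cfg.activity_state_rates is None:
        day_T, night_T = _DAY_T, _NIGHT_T
    else:
        day_T = np.asarray(cfg.activity_state_rates["day"], float)
        night_T = np.asarray(cfg.activity_state_rates["night"], float)
        day_T = day_T / day_T.sum(axis=1, keepdims=True)
        night_T = night_T / night_T.sum(axis=1, keepdims=True)
    minute_states = _minute_states(n_minutes, rng, day_T, night_T)

    # map epochs -> minutes -> states; levels in g
    epoch_start_s = np.arange(n_epochs) * cfg.epoch_len
    ep_states = minute_states[np.minimum((epoch_start_s // 60).astype(int), n_minutes - 1)]
    levels = np.array([cfg.state_enmo_levels[s] for s in STATES]) / 1000.0
    ep_level = levels[ep_states]

    t = np.arange(n_samples) / cfg.sample_rate
    samp_epoch = np.minimum((t / cfg.epoch_len).astype(np.int64), n_epochs - 1)
    samp_level = ep_level[samp_epoch]

    # piecewise-constant orientation
    hold_s = rng.exponential(cfg.orientation_hold_min * 60.0, size=max(8, n_minutes))
    while hold_s.sum() < cfg.days * 86400:
        hold_s = np.concatenate([hold_s, rng.exponential(cfg.orientation_hold_min * 60.0, 64)])
    seg_counts = np.maximum((hold_s * cfg.sample_rate).astype(int), 1)
    seg_counts = seg_counts[np.cumsum(seg_counts) - seg_counts < n_samples]
    total = int(seg_counts.sum())
    if total < n_samples:
        seg_counts = np.append(seg_counts, n_samples - total)
    else:
        seg_counts[-1] -= total - n_samples
        seg_counts = seg_counts[seg_counts > 0]
    orient = np.repeat(_random_unit_vectors(rng, len(seg_counts)), seg_counts, axis=0)

    v = orient * (1.0 + samp_level)[:, None]
    if cfg.noise_sd > 0:
        v = v + rng.normal(0.0, cfg.noise_sd / 1000.0, size=v.shape)

    # non-wear: perfectly still, noise-free, frozen orientation, magnitude 1
    nonwear_sample = np.zeros(n_samples, dtype=bool)
    for w_start, w_dur in cfg.nonwear_windows:
        mask = (t >= w_start) & (t < w_start + w_dur)
        if not mask.any():
            continue
        frozen = orient[np.argmax(mask)]
        v[mask] = frozen
        nonwear_sample[mask] = True
        samp_level = np.where(mask, 0.0, samp_level)

    # per-epoch ground truth (after zeroing non-wear)
    counts = np.bincount(samp_epoch, minlength=n_epochs).astype(float)
    true_enmo = np.bincount(samp_epoch, weights=samp_level, minlength=n_epochs) / counts * 1000.0
    nw_frac = np.bincount(samp_epoch, weights=nonwear_sample, minlength=n_epochs) / counts
    nonwear_epochs = nw_frac >= 0.5

    # inject miscalibration: observed = true/gain + offset
    gains = np.asarray(cfg.axis_gains, float)
    offsets = np.asarray(cfg.axis_offsets, float)
    v = v / gains + offsets

    # spikes beyond the +/-8 g range
    n_spikes = int(rng.poisson(cfg.spike_rate * cfg.days))
    n_spikes = min(n_spikes, n_samples)
    spike_idx = np.sort(rng.choice(n_samples, size=n_spikes, replace=False))
    if n_spikes:
        axes = rng.integers(0, 3, n_spikes)
        signs = rng.choice([-1.0, 1.0], n_spikes)
        v[spike_idx, axes] = signs * 10.0

    rec = RawRecording(
        subject_id=cfg.subject_id,
        sample_rate=cfg.sample_rate,
        start_time=pd.Timestamp(cfg.start_time),
        x=v[:, 0],
        y=v[:, 1],
        z=v[:, 2],
    )
    truth = RawSignalTruth(
        epoch_len=cfg.epoch_len,
        states=ep_states,
        true_enmo=true_enmo,
        nonwear_epochs=nonwear_epochs,
        spike_indices=spike_idx,
        n_spikes=n_spikes,
    )
    return rec, truth


# ---------------------------------------------------------------------------
# epoch tier
# ---------------------------------------------------------------------------


@dataclass
class EpochCohortConfig:
    """Configuration of the cohort-scale epoch-level generator.

    Each subject gets a lognormal activity multiplier (sigma
    ``subject_sigma``) applied to the state ENMO levels — the
    between-subject heterogeneity that makes habitual PA estimable at all.
    ``weekend_activity_factor`` scales the Markov-chain transitions into
    light/MVPA on Saturdays and Sundays (< 1 means less weekend activity).
    With probability ``nonwear_per_day`` a subject-day contains one
    exact-zero non-wear gap of uniform duration in
    ``nonwear_dur_range_min`` minutes.
    """

    n_subjects: int = 100
    n_days: int = 7
    epoch_len: float = 5.0
    start_date: str = "2010-03-01"  # a Monday
    state_enmo_levels: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STATE_LEVELS)
    )
    subject_sigma: float = 0.25
    weekend_activity_factor: float = 0.7
    noise_mg: float = 8.0
    nonwear_per_day: float = 0.1
    nonwear_dur_range_min: tuple[float, float] = (60.0, 360.0)
    seed: int = 0

    def validate(self) -> None:
        _require(self.n_subjects >= 1, "n_subjects", "must be >= 1")
        _require(self.n_days >= 1, "n_days", "must be >= 1")
        _require(self.epoch_len > 0 and 60 % self.epoch_len == 0, "epoch_len",
                 "must be > 0 and divide 60 s")
        _require(self.subject_sigma >= 0, "subject_sigma", "must be >= 0")
        _require(self.weekend_activity_factor > 0, "weekend_activity_factor", "must be > 0")
        _require(0 <= self.nonwear_per_day <= 1, "nonwear_per_day", "must be in [0, 1]")
        _require(self.noise_mg >= 0, "noise_mg", "must be >= 0")


def simulate_epoch_cohort(
    cfg: EpochCohortConfig,
) -> list[tuple[EpochSeries, dict]]:
    """Simulate per-subject ENMO epoch series over whole calendar days.

    Returns ``(series, truth)`` pairs; ``truth`` holds the subject
    multiplier, per-epoch state indices and the true non-wear epoch mask.
    """
    cfg.validate()
    start = pd.Timestamp(cfg.start_date)
    n_minutes = cfg.n_days * 1440
    epm = int(60 // cfg.epoch_len)  # epochs per minute
    levels = np.array([cfg.state_enmo_levels[s] for s in STATES])
    dow = np.array(
        [(start + pd.Timedelta(days=j)).isoweekday() for j in range(cfg.n_days)]
    )
    weekend_minute = np.repeat(np.where(dow >= 6, cfg.weekend_activity_factor, 1.0), 1440)

    out = []
    for i, ss in enumerate(np.random.SeedSequence(cfg.seed).spawn(cfg.n_subjects)):
        rng = np.random.default_rng(ss)
        mult = float(rng.lognormal(0.0, cfg.subject_sigma)) if cfg.subject_sigma else 1.0
        minute_states = _minute_states(
            n_minutes, rng, weekend_factor_by_minute=weekend_minute
        )
        states = np.repeat(minute_states, epm)
        enmo = mult * levels[states]
        if cfg.noise_mg:
            enmo = enmo + rng.normal(0.0, cfg.noise_mg, size=enmo.size)
        enmo = np.maximum(enmo, 0.0)

        nonwear = np.zeros(enmo.size, dtype=bool)
        day_epochs = 1440 * epm
        for j in range(cfg.n_days):
            if rng.random() < cfg.nonwear_per_day:
                dur_min = rng.uniform(*cfg.nonwear_dur_range_min)
                start_min = rng.uniform(0.0, 1440.0 - dur_min)
                a = j * day_epochs + int(start_min * epm)
                b = min((j + 1) * day_epochs, a + int(dur_min * epm))
                nonwear[a:b] = True
        enmo[nonwear] = 0.0

        series = EpochSeries(
            subject_id=f"S{i:04d}",
            epoch_len=cfg.epoch_len,
            start_time=start,
            enmo=enmo,
        )
        out.append(
            (
                series,
                {
                    "multiplier": mult,
                    "states": states,
                    "nonwear_epochs": nonwear,
                },
            )
        )
    return out
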