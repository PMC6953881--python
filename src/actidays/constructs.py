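"""Daily physical-activity constructs from ENMO epoch series.

Three constructs, matching common raw-accelerometry practice:

* overall PA — mean ENMO over wear epochs of a day, in mg;
* LPA — minutes with ENMO in the light band (default 50-100 mg, both
  boundaries inclusive to the light side);
* bouted MVPA — minutes inside accepted >=10-min bouts in which at least
  80% of epochs exceed the MVPA cut-point (default strictly above 100 mg).

Days are calendar days (midnight to midnight, local time); a day is valid
with at least 16 h of wear; the analytical sample keeps subjects with at
least 6 valid days and retains their first 6.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EmptySampleError, InputDataError
from .signal import EpochSeries

logger = logging.getLogger(__name__)

# intensity label codes
NONWEAR, SEDENTARY, LPA, MVPA = -1, 0, 1, 2

CONSTRUCTS = ("overall", "lpa", "mvpa")
#: day-summary column per construct name
CONSTRUCT_COLUMNS = {
    "overall": "overall_pa_mg",
    "lpa": "lpa_min",
    "mvpa": "mvpa_bouted_min",
}

DAY_SUMMARY_COLUMNS = [
    "subject_id",
    "date",
    "dow",
    "wear_hours",
    "overall_pa_mg",
    "lpa_min",
    "mvpa_bouted_min",
    "valid",
]

__all__ = [
    "NONWEAR",
    "SEDENTARY",
    "LPA",
    "MVPA",
    "CONSTRUCTS",
    "CONSTRUCT_COLUMNS",
    "DAY_SUMMARY_COLUMNS",
    "Bout",
    "DaySummary",
    "ConstructMatrix",
    "SampleSelection",
    "classify_epochs",
    "detect_mvpa_bouts",
    "summarize_day",
    "days_to_frame",
    "select_analytical_sample",
]


@dataclass
class Bout:
    """A detected MVPA bout over the half-open epoch range [start, end)."""

    start_epoch: int
    end_epoch: int
    duration_min: float
    fraction_above: float


@dataclass
class DaySummary:
    """One calendar day's wear time and construct values for one subject."""

    subject_id: str
    date: pd.Timestamp
    day_of_week: int  # 1=Monday .. 7=Sunday
    wear_hours: float
    overall_pa: float  # NaN when the day has zero wear epochs
    lpa_min: float
    mvpa_bouted_min: float
    valid: bool


@dataclass
class ConstructMatrix:
    """Balanced subjects x days matrix of one construct for reliability."""

    construct: str
    subject_ids: np.ndarray
    dates: np.ndarray  # (n, k) datetime64
    day_of_week: np.ndarray  # (n, k) int
    values: np.ndarray  # (n, k) float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, k = self.values.shape
        if k < 2:
            raise InputDataError("ConstructMatrix needs at least 2 days per subject")
        if len(self.subject_ids) != n:
            raise InputDataError("subject_ids length does not match values")
        if np.isnan(self.values).any():
            raise InputDataError("ConstructMatrix must have no missing cells")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def k_days(self) -> int:
        return self.values.shape[1]

    def to_long_frame(self) -> pd.DataFrame:
        n, k = self.values.shape
        return pd.DataFrame(
            {
                "subject_id": np.repeat(self.subject_ids, k),
                "day_index": np.tile(np.arange(1, k + 1), n),
                "date": pd.to_datetime(self.dates.reshape(-1)),
                "value": self.values.reshape(-1),
            }
        )

    def to_day_frame(self) -> pd.DataFrame:
        """Day-summary-shaped frame (all days valid) for descriptive stats."""
        long = self.to_long_frame()
        out = pd.DataFrame(
            {
                "subject_id": long["subject_id"],
                "date": long["date"],
                "dow": self.day_of_week.reshape(-1),
                "valid": True,
            }
        )
        out[CONSTRUCT_COLUMNS[self.construct]] = long["value"].to_numpy()
        return out


def classify_epochs(
    ep: EpochSeries, lpa_low: float = 50.0, mvpa_threshold: float = 100.0
) -> np.ndarray:
    """Label wear epochs sedentary / LPA / MVPA from ENMO cut-points.

    MVPA is strictly above ``mvpa_threshold``; LPA spans
    [``lpa_low``, ``mvpa_threshold``] inclusive on both ends; below is
    sedentary. Non-wear epochs get :data:`NONWEAR`.
    """
    if not 0 < lpa_low < mvpa_threshold:
        raise ConfigurationError(
            f"thresholds must satisfy 0 < lpa_low < mvpa_threshold, got "
            f"({lpa_low}, {mvpa_threshold})"
        )
    labels = np.full(ep.n_epochs, SEDENTARY, dtype=np.int8)
    labels[ep.enmo > mvpa_threshold] = MVPA
    labels[(ep.enmo >= lpa_low) & (ep.enmo <= mvpa_threshold)] = LPA
    labels[~ep.wear] = NONWEAR
    return labels


def detect_mvpa_bouts(
    labels: np.ndarray,
    epoch_len: float = 5.0,
    min_bout: float = 10.0,
    min_fraction: float = 0.8,
) -> list[Bout]:
    """Greedy left-to-right scan for sustained MVPA bouts.

    A candidate bout starts at an MVPA epoch and is the longest window
    starting there that (a) spans at least ``min_bout`` minutes, (b) has an
    above-threshold fraction >= ``min_fraction``, (c) ends on an MVPA epoch
    and (d) contains no run of non-MVPA epochs longer than
    ``(1 - min_fraction) * min_bout`` minutes. Non-wear epochs break bouts
    unconditionally. Accepted bouts are non-overlapping; the scan resumes
    immediately after each accepted bout.
    """
    if not min_bout > 0:
        raise ConfigurationError("min_bout must be > 0")
    if not 0 < min_fraction <= 1:
        raise ConfigurationError("min_fraction must be in (0, 1]")
    labels = np.asarray(labels)
    n = len(labels)
    is_mvpa = labels == MVPA
    barrier = labels == NONWEAR
    min_len = int(np.ceil(min_bout * 60.0 / epoch_len - 1e-9))
    max_gap = int(np.floor((1.0 - min_fraction) * min_bout * 60.0 / epoch_len + 1e-9))

    # g[i]: length of the non-MVPA run ending at i (0 on MVPA epochs);
    # barriers reset the run too (windows can never contain them anyway)
    g = np.zeros(n, dtype=np.int64)
    run = 0
    for i in range(n):
        if is_mvpa[i] or barrier[i]:
            run = 0
        else:
            run += 1
        g[i] = run

    # next barrier at or after i
    next_barrier = np.full(n + 1, n, dtype=np.int64)
    for i in range(n - 1, -1, -1):
        next_barrier[i] = i if barrier[i] else next_barrier[i + 1]

    cum = np.concatenate([[0], np.cumsum(is_mvpa)])
    bouts: list[Bout] = []
    pos = 0
    while pos < n:
        if not is_mvpa[pos]:
            pos += 1
            continue
        s = pos
        limit = next_barrier[s]
        # first index with an over-long interruption run: window ends must
        # not reach past it
        seg_g = g[s:limit]
        bad = np.nonzero(seg_g > max_gap)[0]
        emax = s + bad[0] if bad.size else limit
        lo = s + min_len
        if lo <= emax:
            ends = np.arange(lo, emax + 1)
            ok = is_mvpa[ends - 1]
            frac = (cum[ends] - cum[s]) / (ends - s)
            ok &= frac >= min_fraction - 1e-12
            if ok.any():
                e = int(ends[ok][-1])  # longest valid window at this start
                bouts.append(
                    Bout(
                        start_epoch=s,
                        end_epoch=e,
                        duration_min=(e - s) * epoch_len / 60.0,
                        fraction_above=float((cum[e] - cum[s]) / (e - s)),
                    )
                )
                pos = e
                continue
        pos += 1
    return bouts


def summarize_day(
    ep: EpochSeries,
    labels: np.ndarray,
    bouts: list[Bout],
    min_wear_hours: float = 16.0,
) -> list[DaySummary]:
    """Collapse an epoch series into per-calendar-day summaries.

    Only days fully covered by the series (midnight-to-midnight at the
    epoch cadence) are summarised; partial first/last days are excluded.
    Overall PA is the mean ENMO over wear epochs only — no imputation of
    non-wear time — and is NaN (with ``valid=False``) on zero-wear days.
    Bout epochs are credited to the calendar day they fall in, so a bout
    crossing midnight splits its minutes across both days.
    """
    if 86400.0 % ep.epoch_len != 0:
        raise InputDataError("epoch_len must divide 24 h for calendar-day summaries")
    per_day = int(86400.0 / ep.epoch_len)
    times = ep.epoch_times()
    dates = times.normalize()
    in_bout = np.zeros(ep.n_epochs, dtype=bool)
    for b in bouts:
        in_bout[b.start_epoch : b.end_epoch] = True

    df = pd.DataFrame(
        {
            "date": dates,
            "wear": ep.wear,
            "enmo": ep.enmo,
            "lpa": labels == LPA,
            "bout": in_bout,
        }
    )
    out: list[DaySummary] = []
    for date, grp in df.groupby("date", sort=True):
        if len(grp) != per_day:
            continue  # partial day
        wear = grp["wear"].to_numpy()
        wear_hours = wear.sum() * ep.epoch_len / 3600.0
        if wear.any():
            overall = float(grp.loc[grp["wear"], "enmo"].mean())
        else:
            overall = float("nan")
        valid = bool(wear_hours >= min_wear_hours) and wear.any()
        out.append(
            DaySummary(
                subject_id=ep.subject_id,
                date=pd.Timestamp(date),
                day_of_week=pd.Timestamp(date).isoweekday(),
                wear_hours=float(wear_hours),
                overall_pa=overall,
                lpa_min=float(grp["lpa"].sum() * ep.epoch_len / 60.0),
                mvpa_bouted_min=float(grp["bout"].sum() * ep.epoch_len / 60.0),
                valid=valid,
            )
        )
    if not out:
        raise InputDataError("epoch series does not cover one full calendar day")
    return out


def days_to_frame(days: list[DaySummary]) -> pd.DataFrame:
    """Day summaries as a DataFrame with the canonical column schema."""
    return pd.DataFrame(
        {
            "subject_id": [d.subject_id for d in days],
            "date": [d.date for d in days],
            "dow": [d.day_of_week for d in days],
            "wear_hours": [d.wear_hours for d in days],
            "overall_pa_mg": [d.overall_pa for d in days],
            "lpa_min": [d.lpa_min for d in days],
            "mvpa_bouted_min": [d.mvpa_bouted_min for d in days],
            "valid": [d.valid for d in days],
        }
    )


@dataclass
class SampleSelection:
    """Analytical sample: balanced construct matrices plus exclusion counts."""

    matrices: dict[str, ConstructMatrix]
    n_included: int
    n_excluded: int
    excluded_ids: list[str]


def select_analytical_sample(
    days: pd.DataFrame | list[DaySummary],
    min_valid_days: int = 6,
    k_keep: int = 6,
) -> SampleSelection:
    """Restrict to subjects with enough valid days and balance the matrices.

    Keeps subjects with at least ``min_valid_days`` valid days; for each,
    retains the first ``k_keep`` valid days in chronological order, giving
    balanced matrices for overall PA, LPA and bouted MVPA.
    """
    if min_valid_days < 2:
        raise ConfigurationError("min_valid_days must be >= 2")
    if k_keep > min_valid_days:
        raise ConfigurationError("k_keep must be <= min_valid_days")
    df = days if isinstance(days, pd.DataFrame) else days_to_frame(days)
    missing = [c for c in DAY_SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise InputDataError(f"day summary is missing columns: {missing}")
    df = df.copy()
    df["date"] = pd.to_datetime(df["date"])
    valid = df[df["valid"].astype(bool)].sort_values(["subject_id", "date"])
    counts = valid.groupby("subject_id").size()
    keep_ids = sorted(counts[counts >= min_valid_days].index)
    all_ids = sorted(df["subject_id"].unique())
    excluded = [s for s in all_ids if s not in set(keep_ids)]
    if not keep_ids:
        raise EmptySampleError(
            f"no subject has >= {min_valid_days} valid days (n={len(all_ids)} candidates)"
        )
    logger.info(
        "analytical sample: %d included, %d excluded (min %d valid days)",
        len(keep_ids),
        len(excluded),
        min_valid_days,
    )
    kept = valid.groupby("subject_id").head(k_keep)
    kept = kept[kept["subject_id"].isin(keep_ids)]
    n = len(keep_ids)
    dates = np.empty((n, k_keep), dtype="datetime64[ns]")
    dows = np.empty((n, k_keep), dtype=int)
    vals = {c: np.empty((n, k_keep)) for c in CONSTRUCTS}
    for i, sid in enumerate(keep_ids):
        sub = kept[kept["subject_id"] == sid]
        dates[i] = sub["date"].to_numpy()
        dows[i] = sub["dow"].to_numpy()
        for c in CONSTRUCTS:
            vals[c][i] = sub[CONSTRUCT_COLUMNS[c]].to_numpy()
    matrices = {
        c: ConstructMatrix(
            construct=c,
            subject_ids=np.array(keep_ids),
            dates=dates,
            day_of_week=dows,
            values=vals[c],
        )
        for c in CONSTRUCTS
    }
    return SampleSelection(
        matrices=matrices,
        n_included=len(keep_ids),
        n_excluded=len(excluded),
        excluded_ids=excluded,
    )
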