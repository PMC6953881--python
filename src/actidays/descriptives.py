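"""Day-of-week and weekday/weekend medians with rank-based tests.

Subject-days are pooled and treated as independent observations (no
within-subject clustering adjustment) — simple, and appropriate for
descriptive day-of-week profiles; inference on the p-values should keep
that limitation in mind. Differences across the seven days of the week are
tested with Kruskal-Wallis (whose statistic is chi-squared distributed);
weekday (Mon-Fri) versus weekend (Sat-Sun) with a two-sided
Mann-Whitney U.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .constructs import CONSTRUCT_COLUMNS, CONSTRUCTS
from .errors import InputDataError

WEEKEND_DOWS = (6, 7)  # Saturday, Sunday

__all__ = ["DowSummary", "dow_medians", "dow_table"]


@dataclass
class DowSummary:
    """Medians by day of week and weekday/weekend contrast for one construct."""

    construct: str
    group: str | None
    medians: dict[int, float] = field(default_factory=dict)  # 1=Mon .. 7=Sun
    n_obs: dict[int, int] = field(default_factory=dict)
    weekday_median: float = float("nan")
    weekend_median: float = float("nan")
    p_dow: float = float("nan")  # Kruskal-Wallis across the 7 days
    p_wkend: float = float("nan")  # weekday vs weekend rank test
    degenerate: bool = False  # tests undefined (identical values / empty group)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dow": list(range(1, 8)),
                "median": [self.medians.get(d, float("nan")) for d in range(1, 8)],
                "n": [self.n_obs.get(d, 0) for d in range(1, 8)],
            }
        )


def dow_medians(
    days: pd.DataFrame, construct: str, group: str | None = None
) -> DowSummary:
    """Medians of one construct by day of week over valid subject-days.

    ``days`` is a day-summary frame (``dow``, ``valid`` and the construct
    column present). Empty day categories yield a missing median and skip
    the tests with a warning; identical values across all days make the
    rank tests degenerate, which is flagged with ``p = NaN``.
    """
    if construct not in CONSTRUCTS:
        raise InputDataError(f"unknown construct {construct!r}; expected one of {CONSTRUCTS}")
    col = CONSTRUCT_COLUMNS[construct]
    for c in ("dow", "valid", col):
        if c not in days.columns:
            raise InputDataError(f"day summary lacks required column {c!r}")
    valid = days[days["valid"].astype(bool)]
    valid = valid[np.isfinite(valid[col])]

    out = DowSummary(construct=construct, group=group)
    samples = []
    for d in range(1, 8):
        vals = valid.loc[valid["dow"] == d, col].to_numpy()
        out.n_obs[d] = len(vals)
        out.medians[d] = float(np.median(vals)) if len(vals) else float("nan")
        if len(vals):
            samples.append(vals)
    wk = valid.loc[~valid["dow"].isin(WEEKEND_DOWS), col].to_numpy()
    we = valid.loc[valid["dow"].isin(WEEKEND_DOWS), col].to_numpy()
    out.weekday_median = float(np.median(wk)) if len(wk) else float("nan")
    out.weekend_median = float(np.median(we)) if len(we) else float("nan")

    if any(n == 0 for n in out.n_obs.values()):
        warnings.warn(
            f"{construct}: empty day-of-week category; rank tests skipped",
            stacklevel=2,
        )
        out.degenerate = True
        return out
    try:
        out.p_dow = float(stats.kruskal(*samples).pvalue)
    except ValueError:  # all values identical -> statistic undefined
        out.degenerate = True
    if len(wk) and len(we) and not out.degenerate:
        if np.ptp(np.concatenate([wk, we])) == 0:
            out.degenerate = True
        else:
            out.p_wkend = float(stats.mannwhitneyu(wk, we, alternative="two-sided").pvalue)
    return out


def dow_table(days: pd.DataFrame, group: str | None = None) -> pd.DataFrame:
    """Flat table of medians/counts/tests for all three constructs."""
    rows = []
    for c in CONSTRUCTS:
        s = dow_medians(days, c, group=group)
        for d in range(1, 8):
            rows.append(
                {
                    "group": group,
                    "construct": c,
                    "dow": d,
                    "median": s.medians[d],
                    "n": s.n_obs[d],
                    "weekday_median": s.weekday_median,
                    "weekend_median": s.weekend_median,
                    "p_dow": s.p_dow,
                    "p_wkend": s.p_wkend,
                }
            )
    return pd.DataFrame(rows)
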