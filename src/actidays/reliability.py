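"""Single-day ICC and Spearman-Brown prophecy for monitoring-days planning.

The question answered here: given day-to-day replicate measurements of a
physical-activity construct, how many monitoring days must be averaged for
the mean to reliably represent the habitual (between-subject) construct?

The single-day reliability is the one-way random-effects, single-measure
intraclass correlation. With MSB the between-subject and MSW the
within-subject (days) mean square from a one-way ANOVA on a balanced
n x k matrix:

    ICC(1,1) = (MSB - MSW) / (MSB + (k - 1) * MSW)

The prophecy steps a single-day reliability r1 up to the reliability of a
k-day average:

    r_k = k * r1 / (1 + (k - 1) * r1)

and inverts in closed form for the smallest k whose r_k exceeds a target
(0.70 by convention; strictly greater by default).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from sklearn.base import BaseEstimator

from .constructs import ConstructMatrix
from .errors import InputDataError, ReliabilityDomainError

logger = logging.getLogger(__name__)

__all__ = [
    "ReliabilityResult",
    "SpearmanBrownReliability",
    "icc_single_day",
    "spearman_brown",
    "min_days",
    "reliability_report",
    "round_half_away",
]


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round with ties going away from zero (the convention of printed
    reliability tables), unlike Python's banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _as_matrix(m) -> np.ndarray:
    values = m.values if isinstance(m, ConstructMatrix) else np.asarray(m, dtype=float)
    if values.ndim != 2:
        raise InputDataError("expected a 2-D subjects x days matrix")
    n, k = values.shape
    if n < 2 or k < 2:
        raise InputDataError(f"need >= 2 subjects and >= 2 days, got {n} x {k}")
    if np.isnan(values).any():
        raise InputDataError("matrix must be balanced with no missing cells")
    return values


def icc_single_day(m) -> tuple[float, float, float]:
    """One-way random-effects single-measure ICC of a balanced matrix.

    Returns ``(icc1, msb, msw)``. Negative estimates (MSW > MSB, possible
    by sampling noise when the true ICC is near zero) are returned as-is
    and logged; callers decide whether to propagate them.
    """
    values = _as_matrix(m)
    n, k = values.shape
    grand = values.mean()
    if np.allclose(values, grand):
        raise InputDataError("matrix is constant; ICC is undefined")
    row_means = values.mean(axis=1)
    msb = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msw = np.sum((values - row_means[:, None]) ** 2) / (n * (k - 1))
    if msb + (k - 1) * msw == 0:
        raise InputDataError("zero total variance; ICC is undefined")
    icc1 = (msb - msw) / (msb + (k - 1) * msw)
    if icc1 < 0:
        logger.warning("negative single-day ICC estimate (%.4f); flagged", icc1)
    return float(icc1), float(msb), float(msw)


def spearman_brown(r1: float, k: float) -> float:
    """Reliability of the average of ``k`` replicate days, from single-day
    reliability ``r1``: ``k*r1 / (1 + (k-1)*r1)``.

    ``r1`` must be positive (the prophecy is meaningless at or below zero)
    and at most 1; ``r1 = 1`` maps to 1 for every k.
    """
    if r1 <= 0:
        raise ReliabilityDomainError(
            f"Spearman-Brown prophecy undefined for reliability {r1} <= 0"
        )
    if r1 > 1:
        raise ReliabilityDomainError(f"reliability {r1} exceeds 1")
    if k < 1:
        raise ReliabilityDomainError(f"number of days k={k} must be >= 1")
    return k * r1 / (1.0 + (k - 1.0) * r1)


def min_days(r1: float, target: float = 0.70, strict: bool = True) -> int:
    """Smallest number of days whose averaged reliability exceeds ``target``.

    Strict comparison (``> target``) by default. Closed form
    ``ceil(target*(1-r1) / (r1*(1-target)))`` seeds the answer, which is
    then verified by direct evaluation to absorb the boundary semantics.
    """
    if r1 <= 0:
        raise ReliabilityDomainError(f"minimum days undefined for reliability {r1} <= 0")
    if not 0 < target < 1:
        raise ReliabilityDomainError(f"target must be in (0, 1), got {target}")
    if r1 >= 1:
        return 1
    k = max(1, math.ceil(target * (1.0 - r1) / (r1 * (1.0 - target)) - 1e-12))

    def ok(kk: int) -> bool:
        rk = spearman_brown(r1, kk)
        return rk > target if strict else rk >= target

    while not ok(k):
        k += 1
    while k > 1 and ok(k - 1):
        k -= 1
    return k


@dataclass
class ReliabilityResult:
    """Reliability of one construct (optionally within one cohort group)."""

    construct: str
    group: str | None
    icc1: float
    msb: float
    msw: float
    n_subjects: int
    k_days: int
    target: float
    r_by_days: dict[int, float] = field(default_factory=dict)
    min_days: int | None = None  #: None when unattainable within K or icc1 <= 0
    negative_icc: bool = False

    def to_record(self) -> dict:
        return {
            "construct": self.construct,
            "group": self.group,
            "icc1": self.icc1,
            "icc1_2dp": round_half_away(self.icc1),
            "msb": self.msb,
            "msw": self.msw,
            "n_subjects": self.n_subjects,
            "k_days": self.k_days,
            "target": self.target,
            "r_by_days": {str(k): v for k, v in self.r_by_days.items()},
            "r_by_days_2dp": {str(k): round_half_away(v) for k, v in self.r_by_days.items()},
            "min_days": self.min_days,
            "negative_icc": self.negative_icc,
        }


class SpearmanBrownReliability(BaseEstimator):
    """Estimate single-day ICC and the days-to-reliability curve.

    Fit on a balanced subjects x days array (or
    :class:`~actidays.constructs.ConstructMatrix`); fitted attributes carry
    the one-way ICC (``icc1_``, with ``msb_``/``msw_``), the stepped-up
    reliability for 1..``max_days`` days (``r_by_days_``) and the smallest
    number of days exceeding ``target`` (``min_days_``, None when the
    curve cannot reach the target within ``max_days`` or the ICC estimate
    is non-positive).

    ``predict(k)`` evaluates the fitted reliability curve at arbitrary day
    counts.
    """

    def __init__(self, max_days: int = 6, target: float = 0.70, strict: bool = True):
        self.max_days = max_days
        self.target = target
        self.strict = strict

    def fit(self, X, y=None) -> "SpearmanBrownReliability":
        values = _as_matrix(X)
        self.n_subjects_, self.k_days_ = values.shape
        self.icc1_, self.msb_, self.msw_ = icc_single_day(values)
        self.negative_icc_ = self.icc1_ < 0
        if self.icc1_ > 0:
            self.r_by_days_ = {
                k: spearman_brown(self.icc1_, k) for k in range(1, self.max_days + 1)
            }
            md = min_days(self.icc1_, self.target, self.strict)
            self.min_days_ = md if md <= self.max_days else None
        else:
            self.r_by_days_ = {}
            self.min_days_ = None
        return self

    def predict(self, k) -> np.ndarray:
        if not hasattr(self, "icc1_"):
            raise InputDataError("SpearmanBrownReliability is not fitted")
        if self.icc1_ <= 0:
            raise ReliabilityDomainError(
                "fitted ICC is non-positive; the prophecy curve is undefined"
            )
        k = np.atleast_1d(np.asarray(k, dtype=float))
        return np.array([spearman_brown(self.icc1_, kk) for kk in k])

    def result_(self, construct: str = "", group: str | None = None) -> ReliabilityResult:
        """Package the fitted attributes as a :class:`ReliabilityResult`."""
        return ReliabilityResult(
            construct=construct,
            group=group,
            icc1=self.icc1_,
            msb=self.msb_,
            msw=self.msw_,
            n_subjects=self.n_subjects_,
            k_days=self.k_days_,
            target=self.target,
            r_by_days=dict(self.r_by_days_),
            min_days=self.min_days_,
            negative_icc=self.negative_icc_,
        )


def reliability_report(
    matrices: dict,
    K: int = 6,
    target: float = 0.70,
    strict: bool = True,
) -> list[ReliabilityResult]:
    """Per construct (and optionally group): ICC, r(k) for k=1..K, min days.

    ``matrices`` maps either ``construct -> matrix`` or
    ``(group, construct) -> matrix``; a matrix is a
    :class:`~actidays.constructs.ConstructMatrix` or a 2-D array.
    """
    results = []
    for key, m in matrices.items():
        group, construct = key if isinstance(key, tuple) else (None, key)
        est = SpearmanBrownReliability(max_days=K, target=target, strict=strict).fit(m)
        results.append(est.result_(construct=construct, group=group))
    return results
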