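"""Brute-force oracles used by the test suite.

Kept deliberately naive and independent of the package's implementations:
the bout oracle enumerates every candidate window per start and checks the
acceptance conditions directly; the ICC oracle evaluates the one-way ANOVA
sums of squares definitionally with explicit loops.
"""

import math

import numpy as np

MVPA = 2
NONWEAR = -1


def brute_force_bouts(labels, epoch_len=5.0, min_bout=10.0, min_fraction=0.8):
    """All-windows enumeration + leftmost-start longest-window selection.

    A window [s, e) is valid when it starts and ends on MVPA epochs, spans
    at least ``min_bout`` minutes, has an MVPA fraction >= ``min_fraction``,
    contains no non-MVPA run longer than ``(1-min_fraction)*min_bout``
    minutes and no non-wear epoch. Returns [(start, end), ...].
    """
    labels = np.asarray(labels)
    n = len(labels)
    min_len = math.ceil(min_bout * 60.0 / epoch_len - 1e-9)
    max_gap = math.floor((1.0 - min_fraction) * min_bout * 60.0 / epoch_len + 1e-9)

    longest_at = {}
    for s in range(n):
        if labels[s] != MVPA:
            continue
        count = 0
        run = 0
        best = None
        for e in range(s + 1, n + 1):
            lab = labels[e - 1]
            if lab == NONWEAR:
                break
            if lab == MVPA:
                count += 1
                run = 0
            else:
                run += 1
                if run > max_gap:
                    break
            length = e - s
            if (
                length >= min_len
                and lab == MVPA
                and count / length >= min_fraction - 1e-12
            ):
                best = e
        if best is not None:
            longest_at[s] = best

    selected = []
    pos = 0
    for s in sorted(longest_at):
        if s < pos:
            continue
        selected.append((s, longest_at[s]))
        pos = longest_at[s]
    return selected


def icc_oneway_definitional(values):
    """One-way ANOVA ICC(1,1) from definitional sums of squares, looped."""
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    grand = values.sum() / (n * k)
    row_means = [sum(values[i]) / k for i in range(n)]
    ssb = sum(k * (row_means[i] - grand) ** 2 for i in range(n))
    ssw = sum(
        (values[i, j] - row_means[i]) ** 2 for i in range(n) for j in range(k)
    )
    msb = ssb / (n - 1)
    msw = ssw / (n * (k - 1))
    return (msb - msw) / (msb + (k - 1) * msw)


def kruskal_statistic_by_hand(groups):
    """Kruskal-Wallis H with midrank ties, from first principles."""
    pooled = np.concatenate(groups)
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled))
    i = 0
    srt = pooled[order]
    while i < len(srt):
        j = i
        while j < len(srt) and srt[j] == srt[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0  # midrank, 1-based
        i = j
    N = len(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)]
        start += len(g)
        h += len(g) * (r.mean() - (N + 1) / 2.0) ** 2
    h *= 12.0 / (N * (N + 1))
    _, counts = np.unique(srt, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (N**3 - N)
    return h / tie
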