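"""Mean-shift changepoint detection for egg-laying series.

Penalized least-squares segmentation: minimize the sum over segments of
within-segment squared deviations from the segment mean, plus a penalty
per changepoint. ``exhaustive`` is the O(n^2) optimal-partitioning
dynamic program, ``pelt`` the same optimum with pruning, and ``binseg``
greedy binary segmentation. The default penalty is SIC-style:
sigma^2 * log(n) per changepoint, with sigma^2 estimated from first
differences (robust to the mean shifts being sought).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np


@dataclass
class ChangepointResult:
    breakpoints: list       # index of the last point of each segment, except the final one
    segment_means: list
    penalty_value: float
    method_label: str
    n: int = 0

    @property
    def segments(self) -> list:
        """(start, end) index pairs, end exclusive, partitioning the series."""
        bounds = [0] + [b + 1 for b in self.breakpoints] + [self.n]
        return list(zip(bounds[:-1], bounds[1:]))


def sic_penalty(series: np.ndarray) -> float:
    """SIC-style penalty: 2 log(n) scaled by a noise-variance estimate.

    Each changepoint introduces two free parameters (a new segment mean
    and the break location), hence the factor 2. sigma^2 is the Rice
    difference-based estimator sum(diff^2) / (2 (n-1)), largely
    insensitive to the piecewise-constant mean structure being sought.
    """
    y = np.asarray(series, dtype=float)
    n = len(y)
    sigma2 = float(np.sum(np.diff(y) ** 2) / (2.0 * (n - 1)))
    return 2.0 * max(sigma2, 1e-12) * np.log(n)


def _prefix_sums(y: np.ndarray):
    s1 = np.concatenate([[0.0], np.cumsum(y)])
    s2 = np.concatenate([[0.0], np.cumsum(y ** 2)])
    return s1, s2


def _seg_cost(s1, s2, i, j):
    """Within-segment SSE for y[i:j]."""
    n = j - i
    tot = s1[j] - s1[i]
    return (s2[j] - s2[i]) - tot * tot / n


def _optimal_partition(y: np.ndarray, penalty: float, min_seg_len: int,
                       prune: bool) -> list:
    """Optimal-partitioning dynamic program over segment ends.

    With ``prune`` this is PELT. Because segments have a minimum length,
    a dominated candidate is only discarded ``min_seg_len - 1`` steps
    after domination is observed, which preserves exact optimality (the
    standard domination argument needs a feasible path through the
    dominating end point).
    """
    n = len(y)
    s1, s2 = _prefix_sums(y)
    F = np.full(n + 1, np.inf)
    F[0] = -penalty
    last = np.zeros(n + 1, dtype=int)
    candidates = {0: None}  # start index -> step at which it may be dropped
    for t in range(min_seg_len, n + 1):
        s_new = t - min_seg_len
        if s_new not in candidates and np.isfinite(F[s_new]):
            candidates[s_new] = None
        if prune:
            for s in [s for s, drop in candidates.items()
                      if drop is not None and t >= drop]:
                del candidates[s]
        best, arg = np.inf, 0
        for s in candidates:
            if t - s < min_seg_len:
                continue
            val = F[s] + _seg_cost(s1, s2, s, t) + penalty
            if val < best:
                best, arg = val, s
        F[t] = best
        last[t] = arg
        if prune:
            for s in candidates:
                if (candidates[s] is None and t - s >= min_seg_len
                        and F[s] + _seg_cost(s1, s2, s, t) > F[t]):
                    candidates[s] = t + min_seg_len
    cps = []
    t = n
    while t > 0:
        s = last[t]
        if s > 0:
            cps.append(s)
        t = s
    return sorted(cps)


def _binseg(y: np.ndarray, penalty: float, min_seg_len: int) -> list:
    """Greedy binary segmentation: keep splitting while the best split
    reduces the cost by more than the penalty."""
    s1, s2 = _prefix_sums(y)
    segments = [(0, len(y))]
    cps = []
    improved = True
    while improved:
        improved = False
        best_gain, best_split, best_seg = penalty, None, None
        for seg in segments:
            i, j = seg
            base = _seg_cost(s1, s2, i, j)
            for s in range(i + min_seg_len, j - min_seg_len + 1):
                gain = base - _seg_cost(s1, s2, i, s) - _seg_cost(s1, s2, s, j)
                if gain > best_gain:
                    best_gain, best_split, best_seg = gain, s, seg
        if best_split is not None:
            i, j = best_seg
            segments.remove(best_seg)
            segments.extend([(i, best_split), (best_split, j)])
            cps.append(best_split)
            improved = True
    return sorted(cps)


def segment_mean(series: Sequence[float],
                 penalty: Union[float, str] = "sic",
                 method: str = "pelt",
                 min_seg_len: int = 2) -> ChangepointResult:
    """Segment a series into constant-mean pieces.

    Parameters
    ----------
    series : sequence of per-census egg counts.
    penalty : nonnegative cost per changepoint, or "sic" for the default.
    method : "exhaustive", "pelt" (both globally optimal) or "binseg".
    min_seg_len : minimum points per segment.
    """
    y = np.asarray(series, dtype=float)
    n = len(y)
    if min_seg_len < 1:
        raise ValueError("min_seg_len must be >= 1")
    if n < 2 * min_seg_len:
        raise ValueError(
            f"series of length {n} too short for two segments of {min_seg_len}")
    if penalty == "sic":
        pen = sic_penalty(y)
    else:
        pen = float(penalty)
        if pen < 0:
            raise ValueError("penalty must be nonnegative")
    if method in ("exhaustive", "pelt"):
        cps = _optimal_partition(y, pen, min_seg_len, prune=(method == "pelt"))
    elif method == "binseg":
        cps = _binseg(y, pen, min_seg_len)
    else:
        raise ValueError(f"unknown method {method!r}")
    bounds = [0] + cps + [n]
    means = [float(y[i:j].mean()) for i, j in zip(bounds[:-1], bounds[1:])]
    return ChangepointResult(
        breakpoints=[c - 1 for c in cps], segment_means=means,
        penalty_value=pen, method_label=method, n=n)


def segment_durations(result: ChangepointResult,
                      days: Sequence[int]) -> list:
    """Map index segments to (start_day, end_day, mean) spans."""
    days = np.asarray(days)
    if len(days) != result.n:
        raise ValueError("day axis length does not match the segmented series")
    return [
        (int(days[i]), int(days[j - 1]), result.segment_means[s])
        for s, (i, j) in enumerate(result.segments)
    ]
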