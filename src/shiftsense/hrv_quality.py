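"""Interbeat-interval signal quality.

A wrist photoplethysmogram loses beats during motion, so before any heart
rate variability analysis the interbeat-interval (IBI) record is profiled
with three quantities: the longest segment of valid data, the mean and
standard deviation of the gaps, and a per-20-second-window quality rating on
the same {−4, −2, 0, 2, 4} scale as the electrodermal bad-data value.

A beat at offset ``o`` with interval ``d`` covers ``[o − d, o]``.  "Valid"
means gap-free tiling: a gap opens wherever a beat's interval fails to reach
back to the previous beat by more than a tolerance (default 0.25 s), and at
the session edges.  Valid segments are the complementary spans, so segment
lengths plus gap lengths tile the session duration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["IbiQualityReport", "ibi_gap_stats", "ibi_window_quality"]

GAP_TOLERANCE = 0.25   # s of slack before a shortfall counts as a gap
GOOD_COVERAGE = 0.8    # beat-coverage fraction for a good 5-s interval


@dataclass
class IbiQualityReport:
    """Signal-quality summary for one session's interbeat intervals."""

    longest_valid_segment: float        # s
    gap_mean: float                     # s; NaN when no gaps
    gap_sd: float                       # s; NaN when no gaps
    gaps: list[tuple[float, float]]     # (start, end) seconds from start
    window_quality: np.ndarray | None = None  # per-20-s rating


def _gap_intervals(
    ibi: np.ndarray, session_duration: float, tolerance: float
) -> list[tuple[float, float]]:
    ibi = np.asarray(ibi, dtype=float).reshape(-1, 2)
    if len(ibi) == 0:
        return [(0.0, session_duration)]
    offsets, durations = ibi[:, 0], ibi[:, 1]
    if np.any(np.diff(offsets) <= 0):
        raise ValueError("IBI offsets must strictly increase")
    if np.any(durations <= 0):
        raise ValueError("IBI durations must be > 0")
    gaps: list[tuple[float, float]] = []
    lead = offsets[0] - durations[0]
    if lead > tolerance:
        gaps.append((0.0, lead))
    shortfall = offsets[1:] - durations[1:] - offsets[:-1]
    for i in np.nonzero(shortfall > tolerance)[0]:
        gaps.append((offsets[i], offsets[i + 1] - durations[i + 1]))
    if session_duration - offsets[-1] > tolerance:
        gaps.append((offsets[-1], session_duration))
    return gaps


def ibi_gap_stats(
    ibi: np.ndarray,
    session_duration: float,
    tolerance: float = GAP_TOLERANCE,
) -> IbiQualityReport:
    """Longest valid segment and gap statistics for an IBI record.

    Gap SD is the population standard deviation, so a single gap reports
    SD 0; with no gaps both statistics are NaN and the whole session is one
    valid segment.
    """
    gaps = _gap_intervals(ibi, session_duration, tolerance)
    # valid segments = complement of the gaps within [0, duration]
    edges = [0.0] + [t for g in gaps for t in g] + [session_duration]
    seg_lengths = [b - a for a, b in zip(edges[::2], edges[1::2])]
    longest = max(seg_lengths) if seg_lengths else 0.0
    if gaps:
        lengths = np.array([b - a for a, b in gaps])
        gap_mean, gap_sd = float(lengths.mean()), float(lengths.std(ddof=0))
    else:
        gap_mean = gap_sd = float("nan")
    return IbiQualityReport(
        longest_valid_segment=float(longest),
        gap_mean=gap_mean,
        gap_sd=gap_sd,
        gaps=gaps,
    )


def _coverage_cdf(ibi: np.ndarray, duration: float):
    """Cumulative beat-coverage function C(t) from the union of beat spans."""
    ibi = np.asarray(ibi, dtype=float).reshape(-1, 2)
    intervals = []
    for o, d in ibi:
        a, b = max(0.0, o - d), min(duration, o)
        if b > a:
            intervals.append((a, b))
    merged: list[list[float]] = []
    for a, b in sorted(intervals):
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    if not merged:
        return lambda t: np.zeros_like(np.asarray(t, dtype=float))
    starts = np.array([m[0] for m in merged])
    ends = np.array([m[1] for m in merged])
    cum = np.concatenate([[0.0], np.cumsum(ends - starts)])

    def cdf(t: float | np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        i = np.searchsorted(starts, t, side="right") - 1
        i = np.clip(i, -1, len(starts) - 1)
        inside = np.where(
            i >= 0, np.minimum(np.maximum(t - starts[i], 0.0), ends[i] - starts[i]), 0.0
        )
        return cum[np.maximum(i, 0)] * (i >= 0) + inside

    return cdf


def ibi_window_quality(
    ibi: np.ndarray,
    n_windows: int,
    coverage: float = GOOD_COVERAGE,
) -> np.ndarray:
    """Per-20-s-window quality rating in {−4, −2, 0, 2, 4}.

    Each window's four 5-second intervals are rated good (+1) when beats
    cover at least ``coverage`` of the interval, bad (−1) otherwise; the
    rating is their sum, mirroring the electrodermal bad-data scale.
    """
    duration = n_windows * 20.0
    cdf = _coverage_cdf(ibi, duration)
    edges = np.arange(n_windows * 4 + 1) * 5.0
    covered = np.diff(cdf(edges))
    flags = np.where(covered >= coverage * 5.0, 1, -1)
    return flags.reshape(n_windows, 4).sum(axis=1)
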