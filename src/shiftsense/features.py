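"""Windowed feature extraction: 19 metrics on nonoverlapping 20-s windows.

The derived dataset has one row per 20-second window and 19 columns:

* time (3): ``time_stamp``, ``elapsed_time``, ``elapsed_from_midnight``;
* event (1): ``event_code`` — the windowed mode of the 1 Hz dispatch-event
  assignment (see :mod:`shiftsense.fusion`);
* bad data (1): ``bad_data_value`` — the sum of the four ±1 quality flags
  (5-second intervals) spanned by the window, so values lie in
  {−4, −2, 0, 2, 4};
* activity (1): ``avg_activity_count`` — mean of the 1 Hz activity counts;
* skin temperature (1): ``avg_temp`` — mean of the 4 Hz temperature;
* electrodermal activity (12): level, level difference and z score against
  the preceding 20-minute history, 20-s and 120-s level slopes, RMS of the
  band-passed fluctuation signal with its difference and z score, and peak
  counts / mean peak heights at a high (0.15 µS) and a low (0.02 µS)
  threshold.

The electrodermal signal is decomposed into a 0–0.04 Hz *baseline* (tonic
level) by a 101-point third-order polynomial (Savitzky–Golay) filter and a
0.04–0.4 Hz *bandpass* (phasic fluctuation) signal by an 11-point
third-order polynomial filter applied to the baseline-removed residual.
Activity is the Euclidean norm of the three accelerometer axes, band-passed
to 0.1–7 Hz with a zero-phase (forward–backward) fifth-order Butterworth
filter, then summed as |activity| over 1-second epochs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, savgol_filter, sosfiltfilt

from .session_io import METRIC_COLUMNS, RawStream, SensorSession

logger = logging.getLogger(__name__)

__all__ = [
    "EdaDecomposition",
    "FeatureConfig",
    "decompose_eda",
    "acc_magnitude",
    "activity_signal",
    "activity_counts",
    "window_time_metrics",
    "eda_window_metrics",
    "detect_peaks",
    "peak_metrics",
    "quality_flags",
    "bad_data_values",
    "extract_metrics",
]

WINDOW_S = 20.0
EDA_RATE = 4.0
SAMPLES_PER_WINDOW = int(WINDOW_S * EDA_RATE)  # 80


@dataclass
class FeatureConfig:
    """Tunable extraction parameters (defaults are the pipeline's canon)."""

    window_s: float = 20.0
    baseline_window: int = 101      # samples; ~0.04 Hz cutoff at 4 Hz
    bandpass_window: int = 11       # samples; ~0.4 Hz cutoff at 4 Hz
    polyorder: int = 3
    activity_band: tuple[float, float] = (0.1, 7.0)  # Hz
    activity_order: int = 5
    history_windows: int = 60       # normalization population size
    history_lag: int = 1            # windows skipped before the population
    peak_high: float = 0.15         # µS
    peak_low: float = 0.02          # µS
    peak_separation: float = 1.0    # s
    tz_offset: float = 0.0          # seconds east of UTC, for local midnight
    # surrogate quality rule (the vendor's flag algorithm is proprietary)
    eda_range: tuple[float, float] = (0.01, 100.0)   # µS
    eda_max_jump: float = 5.0       # µS between consecutive samples
    temp_range: tuple[float, float] = (20.0, 45.0)   # °C


@dataclass
class EdaDecomposition:
    """Tonic/phasic split of the electrodermal signal.

    ``baseline`` is the 0–0.04 Hz level signal; ``bandpass`` the 0.04–0.4 Hz
    fluctuation signal.  Both have the length and rate of the input.
    """

    baseline: RawStream
    bandpass: RawStream


def decompose_eda(eda: RawStream, config: FeatureConfig | None = None) -> EdaDecomposition:
    """Split a 4 Hz electrodermal stream into baseline and bandpass signals.

    The baseline is a third-order Savitzky–Golay smooth over a 101-point
    window (cutoff ≈ 0.04 Hz); the bandpass signal is an 11-point third-order
    smooth (cutoff ≈ 0.4 Hz) of the baseline-removed residual.  Edges use
    reflect padding; third-order polynomial filters pass constants and ramps
    exactly away from the edges.
    """
    config = config or FeatureConfig()
    x = eda.values
    if x.ndim != 1:
        raise ValueError("EDA stream must be single-channel")
    if len(x) <= config.baseline_window:
        raise ValueError(
            f"EDA stream length {len(x)} not longer than the "
            f"{config.baseline_window}-point baseline filter"
        )
    baseline = savgol_filter(x, config.baseline_window, config.polyorder,
                             mode="mirror")
    residual = x - baseline
    bandpass = savgol_filter(residual, config.bandpass_window, config.polyorder,
                             mode="mirror")
    return EdaDecomposition(
        baseline=RawStream(eda.start_time, eda.sample_rate, baseline),
        bandpass=RawStream(eda.start_time, eda.sample_rate, bandpass),
    )


def acc_magnitude(acc: RawStream) -> RawStream:
    """Per-sample Euclidean norm sqrt(x² + y² + z²) of 3-axis acceleration."""
    if acc.n_channels != 3:
        raise ValueError(f"need 3 acceleration channels, got {acc.n_channels}")
    return RawStream(acc.start_time, acc.sample_rate,
                     np.sqrt(np.sum(acc.values**2, axis=1)))


def activity_signal(acc: RawStream, config: FeatureConfig | None = None) -> RawStream:
    """Single activity signal from 3-axis acceleration.

    Per-sample Euclidean norm sqrt(x² + y² + z²), then a zero-phase
    (forward–backward) band-pass 0.1–7 Hz Butterworth of design order 5
    (effective order 10, zero phase).  Gravity and posture (DC) are removed
    by the 0.1 Hz high-pass edge.
    """
    config = config or FeatureConfig()
    norm = acc_magnitude(acc).values
    sos = butter(config.activity_order, config.activity_band,
                 btype="bandpass", fs=acc.sample_rate, output="sos")
    filtered = sosfiltfilt(sos, norm)
    return RawStream(acc.start_time, acc.sample_rate, filtered)


def activity_counts(activity: RawStream) -> RawStream:
    """1 Hz activity counts: sum of |activity| over 1-second epochs."""
    rate = int(round(activity.sample_rate))
    n_epochs = activity.n_samples // rate
    x = np.abs(activity.values[: n_epochs * rate]).reshape(n_epochs, rate)
    return RawStream(activity.start_time, 1.0, x.sum(axis=1))


def window_time_metrics(
    session_start: float, n_windows: int, tz_offset: float = 0.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-window time stamp, elapsed time, and elapsed time from midnight.

    Window k starts at ``session_start + 20 k``; elapsed-from-midnight is the
    time stamp's offset from the most recent local midnight (``tz_offset``
    seconds east of UTC, default UTC).
    """
    k = np.arange(n_windows, dtype=float)
    time_stamp = session_start + WINDOW_S * k
    elapsed = WINDOW_S * k
    from_midnight = np.mod(time_stamp + tz_offset, 86400.0)
    return time_stamp, elapsed, from_midnight


def _window_view(x: np.ndarray, n_windows: int) -> np.ndarray:
    return x[: n_windows * SAMPLES_PER_WINDOW].reshape(
        n_windows, SAMPLES_PER_WINDOW
    )


def _history_norm(
    per_window: np.ndarray, history: int, lag: int
) -> tuple[np.ndarray, np.ndarray]:
    """Difference and z score of each window's value against the population
    of the ``history`` windows ending ``lag`` windows before it.

    For window k the population is windows k−history−lag … k−1−lag; windows
    without a full population get NaN, as does the z score when the
    population variance is zero.
    """
    n = len(per_window)
    diff = np.full(n, np.nan)
    z = np.full(n, np.nan)
    first = history + lag  # first window with a full population
    for k in range(first, n):
        pop = per_window[k - history - lag : k - lag]
        mu = pop.mean()
        sd = pop.std(ddof=1)
        diff[k] = per_window[k] - mu
        if sd > 0:
            z[k] = (per_window[k] - mu) / sd
    return diff, z


def eda_window_metrics(
    decomp: EdaDecomposition,
    n_windows: int,
    config: FeatureConfig | None = None,
) -> dict[str, np.ndarray]:
    """The eight level/slope/RMS electrodermal metrics per window.

    Normalized metrics (difference and z score) compare each window with the
    sixty windows spanning 20 min 20 s to 20 s before it, so the first 61
    windows have no full history and report missing values.  The 120-s slope
    is fit over ±60 s around the window midpoint, truncated at the session
    edges, and reported missing below 50% coverage.
    """
    config = config or FeatureConfig()
    baseline = decomp.baseline.values
    bandpass = decomp.bandpass.values
    if n_windows * SAMPLES_PER_WINDOW > len(baseline):
        raise ValueError("window grid extends past the decomposition")
    bw = _window_view(baseline, n_windows)
    pw = _window_view(bandpass, n_windows)

    avg_level = bw.mean(axis=1)
    rms = np.sqrt((pw**2).mean(axis=1))

    level_diff, level_z = _history_norm(avg_level, config.history_windows,
                                        config.history_lag)
    rms_diff, rms_z = _history_norm(rms, config.history_windows,
                                    config.history_lag)

    # 20-s slope: least-squares line over the window's 80 samples
    t_win = np.arange(SAMPLES_PER_WINDOW) / EDA_RATE
    tc = t_win - t_win.mean()
    denom = (tc**2).sum()
    slope20 = (bw * tc).sum(axis=1) / denom

    # 120-s slope: line over ±60 s around the window midpoint
    slope120 = np.full(n_windows, np.nan)
    half = int(60 * EDA_RATE)
    span = 2 * half
    for k in range(n_windows):
        mid = k * SAMPLES_PER_WINDOW + SAMPLES_PER_WINDOW // 2
        i0, i1 = max(0, mid - half), min(len(baseline), mid + half)
        if i1 - i0 < span // 2:  # below 50% coverage
            continue
        t = np.arange(i0, i1) / EDA_RATE
        tcc = t - t.mean()
        slope120[k] = (baseline[i0:i1] * tcc).sum() / (tcc**2).sum()

    return {
        "avg_eda_level": avg_level,
        "avg_eda_level_diff": level_diff,
        "avg_eda_level_z": level_z,
        "eda_slope_20s": slope20,
        "eda_slope_120s": slope120,
        "rms_eda": rms,
        "rms_eda_diff": rms_diff,
        "rms_eda_z": rms_z,
    }


def detect_peaks(
    segment: np.ndarray,
    height_threshold: float,
    min_separation: float = 1.0,
    rate_hz: float = EDA_RATE,
) -> tuple[np.ndarray, np.ndarray]:
    """Peaks in a signal segment: local maxima with height ≥ threshold,
    separated by at least ``min_separation`` seconds.

    Height is the signal value at the maximum.  Among maxima closer than the
    separation, the larger is kept (ties: the earlier).  Returns (times in
    seconds from segment start, heights).
    """
    x = np.asarray(segment, dtype=float)
    n = len(x)
    if n < 3:
        return np.empty(0), np.empty(0)
    interior = np.nonzero(
        (x[1:-1] >= x[:-2]) & (x[1:-1] > x[2:]) & (x[1:-1] >= height_threshold)
    )[0] + 1
    # plateau rule: >= on the left, > on the right keeps the first sample of
    # a flat top and rejects the rest
    min_sep = min_separation * rate_hz
    order = sorted(interior, key=lambda i: (-x[i], i))
    kept: list[int] = []
    for i in order:
        if all(abs(i - j) >= min_sep for j in kept):
            kept.append(i)
    kept.sort()
    idx = np.asarray(kept, dtype=int)
    return idx / rate_hz, x[idx]


def peak_metrics(
    decomp: EdaDecomposition,
    n_windows: int,
    config: FeatureConfig | None = None,
) -> dict[str, np.ndarray]:
    """Peak counts and mean peak heights per window, at both thresholds.

    A window with no retained peaks reports count 0 and a missing mean
    height (the mean of an empty set is undefined, not zero).
    """
    config = config or FeatureConfig()
    pw = _window_view(decomp.bandpass.values, n_windows)
    out = {
        "n_peaks_high": np.zeros(n_windows),
        "avg_peak_height_high": np.full(n_windows, np.nan),
        "n_peaks_low": np.zeros(n_windows),
        "avg_peak_height_low": np.full(n_windows, np.nan),
    }
    for k in range(n_windows):
        for name, thr in (("high", config.peak_high), ("low", config.peak_low)):
            _, heights = detect_peaks(pw[k], thr, config.peak_separation)
            out[f"n_peaks_{name}"][k] = len(heights)
            if len(heights):
                out[f"avg_peak_height_{name}"][k] = heights.mean()
    return out


def quality_flags(
    session: SensorSession, config: FeatureConfig | None = None
) -> np.ndarray:
    """±1 quality flag per 5-second interval (a surrogate for the vendor's
    proprietary rating, and pluggable via :class:`FeatureConfig`).

    An interval is bad (−1) when the electrodermal signal leaves
    ``eda_range``, shows a one-sample jump above ``eda_max_jump``, or skin
    temperature leaves ``temp_range``; good (+1) otherwise.
    """
    config = config or FeatureConfig()
    eda = session.eda.values
    temp = session.temp.values
    n_flags = int(math.ceil(session.eda.duration / 5.0))
    per = int(5 * EDA_RATE)  # 20 samples per interval
    flags = np.ones(n_flags, dtype=int)
    jumps = np.abs(np.diff(eda, prepend=eda[:1]))
    lo, hi = config.eda_range
    tlo, thi = config.temp_range
    for i in range(n_flags):
        s = slice(i * per, (i + 1) * per)
        e, tp, j = eda[s], temp[s], jumps[s]
        if (
            np.any(e < lo) or np.any(e > hi)
            or np.any(j > config.eda_max_jump)
            or np.any(tp < tlo) or np.any(tp > thi)
        ):
            flags[i] = -1
    return flags


def bad_data_values(flags: np.ndarray, n_windows: int) -> np.ndarray:
    """Per-window bad-data value: the sum of the four 5-s flags the window
    spans, so 4 = all good, 2 = one bad, 0 = two bad, −2 = three bad,
    −4 = all bad."""
    if n_windows * 4 > len(flags):
        raise ValueError("flag stream does not cover the window grid")
    return flags[: n_windows * 4].reshape(n_windows, 4).sum(axis=1)


def extract_metrics(
    session: SensorSession,
    event_values: np.ndarray | None = None,
    config: FeatureConfig | None = None,
) -> pd.DataFrame:
    """Assemble the full 19-metric window table for one session.

    ``event_values`` is the 1 Hz dispatch-event assignment stream (see
    :func:`shiftsense.fusion.event_assignment_timeline`); when omitted every
    window's event code is 0 (unallocated).
    """
    from .fusion import window_event_code

    config = config or FeatureConfig()
    durations = {
        name: getattr(session, name).duration
        for name in ("eda", "temp", "acc", "bvp")
    }
    n_windows = int(min(durations.values()) // WINDOW_S)
    if max(durations.values()) - min(durations.values()) > WINDOW_S:
        logger.warning(
            "channel spans differ by more than one window: %s", durations
        )
    time_stamp, elapsed, from_midnight = window_time_metrics(
        session.start_time, n_windows, config.tz_offset
    )
    if event_values is None:
        event_values = np.zeros(int(n_windows * WINDOW_S))
    event_code = window_event_code(event_values, n_windows)

    flags = quality_flags(session, config)
    bad = bad_data_values(flags, n_windows)

    counts = activity_counts(activity_signal(session.acc, config))
    n_sec = int(n_windows * WINDOW_S)
    avg_activity = counts.values[:n_sec].reshape(n_windows, 20).mean(axis=1)

    temp_w = _window_view(session.temp.values, n_windows)
    avg_temp = temp_w.mean(axis=1)

    decomp = decompose_eda(session.eda, config)
    eda_metrics = eda_window_metrics(decomp, n_windows, config)
    peaks = peak_metrics(decomp, n_windows, config)

    table = pd.DataFrame(
        {
            "time_stamp": time_stamp,
            "elapsed_time": elapsed,
            "elapsed_from_midnight": from_midnight,
            "event_code": event_code,
            "bad_data_value": bad.astype(float),
            "avg_activity_count": avg_activity,
            "avg_temp": avg_temp,
            **eda_metrics,
            **{k: peaks[k] for k in ("n_peaks_high", "avg_peak_height_high",
                                     "n_peaks_low", "avg_peak_height_low")},
        }
    )
    return table[METRIC_COLUMNS]
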