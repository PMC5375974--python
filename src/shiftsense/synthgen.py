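"""Synthetic officer-shift generator.

Produces, from one seeded configuration, everything a real shift would yield:
wrist-sensor streams (electrodermal activity, skin temperature, 3-axis
acceleration, blood volume pulse, interbeat intervals), a matching dispatch
(CAD) log, and a vehicle-location (AVL) track — plus the ground-truth event
schedules (injected skin-conductance responses, interbeat gaps, movement
spans) that downstream stages are tested against.

The electrodermal signal is modeled as a slowly drifting tonic level plus a
train of skin-conductance responses (SCRs) and Gaussian sensor noise.  Each
SCR is a bi-exponential kernel, normalized to unit peak,

    k(t) = (exp(-t/decay) - exp(-t/rise)) / k_max ,   t >= 0,

the minimal standard shape with a fast rise and slow recovery.  SCR events
arrive as an inhomogeneous Poisson process whose rate is set per stress
level: a background rate off-call and elevated rates while the officer is
working a low- or high-stress call.  Conductance is clipped at 0.001 µS
because skin conductance is positive.

Interbeat intervals come from a stress-modulated heart period; contiguous
spans of beats are then deleted to create the signal gaps a wrist
photoplethysmogram shows during motion, and the realized gap schedule is
logged as truth.

Vehicle pings follow the speed-dependent cadence of real AVL feeds: a fast
interval while en route to a call, a slow one while stationary.  Coordinates
are planar meters from an arbitrary origin — location is only used for
linkage, so no geodesy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .session_io import AvlTrack, CadCall, CadEventLog, RawStream, SensorSession

__all__ = [
    "CallSpec",
    "SynthConfig",
    "ShiftTruth",
    "SyntheticShift",
    "synth_scr_train",
    "synth_session",
    "synth_cad_log",
    "synth_avl_track",
    "simulate_shift",
    "default_calls",
]

STRESS_LEVELS = ("low", "high")

# seconds a canceled call is treated as pending after dispatch
CANCELED_HOLD = 300.0


@dataclass(frozen=True)
class CallSpec:
    """One planned call for the synthetic shift.

    Lifecycle timestamps are UNIX seconds and must be nondecreasing in order
    received → dispatched → arrive1 → arrive2 → transport → cleared.  A
    canceled call has only received and dispatched times.
    """

    call_type: str
    priority: int
    stress_level: str
    received: float
    dispatched: float
    arrive1: float | None = None
    arrive2: float | None = None
    transport: float | None = None
    cleared: float | None = None
    canceled: bool = False

    def __post_init__(self) -> None:
        if self.stress_level not in STRESS_LEVELS:
            raise ValueError(f"stress_level must be one of {STRESS_LEVELS}")
        times = [t for t in (self.received, self.dispatched, self.arrive1,
                             self.arrive2, self.transport, self.cleared)
                 if t is not None]
        if sorted(times) != times:
            raise ValueError("call lifecycle timestamps out of order")
        if self.canceled and any(
            t is not None for t in (self.arrive1, self.arrive2,
                                    self.transport, self.cleared)
        ):
            raise ValueError("canceled calls have no arrive/transport/cleared times")
        if not self.canceled and self.cleared is None:
            raise ValueError("non-canceled calls need a cleared time")

    @property
    def start(self) -> float:
        return self.received

    @property
    def end(self) -> float:
        """End of the call's active span (cancellation hold for canceled)."""
        return self.cleared if self.cleared is not None else \
            self.dispatched + CANCELED_HOLD


@dataclass
class SynthConfig:
    """Study conditions for one synthetic 12-hour shift.

    Rates are events/minute (`scr_rate_by_stress`, keyed by ``none`` for
    off-call time plus the per-call stress levels), bouts/hour
    (`activity_bout_rate`) and gaps/hour (`ibi_gap_rate`).
    """

    seed: int
    shift_start: float = 1_700_000_000.0
    shift_hours: float = 12.0
    calls: list[CallSpec] = field(default_factory=list)
    officer_id: str = "officer-1"
    # electrodermal activity
    tonic_level: float = 1.0            # µS
    tonic_drift: float = 0.05           # µS/hour
    noise_sd: float = 0.01              # µS
    scr_rise: float = 0.75              # s
    scr_decay: float = 4.0              # s
    scr_rate_by_stress: dict[str, float] = field(
        default_factory=lambda: {"none": 0.5, "low": 1.0, "high": 5.0}
    )
    scr_amp_range: tuple[float, float] = (0.2, 0.8)  # µS
    scr_min_separation: float = 2.0     # s between injected events
    # skin temperature
    temp_base: float = 33.0             # °C
    temp_noise_sd: float = 0.02         # °C
    # acceleration
    activity_bout_rate: float = 4.0     # bouts/hour
    activity_bout_duration: float = 60.0  # s
    acc_noise_sd: float = 0.01          # g
    # interbeat intervals
    ibi_base_period: float = 0.85       # s; ~70 bpm at rest
    ibi_stress_drop: float = 0.12       # s shorter during high-stress calls
    ibi_jitter_sd: float = 0.02         # s beat-to-beat variability
    ibi_gap_rate: float = 2.0           # gaps/hour
    ibi_gap_range: tuple[float, float] = (10.0, 60.0)  # s
    # vehicle locator
    avl_ping_fast: float = 5.0          # s while moving
    avl_ping_slow: float = 30.0         # s while stationary

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.shift_hours <= 0:
            raise ValueError("shift_hours must be > 0")
        if not (self.scr_decay > self.scr_rise > 0):
            raise ValueError("need scr_decay > scr_rise > 0")
        if self.avl_ping_fast > self.avl_ping_slow:
            raise ValueError("avl_ping_fast must be <= avl_ping_slow")
        rates = list(self.scr_rate_by_stress.values()) + [
            self.activity_bout_rate, self.ibi_gap_rate]
        if any(r < 0 for r in rates):
            raise ValueError("all rates must be >= 0")
        if self.noise_sd < 0 or self.temp_noise_sd < 0 or self.acc_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        end = self.shift_start + self.shift_hours * 3600.0
        for c in self.calls:
            if c.received < self.shift_start or c.end > end:
                raise ValueError(
                    f"call span [{c.received}, {c.end}] outside shift "
                    f"[{self.shift_start}, {end}]"
                )

    @property
    def duration(self) -> float:
        return self.shift_hours * 3600.0

    # -- config file round trip ------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        def plain(v):
            if isinstance(v, dict):
                return {k: plain(x) for k, x in v.items()}
            if isinstance(v, (list, tuple)):
                return [plain(x) for x in v]
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            return v

        d = plain(asdict(self))
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SynthConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["calls"] = [CallSpec(**c) for c in d.get("calls", [])]
        for key in ("scr_amp_range", "ibi_gap_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class ShiftTruth:
    """Ground-truth schedules retained from generation (seconds from start)."""

    scr_times: np.ndarray          # injected SCR event times
    scr_amps: np.ndarray           # their amplitudes, µS
    ibi_gaps: list[tuple[float, float]]   # realized measurable beat gaps
    movement_spans: list[tuple[float, float]]  # en-route spans
    stress_spans: list[tuple[float, float, str]]  # active call spans


@dataclass
class SyntheticShift:
    """One complete synthetic officer-shift with its generation truth."""

    config: SynthConfig
    session: SensorSession
    cad: CadEventLog
    avl: AvlTrack
    truth: ShiftTruth


# ---------------------------------------------------------------------------
# SCR kernel / train
# ---------------------------------------------------------------------------


def _kernel_peak(rise: float, decay: float) -> float:
    """Maximum of exp(-t/decay) - exp(-t/rise) over t >= 0."""
    tp = math.log(decay / rise) * rise * decay / (decay - rise)
    return math.exp(-tp / decay) - math.exp(-tp / rise)


def synth_scr_train(
    event_times: Sequence[float],
    rise: float,
    decay: float,
    amplitudes: Sequence[float],
    rate_hz: float,
    duration: float,
) -> np.ndarray:
    """Phasic conductance: a sum of unit-peak bi-exponential SCR kernels.

    Each event at time ``t0`` contributes
    ``amp * (exp(-(t-t0)/decay) - exp(-(t-t0)/rise)) / k_max`` for
    ``t >= t0`` so the kernel's peak equals ``amp`` exactly.  The stream
    covers ``[0, duration)`` at ``rate_hz`` and is zero before the first
    event.
    """
    if not (decay > rise > 0):
        raise ValueError("need decay > rise > 0")
    event_times = np.asarray(event_times, dtype=float)
    amplitudes = np.asarray(amplitudes, dtype=float)
    if event_times.shape != amplitudes.shape:
        raise ValueError("event_times and amplitudes must have equal length")
    if np.any(amplitudes < 0):
        raise ValueError("SCR amplitudes must be >= 0")
    if len(event_times) and (
        event_times.min() < 0 or event_times.max() > duration
    ):
        raise ValueError("SCR events must lie within [0, duration]")
    n = int(round(duration * rate_hz))
    out = np.zeros(n)
    if not len(event_times):
        return out
    peak = _kernel_peak(rise, decay)
    support = int(math.ceil(12.0 * decay * rate_hz))  # kernel ~0 beyond this
    tau = np.arange(support + 1) / rate_hz
    kernel = (np.exp(-tau / decay) - np.exp(-tau / rise)) / peak
    for t0, amp in zip(event_times, amplitudes):
        i0 = int(math.ceil(t0 * rate_hz))
        i1 = min(n, i0 + support + 1)
        if i1 <= i0:
            continue
        off = i0 / rate_hz - t0  # sub-sample offset of the first sample
        if off == 0.0:
            seg = kernel[: i1 - i0]
        else:
            tt = np.arange(i1 - i0) / rate_hz + off
            seg = (np.exp(-tt / decay) - np.exp(-tt / rise)) / peak
        out[i0:i1] += amp * seg
    return out


# ---------------------------------------------------------------------------
# Event schedules
# ---------------------------------------------------------------------------


def _stress_spans(config: SynthConfig) -> list[tuple[float, float, str]]:
    """Active call spans (seconds from shift start) with their stress level."""
    spans = []
    for c in config.calls:
        t0 = c.dispatched - config.shift_start
        t1 = c.end - config.shift_start
        spans.append((t0, t1, c.stress_level))
    return sorted(spans)


def _piecewise_rate_segments(
    config: SynthConfig,
) -> list[tuple[float, float, float]]:
    """(start, end, rate in events/s) segments tiling [0, duration)."""
    base = config.scr_rate_by_stress.get("none", 0.0) / 60.0
    edges = [0.0, config.duration]
    spans = _stress_spans(config)
    for t0, t1, _ in spans:
        edges += [t0, t1]
    edges = sorted(set(np.clip(edges, 0.0, config.duration)))
    segments = []
    for a, b in zip(edges[:-1], edges[1:]):
        rate = base
        mid = 0.5 * (a + b)
        for t0, t1, level in spans:
            if t0 <= mid < t1:
                rate = config.scr_rate_by_stress.get(level, 0.0) / 60.0
                break
        segments.append((a, b, rate))
    return segments


def _draw_scr_events(
    config: SynthConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    times: list[float] = []
    for a, b, rate in _piecewise_rate_segments(config):
        if rate <= 0:
            continue
        count = rng.poisson(rate * (b - a))
        times.extend(rng.uniform(a, b, size=count))
    times = np.sort(np.asarray(times))
    # enforce a refractory separation so every injected event is resolvable
    kept: list[float] = []
    for t in times:
        if not kept or t - kept[-1] >= config.scr_min_separation:
            kept.append(t)
    times = np.asarray(kept)
    amps = rng.uniform(*config.scr_amp_range, size=len(times))
    return times, amps


# ---------------------------------------------------------------------------
# Channel generators (each on its own deterministic child seed)
# ---------------------------------------------------------------------------


def _rng(config: SynthConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _gen_eda(config: SynthConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    rng = _rng(config, 1)
    n = int(round(config.duration * 4.0))
    t = np.arange(n) / 4.0
    tonic = config.tonic_level + config.tonic_drift * t / 3600.0
    scr_times, scr_amps = _draw_scr_events(config, rng)
    phasic = synth_scr_train(
        scr_times, config.scr_rise, config.scr_decay, scr_amps, 4.0,
        config.duration,
    )
    noise = rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd else 0.0
    eda = np.maximum(tonic + phasic + noise, 0.001)
    return eda, scr_times, scr_amps


def _gen_temp(config: SynthConfig) -> np.ndarray:
    rng = _rng(config, 2)
    n = int(round(config.duration * 4.0))
    t = np.arange(n) / 4.0
    slow = 0.4 * np.sin(2 * np.pi * t / 7200.0)  # gentle thermoregulation swing
    noise = rng.normal(0.0, config.temp_noise_sd, size=n) if config.temp_noise_sd else 0.0
    return config.temp_base + slow + noise


def _gen_acc(
    config: SynthConfig, movement_spans: list[tuple[float, float]]
) -> np.ndarray:
    rng = _rng(config, 3)
    n = int(round(config.duration * 32.0))
    t = np.arange(n) / 32.0
    acc = np.zeros((n, 3))
    acc[:, 2] = 1.0  # gravity on z at rest
    if config.acc_noise_sd:
        acc += rng.normal(0.0, config.acc_noise_sd, size=(n, 3))
    # spontaneous wrist-movement bouts
    n_bouts = rng.poisson(config.activity_bout_rate * config.shift_hours)
    starts = np.sort(rng.uniform(0.0, config.duration, size=n_bouts))
    for start in starts:
        dur = rng.uniform(0.5, 1.5) * config.activity_bout_duration
        i0, i1 = int(start * 32), min(n, int((start + dur) * 32))
        if i1 <= i0:
            continue
        freq = rng.uniform(1.0, 3.0)
        amp = rng.uniform(0.2, 0.6)
        phase = rng.uniform(0, 2 * np.pi, size=3)
        seg_t = t[i0:i1]
        for ax in range(3):
            acc[i0:i1, ax] += amp * np.sin(2 * np.pi * freq * seg_t + phase[ax])
    # low-level vehicle vibration while en route
    for a, b in movement_spans:
        i0, i1 = int(a * 32), min(n, int(b * 32))
        if i1 > i0:
            acc[i0:i1] += rng.normal(0.0, 0.05, size=(i1 - i0, 3))
    return acc


def _gen_bvp(config: SynthConfig) -> np.ndarray:
    rng = _rng(config, 4)
    n = int(round(config.duration * 64.0))
    t = np.arange(n) / 64.0
    hr = 1.0 / config.ibi_base_period  # Hz
    phase = 2 * np.pi * hr * t
    wave = 40.0 * np.sin(phase) + 12.0 * np.sin(2 * phase + 0.8)
    return wave + rng.normal(0.0, 2.0, size=n)


def _gen_ibi(
    config: SynthConfig,
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    rng = _rng(config, 5)
    spans = [(a, b) for a, b, lvl in _stress_spans(config) if lvl == "high"]
    beats = []
    t = config.ibi_base_period
    while t < config.duration:
        period = config.ibi_base_period
        if any(a <= t < b for a, b in spans):
            period -= config.ibi_stress_drop
        period = max(0.3, period + rng.normal(0.0, config.ibi_jitter_sd))
        beats.append((t, period))
        t += period
    offsets = np.array([b[0] for b in beats])
    # durations reported per beat are the interval that *ended* at the beat
    durations = np.empty(len(beats))
    durations[0] = config.ibi_base_period
    durations[1:] = np.diff(offsets)
    # delete contiguous spans to create gaps
    n_gaps = rng.poisson(config.ibi_gap_rate * config.shift_hours)
    gap_starts = np.sort(rng.uniform(0.0, config.duration, size=n_gaps))
    keep = np.ones(len(offsets), dtype=bool)
    for g0 in gap_starts:
        g1 = g0 + rng.uniform(*config.ibi_gap_range)
        keep &= ~((offsets >= g0) & (offsets < g1))
    offsets, durations = offsets[keep], durations[keep]
    # realized measurable gaps: where a surviving beat's interval does not
    # reach back to the previous surviving beat
    gaps: list[tuple[float, float]] = []
    tol = 0.25
    if len(offsets):
        if offsets[0] - durations[0] > tol:
            gaps.append((0.0, offsets[0] - durations[0]))
        lag = offsets[1:] - durations[1:] - offsets[:-1]
        for i in np.nonzero(lag > tol)[0]:
            gaps.append((offsets[i], offsets[i + 1] - durations[i + 1]))
        if config.duration - offsets[-1] > tol:
            gaps.append((offsets[-1], config.duration))
    else:
        gaps.append((0.0, config.duration))
    ibi = np.column_stack([offsets, durations])
    return ibi, gaps


# ---------------------------------------------------------------------------
# Public generators
# ---------------------------------------------------------------------------


def _movement_spans(config: SynthConfig) -> list[tuple[float, float]]:
    spans = []
    for c in config.calls:
        if c.canceled or c.arrive1 is None:
            continue
        spans.append((c.dispatched - config.shift_start,
                      c.arrive1 - config.shift_start))
    return sorted(spans)


def synth_session(
    config: SynthConfig, return_truth: bool = False
) -> SensorSession | tuple[SensorSession, ShiftTruth]:
    """Generate the wrist-sensor streams for one shift.

    Streams come out at exactly 4 Hz (EDA, temperature), 32 Hz (acceleration)
    and 64 Hz (blood volume pulse), covering ``[start, start + duration)``;
    interbeat intervals are irregular with deleted gap spans.  Deterministic
    for a fixed config (including seed).  With ``return_truth=True`` the
    injected event schedules are returned alongside the session.
    """
    config.validate()
    eda, scr_times, scr_amps = _gen_eda(config)
    movement = _movement_spans(config)
    ibi, gaps = _gen_ibi(config)
    session = SensorSession(
        eda=RawStream(config.shift_start, 4.0, eda),
        temp=RawStream(config.shift_start, 4.0, _gen_temp(config)),
        acc=RawStream(config.shift_start, 32.0, _gen_acc(config, movement)),
        bvp=RawStream(config.shift_start, 64.0, _gen_bvp(config)),
        ibi=ibi,
    )
    if not return_truth:
        return session
    truth = ShiftTruth(
        scr_times=scr_times,
        scr_amps=scr_amps,
        ibi_gaps=gaps,
        movement_spans=movement,
        stress_spans=_stress_spans(config),
    )
    return session, truth


def synth_cad_log(config: SynthConfig) -> CadEventLog:
    """Materialize the config's call specs as a dispatch log.

    Overlapping active spans for the one officer are rejected.
    """
    config.validate()
    spans = sorted((c.dispatched, c.end, c) for c in config.calls)
    for (a0, a1, ca), (b0, b1, cb) in zip(spans[:-1], spans[1:]):
        if b0 < a1:
            raise ValueError(
                f"overlapping calls for officer {config.officer_id}: "
                f"[{a0},{a1}] and [{b0},{b1}]"
            )
    calls = [
        CadCall(
            officer_id=config.officer_id,
            call_id=f"C{i + 1:03d}",
            call_type=c.call_type,
            priority=c.priority,
            received=c.received,
            dispatched=c.dispatched,
            arrive1=c.arrive1,
            arrive2=c.arrive2,
            transport=c.transport,
            cleared=c.cleared,
            canceled=c.canceled,
        )
        for i, c in enumerate(sorted(config.calls, key=lambda c: c.received))
    ]
    return CadEventLog(calls)


def synth_avl_track(config: SynthConfig, cad: CadEventLog) -> AvlTrack:
    """Generate vehicle pings at a speed-dependent cadence.

    The vehicle sits at a precinct origin, drives to each call's scene over
    the dispatch→arrive-1 span (pings every ``avl_ping_fast`` s), and is
    otherwise stationary (pings every ``avl_ping_slow`` s).  Each ping
    carries time, planar xy, speed, status, call id and officer id.
    """
    import pandas as pd

    config.validate()
    rng = _rng(config, 6)
    duration = config.duration
    # one scene location per call, reproducible from the config seed
    scenes = {c.call_id: rng.uniform(-2500.0, 2500.0, size=2) for c in cad}
    legs = []  # (t0, t1, from_xy, to_xy, call_id)
    pos = np.zeros(2)
    for c in sorted(cad, key=lambda c: c.dispatched):
        if c.canceled or c.arrive1 is None:
            continue
        t0 = c.dispatched - config.shift_start
        t1 = c.arrive1 - config.shift_start
        legs.append((t0, t1, pos.copy(), scenes[c.call_id], c.call_id))
        pos = scenes[c.call_id]

    def locate(t: float) -> tuple[np.ndarray, float, str, str]:
        here = np.zeros(2)
        for t0, t1, a, b, cid in legs:
            if t < t0:
                break
            if t0 <= t <= t1:
                frac = (t - t0) / (t1 - t0) if t1 > t0 else 1.0
                xy = a + frac * (b - a)
                speed = float(np.linalg.norm(b - a) / (t1 - t0)) if t1 > t0 else 0.0
                return xy, speed, "enroute", cid
            here = b
        # stationary: on scene if inside a call's active span, else idle
        now = config.shift_start + t
        for c in cad:
            if c.canceled or c.cleared is None or c.arrive1 is None:
                continue
            if c.arrive1 <= now <= c.cleared:
                return here, 0.0, "onscene", c.call_id
        return here, 0.0, "idle", ""

    moving = _movement_spans(config)
    rows = []
    t = 0.0
    while t <= duration:
        xy, speed, status, cid = locate(t)
        jitter = rng.normal(0.0, 2.0, size=2)  # GPS scatter, meters
        rows.append(
            {
                "time": config.shift_start + t,
                "x": xy[0] + jitter[0],
                "y": xy[1] + jitter[1],
                "speed": speed,
                "heading": float(rng.uniform(0, 360)),
                "status": status,
                "call_id": cid,
                "officer_id": config.officer_id,
            }
        )
        in_motion = any(a <= t < b for a, b in moving)
        t += config.avl_ping_fast if in_motion else config.avl_ping_slow
    return AvlTrack(pd.DataFrame(rows))


def simulate_shift(config: SynthConfig) -> SyntheticShift:
    """Generate the complete shift: session, CAD log, AVL track and truth."""
    session, truth = synth_session(config, return_truth=True)
    cad = synth_cad_log(config)
    avl = synth_avl_track(config, cad)
    return SyntheticShift(config=config, session=session, cad=cad, avl=avl,
                          truth=truth)


def default_calls(
    seed: int,
    shift_start: float,
    shift_hours: float = 12.0,
    n_calls: int = 6,
    include_canceled: bool = False,
) -> list[CallSpec]:
    """A realistic deterministic call schedule: calls spread over the shift,
    alternating low/high stress, ~25–35 min on scene, occasional transport."""
    rng = np.random.default_rng([seed, 99])
    duration = shift_hours * 3600.0
    slot = duration / (n_calls + 1)
    # shrink call durations on short shifts so every call fits its slot
    scale = min(1.0, slot / 4500.0)
    calls = []
    for i in range(n_calls):
        received = shift_start + slot * (i + 1) + rng.uniform(-0.1, 0.1) * slot
        dispatched = received + scale * rng.uniform(30, 90)
        stress = "high" if i % 2 == 1 else "low"
        if include_canceled and i == n_calls - 1:
            calls.append(
                CallSpec("check-area", 3, "low", received, dispatched,
                         canceled=True)
            )
            continue
        arrive1 = dispatched + scale * rng.uniform(240, 420)
        on_scene = scale * rng.uniform(1500, 2100)
        transport = None
        arrive2 = None
        if stress == "high" and rng.uniform() < 0.5:
            transport = arrive1 + on_scene
            cleared = transport + scale * rng.uniform(600, 900)
        else:
            cleared = arrive1 + on_scene
        call_type = "domestic-dispute" if stress == "high" else "property-check"
        priority = 1 if stress == "high" else 3
        calls.append(
            CallSpec(call_type, priority, stress, received, dispatched,
                     arrive1=arrive1, arrive2=arrive2, transport=transport,
                     cleared=cleared)
        )
    return calls
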