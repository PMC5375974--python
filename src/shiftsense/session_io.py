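"""Readers and writers for the three shift data sources.

A shift is described by three artifacts, all plain CSV:

* a *sensor session directory* in the wrist-device export dialect — one file
  per channel, where row 1 is the session start time (UNIX seconds), row 2 is
  the sample rate in Hz, and every following row is one sample (three
  comma-separated values per row for the 3-axis accelerometer).  The
  interbeat-interval file instead has the start time on row 1 followed by
  ``offset,duration`` rows in seconds.
* a *computer-aided dispatch (CAD) log* — one row per call with lifecycle
  timestamps (received, dispatched, arrive-1, arrive-2, transport, cleared).
* an *automated vehicle locator (AVL) track* — one row per GPS ping.

All readers validate invariants and refuse to silently coerce malformed
input; each failure mode raises a distinct exception type.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "RawStream",
    "SensorSession",
    "CadCall",
    "CadEventLog",
    "AvlTrack",
    "SessionIOError",
    "MissingChannelError",
    "MalformedHeaderError",
    "SampleValueError",
    "read_e4_session",
    "write_e4_session",
    "read_cad_log",
    "write_cad_log",
    "read_avl_track",
    "write_avl_track",
    "read_window_table",
    "write_window_table",
    "METRIC_COLUMNS",
    "EDA_COLUMNS",
    "FUSED_COLUMNS",
]


class SessionIOError(ValueError):
    """Base class for session file-format problems."""


class MissingChannelError(SessionIOError):
    """A required per-channel CSV file is absent from the session directory."""


class MalformedHeaderError(SessionIOError):
    """The start-time / sample-rate header rows could not be parsed."""


class SampleValueError(SessionIOError):
    """A sample row is non-numeric or has the wrong channel count."""


# ---------------------------------------------------------------------------
# In-memory containers
# ---------------------------------------------------------------------------


@dataclass
class RawStream:
    """A uniformly sampled sensor stream.

    Parameters
    ----------
    start_time : float
        Session start in UNIX seconds.
    sample_rate : float
        Sampling rate in Hz (> 0).
    values : ndarray
        Shape ``(n,)`` for single-channel streams or ``(n, 3)`` for the
        accelerometer.  All values must be finite.
    """

    start_time: float
    sample_rate: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be > 0, got {self.sample_rate}")
        if self.values.ndim not in (1, 2):
            raise SampleValueError(
                f"stream values must be 1-D or 2-D, got ndim={self.values.ndim}"
            )
        if not np.all(np.isfinite(self.values)):
            raise SampleValueError("stream contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return 1 if self.values.ndim == 1 else self.values.shape[1]

    @property
    def duration(self) -> float:
        """Span covered by the stream in seconds: ``[start, start + n/rate)``."""
        return self.n_samples / self.sample_rate

    def times(self, relative: bool = False) -> np.ndarray:
        """Per-sample timestamps (UNIX seconds, or seconds from start)."""
        t = np.arange(self.n_samples) / self.sample_rate
        return t if relative else t + self.start_time


@dataclass
class SensorSession:
    """One officer-shift of raw channel streams sharing a single start time.

    ``ibi`` is an ``(n, 2)`` array of (offset from start [s], beat-to-beat
    interval [s]) records; offsets strictly increase and intervals are > 0.
    """

    eda: RawStream
    temp: RawStream
    acc: RawStream
    bvp: RawStream
    ibi: np.ndarray

    def __post_init__(self) -> None:
        self.ibi = np.asarray(self.ibi, dtype=float).reshape(-1, 2)
        starts = {s.start_time for s in (self.eda, self.temp, self.acc, self.bvp)}
        if len(starts) != 1:
            raise SessionIOError(
                f"channel start times disagree: {sorted(starts)}"
            )
        if self.acc.n_channels != 3:
            raise SampleValueError(
                f"acceleration channel count must be 3, got {self.acc.n_channels}"
            )
        for name, stream, rate in (
            ("eda", self.eda, 4.0),
            ("temp", self.temp, 4.0),
            ("acc", self.acc, 32.0),
            ("bvp", self.bvp, 64.0),
        ):
            if stream.sample_rate != rate:
                raise SessionIOError(
                    f"{name} sample rate must be {rate} Hz, got {stream.sample_rate}"
                )
        if len(self.ibi):
            if np.any(np.diff(self.ibi[:, 0]) <= 0):
                raise SessionIOError("IBI offsets must strictly increase")
            if np.any(self.ibi[:, 1] <= 0):
                raise SessionIOError("IBI durations must be > 0")

    @property
    def start_time(self) -> float:
        return self.eda.start_time

    @property
    def duration(self) -> float:
        """Shortest channel span, in seconds."""
        return min(
            s.duration for s in (self.eda, self.temp, self.acc, self.bvp)
        )


_LIFECYCLE = ("received", "dispatched", "arrive1", "arrive2", "transport", "cleared")


@dataclass(frozen=True)
class CadCall:
    """One call lifecycle from the dispatch system.

    Timestamps are UNIX seconds; any of arrive1/arrive2/transport/cleared may
    be absent (``None``).  Present timestamps must be nondecreasing in
    lifecycle order, and a canceled call carries no arrive/transport/cleared
    times (it was closed before anyone arrived on scene).
    """

    officer_id: str
    call_id: str
    call_type: str
    priority: int
    received: float
    dispatched: float
    arrive1: float | None = None
    arrive2: float | None = None
    transport: float | None = None
    cleared: float | None = None
    canceled: bool = False

    def __post_init__(self) -> None:
        present = [
            (name, getattr(self, name))
            for name in _LIFECYCLE
            if getattr(self, name) is not None
        ]
        times = [t for _, t in present]
        if sorted(times) != times:
            raise SessionIOError(
                f"call {self.call_id}: lifecycle timestamps out of order: {present}"
            )
        if self.canceled:
            extra = [n for n in ("arrive1", "arrive2", "transport", "cleared")
                     if getattr(self, n) is not None and n != "cleared"]
            if extra:
                raise SessionIOError(
                    f"call {self.call_id}: canceled call has on-scene timestamps {extra}"
                )

    def timestamp(self, name: str) -> float | None:
        return getattr(self, name)


@dataclass
class CadEventLog:
    """Validated collection of :class:`CadCall` records."""

    calls: list[CadCall] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self) -> Iterator[CadCall]:
        return iter(self.calls)

    def __getitem__(self, i: int) -> CadCall:
        return self.calls[i]

    @property
    def officer_ids(self) -> set[str]:
        return {c.officer_id for c in self.calls}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.calls:
            rows.append(
                {
                    "officer_id": c.officer_id,
                    "call_id": c.call_id,
                    "call_type": c.call_type,
                    "priority": c.priority,
                    "received": c.received,
                    "dispatched": c.dispatched,
                    "arrive1": c.arrive1,
                    "arrive2": c.arrive2,
                    "transport": c.transport,
                    "cleared": c.cleared,
                    "canceled": int(c.canceled),
                }
            )
        return pd.DataFrame(rows, columns=_CAD_COLUMNS)


_CAD_COLUMNS = [
    "officer_id", "call_id", "call_type", "priority",
    "received", "dispatched", "arrive1", "arrive2", "transport", "cleared",
    "canceled",
]
_CAD_MANDATORY = ["officer_id", "call_id", "call_type", "priority",
                  "received", "dispatched", "canceled"]

_AVL_COLUMNS = ["time", "x", "y", "speed", "heading", "status", "call_id",
                "officer_id"]
_AVL_MANDATORY = ["time", "x", "y", "status", "officer_id"]


@dataclass
class AvlTrack:
    """Vehicle-location pings, sorted by time.

    ``pings`` has columns time (UNIX s), x, y (planar meters), speed (m/s,
    may be NaN), heading (degrees, may be NaN), status, call_id (empty when
    unassigned), officer_id.
    """

    pings: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _AVL_MANDATORY if c not in self.pings.columns]
        if missing:
            raise SessionIOError(f"AVL track missing mandatory columns {missing}")
        for c in _AVL_COLUMNS:
            if c not in self.pings.columns:
                self.pings[c] = np.nan if c in ("speed", "heading") else ""
        self.pings = self.pings[_AVL_COLUMNS].reset_index(drop=True)
        t = self.pings["time"].to_numpy(dtype=float)
        if len(t) and np.any(np.diff(t) < 0):
            raise SessionIOError("AVL ping times must be nondecreasing")

    def __len__(self) -> int:
        return len(self.pings)

    @property
    def officer_ids(self) -> set[str]:
        return set(self.pings["officer_id"].astype(str)) if len(self.pings) else set()


# ---------------------------------------------------------------------------
# Sensor session directory I/O
# ---------------------------------------------------------------------------

#: channel -> (file name, sample rate, channel count)
_CHANNEL_SPEC = {
    "eda": ("EDA.csv", 4.0, 1),
    "temp": ("TEMP.csv", 4.0, 1),
    "acc": ("ACC.csv", 32.0, 3),
    "bvp": ("BVP.csv", 64.0, 1),
}
_IBI_FILE = "IBI.csv"


def _parse_header_row(line: str, n_channels: int, path: Path, what: str) -> float:
    parts = [p.strip() for p in line.strip().split(",")]
    if len(parts) != n_channels:
        raise MalformedHeaderError(
            f"{path}: {what} row has {len(parts)} fields, expected {n_channels}"
        )
    try:
        vals = [float(p) for p in parts]
    except ValueError as exc:
        raise MalformedHeaderError(f"{path}: non-numeric {what} row: {line!r}") from exc
    if len(set(vals)) != 1:
        raise MalformedHeaderError(f"{path}: {what} differs across channels: {vals}")
    return vals[0]


def _read_channel(path: Path, rate: float, n_channels: int) -> RawStream:
    if not path.exists():
        raise MissingChannelError(f"missing channel file {path}")
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 2:
        raise MalformedHeaderError(f"{path}: needs start-time and sample-rate rows")
    start = _parse_header_row(lines[0], n_channels, path, "start-time")
    declared_rate = _parse_header_row(lines[1], n_channels, path, "sample-rate")
    if declared_rate != rate:
        raise MalformedHeaderError(
            f"{path}: declared rate {declared_rate} Hz, expected {rate} Hz"
        )
    body = "\n".join(lines[2:])
    if body.strip():
        try:
            values = np.loadtxt(io.StringIO(body), delimiter=",", ndmin=2)
        except ValueError as exc:
            raise SampleValueError(f"{path}: non-numeric sample row ({exc})") from exc
    else:
        values = np.empty((0, n_channels))
    if values.shape[1] != n_channels:
        raise SampleValueError(
            f"{path}: channel count {values.shape[1]}, expected {n_channels}"
        )
    if n_channels == 1:
        values = values[:, 0]
    return RawStream(start_time=start, sample_rate=rate, values=values)


def _read_ibi(path: Path) -> tuple[float, np.ndarray]:
    if not path.exists():
        raise MissingChannelError(f"missing channel file {path}")
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise MalformedHeaderError(f"{path}: needs a start-time row")
    start = _parse_header_row(lines[0], 1, path, "start-time")
    body = "\n".join(lines[1:])
    if body.strip():
        try:
            ibi = np.loadtxt(io.StringIO(body), delimiter=",", ndmin=2)
        except ValueError as exc:
            raise SampleValueError(f"{path}: non-numeric IBI row ({exc})") from exc
        if ibi.shape[1] != 2:
            raise SampleValueError(f"{path}: IBI rows need offset,duration fields")
    else:
        ibi = np.empty((0, 2))
    return start, ibi


def read_e4_session(path: str | Path) -> SensorSession:
    """Read a sensor session directory in the per-channel CSV dialect.

    Raises :class:`MissingChannelError`, :class:`MalformedHeaderError` or
    :class:`SampleValueError` for the corresponding failure; mismatched
    per-channel start times raise :class:`SessionIOError`.
    """
    path = Path(path)
    streams = {
        name: _read_channel(path / fname, rate, nch)
        for name, (fname, rate, nch) in _CHANNEL_SPEC.items()
    }
    ibi_start, ibi = _read_ibi(path / _IBI_FILE)
    if ibi_start != streams["eda"].start_time:
        raise SessionIOError(
            f"IBI start time {ibi_start} differs from session start "
            f"{streams['eda'].start_time}"
        )
    return SensorSession(ibi=ibi, **streams)


def write_e4_session(session: SensorSession, path: str | Path) -> None:
    """Write a session in the dialect :func:`read_e4_session` accepts.

    Numeric formatting keeps a write→read round trip equal within 1e-6.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for name, (fname, rate, nch) in _CHANNEL_SPEC.items():
        stream: RawStream = getattr(session, name)
        header = ",".join([f"{stream.start_time:.6f}"] * nch)
        rate_row = ",".join([f"{rate:.6f}"] * nch)
        with open(path / fname, "w") as fh:
            fh.write(header + "\n" + rate_row + "\n")
            np.savetxt(fh, stream.values, fmt="%.6f", delimiter=",")
    with open(path / _IBI_FILE, "w") as fh:
        fh.write(f"{session.start_time:.6f}\n")
        if len(session.ibi):
            np.savetxt(fh, session.ibi, fmt="%.6f", delimiter=",")


# ---------------------------------------------------------------------------
# CAD / AVL CSV I/O
# ---------------------------------------------------------------------------


def _opt_float(v) -> float | None:
    if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
        return None
    return float(v)


def read_cad_log(path: str | Path) -> CadEventLog:
    """Read a dispatch log CSV into a validated :class:`CadEventLog`.

    Unknown columns are ignored with a logged warning; a missing mandatory
    column or an unparseable timestamp raises :class:`SessionIOError`.
    """
    df = pd.read_csv(path, dtype={"officer_id": str, "call_id": str,
                                  "call_type": str})
    missing = [c for c in _CAD_MANDATORY if c not in df.columns]
    if missing:
        raise SessionIOError(f"CAD log missing mandatory columns {missing}")
    unknown = [c for c in df.columns if c not in _CAD_COLUMNS]
    if unknown:
        logger.warning("CAD log: ignoring unknown columns %s", unknown)
    calls = []
    for _, row in df.iterrows():
        try:
            timestamps = {
                name: _opt_float(row.get(name)) for name in _LIFECYCLE
            }
        except (TypeError, ValueError) as exc:
            raise SessionIOError(
                f"call {row['call_id']}: unparseable timestamp ({exc})"
            ) from exc
        if timestamps["received"] is None or timestamps["dispatched"] is None:
            raise SessionIOError(
                f"call {row['call_id']}: received/dispatched are mandatory"
            )
        calls.append(
            CadCall(
                officer_id=str(row["officer_id"]),
                call_id=str(row["call_id"]),
                call_type=str(row["call_type"]),
                priority=int(row["priority"]),
                canceled=bool(int(row["canceled"])),
                **timestamps,
            )
        )
    return CadEventLog(calls)


def write_cad_log(log: CadEventLog, path: str | Path) -> None:
    """Write a CAD log CSV; absent lifecycle timestamps become empty fields."""
    log.to_frame().to_csv(path, index=False, float_format="%.6f", na_rep="")


def read_avl_track(path: str | Path) -> AvlTrack:
    """Read a vehicle-location ping CSV into a validated :class:`AvlTrack`."""
    df = pd.read_csv(path, dtype={"officer_id": str, "status": str,
                                  "call_id": str}, keep_default_na=False,
                     na_values=[""])
    missing = [c for c in _AVL_MANDATORY if c not in df.columns]
    if missing:
        raise SessionIOError(f"AVL track missing mandatory columns {missing}")
    unknown = [c for c in df.columns if c not in _AVL_COLUMNS]
    if unknown:
        logger.warning("AVL track: ignoring unknown columns %s", unknown)
        df = df.drop(columns=unknown)
    try:
        df["time"] = df["time"].astype(float)
    except (TypeError, ValueError) as exc:
        raise SessionIOError(f"AVL track: unparseable timestamp ({exc})") from exc
    df["call_id"] = df.get("call_id", "").fillna("")
    return AvlTrack(df)


def write_avl_track(track: AvlTrack, path: str | Path) -> None:
    track.pings.to_csv(path, index=False, float_format="%.6f", na_rep="")


# ---------------------------------------------------------------------------
# Window-table CSV I/O
# ---------------------------------------------------------------------------

#: The 19 windowed metrics, in the canonical reporting order: three time
#: metrics, event code, bad-data value, activity, skin temperature, then the
#: twelve electrodermal parameters.
METRIC_COLUMNS = [
    "time_stamp",
    "elapsed_time",
    "elapsed_from_midnight",
    "event_code",
    "bad_data_value",
    "avg_activity_count",
    "avg_temp",
    "avg_eda_level",
    "avg_eda_level_diff",
    "avg_eda_level_z",
    "eda_slope_20s",
    "eda_slope_120s",
    "rms_eda",
    "rms_eda_diff",
    "rms_eda_z",
    "n_peaks_high",
    "avg_peak_height_high",
    "n_peaks_low",
    "avg_peak_height_low",
]

#: The 12 electrodermal-activity-derived metrics.
EDA_COLUMNS = METRIC_COLUMNS[7:]

#: Context columns a fused table appends to the 19 metrics.
FUSED_COLUMNS = ["call_id", "call_type", "priority", "allocated", "x", "y"]


def write_window_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a window (or fused) table: one row per 20-s window, fixed column
    order, missing values as empty fields."""
    missing = [c for c in METRIC_COLUMNS if c not in table.columns]
    if missing:
        raise SessionIOError(f"window table missing metric columns {missing}")
    extras = [c for c in FUSED_COLUMNS if c in table.columns]
    table[METRIC_COLUMNS + extras].to_csv(
        path, index=False, float_format="%.6f", na_rep=""
    )


def read_window_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in METRIC_COLUMNS if c not in df.columns]
    if missing:
        raise SessionIOError(f"window table missing metric columns {missing}")
    return df
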