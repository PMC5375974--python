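"""Fuse biometric windows with dispatch events and vehicle locations.

Every data source is placed on one UNIX-seconds timeline.  Dispatch (CAD)
call lifecycles become a 1 Hz *event assignment* stream:

====== =====================================================
value  phase
====== =====================================================
0      unassigned (general patrol)
0.5    call that was ultimately canceled (its pending span)
1.0    dispatch to arrive-1 (driving to scene)
2.0    arrive-1 until the next lifecycle event
       (arrive-2, transport, or cleared)
2.5    arrive-2 to transport (when arrive-2 precedes transport)
3.0    transport to cleared (arrestee transport)
====== =====================================================

The per-window *event code* is the mode of the 20 per-second values, ties
broken toward the larger value (the deeper call phase).  Vehicle pings are
linked to windows by nearest ping to the window midpoint within a tolerance
matching the slowest ping cadence (30 s).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .session_io import AvlTrack, CadCall, CadEventLog

__all__ = [
    "EVENT_VALUES",
    "event_assignment_timeline",
    "window_event_code",
    "link_avl",
    "fuse",
]

EVENT_VALUES = (0.0, 0.5, 1.0, 2.0, 2.5, 3.0)

#: seconds a canceled call stays pending after dispatch when the log has no
#: cancellation (cleared) time
CANCELED_HOLD = 300.0

WINDOW_S = 20


def _call_segments(call: CadCall, canceled_hold: float) -> list[tuple[float, float, float]]:
    """(t0, t1, value) phases of one call on the absolute timeline."""
    if call.canceled:
        end = call.cleared if call.cleared is not None else \
            call.dispatched + canceled_hold
        return [(call.dispatched, end, 0.5)]
    segs: list[tuple[float, float, float]] = []
    end = call.cleared
    if call.arrive1 is None:
        # no arrival recorded: the whole span counts as driving to scene
        segs.append((call.dispatched, end, 1.0))
        return segs
    segs.append((call.dispatched, call.arrive1, 1.0))
    nxt = min(t for t in (call.arrive2, call.transport, call.cleared)
              if t is not None)
    segs.append((call.arrive1, nxt, 2.0))
    if call.arrive2 is not None and call.transport is not None:
        segs.append((call.arrive2, call.transport, 2.5))
    if call.transport is not None:
        segs.append((call.transport, call.cleared, 3.0))
    elif call.arrive2 is not None:
        # arrive-2 with no transport: still on scene until cleared
        segs.append((call.arrive2, call.cleared, 2.0))
    return segs


def _timelines(
    cad: CadEventLog,
    span: tuple[float, float],
    canceled_hold: float = CANCELED_HOLD,
) -> tuple[np.ndarray, np.ndarray]:
    start, end = span
    n = int(round(end - start))
    values = np.zeros(n)
    call_idx = np.full(n, -1, dtype=int)
    calls = sorted(cad, key=lambda c: c.dispatched)
    active = [
        (c.dispatched,
         c.cleared if c.cleared is not None
         else (c.dispatched + canceled_hold if c.canceled else c.dispatched),
         c)
        for c in calls
    ]
    for (a0, a1, ca), (b0, b1, cb) in zip(active[:-1], active[1:]):
        if b0 < a1:
            raise ValueError(
                f"overlapping calls {ca.call_id} and {cb.call_id}"
            )
    for ci, c in enumerate(calls):
        for t0, t1, v in _call_segments(c, canceled_hold):
            i0 = int(np.clip(np.floor(t0 - start), 0, n))
            i1 = int(np.clip(np.ceil(t1 - start), 0, n))
            values[i0:i1] = v
            call_idx[i0:i1] = ci
    return values, call_idx


def event_assignment_timeline(
    cad: CadEventLog,
    span: tuple[float, float],
    canceled_hold: float = CANCELED_HOLD,
) -> np.ndarray:
    """1 Hz event-assignment values over ``span = (start, end)`` UNIX seconds.

    Second ``t`` covers ``[start + t, start + t + 1)``; unassigned seconds
    carry 0.  Overlapping calls for one officer are rejected.
    """
    values, _ = _timelines(cad, span, canceled_hold)
    return values


def window_event_code(values: np.ndarray, n_windows: int) -> np.ndarray:
    """Mode of the 20 per-second assignment values per window; ties break
    toward the larger value (the deeper call phase)."""
    values = np.asarray(values, dtype=float)
    if n_windows * WINDOW_S > len(values):
        raise ValueError("event stream does not cover the window grid")
    w = values[: n_windows * WINDOW_S].reshape(n_windows, WINDOW_S)
    codes = np.empty(n_windows)
    for k in range(n_windows):
        vals, counts = np.unique(w[k], return_counts=True)
        codes[k] = vals[counts == counts.max()].max()
    return codes


def link_avl(
    time_stamps: np.ndarray,
    avl: AvlTrack,
    tolerance: float = 30.0,
) -> pd.DataFrame:
    """Per-window (x, y): the ping nearest the window midpoint, within
    ``tolerance`` seconds; missing otherwise."""
    time_stamps = np.asarray(time_stamps, dtype=float)
    mid = time_stamps + WINDOW_S / 2.0
    out = pd.DataFrame({"x": np.full(len(mid), np.nan),
                        "y": np.full(len(mid), np.nan)})
    if not len(avl.pings):
        return out
    t = avl.pings["time"].to_numpy(dtype=float)
    right = np.searchsorted(t, mid)
    left = np.clip(right - 1, 0, len(t) - 1)
    right = np.clip(right, 0, len(t) - 1)
    pick = np.where(np.abs(t[right] - mid) < np.abs(t[left] - mid),
                    right, left)
    ok = np.abs(t[pick] - mid) <= tolerance
    out.loc[ok, "x"] = avl.pings["x"].to_numpy(dtype=float)[pick[ok]]
    out.loc[ok, "y"] = avl.pings["y"].to_numpy(dtype=float)[pick[ok]]
    return out


def fuse(
    table: pd.DataFrame,
    cad: CadEventLog,
    avl: AvlTrack,
    tolerance: float = 30.0,
    canceled_hold: float = CANCELED_HOLD,
) -> pd.DataFrame:
    """Join call context and location onto a window table.

    Recomputes the event timeline over the table's span, sets each window's
    event code and ``allocated`` flag (event value > 0 for the majority of
    the window's 20 seconds), joins the attributes of the call covering most
    of the window, and links the nearest vehicle ping.  The row count never
    changes (left-join contract).
    """
    officer_sets = [s for s in (cad.officer_ids, avl.officer_ids) if s]
    officers = set().union(*officer_sets) if officer_sets else set()
    if len(officers) > 1:
        raise ValueError(f"officer-id mismatch across sources: {sorted(officers)}")

    fused = table.copy()
    n_windows = len(fused)
    start = float(fused["time_stamp"].iloc[0]) if n_windows else 0.0
    span = (start, start + n_windows * WINDOW_S)
    values, call_idx = _timelines(cad, span, canceled_hold)
    fused["event_code"] = window_event_code(values, n_windows)

    calls = sorted(cad, key=lambda c: c.dispatched)
    wv = values.reshape(n_windows, WINDOW_S) if n_windows else values
    wc = call_idx.reshape(n_windows, WINDOW_S) if n_windows else call_idx
    allocated = (wv > 0).sum(axis=1) > WINDOW_S / 2 if n_windows else np.array([], bool)

    call_id = np.full(n_windows, "", dtype=object)
    call_type = np.full(n_windows, "", dtype=object)
    priority = np.full(n_windows, np.nan)
    for k in range(n_windows):
        if fused["event_code"].iloc[k] <= 0:
            continue
        assigned = wc[k][wc[k] >= 0]
        if not len(assigned):
            continue
        ci, counts = np.unique(assigned, return_counts=True)
        c = calls[int(ci[np.argmax(counts)])]
        call_id[k] = c.call_id
        call_type[k] = c.call_type
        priority[k] = c.priority

    fused["call_id"] = call_id
    fused["call_type"] = call_type
    fused["priority"] = priority
    fused["allocated"] = allocated
    loc = link_avl(fused["time_stamp"].to_numpy(dtype=float), avl, tolerance)
    fused["x"] = loc["x"].to_numpy()
    fused["y"] = loc["y"].to_numpy()
    return fused
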