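"""Departure-event detection from automated radio-telemetry streams.

A nocturnal departure shows a characteristic signature in the raw
signal-strength series of a multi-antenna station: a rapid surge on
all/most antennas as the bird becomes airborne, a decline on fewer and
fewer antennas as it leaves the detection volume, and finally permanent
signal loss.  This module segments that terminal event from a per-tag
detection stream, fixes the take-off at the single highest signal
strength inside the event, and rates the departure bearing as a
weighted circular mean of the bearings of the antennas that received
the second half of the event, weighting each detection by its temporal
proximity to the last one.

Quality control follows the field protocol: bearings are discarded when
the signal is lost less than three minutes after take-off
(``short_event``) or when no antenna aligned near the computed bearing
received the event (``pivotal_antenna_missing``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Mapping, Optional, Set

import numpy as np
import pandas as pd

from .circular import circular_mean_and_rho

#: QC flag names.
NO_EVENT = "no_event_found"
SHORT_EVENT = "short_event"
PIVOTAL_MISSING = "pivotal_antenna_missing"

#: Bearings from events lost sooner than this after take-off are discarded.
SHORT_EVENT_S = 180.0


@dataclass(frozen=True)
class EventParams:
    """Segmentation thresholds (all configurable; defaults in seconds/dB)."""

    rise_db: float = 10.0          # surge above trailing baseline that opens an event
    rise_window_s: float = 600.0   # trailing window over which the baseline is taken
    gap_min_s: float = 1800.0      # silence this long counts as permanent signal loss
    short_event_s: float = 180.0   # bearings from events shorter than this are discarded
    min_baseline_samples: int = 3  # baseline support required before a candidate rise


@dataclass
class DepartureEvent:
    tag_id: str
    event_start: Optional[pd.Timestamp] = None
    event_end: Optional[pd.Timestamp] = None
    take_off_time: Optional[pd.Timestamp] = None
    bearing: Optional[float] = None
    qc: Set[str] = field(default_factory=set)
    min_stopover_days: Optional[int] = None

    @property
    def found(self) -> bool:
        return NO_EVENT not in self.qc and self.take_off_time is not None


def _aggregate_series(stream: pd.DataFrame) -> pd.DataFrame:
    """Across-antenna max signal per timestamp, time-sorted."""
    agg = stream.groupby("ts", sort=True)["sig_db"].max().reset_index()
    return agg


def segment_departure_event(stream: pd.DataFrame, params: EventParams = EventParams()) -> DepartureEvent:
    """Segment the terminal departure event of a single tag's stream.

    ``stream`` needs columns ``ts`` (timestamps, sorted), ``tag_id``,
    ``antenna_id``, ``sig_db``.  Returns a :class:`DepartureEvent`; if
    the stream simply ceases without the surge-and-decline shape the
    event carries the ``no_event_found`` flag.
    """
    tag = str(stream["tag_id"].iloc[0]) if len(stream) else ""
    ev = DepartureEvent(tag_id=tag)
    if stream.empty:
        ev.qc.add(NO_EVENT)
        return ev
    if not stream["ts"].is_monotonic_increasing:
        stream = stream.sort_values("ts")
    agg = _aggregate_series(stream)
    t = agg["ts"].astype("int64").to_numpy() / 1e9  # seconds
    sig = agg["sig_db"].to_numpy()

    # Candidate rises: aggregate signal >= trailing-window median + rise_db.
    candidates = []
    for i in range(len(t)):
        in_win = (t >= t[i] - params.rise_window_s) & (t < t[i])
        if np.count_nonzero(in_win) < params.min_baseline_samples:
            continue
        baseline = float(np.median(sig[in_win]))
        if sig[i] >= baseline + params.rise_db:
            candidates.append(i)

    # Group consecutive candidate samples into rises; each rise is
    # represented by its onset (elevated samples during the subsequent
    # decay belong to the same event, not to a new one).
    onsets = []
    for k, i in enumerate(candidates):
        if k == 0 or i != candidates[k - 1] + 1:
            onsets.append(i)

    # The departure is the final rise that runs gap-free to the end of the
    # stream (permanent loss).  A rise followed by a long gap and renewed
    # activity is not terminal.
    chosen = None
    for i in reversed(onsets):
        gaps = np.diff(t[i:])
        if gaps.size == 0 or np.max(gaps) < params.gap_min_s:
            chosen = i
            break
    if chosen is None:
        ev.qc.add(NO_EVENT)
        return ev

    ev.event_start = agg["ts"].iloc[chosen]
    ev.event_end = agg["ts"].iloc[len(t) - 1]
    window = agg.iloc[chosen:]
    # Take-off = single highest signal; earliest wins on ties.
    k = int(np.argmax(window["sig_db"].to_numpy()))
    ev.take_off_time = window["ts"].iloc[k]
    return ev


def estimate_bearing(
    event: DepartureEvent,
    stream: pd.DataFrame,
    antenna_bearings: Mapping[str, float],
    spacing_deg: float = 30.0,
    short_event_s: float = SHORT_EVENT_S,
) -> DepartureEvent:
    """Rate the departure bearing of a segmented event (in place).

    Only detections in the second half of the event window (time axis)
    contribute; each carries its antenna's bearing with weight
    ``w = (t - t_mid)/(t_last - t_mid)``, a linear ramp toward the last
    detection.  The bearing is discarded (flag set, value ``None``) when
    the event ends < 3 min after take-off or when no antenna within half
    the array spacing of the result received the event.
    """
    if not event.found:
        return event
    sub = stream[(stream["ts"] >= event.event_start) & (stream["ts"] <= event.event_end)]
    # Seconds relative to event start (avoids precision loss on epoch values).
    base = event.event_start.value
    t_all = (sub["ts"].astype("int64").to_numpy() - base) / 1e9
    t_end = (event.event_end.value - base) / 1e9
    t1 = float(t_all.max()) if t_all.size else t_end  # last detection
    # Short-event rule: signal lost < 3 min after take-off.
    if (t1 - (event.take_off_time.value - base) / 1e9) < short_event_s:
        event.bearing = None
        event.qc.add(SHORT_EVENT)
        return event
    t_mid = t_end / 2.0
    half = sub[t_all >= t_mid]
    th = t_all[t_all >= t_mid]
    if len(half) == 0:
        event.bearing = None
        event.qc.add(NO_EVENT)
        return event
    bearings = np.array([antenna_bearings[a] for a in half["antenna_id"]], dtype=float)
    if t1 > t_mid:
        w = (th - t_mid) / (t1 - t_mid)
    else:
        w = np.ones_like(th)
    if not np.any(w > 0):
        w = np.ones_like(w)  # single detection exactly at midpoint
    mean, _rho = circular_mean_and_rho(bearings, weights=w)
    if mean is None:
        event.bearing = None
        event.qc.add(PIVOTAL_MISSING)
        return event
    # Pivotal-antenna check over the whole event window.
    ev_bearings = np.array([antenna_bearings[a] for a in sub["antenna_id"]], dtype=float)
    diff = np.abs((ev_bearings - mean + 180.0) % 360.0 - 180.0)
    if not np.any(diff <= spacing_deg / 2.0):
        event.bearing = None
        event.qc.add(PIVOTAL_MISSING)
        return event
    event.bearing = float(mean % 360.0)
    return event


def minimum_stopover(capture_date: date, take_off_time: pd.Timestamp) -> int:
    """Minimum stopover duration in days (capture day to departure night).

    A departure during the night following the capture day counts as 1.
    Take-offs after midnight (UTC hour < 12) belong to the previous
    evening's night.
    """
    t = pd.Timestamp(take_off_time)
    if t.tzinfo is not None:
        t = t.tz_convert("UTC")
    night_date = t.date() if t.hour >= 12 else (t - pd.Timedelta(days=1)).date()
    days = (night_date - capture_date).days + 1
    if days < 1:
        raise ValueError(f"take-off {take_off_time} precedes capture date {capture_date}")
    return days


def read_detections(path) -> pd.DataFrame:
    """Read a detection-stream CSV (ts ISO-8601 UTC, tag_id, antenna_id, sig_db)."""
    df = pd.read_csv(path, parse_dates=["ts"])
    df["ts"] = pd.to_datetime(df["ts"], utc=True)
    return df.sort_values(["tag_id", "ts"]).reset_index(drop=True)


def read_antennas(path) -> pd.DataFrame:
    """Read an antenna-configuration CSV (antenna_id, site, bearing_deg)."""
    return pd.read_csv(path)


def process_stream(
    detections: pd.DataFrame,
    antennas: pd.DataFrame,
    params: EventParams = EventParams(),
    capture_dates: Optional[Mapping[str, date]] = None,
) -> pd.DataFrame:
    """Segment and rate every tag in a detection stream.

    Returns one row per tag: event window, take-off, bearing, QC flags
    and (when ``capture_dates`` maps the tag) minimum stopover days.
    """
    bearing_map = dict(zip(antennas["antenna_id"].astype(str), antennas["bearing_deg"]))
    spacings = np.diff(np.sort(np.asarray(antennas["bearing_deg"], dtype=float)))
    spacing = float(np.min(spacings)) if spacings.size else 30.0
    rows = []
    for tag, grp in detections.groupby("tag_id", sort=True):
        grp = grp.sort_values("ts")
        grp = grp.assign(antenna_id=grp["antenna_id"].astype(str))
        ev = segment_departure_event(grp, params)
        if ev.found:
            estimate_bearing(
                ev, grp, bearing_map, spacing_deg=spacing, short_event_s=params.short_event_s
            )
            if capture_dates and str(tag) in capture_dates:
                ev.min_stopover_days = minimum_stopover(capture_dates[str(tag)], ev.take_off_time)
        rows.append(
            {
                "tag_id": str(tag),
                "event_start": ev.event_start,
                "event_end": ev.event_end,
                "take_off_time": ev.take_off_time,
                "bearing_deg": ev.bearing,
                "qc": ";".join(sorted(ev.qc)),
                "min_stopover_days": ev.min_stopover_days,
            }
        )
    return pd.DataFrame(rows)
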