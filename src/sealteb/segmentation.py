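"""Deployment segmentation: location, behaviour events, dives, trips.

Location is assigned per second from the wet/dry switch and depth:
dry -> land; wet at <= 1 m -> surface; wet below 1 m -> underwater.
Classified epochs are merged into behaviour events — maximal runs of a
constant (behaviour, location) state — with a persistence rule: a
candidate state change opens a new event only if the new state persists
for more than 15 s; shorter excursions are absorbed into the enclosing
event.  Dives are submergence excursions reaching at least 5 m
(excluding wave action); trips are wet intervals containing at least
one dive of 10 m or more.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

SURFACE_DEPTH_M = 1.0
DIVE_MIN_DEPTH_M = 5.0
TRIP_MIN_DIVE_DEPTH_M = 10.0
EVENT_PERSISTENCE_S = 15.0

#: Fallback water temperature (deg C) when no thermistor channel exists.
DEFAULT_WATER_TEMP_C = {"winter": 14.0, "summer": 18.0}


@dataclass
class BehaviourEvent:
    """Maximal run of constant (behaviour, location)."""

    behaviour: str
    location: str
    start_s: float
    end_s: float
    season: str = "winter"
    water_temp_c: Optional[float] = None

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("event must have end_s > start_s")

    @property
    def duration_min(self) -> float:
        return (self.end_s - self.start_s) / 60.0


@dataclass
class DiveRecord:
    start_s: int
    end_s: int
    max_depth_m: float
    duration_s: int


@dataclass
class TripRecord:
    start_s: int
    end_s: int
    n_dives: int
    duration_s: int


def assign_location(wet: np.ndarray, depth: np.ndarray,
                    surface_depth_m: float = SURFACE_DEPTH_M) -> np.ndarray:
    """Per-second location from the wet/dry switch and depth.

    Dry seconds are land regardless of depth; wet seconds are surface
    down to ``surface_depth_m`` (inclusive — "more than 1 m" is read
    strictly) and underwater below it.
    """
    wet = np.asarray(wet, dtype=bool)
    depth = np.asarray(depth, dtype=float)
    if len(wet) != len(depth):
        raise ValueError(
            f"wet length {len(wet)} != depth length {len(depth)}"
        )
    loc = np.where(wet, np.where(depth > surface_depth_m, "underwater", "surface"),
                   "land")
    return loc.astype(object)


def expand_epochs_to_seconds(
    behaviours: Sequence[str], locations: Sequence[str], epoch_s: float
) -> tuple[np.ndarray, np.ndarray]:
    """Repeat per-epoch states to a per-second track."""
    reps = int(round(epoch_s))
    b = np.repeat(np.asarray(behaviours, dtype=object), reps)
    l = np.repeat(np.asarray(locations, dtype=object), reps)
    return b, l


def build_events(
    behaviours: Sequence[str],
    locations: Sequence[str],
    min_change_s: float = EVENT_PERSISTENCE_S,
    start_s: float = 0.0,
    season: str = "winter",
    temperature: Optional[np.ndarray] = None,
    wet: Optional[np.ndarray] = None,
) -> list[BehaviourEvent]:
    """Merge per-second states into behaviour events.

    A run of a new (behaviour, location) state opens a new event only
    when it lasts strictly more than ``min_change_s`` seconds; shorter
    excursions are absorbed into the enclosing event.  The returned
    events tile the track without gaps or overlaps.

    When a 0.5 Hz ``temperature`` channel is supplied, each water event
    gets the median device temperature over its wet seconds (falling
    back to a season default when none are available).
    """
    b = np.asarray(behaviours, dtype=object)
    l = np.asarray(locations, dtype=object)
    if len(b) != len(l):
        raise ValueError("behaviour and location tracks must have equal length")
    n = len(b)
    if n == 0:
        return []

    # run-length encode the joint state
    state = np.array([f"{x}\x00{y}" for x, y in zip(b, l)], dtype=object)
    change = np.flatnonzero(state[1:] != state[:-1]) + 1
    run_starts = np.concatenate([[0], change])
    run_ends = np.concatenate([change, [n]])

    events: list[BehaviourEvent] = []
    cur_state = state[0]
    cur_start = 0
    for rs, re in zip(run_starts[1:], run_ends[1:]):
        run_len = re - rs
        if state[rs] != cur_state and run_len > min_change_s:
            events.append(_make_event(cur_state, cur_start, rs, start_s, season))
            cur_state, cur_start = state[rs], rs
    events.append(_make_event(cur_state, cur_start, n, start_s, season))

    _attach_temperature(events, temperature, wet, season, start_s)
    return events


def _make_event(
    state: str, i0: int, i1: int, start_s: float, season: str
) -> BehaviourEvent:
    beh, loc = state.split("\x00")
    return BehaviourEvent(
        behaviour=beh, location=loc,
        start_s=start_s + i0, end_s=start_s + i1, season=season,
    )


def _attach_temperature(
    events: list[BehaviourEvent],
    temperature: Optional[np.ndarray],
    wet: Optional[np.ndarray],
    season: str,
    start_s: float,
) -> None:
    fallback = DEFAULT_WATER_TEMP_C[season]
    for ev in events:
        if ev.location == "land":
            continue
        if temperature is None:
            ev.water_temp_c = fallback
            continue
        i0 = int(ev.start_s - start_s)
        i1 = int(ev.end_s - start_s)
        sl = slice(i0 // 2, max(i0 // 2 + 1, i1 // 2))
        vals = np.asarray(temperature[sl], dtype=float)
        if wet is not None:
            wsl = np.asarray(wet[i0:i1], dtype=bool)
            # thermistor runs at 0.5 Hz; match by halved index
            wmask = wsl[:: 2][: len(vals)]
            vals = vals[: len(wmask)][wmask]
        vals = vals[np.isfinite(vals)]
        ev.water_temp_c = float(np.median(vals)) if len(vals) else fallback


def events_to_seconds(events: list[BehaviourEvent]) -> tuple[np.ndarray, np.ndarray]:
    """Expand events back to per-second behaviour/location tracks."""
    if not events:
        return np.array([], dtype=object), np.array([], dtype=object)
    t0 = events[0].start_s
    n = int(events[-1].end_s - t0)
    b = np.empty(n, dtype=object)
    l = np.empty(n, dtype=object)
    for ev in events:
        i0, i1 = int(ev.start_s - t0), int(ev.end_s - t0)
        b[i0:i1] = ev.behaviour
        l[i0:i1] = ev.location
    return b, l


def detect_dives(
    depth: np.ndarray,
    min_depth_m: float = DIVE_MIN_DEPTH_M,
    surface_threshold_m: float = 0.0,
) -> list[DiveRecord]:
    """Submergence excursions whose maximum depth reaches ``min_depth_m``.

    Expects zero-offset-corrected depth.  An excursion runs from the
    first strictly submerged second to the last, bounded by surface
    crossings.
    """
    depth = np.asarray(depth, dtype=float)
    sub = depth > surface_threshold_m
    dives: list[DiveRecord] = []
    n = len(depth)
    i = 0
    while i < n:
        if not sub[i]:
            i += 1
            continue
        j = i
        while j < n and sub[j]:
            j += 1
        dmax = float(depth[i:j].max())
        if dmax >= min_depth_m:
            dives.append(DiveRecord(start_s=i, end_s=j, max_depth_m=dmax,
                                    duration_s=j - i))
        i = j
    return dives


def detect_trips(
    wet: np.ndarray,
    dives: list[DiveRecord],
    min_dive_depth_m: float = TRIP_MIN_DIVE_DEPTH_M,
) -> list[TripRecord]:
    """Wet intervals promoted to trips when they contain a dive of at
    least ``min_dive_depth_m`` (wet periods with only shallow diving are
    resting at the surface near the colony, not trips)."""
    wet = np.asarray(wet, dtype=bool)
    trips: list[TripRecord] = []
    n = len(wet)
    i = 0
    while i < n:
        if not wet[i]:
            i += 1
            continue
        j = i
        while j < n and wet[j]:
            j += 1
        inside = [d for d in dives if d.start_s >= i and d.end_s <= j]
        if any(d.max_depth_m >= min_dive_depth_m for d in inside):
            trips.append(TripRecord(start_s=i, end_s=j, n_dives=len(inside),
                                    duration_s=j - i))
        i = j
    return trips
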