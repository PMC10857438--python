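"""Synthetic CASAS-format smart-home logs with known ground truth.

A semi-Markov activity process drives the simulator: an activity is drawn
from a time-of-day prior combined with a transition preference from the
previous activity, holds for a log-normally distributed duration, and
emits motion ON/OFF firing pairs from its room-affine sensors with
exponentially distributed gaps. Activities flagged with a door sensor
(entries/exits) open and close it at the episode boundary. Episode
boundaries carry ``begin``/``end`` annotations exactly as real logs do;
the per-event ground-truth activity is returned alongside, so label
propagation can be checked against the truth.

The generator provides structure, not realism: it makes no attempt to fit
real CASAS statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np

from .casas import Marker, Modality, SensorEvent, SensorMap

__all__ = [
    "ActivitySpec",
    "SyntheticHomeConfig",
    "generate_home",
    "simulate_events",
    "default_home_config",
    "expected_event_count",
]


@dataclass(frozen=True)
class ActivitySpec:
    """One activity's duration, timing, and sensor-affinity laws."""

    name: str
    rooms: tuple[str, ...]  # rooms whose sensors the activity fires
    median_duration_s: float = 600.0
    duration_spread: float = 0.4  # sigma of log(duration)
    event_rate_hz: float = 0.2  # exponential inter-firing rate
    peak_hour: float = 12.0  # time-of-day prior center
    tod_concentration: float = 1.0  # 0 = uniform over the day
    uses_door: bool = False  # bracket the episode with a door sensor

    def __post_init__(self):
        if self.median_duration_s <= 0 or self.event_rate_hz <= 0:
            raise ValueError("durations and rates must be positive")


@dataclass(frozen=True)
class SyntheticHomeConfig:
    """Home layout plus the activity schedule the simulator realizes."""

    rooms: tuple[tuple[str, int], ...]  # (room name, number of motion sensors)
    door_rooms: tuple[str, ...] = ()  # rooms that also get a door sensor
    activities: tuple[ActivitySpec, ...] = ()
    self_transition_weight: float = 0.0  # added preference to repeat an activity
    cross_room_noise: float = 0.0  # P(firing comes from a random other sensor)
    label_noise: float = 0.0  # P(an episode is left unannotated)
    start: datetime = datetime(2024, 1, 6, 0, 0, 0)

    def __post_init__(self):
        if not self.rooms or all(n <= 0 for _, n in self.rooms):
            raise ValueError("need at least one room with a motion sensor")
        if not 0 <= self.cross_room_noise <= 1 or not 0 <= self.label_noise <= 1:
            raise ValueError("noise fractions must lie in [0, 1]")
        room_names = {name for name, _ in self.rooms}
        for spec in self.activities:
            missing = set(spec.rooms) - room_names
            if missing:
                raise ValueError(f"activity {spec.name!r} references unknown rooms {missing}")


def generate_home(config: SyntheticHomeConfig) -> SensorMap:
    """Lay out sensors: M001... over rooms in order, D001... for door rooms."""
    entries: dict[str, tuple[str, Modality]] = {}
    m = d = 0
    for room, n_motion in config.rooms:
        for _ in range(n_motion):
            m += 1
            entries[f"M{m:03d}"] = (room, Modality.motion)
    for room in config.door_rooms:
        d += 1
        entries[f"D{d:03d}"] = (room, Modality.door)
    return SensorMap(entries)


def _tod_weight(spec: ActivitySpec, hour: float) -> float:
    angle = 2 * math.pi * (hour - spec.peak_hour) / 24.0
    return math.exp(spec.tod_concentration * math.cos(angle))


def expected_event_count(
    config: SyntheticHomeConfig, horizon_days: float
) -> float:
    """Analytic mean event count for a schedule with no time-of-day prior.

    Exact (up to horizon truncation) when every activity has
    ``tod_concentration = 0`` and ``self_transition_weight = 0``, so episode
    types are drawn uniformly. By the renewal-reward theorem the long-run
    event rate is E[events per episode] / E[episode duration]: an episode
    of activity ``a`` contributes ``2 * rate_a * E[D_a]`` ON/OFF events
    (plus an OPEN/CLOSE bracket when it uses a door), with log-normal mean
    duration ``E[D_a] = median_a * exp(spread_a^2 / 2)``.
    """
    horizon_s = horizon_days * 86400.0
    mean_dur = np.array(
        [a.median_duration_s * math.exp(a.duration_spread**2 / 2) for a in config.activities]
    )
    per_episode = np.array(
        [2 * a.event_rate_hz for a in config.activities]
    ) * mean_dur + np.array([2.0 if a.uses_door else 0.0 for a in config.activities])
    return horizon_s * float(per_episode.mean() / mean_dur.mean())


def simulate_events(
    sensor_map: SensorMap,
    config: SyntheticHomeConfig,
    horizon_days: float,
    seed: int = 0,
) -> tuple[list[SensorEvent], list[str]]:
    """Simulate ``horizon_days`` of life; return (events, ground-truth labels).

    Events are time-sorted with strictly increasing microsecond timestamps;
    each annotated episode opens with ``<activity> begin`` on its first
    event and closes with ``<activity> end`` on its last.
    """
    if horizon_days < 1:
        raise ValueError("horizon must be at least one day")
    if not config.activities:
        raise ValueError("the activity set is empty")
    rng = np.random.default_rng(seed)

    by_room: dict[str, list[str]] = {}
    for sid in sensor_map.sensor_ids:
        if sensor_map.modality(sid) == Modality.motion:
            by_room.setdefault(sensor_map.location(sid), []).append(sid)
    doors_by_room = {
        sensor_map.location(sid): sid
        for sid in sensor_map.sensor_ids
        if sensor_map.modality(sid) == Modality.door
    }
    all_motion = sorted({s for ss in by_room.values() for s in ss})

    events: list[SensorEvent] = []
    truth: list[str] = []
    t = 0.0
    horizon_s = horizon_days * 86400.0
    prev_idx: int | None = None
    specs = config.activities

    while t < horizon_s:
        hour = (t / 3600.0) % 24.0
        weights = np.array([_tod_weight(a, hour) for a in specs])
        if prev_idx is not None and config.self_transition_weight:
            weights[prev_idx] += config.self_transition_weight * weights.sum()
        weights /= weights.sum()
        idx = int(rng.choice(len(specs), p=weights))
        spec = specs[idx]
        prev_idx = idx

        duration = float(
            rng.lognormal(math.log(spec.median_duration_s), spec.duration_spread)
        )
        duration = min(duration, horizon_s - t)
        pool = [s for room in spec.rooms for s in by_room.get(room, [])]
        if not pool:
            pool = all_motion

        episode: list[tuple[float, str, str]] = []
        door = doors_by_room.get(spec.rooms[0]) if spec.uses_door else None
        if door is not None:
            episode.append((t, door, "OPEN"))
        # firing instants form a Poisson process at the activity's rate
        firings: list[float] = []
        tau = t
        while True:
            tau += float(rng.exponential(1.0 / spec.event_rate_hz))
            if tau >= t + duration:
                break
            firings.append(tau)
        for i, ft in enumerate(firings):
            nxt = firings[i + 1] if i + 1 < len(firings) else t + duration
            if config.cross_room_noise and rng.random() < config.cross_room_noise:
                sid = all_motion[int(rng.integers(len(all_motion)))]
            else:
                sid = pool[int(rng.integers(len(pool)))]
            # the OFF echo lands before the next firing of any sensor
            episode.append((ft, sid, "ON"))
            episode.append((ft + min(0.45 * (nxt - ft), 2.0), sid, "OFF"))
        if door is not None:
            episode.append((t + duration - 1e-3, door, "CLOSE"))
        if not firings and door is None:  # guarantee one firing per episode
            sid = pool[int(rng.integers(len(pool)))]
            episode = [(t, sid, "ON"), (t + 0.5, sid, "OFF")]

        episode.sort(key=lambda e: e[0])
        annotated = rng.random() >= config.label_noise
        last = len(episode) - 1
        for j, (et, sid, state) in enumerate(episode):
            ts = config.start + timedelta(seconds=et)
            marker = activity = None
            if annotated and j == 0:
                activity, marker = spec.name, Marker.begin
            elif annotated and j == last:
                activity, marker = spec.name, Marker.end
            events.append(SensorEvent(ts, sid, state, activity, marker))
            truth.append(spec.name)
        t += duration

    # enforce strictly increasing, microsecond-distinct timestamps
    fixed: list[SensorEvent] = []
    prev_ts: datetime | None = None
    for ev in events:
        ts = ev.timestamp
        if prev_ts is not None and ts <= prev_ts:
            ts = prev_ts + timedelta(microseconds=1)
        fixed.append(SensorEvent(ts, ev.sensor_id, ev.state, ev.activity, ev.marker))
        prev_ts = ts
    return fixed, truth


def default_home_config(
    label_noise: float = 0.0, cross_room_noise: float = 0.0
) -> SyntheticHomeConfig:
    """A small five-activity home with disjoint room affinities.

    Disjoint affinities give well-separated activity signatures, so a
    fully supervised run should approach perfect F1 — the sanity ceiling
    for the protocol tests.
    """
    return SyntheticHomeConfig(
        rooms=(
            ("Kitchen", 3),
            ("Living room", 2),
            ("Bedroom", 2),
            ("Bathroom", 1),
            ("Office", 2),
        ),
        door_rooms=("Kitchen", "Living room"),
        activities=(
            ActivitySpec(
                "Meal_Preparation",
                rooms=("Kitchen",),
                median_duration_s=900,
                event_rate_hz=0.5,
                peak_hour=18,
                tod_concentration=1.2,
                uses_door=True,
            ),
            ActivitySpec(
                "Relax",
                rooms=("Living room",),
                median_duration_s=1800,
                event_rate_hz=0.15,
                peak_hour=20,
                tod_concentration=1.0,
            ),
            ActivitySpec(
                "Sleeping",
                rooms=("Bedroom",),
                median_duration_s=7200,
                duration_spread=0.3,
                event_rate_hz=0.03,
                peak_hour=2,
                tod_concentration=2.0,
            ),
            ActivitySpec(
                "Bed_to_Toilet",
                rooms=("Bathroom",),
                median_duration_s=240,
                event_rate_hz=0.6,
                peak_hour=4,
                tod_concentration=1.5,
            ),
            ActivitySpec(
                "Work",
                rooms=("Office",),
                median_duration_s=3600,
                event_rate_hz=0.25,
                peak_hour=10,
                tod_concentration=1.5,
            ),
        ),
        self_transition_weight=0.0,
        cross_room_noise=cross_room_noise,
        label_noise=label_noise,
    )
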