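"""Feature extraction and windowing for ambient sensor event streams.

A cleaned, label-propagated event stream is summarized block-by-block:
every consecutive, non-overlapping run of ``event_window_len`` (default 30)
events becomes one feature vector of length ``2*S + 14``, where ``S`` is
the number of non-temperature sensors in the home:

==============  ==========================================================
feature          meaning
==============  ==========================================================
1                hour of the block's last event (0-23)
2                seconds-of-day of the last event
3                day-of-week of the last event (Mon=0)
4                block duration in seconds
5                seconds between the last event and the one before it
6                dominant (most frequent) sensor index, previous block
7                dominant sensor index, two blocks back
8                index of the last event's sensor
9                location index of the last event's sensor
10               location index of the last *motion* event's sensor
11               entropy (nats) of the block's sensor-count distribution
12               event-rate change: second half minus first half (ev/s)
13               number of location transitions between consecutive events
14               number of distinct sensors
15 .. S+14       per-sensor event counts (sum = block length)
S+15 .. 2S+14    per-sensor seconds since that sensor last fired
==============  ==========================================================

Sensor and location indices follow the sorted order of
:attr:`homeclr.casas.SensorMap.sensor_ids` / ``locations``. Feature-vector
sequences are then cut into sliding windows (length 10, 50 % overlap by
default), standardized with training-split statistics, and split into
train/val/test sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .casas import Modality, SensorEvent, SensorMap

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureVector",
    "WindowedDataset",
    "feature_dimension",
    "featurize",
    "window_label",
    "make_sliding_windows",
    "expected_window_count",
    "Standardizer",
    "split_dataset",
    "subsample_label_fraction",
    "vectors_to_frame",
]

STANDARDIZE_SD_FLOOR = 1e-8


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray  # length 2*S + 14
    label: str | None


@dataclass
class WindowedDataset:
    """Sliding windows ready for the model: ``data`` is (n, T, F)."""

    data: np.ndarray
    labels: np.ndarray  # object array of activity names or None, length n
    split_tag: str = "all"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.data.ndim != 3:
            raise ValueError(f"window data must be 3-D, got shape {self.data.shape}")
        if len(self.labels) != len(self.data):
            raise ValueError("labels and data disagree in length")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_features(self) -> int:
        return self.data.shape[2]

    def labeled_subset(self) -> "WindowedDataset":
        mask = np.array([lab is not None for lab in self.labels])
        return WindowedDataset(self.data[mask], self.labels[mask], self.split_tag)

    def take(self, idx: np.ndarray, split_tag: str | None = None) -> "WindowedDataset":
        return WindowedDataset(self.data[idx], self.labels[idx], split_tag or self.split_tag)


def feature_dimension(n_sensors: int) -> int:
    """Length of the feature vector for a home with ``n_sensors`` sensors."""
    return 2 * n_sensors + 14


def _entropy(counts: np.ndarray) -> float:
    """Shannon entropy (natural log) of a count vector."""
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def window_label(labels: Sequence[str | None]) -> str | None:
    """Label for a block: majority vote, ties broken by the last event's label."""
    present = [lab for lab in labels if lab is not None]
    if not present:
        return None
    counts = pd.Series(present).value_counts()
    top = counts.max()
    winners = set(counts[counts == top].index)
    if len(winners) > 1:
        for lab in reversed(labels):
            if lab in winners:
                return lab
    return counts.idxmax()


def featurize(
    labeled_events: Sequence[tuple[SensorEvent, str | None]],
    sensor_map: SensorMap,
    event_window_len: int = 30,
) -> list[FeatureVector]:
    """Summarize consecutive non-overlapping event blocks into feature vectors.

    ``labeled_events`` is the output of
    :func:`homeclr.casas.propagate_activity_labels` on a cleaned stream.
    A trailing partial block is dropped. An event from a sensor missing
    from ``sensor_map`` is an error.
    """
    sensor_ids = sensor_map.sensor_ids
    sensor_index = {s: i for i, s in enumerate(sensor_ids)}
    locations = sensor_map.locations
    location_index = {loc: i for i, loc in enumerate(locations)}
    S = len(sensor_ids)

    events = [ev for ev, _ in labeled_events]
    labels = [lab for _, lab in labeled_events]
    for ev in events:
        if ev.sensor_id not in sensor_index:
            raise KeyError(f"sensor {ev.sensor_id!r} not in the sensor map")

    n_blocks = len(events) // event_window_len
    dropped = len(events) - n_blocks * event_window_len
    if dropped:
        logger.info("featurize: dropping trailing partial block of %d events", dropped)

    if n_blocks == 0:
        return []

    t0 = events[0].timestamp
    span = (events[-1].timestamp - t0).total_seconds()
    never_fired_sentinel = max(span, 1.0)

    last_fired: dict[str, float] = {}  # sensor -> seconds since stream start
    vectors: list[FeatureVector] = []
    dominant_history: list[int] = []

    for b in range(n_blocks):
        block = events[b * event_window_len : (b + 1) * event_window_len]
        block_labels = labels[b * event_window_len : (b + 1) * event_window_len]
        times = np.array([(ev.timestamp - t0).total_seconds() for ev in block])
        idxs = np.array([sensor_index[ev.sensor_id] for ev in block])
        last_ev = block[-1]
        t_last = times[-1]

        counts = np.bincount(idxs, minlength=S).astype(float)
        dominant = int(np.argmax(counts))

        # previous event: last event of the previous block, if any
        if b > 0:
            prev_time = (events[b * event_window_len - 1].timestamp - t0).total_seconds()
            gap_prev = times[-1] - prev_time if len(block) == 1 else times[-1] - times[-2]
        else:
            gap_prev = times[-1] - times[-2] if len(block) > 1 else 0.0

        half = len(block) // 2
        first_half, second_half = times[:half], times[half:]

        def _rate(ts: np.ndarray) -> float:
            if len(ts) < 2:
                return 0.0
            dur = ts[-1] - ts[0]
            return len(ts) / dur if dur > 0 else float(len(ts))

        locs = [location_index[sensor_map.location(ev.sensor_id)] for ev in block]
        transitions = int(np.sum(np.asarray(locs[1:]) != np.asarray(locs[:-1])))

        motion_locs = [
            location_index[sensor_map.location(ev.sensor_id)]
            for ev in block
            if sensor_map.modality(ev.sensor_id) == Modality.motion
        ]
        last_motion_loc = motion_locs[-1] if motion_locs else locs[-1]

        # per-sensor recency relative to the block's last event
        for ev, t in zip(block, times):
            last_fired[ev.sensor_id] = t
        recency = np.array(
            [
                t_last - last_fired[s] if s in last_fired else never_fired_sentinel
                for s in sensor_ids
            ]
        )

        vec = np.empty(2 * S + 14)
        vec[0] = last_ev.timestamp.hour
        vec[1] = (
            last_ev.timestamp.hour * 3600
            + last_ev.timestamp.minute * 60
            + last_ev.timestamp.second
            + last_ev.timestamp.microsecond / 1e6
        )
        vec[2] = last_ev.timestamp.weekday()
        vec[3] = times[-1] - times[0]
        vec[4] = gap_prev
        vec[5] = dominant_history[-1] if dominant_history else dominant
        vec[6] = dominant_history[-2] if len(dominant_history) >= 2 else vec[5]
        vec[7] = idxs[-1]
        vec[8] = locs[-1]
        vec[9] = last_motion_loc
        vec[10] = _entropy(counts)
        vec[11] = _rate(second_half) - _rate(first_half)
        vec[12] = transitions
        vec[13] = len(set(idxs.tolist()))
        vec[14 : 14 + S] = counts
        vec[14 + S :] = recency

        dominant_history.append(dominant)
        vectors.append(FeatureVector(vec, window_label(block_labels)))

    return vectors


def expected_window_count(n_vectors: int, T: int, step: int) -> int:
    """Number of fully-contained sliding windows: floor((N-T)/step) + 1."""
    if n_vectors < T:
        return 0
    return (n_vectors - T) // step + 1


def make_sliding_windows(
    vectors: Sequence[FeatureVector] | np.ndarray,
    T: int = 10,
    overlap: float = 0.5,
    labels: Sequence[str | None] | None = None,
) -> WindowedDataset:
    """Cut a feature-vector sequence into overlapping windows of length ``T``.

    ``overlap`` in [0, 1); the stride is ``round(T * (1 - overlap))``,
    at least 1 (5 for the default ``T=10, overlap=0.5``). Each window's
    label is the label of its last feature vector.
    """
    if not 0 <= overlap < 1:
        raise ValueError("overlap must lie in [0, 1)")
    step = max(1, round(T * (1 - overlap)))
    if isinstance(vectors, np.ndarray):
        X = np.asarray(vectors, dtype=np.float64)
        labs = list(labels) if labels is not None else [None] * len(X)
    else:
        X = np.stack([fv.values for fv in vectors]) if len(vectors) else np.empty((0, 0))
        labs = [fv.label for fv in vectors]
    N = len(X)
    n = expected_window_count(N, T, step)
    if n == 0:
        logger.warning("fewer vectors (%d) than window length (%d): empty dataset", N, T)
        F = X.shape[1] if X.ndim == 2 and X.shape[1] else 0
        return WindowedDataset(np.empty((0, T, F)), np.empty((0,), dtype=object))
    starts = np.arange(n) * step
    data = np.stack([X[s : s + T] for s in starts])
    win_labels = np.array([labs[s + T - 1] for s in starts], dtype=object)
    return WindowedDataset(data, win_labels)


@dataclass
class Standardizer:
    """Per-feature z-scoring with statistics frozen on the training split."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, dataset: WindowedDataset) -> "Standardizer":
        flat = dataset.data.reshape(-1, dataset.n_features)
        mean = flat.mean(axis=0)
        sd = flat.std(axis=0)  # population sd
        # a channel whose spread is rounding noise relative to its level is
        # constant; unit scale maps it to ~0 instead of amplifying the noise
        const = sd < STANDARDIZE_SD_FLOOR * (1.0 + np.abs(mean))
        if const.any():
            logger.warning("%d constant feature channel(s); sd floored",
                           int(const.sum()))
        return cls(mean, np.where(const, 1.0, sd))

    def transform(self, dataset: WindowedDataset) -> WindowedDataset:
        return WindowedDataset(
            (dataset.data - self.mean) / self.sd, dataset.labels, dataset.split_tag
        )


def standardize(
    dataset: WindowedDataset, reference_stats: Standardizer
) -> WindowedDataset:
    """Apply training-split statistics to any split (no leakage)."""
    return reference_stats.transform(dataset)


def split_dataset(
    dataset: WindowedDataset,
    proportions: tuple[float, float, float],
    seed: int,
) -> tuple[WindowedDataset, WindowedDataset, WindowedDataset]:
    """Random disjoint, exhaustive train/val/test split, reproducible by seed."""
    if not np.isclose(sum(proportions), 1.0):
        raise ValueError(f"proportions must sum to 1, got {proportions}")
    rng = np.random.default_rng(seed)
    n = len(dataset)
    perm = rng.permutation(n)
    n_train = int(round(proportions[0] * n))
    n_val = int(round(proportions[1] * n))
    n_val = min(n_val, n - n_train)
    parts = (
        dataset.take(np.sort(perm[:n_train]), "train"),
        dataset.take(np.sort(perm[n_train : n_train + n_val]), "val"),
        dataset.take(np.sort(perm[n_train + n_val :]), "test"),
    )
    return parts


def subsample_label_fraction(
    dataset: WindowedDataset, fraction: float, seed: int
) -> WindowedDataset:
    """Draw ``floor(fraction * n)`` labeled windows for semi-supervised runs."""
    if not 0 < fraction <= 1:
        raise ValueError("label fraction must lie in (0, 1]")
    labeled = dataset.labeled_subset()
    if fraction == 1.0:
        return labeled
    rng = np.random.default_rng(seed)
    k = int(np.floor(fraction * len(labeled)))
    if k == 0:
        raise ValueError(f"label fraction {fraction} yields zero labeled windows")
    idx = np.sort(rng.choice(len(labeled), size=k, replace=False))
    sub = labeled.take(idx)
    kept_classes = {lab for lab in sub.labels}
    missing = {lab for lab in labeled.labels} - kept_classes
    if missing:
        logger.warning("label fraction %.3g lost class(es): %s", fraction, sorted(missing))
    return sub


def vectors_to_frame(vectors: Sequence[FeatureVector]) -> pd.DataFrame:
    """Feature vectors as a columnar table (one row per vector, label column)."""
    if not vectors:
        return pd.DataFrame()
    X = np.stack([fv.values for fv in vectors])
    df = pd.DataFrame(X, columns=[f"f{i+1}" for i in range(X.shape[1])])
    df["label"] = [fv.label for fv in vectors]
    return df
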