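"""Feature extraction, windowing, standardization, and splitting."""

from datetime import datetime, timedelta

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from homeclr.casas import Modality, SensorEvent, SensorMap
from homeclr.features import (
    Standardizer,
    expected_window_count,
    feature_dimension,
    featurize,
    make_sliding_windows,
    split_dataset,
    subsample_label_fraction,
    window_label,
)


def _map_of(n_sensors: int) -> SensorMap:
    return SensorMap(
        {f"M{i:03d}": (f"Room{i % 3}", Modality.motion) for i in range(1, n_sensors + 1)}
    )


def _stream(sensor_ids, start=datetime(2024, 1, 3, 8, 0, 0), gap_s=2.0, label="Relax"):
    events = []
    for i, sid in enumerate(sensor_ids):
        ts = start + timedelta(seconds=i * gap_s)
        events.append((SensorEvent(ts, sid, "ON"), label))
    return events


class TestFeaturize:
    @pytest.mark.parametrize("n_sensors,expected", [(35, 84), (33, 80), (10, 34)])
    def test_vector_length_is_2s_plus_14(self, n_sensors, expected):
        assert feature_dimension(n_sensors) == expected
        smap = _map_of(n_sensors)
        ids = smap.sensor_ids
        stream = _stream([ids[i % n_sensors] for i in range(30)])
        (vec,) = featurize(stream, smap)
        assert len(vec.values) == expected

    def test_single_sensor_block_degenerate_features(self):
        smap = _map_of(5)
        stream = _stream(["M001"] * 30)
        (vec,) = featurize(stream, smap)
        assert vec.values[10] == 0.0  # entropy of a point mass
        assert vec.values[13] == 1.0  # one distinct sensor
        assert vec.values[14] == 30.0  # that sensor's count
        assert vec.values[12] == 0.0  # no location transitions

    @pytest.mark.parametrize("k", [2, 3, 5, 6])
    def test_uniform_block_entropy_matches_brute_force(self, k):
        smap = _map_of(k)
        ids = smap.sensor_ids
        reps = 30 // k
        stream = _stream([sid for sid in ids for _ in range(reps)][:30])
        (vec,) = featurize(stream[: reps * k], smap, event_window_len=reps * k)
        p = np.full(k, 1 / k)
        brute = -(p * np.log(p)).sum()
        assert vec.values[10] == pytest.approx(brute)
        assert vec.values[10] == pytest.approx(np.log(k))

    def test_counts_sum_to_block_length(self, labeled_events, sensor_map):
        vectors = featurize(labeled_events[:900], sensor_map)
        S = len(sensor_map)
        for vec in vectors:
            counts = vec.values[14 : 14 + S]
            assert counts.sum() == 30
            assert np.all(counts == np.round(counts)) and np.all(counts >= 0)

    def test_trailing_partial_block_dropped(self):
        smap = _map_of(3)
        stream = _stream(["M001"] * 75)
        assert len(featurize(stream, smap)) == 2

    def test_unknown_sensor_is_an_error(self):
        smap = _map_of(3)
        stream = _stream(["M001"] * 29 + ["M099"])
        with pytest.raises(KeyError, match="M099"):
            featurize(stream, smap)

    def test_time_features_of_last_event(self):
        smap = _map_of(3)
        start = datetime(2024, 1, 3, 8, 0, 0)  # a Wednesday
        stream = _stream(["M001"] * 30, start=start, gap_s=2.0)
        (vec,) = featurize(stream, smap)
        last = start + timedelta(seconds=29 * 2.0)
        assert vec.values[0] == last.hour
        assert vec.values[1] == last.hour * 3600 + last.minute * 60 + last.second
        assert vec.values[2] == 2  # Wednesday
        assert vec.values[3] == pytest.approx(58.0)  # block duration
        assert vec.values[4] == pytest.approx(2.0)  # gap to previous event


class TestWindowLabel:
    def test_unanimous(self):
        assert window_label(["Relax"] * 30) == "Relax"

    def test_majority(self):
        assert window_label(["Relax"] * 16 + ["Eating"] * 14) == "Relax"

    def test_tie_broken_by_last_event(self):
        labels = ["Relax"] * 15 + ["Eating"] * 15
        assert labels[-1] == "Eating"
        assert window_label(labels) == "Eating"

    def test_all_unlabeled(self):
        assert window_label([None] * 30) is None

    def test_nones_do_not_vote(self):
        assert window_label([None] * 28 + ["Work", None]) == "Work"


class TestSlidingWindows:
    def brute_force_starts(self, N, T, step):
        return [s for s in range(0, N + 1) if s % step == 0 and s + T <= N]

    @given(
        N=st.integers(0, 200),
        T=st.integers(1, 20),
        step=st.integers(1, 10),
    )
    @settings(max_examples=200, deadline=None)
    def test_count_matches_enumeration(self, N, T, step):
        assert expected_window_count(N, T, step) == len(self.brute_force_starts(N, T, step))

    def test_count_for_the_reference_corpus(self):
        # 731,106 feature vectors, window 10, 50% overlap -> 146,220 windows
        assert expected_window_count(731_106, 10, 5) == 146_220

    @pytest.mark.parametrize("N,expected", [(10, 1), (14, 1), (15, 2), (9, 0)])
    def test_small_counts(self, N, expected):
        X = np.arange(N * 3, dtype=float).reshape(N, 3)
        ds = make_sliding_windows(X, T=10, overlap=0.5)
        assert len(ds) == expected

    def test_window_contents_and_labels(self):
        X = np.arange(15, dtype=float).reshape(15, 1)
        labels = [f"L{i}" for i in range(15)]
        ds = make_sliding_windows(X, T=10, overlap=0.5, labels=labels)
        assert np.array_equal(ds.data[0, :, 0], np.arange(10))
        assert np.array_equal(ds.data[1, :, 0], np.arange(5, 15))
        assert list(ds.labels) == ["L9", "L14"]  # label of the last vector

    def test_invalid_overlap_rejected(self):
        with pytest.raises(ValueError):
            make_sliding_windows(np.zeros((20, 2)), T=10, overlap=1.0)


class TestStandardize:
    def test_closed_form_z_scores(self):
        data = np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1)
        ds = make_sliding_windows(data.reshape(3, 1), T=1, overlap=0.0)
        stats = Standardizer.fit(ds)
        z = stats.transform(ds).data.ravel()
        assert z == pytest.approx([-1.224745, 0.0, 1.224745], abs=1e-6)

    def test_idempotent_on_standardized_data(self, splits):
        train, _ = splits
        stats = Standardizer.fit(train)
        once = stats.transform(train)
        again = Standardizer.fit(once).transform(once)
        assert np.allclose(once.data, again.data, atol=1e-9)

    def test_constant_channel_maps_to_zero(self):
        ds = make_sliding_windows(np.full((12, 2), 7.0), T=4, overlap=0.0)
        z = Standardizer.fit(ds).transform(ds)
        assert np.allclose(z.data[:, :, 0], 0.0)

    def test_train_stats_standardize_train_split(self, splits):
        train, _ = splits
        flat = train.data.reshape(-1, train.n_features)
        sd = flat.std(axis=0)
        assert np.allclose(flat.mean(axis=0), 0.0, atol=1e-6)
        # non-degenerate channels have unit spread
        assert np.allclose(sd[sd > 1e-6], 1.0, atol=1e-6)


class TestSplit:
    def _toy(self, n=100):
        X = np.arange(n * 2, dtype=float).reshape(n, 1, 2)
        labels = np.array([f"c{i % 3}" for i in range(n)], dtype=object)
        from homeclr.features import WindowedDataset

        return WindowedDataset(X, labels)

    def test_disjoint_exhaustive_reproducible(self):
        ds = self._toy()
        a = split_dataset(ds, (0.6, 0.2, 0.2), seed=5)
        b = split_dataset(ds, (0.6, 0.2, 0.2), seed=5)
        sizes = [len(part) for part in a]
        assert sum(sizes) == len(ds)
        rows = np.concatenate([part.data[:, 0, 0] for part in a])
        assert sorted(rows.tolist()) == sorted(ds.data[:, 0, 0].tolist())
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.data, pb.data)

    def test_everything_in_train(self):
        ds = self._toy()
        train, val, test = split_dataset(ds, (1.0, 0.0, 0.0), seed=0)
        assert len(train) == len(ds) and len(val) == 0 and len(test) == 0

    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(self._toy(), (0.5, 0.2, 0.2), seed=0)

    def test_label_fraction_subsample_floor(self):
        ds = self._toy(1000)
        sub = subsample_label_fraction(ds, 0.011, seed=0)
        assert len(sub) == 11  # floor(0.011 * 1000)
        # the reference corpus arithmetic: 1% of 146,220 windows
        assert int(np.floor(0.01 * 146_220)) == 1462

    def test_full_fraction_keeps_all_labeled(self):
        ds = self._toy(50)
        assert len(subsample_label_fraction(ds, 1.0, seed=0)) == 50
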