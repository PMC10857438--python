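"""CASAS log parsing, cleaning, label propagation, and round-trips."""

import io
from datetime import datetime

import pytest

from homeclr.casas import (
    MalformedLineError,
    Marker,
    Modality,
    ParseReport,
    SensorEvent,
    SensorMap,
    clean_events,
    load_sensor_map,
    packaged_sensor_map,
    parse_casas_log,
    propagate_activity_labels,
    remap_milan_activities,
    write_casas_log,
)

# the published sample rows of a raw annotated log
SAMPLE_LOG = """\
2010-11-04 08:33:52.929406 M018 ON Meal_Preparation begin
2010-11-04 08:33:53.911115 M019 OFF
2010-11-04 08:33:54.892943 M017 ON
2010-11-04 08:33:57.253739 M018 OFF
2010-11-04 08:35:43.498813 M019 OFF
2010-11-04 08:35:44.246428 M019 ON
2010-11-04 08:35:45.822482 M018 OFF Meal_Preparation end
"""


class TestParse:
    def test_sample_log_shape(self):
        events = parse_casas_log(io.StringIO(SAMPLE_LOG))
        assert len(events) == 7
        assert events[0].marker is Marker.begin
        assert events[-1].marker is Marker.end
        assert all(ev.marker is None and ev.activity is None for ev in events[1:-1])

    def test_annotated_line_fields(self):
        (ev,) = parse_casas_log(
            io.StringIO("2010-11-04 08:33:52.929406 M018 ON Meal_Preparation begin\n")
        )
        assert ev.sensor_id == "M018"
        assert ev.state == "ON"
        assert ev.activity == "Meal_Preparation"
        assert ev.marker is Marker.begin
        assert ev.timestamp == datetime(2010, 11, 4, 8, 33, 52, 929406)

    def test_empty_stream(self):
        assert parse_casas_log(io.StringIO("")) == []

    def test_colon_fraction_dialect_normalized(self):
        (ev,) = parse_casas_log(io.StringIO("2010-11-04 08:33:52:929406 M018 ON\n"))
        assert ev.timestamp.microsecond == 929406

    @pytest.mark.parametrize(
        "line,reason_part",
        [
            ("2010-11-04 08:33:52.929406 M018 ON Meal_Preparation", "5-field"),
            ("2010-11-04 08:33:52.929406 M018", "expected 4-6"),
            ("2010-13-04 08:33:52.929406 M018 ON", "unparseable"),
            ("2010-11-04 08:33:52.929406 M018 ON Meal_Preparation middle", "unknown activity status"),
        ],
    )
    def test_malformed_lines_rejected(self, line, reason_part):
        report = ParseReport()
        assert parse_casas_log(io.StringIO(line + "\n"), report=report) == []
        assert len(report) == 1
        assert reason_part in report.rejects[0][2]
        with pytest.raises(MalformedLineError):
            parse_casas_log(io.StringIO(line + "\n"), strict=True)

    def test_bare_activity_tolerated_when_configured(self):
        line = "2010-11-04 08:33:52.929406 M018 ON Meal_Preparation\n"
        (ev,) = parse_casas_log(io.StringIO(line), allow_bare_activity=True)
        assert ev.activity == "Meal_Preparation" and ev.marker is None

    def test_roundtrip_is_identity(self, tmp_path):
        events = parse_casas_log(io.StringIO(SAMPLE_LOG))
        path = tmp_path / "log.txt"
        write_casas_log(events, path)
        again = parse_casas_log(path)
        assert again == events
        # write . parse . write is a byte fixpoint
        path2 = tmp_path / "log2.txt"
        write_casas_log(again, path2)
        assert path.read_bytes() == path2.read_bytes()


class TestClean:
    def _ev(self, sec, sensor="M001", state="ON"):
        return SensorEvent(datetime(2024, 1, 1, 0, 0, sec), sensor, state)

    def test_exact_duplicates_removed(self):
        ev = self._ev(1)
        assert clean_events([ev, ev]) == [ev]

    def test_duplicate_is_timestamp_sensor_state_triple(self):
        base = self._ev(1)
        annotated = SensorEvent(base.timestamp, "M001", "ON", "Relax", Marker.begin)
        assert len(clean_events([base, annotated])) == 1

    def test_temperature_events_dropped(self):
        events = [self._ev(1), self._ev(2, sensor="T003", state="21.5")]
        assert clean_events(events) == [events[0]]

    def test_sorts_by_time_stable(self):
        a, b = self._ev(2), self._ev(1, sensor="M002")
        assert clean_events([a, b]) == [b, a]

    def test_idempotent_on_clean_stream(self):
        events = [self._ev(1), self._ev(2, "M002"), self._ev(3, "D001", "OPEN")]
        once = clean_events(events)
        assert once == events
        assert clean_events(once) == once


class TestPropagate:
    def _ev(self, sec, activity=None, marker=None):
        return SensorEvent(datetime(2024, 1, 1, 0, 0, sec), "M001", "ON", activity, marker)

    def test_sample_log_fully_labeled(self):
        events = parse_casas_log(io.StringIO(SAMPLE_LOG))
        labeled = propagate_activity_labels(events)
        assert [lab for _, lab in labeled] == ["Meal_Preparation"] * 7

    def test_no_markers_no_labels(self):
        events = [self._ev(i) for i in range(4)]
        assert [lab for _, lab in propagate_activity_labels(events)] == [None] * 4

    def test_sequential_brackets_with_gap(self):
        # begin(A), 3 events, end(A), 2 events, begin(B), end(B)
        events = (
            [self._ev(0, "A", Marker.begin)]
            + [self._ev(i) for i in (1, 2, 3)]
            + [self._ev(4, "A", Marker.end)]
            + [self._ev(i) for i in (5, 6)]
            + [self._ev(7, "B", Marker.begin), self._ev(8, "B", Marker.end)]
        )
        labels = [lab for _, lab in propagate_activity_labels(events)]
        assert labels == ["A", "A", "A", "A", "A", None, None, "B", "B"]

    def test_interleaved_brackets_innermost_wins(self):
        events = [
            self._ev(0, "A", Marker.begin),
            self._ev(1, "B", Marker.begin),
            self._ev(2),
            self._ev(3, "B", Marker.end),
            self._ev(4),
            self._ev(5, "A", Marker.end),
        ]
        labels = [lab for _, lab in propagate_activity_labels(events)]
        assert labels == ["A", "B", "B", "B", "A", "A"]

    def test_unmatched_begin_closed_at_stream_end(self):
        events = [self._ev(0, "A", Marker.begin), self._ev(1), self._ev(2)]
        labels = [lab for _, lab in propagate_activity_labels(events)]
        assert labels == ["A", "A", "A"]

    def test_end_without_begin_unlabeled(self):
        events = [self._ev(0), self._ev(1, "A", Marker.end)]
        labels = [lab for _, lab in propagate_activity_labels(events)]
        assert labels == [None, None]

    def test_preserves_count_and_order(self):
        events = parse_casas_log(io.StringIO(SAMPLE_LOG))
        labeled = propagate_activity_labels(events)
        assert [ev for ev, _ in labeled] == events


class TestMilanRemap:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("Kitchen_Activity", "Meal_Preparation"),
            ("Kitchen Activity", "Meal_Preparation"),
            ("Morning_Meds", "Medication"),
            ("Eve_Meds", "Medication"),
            ("Read", "Relax"),
            ("Watch_TV", "Relax"),
            ("Master_Bathrm", "Other"),  # unknown spelling falls back to Other
            ("Meditate", "Other"),
            ("Dining_Rm_Activity", "Eating"),
            ("Relax", "Relax"),  # already canonical
            (None, "Other"),  # idle time
        ],
    )
    def test_mapping(self, raw, expected):
        assert remap_milan_activities(raw) == expected

    def test_unknown_label_can_raise(self):
        with pytest.raises(KeyError):
            remap_milan_activities("Jazzercise", on_unknown="raise")


class TestSensorMap:
    def test_packaged_aruba_map_has_35_sensors(self):
        m = packaged_sensor_map("aruba")
        assert len(m) == 35
        assert m.location("M018") == "Kitchen"
        assert m.modality("D001") is Modality.door

    def test_modality_must_match_prefix(self):
        with pytest.raises(ValueError, match="contradicts"):
            SensorMap({"M001": ("Kitchen", Modality.door)})

    def test_duplicate_sensor_rejected(self):
        tsv = "M001\tKitchen\tmotion\nM001\tOffice\tmotion\n"
        with pytest.raises(ValueError, match="duplicate"):
            load_sensor_map(io.StringIO(tsv))

    def test_non_temperature_filter(self):
        m = SensorMap(
            {
                "M001": ("Kitchen", Modality.motion),
                "T001": ("Kitchen", Modality.temperature),
            }
        )
        assert m.non_temperature().sensor_ids == ["M001"]
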