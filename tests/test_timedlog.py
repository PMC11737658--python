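"""Log dialect: serialization, parsing, filters, intervals, performance."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from domekit.timedlog import (
    LineType,
    LogConversionError,
    LogParseError,
    LogRecord,
    SessionHeader,
    StateInterval,
    StimulusSettings,
    StimulusType,
    extract_state_intervals,
    extract_trajectory,
    parse_log,
    parse_record,
    performance_summary,
    serialize_record,
    verbosity_types,
    write_log,
)

# -- strategies: values representable in the dialect (7-decimal grid) -------

q7 = st.integers(min_value=-(10**10), max_value=10**10).map(lambda n: n / 10**7)
q7pos = st.integers(min_value=0, max_value=10**10).map(lambda n: n / 10**7)
names = st.text(alphabet="abcdefghijklmnopqrstuvwxyzABC_", min_size=1, max_size=12)


@st.composite
def records(draw):
    t = draw(q7pos)
    oid = draw(st.integers(min_value=0, max_value=10**6))
    lt = draw(st.sampled_from(list(LineType)))
    if lt is LineType.EVENT_MARKER:
        payload = (draw(st.integers(0, 0xFFFF)), draw(q7))
    elif lt is LineType.INPUT:
        payload = (draw(q7), draw(q7), draw(q7))
    elif lt is LineType.POSITION:
        n = draw(st.sampled_from([4, 6]))
        payload = tuple(draw(q7) for _ in range(n))
    elif lt in (LineType.STATE_ENTER, LineType.STATE_EXIT):
        payload = (draw(names),)
    elif lt is LineType.FRAME:
        payload = (draw(st.integers(0, 10**6)), draw(q7))
    elif lt is LineType.CUSTOM:
        payload = (draw(st.text(alphabet="abc xyz0123", min_size=1, max_size=30).map(str.strip).filter(bool)),)
    else:  # stimulus
        stype = draw(st.sampled_from(list(StimulusType)))
        settings_ = StimulusSettings(
            stimulus_type=stype,
            scale=draw(st.integers(1, 10**8).map(lambda n: n / 10**7)),
            height=draw(q7),
            hide=draw(st.booleans()),
            type_params=(
                (sorted(  # one legal parameter with a safe value
                    __import__("domekit.timedlog", fromlist=["STIMULUS_PARAM_KEYS"]).STIMULUS_PARAM_KEYS[stype]
                )[0], draw(names)),
            ),
        )
        payload = (settings_, draw(q7), draw(q7), draw(q7))
    return LogRecord(t, oid, lt, payload)


class TestSerialization:
    def test_event_marker_line_has_five_columns(self):
        rec = LogRecord(1.5, 2, LineType.EVENT_MARKER, (42, 1.4))
        assert len(serialize_record(rec).split("\t")) == 5

    def test_input_line_has_six_columns(self):
        rec = LogRecord(1.5, 2, LineType.INPUT, (0.1, -0.2, 3.0))
        assert len(serialize_record(rec).split("\t")) == 6

    def test_every_line_has_at_least_four_columns(self):
        for lt, payload in [
            (LineType.STATE_ENTER, ("Correct",)),
            (LineType.CUSTOM, ("note",)),
            (LineType.FRAME, (3, 0.05)),
            (LineType.POSITION, (1.0, 2.0, 3.0, 90.0)),
        ]:
            assert len(serialize_record(LogRecord(0.0, 1, lt, payload)).split("\t")) >= 4

    def test_unknown_line_type_rejected_by_name(self):
        rec = LogRecord(0.0, 1, "BOGUS", ("x",))
        with pytest.raises(ValueError, match="BOGUS"):
            serialize_record(rec)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(records())
    def test_round_trip_identity(self, rec):
        line = serialize_record(rec)
        back = parse_record(line)
        assert back == rec
        assert serialize_record(back) == line

    def test_stimulus_round_trip(self):
        s = StimulusSettings(StimulusType.GRATING, scale=2.0, type_params=(("spatial_frequency", "0.5"),))
        rec = LogRecord(1.0, 9, LineType.STIMULUS_CREATE, (s, 10.0, 0.0, -3.0))
        assert parse_record(serialize_record(rec)) == rec

    def test_illegal_stimulus_parameter_rejected(self):
        with pytest.raises(ValueError, match="spatial_frequency"):
            StimulusSettings(StimulusType.IMAGE, type_params=(("spatial_frequency", "1"),))


def _make_log(records, verbosity=None, **header_kw):
    header = SessionHeader(
        level_start_time="2025-01-16T00:00:00",
        subject="s1",
        experimenter="e1",
        experiment="exp",
        level_name="lvl",
        **header_kw,
    )
    buf = io.StringIO()
    write_log(buf, header, records, verbosity=verbosity)
    buf.seek(0)
    return buf


class TestParsing:
    def test_parse_returns_written_records(self, clean_session):
        buf = io.StringIO(clean_session.log_text())
        parsed = parse_log(buf, convert=False)
        recs = parsed.records()
        assert recs == clean_session.records
        assert parsed.header.subject == "synthetic"

    def test_type_filter_keeps_only_requested(self, clean_session):
        buf = io.StringIO(clean_session.log_text())
        recs = parse_log(buf, line_types={LineType.EVENT_MARKER}, convert=False).records()
        assert recs
        assert {r.line_type for r in recs} == {LineType.EVENT_MARKER}

    def test_object_filter(self, clean_session):
        buf = io.StringIO(clean_session.log_text())
        recs = parse_log(buf, object_ids={1}, convert=False).records()
        assert recs and all(r.object_id == 1 for r in recs)

    def test_malformed_line_reports_line_number(self):
        buf = _make_log([LogRecord(0.0, 1, LineType.CUSTOM, ("ok",))])
        text = buf.getvalue() + "not\ta\tvalid\n"
        with pytest.raises(LogParseError, match="line 8"):
            parse_log(io.StringIO(text), convert=False).records()

    def test_convert_without_frames_is_an_error(self):
        buf = _make_log([LogRecord(0.0, 1, LineType.CUSTOM, ("ok",))])
        with pytest.raises(LogConversionError, match="FRAME"):
            parse_log(buf, convert=True)

    def test_converted_times_match_ground_truth_within_quantum(self, clean_session):
        gt = clean_session.ground_truth
        buf = io.StringIO(clean_session.log_text())
        parsed = parse_log(buf, line_types={LineType.EVENT_MARKER}, convert=True)
        checked = 0
        for rec in parsed:
            if rec.time_approx:
                continue
            k = int(np.searchsorted(gt.queue_time, rec.payload[1] + 1e-9, side="right")) - 1
            assert abs(rec.game_time - gt.display_time[k]) <= 1e-7
            checked += 1
        assert checked > 300

    def test_verbosity_zero_is_a_state_and_marker_subset(self, clean_session):
        full = clean_session.log_text()
        abbrev = clean_session.log_text(verbosity=0)
        full_lines = set(l for l in full.splitlines() if not l.startswith("#"))
        ab_lines = [l for l in abbrev.splitlines() if not l.startswith("#")]
        assert ab_lines and set(ab_lines) <= full_lines
        kept = {l.split("\t")[2] for l in ab_lines}
        assert kept <= {"STATE_ENTER", "STATE_EXIT", "EVENT_MARKER"}
        assert "STATE_ENTER" in kept

    def test_max_verbosity_equals_continuous(self, clean_session):
        assert clean_session.log_text(verbosity=3) == clean_session.log_text()

    def test_verbosity_levels_nest(self):
        assert verbosity_types(0) < verbosity_types(1) < verbosity_types(2) < verbosity_types(3)


class TestTrajectory:
    def _pos(self, t, oid, x):
        return LogRecord(t, oid, LineType.POSITION, (x, 0.0, 0.0, 0.0))

    def test_unit_steps_give_path_length(self):
        recs = [self._pos(i * 0.01, 1, float(i)) for i in range(51)]
        traj = extract_trajectory(recs, 1)
        path = sum(
            np.linalg.norm(np.subtract(b.position, a.position))
            for a, b in zip(traj, traj[1:])
        )
        assert path == pytest.approx(50.0)

    def test_stationary_object_constant(self):
        recs = [self._pos(i * 0.01, 1, 2.5) for i in range(10)]
        traj = extract_trajectory(recs, 1)
        assert all(s.position == traj[0].position for s in traj)

    def test_interleaved_objects_partition(self, rng):
        recs = []
        for i in range(200):
            oid = int(rng.integers(1, 3))
            recs.append(self._pos(i * 0.01, oid, float(rng.normal())))
        for oid in (1, 2):
            expected = [r for r in recs if r.object_id == oid]
            traj = extract_trajectory(recs, oid)
            assert len(traj) == len(expected)
            assert [s.time for s in traj] == [r.game_time for r in expected]
            assert [s.position[0] for s in traj] == [r.payload[0] for r in expected]

    def test_unknown_object_warns_and_returns_empty(self):
        recs = [self._pos(0.0, 1, 0.0)]
        with pytest.warns(UserWarning, match="object 99"):
            assert extract_trajectory(recs, 99) == []


def _state(t, oid, lt, name):
    return LogRecord(t, oid, lt, (name,))


class TestStateIntervals:
    def test_simple_pair(self):
        recs = [
            _state(10.0, 1, LineType.STATE_ENTER, "Correct"),
            _state(10.5, 1, LineType.STATE_EXIT, "Correct"),
        ]
        (iv,) = extract_state_intervals(recs)
        assert (iv.state_name, iv.enter_time, iv.exit_time) == ("Correct", 10.0, 10.5)

    def test_block_containing_three_trials(self):
        recs = [_state(0.0, 1, LineType.STATE_ENTER, "Block")]
        for i in range(3):
            recs.append(_state(1.0 + i, 2, LineType.STATE_ENTER, "Trial"))
            recs.append(_state(1.5 + i, 2, LineType.STATE_EXIT, "Trial"))
        recs.append(_state(10.0, 1, LineType.STATE_EXIT, "Block"))
        ivs = extract_state_intervals(recs)
        blocks = [iv for iv in ivs if iv.state_name == "Block"]
        trials = [iv for iv in ivs if iv.state_name == "Trial"]
        assert len(blocks) == 1 and len(trials) == 3
        assert all(blocks[0].enter_time <= t.enter_time and t.exit_time <= blocks[0].exit_time for t in trials)

    def test_unmatched_exit_is_an_error(self):
        recs = [_state(1.0, 1, LineType.STATE_EXIT, "Ghost")]
        with pytest.raises(LogParseError, match="Ghost"):
            extract_state_intervals(recs)

    def test_truncated_file_leaves_open_interval_with_warning(self):
        recs = [_state(5.0, 1, LineType.STATE_ENTER, "Trial")]
        with pytest.warns(UserWarning, match="truncated"):
            (iv,) = extract_state_intervals(recs)
        assert iv.exit_time is None and iv.enter_time == 5.0


def _outcomes(names):
    return [
        StateInterval(n, float(i), float(i) + 0.5, 4) for i, n in enumerate(names)
    ]


class TestPerformance:
    def test_all_correct_window20(self):
        ivs = _outcomes(["CorrectResponse"] * 20)
        res = performance_summary(ivs, {"CorrectResponse", "Wrong"}, {"CorrectResponse"}, 20)
        assert res.series[-1] == 1.0
        assert res.counts == {"CorrectResponse": 20, "Wrong": 0}

    def test_half_correct_window20(self):
        ivs = _outcomes(["CorrectResponse"] * 10 + ["Wrong"] * 10)
        res = performance_summary(ivs, {"CorrectResponse", "Wrong"}, {"CorrectResponse"}, 20)
        assert res.series[-1] == pytest.approx(0.5)

    def test_matches_brute_force_on_random_sequences(self, rng):
        for _ in range(1000):
            n = int(rng.integers(1, 40))
            w = int(rng.integers(1, 25))
            seq = ["A" if rng.random() < 0.5 else "B" for _ in range(n)]
            res = performance_summary(_outcomes(seq), {"A", "B"}, {"A"}, w)
            brute = [
                np.mean([s == "A" for s in seq[max(0, i - w + 1) : i + 1]])
                for i in range(n)
            ]
            np.testing.assert_allclose(res.series, brute)

    def test_empty_input(self):
        res = performance_summary([], {"A"}, {"A"}, 5)
        assert res.series.size == 0 and res.counts == {"A": 0}

    def test_correct_must_be_subset(self):
        with pytest.raises(ValueError, match="subset"):
            performance_summary([], {"A"}, {"Z"}, 5)
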