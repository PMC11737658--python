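"""Screen-time conversion: fixed delay, frame table, skips, monotonicity."""

import numpy as np
import pytest

from domekit.simulate import SimulationParams, simulate_session
from domekit.timedlog import LineType, LogRecord
from domekit.timing import (
    FrameTable,
    TimingConfig,
    build_frame_table,
    convert_times,
    detect_frame_skips,
    fixed_display_delay,
    read_timing_config,
    to_screen_time,
    to_screen_time_checked,
    write_timing_config,
)


def _frame(t, idx, flip):
    return LogRecord(t, 0, LineType.FRAME, (idx, flip))


def _marker(t, mid, qpc):
    return LogRecord(t, 2, LineType.EVENT_MARKER, (mid, qpc))


class TestFixedDelay:
    @pytest.mark.parametrize(
        "rate,frames,delay,expected",
        [
            (100.0, 1, 0.0, 10.0),
            (60.0, 0, 0.0, 0.0),
            (59.952, 2, 18.0, 51.360),
        ],
    )
    def test_arithmetic(self, rate, frames, delay, expected):
        cfg = TimingConfig(rate, frames, delay)
        assert fixed_display_delay(cfg) == pytest.approx(expected, abs=5e-4)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TimingConfig(frame_rate_hz=0.0)


class TestFrameTable:
    def test_zero_offset_anchor_map_is_identity(self):
        frames = [_frame(0.1 + k * 0.01, k, 0.1 + k * 0.01) for k in range(10)]
        markers = [_marker(0.105 + k * 0.01, 40000, 0.105 + k * 0.01) for k in range(10)]
        table = build_frame_table(frames, markers)
        assert table.clock_offset() == pytest.approx(0.0, abs=1e-9)
        assert table.game_to_qpc(0.123) == pytest.approx(0.123, abs=1e-9)

    def test_constant_offset_recovered(self):
        offset = 5.0
        frames = [_frame(offset + k * 0.01, k, k * 0.01) for k in range(10)]
        markers = [_marker(offset + 0.005 + k * 0.01, 40000, 0.005 + k * 0.01) for k in range(10)]
        table = build_frame_table(frames, markers)
        assert table.clock_offset() == pytest.approx(5.0, abs=1e-12)

    def test_table_may_start_at_frame_three(self):
        frames = [_frame(0.1 + k * 0.01, k, 0.1 + k * 0.01) for k in range(2, 12)]
        table = build_frame_table(frames)
        assert table.first_frame == 2

    def test_non_monotone_flips_rejected(self):
        frames = [_frame(0.0, 0, 0.2), _frame(0.01, 1, 0.1)]
        with pytest.raises(ValueError, match="increasing"):
            build_frame_table(frames)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError, match="2 FRAME"):
            build_frame_table([_frame(0.0, 0, 0.0)])


class TestSkipDetection:
    def test_doubled_interval_flagged(self):
        flips = np.cumsum([0.0, 0.01668, 0.01668, 0.03336, 0.01668])
        frames = [_frame(f, k, f) for k, f in enumerate(flips)]
        table = build_frame_table(frames)
        cfg = TimingConfig(frame_rate_hz=1.0 / 0.01668)
        assert detect_frame_skips(table, cfg).tolist() == [2]

    def test_nominal_intervals_give_empty(self):
        flips = np.arange(10) * 0.01668
        table = build_frame_table([_frame(f, k, f) for k, f in enumerate(flips)])
        cfg = TimingConfig(frame_rate_hz=1.0 / 0.01668)
        assert detect_frame_skips(table, cfg).size == 0

    def test_detected_set_equals_injected_set(self):
        p = SimulationParams(n_frames=2000, skip_probability=0.02, noise_sd_fraction=0.0, seed=5)
        s = simulate_session(p)
        frames = [r for r in s.records if r.line_type is LineType.FRAME]
        table = build_frame_table(frames)
        detected = set(detect_frame_skips(table, p.timing).tolist())
        injected = {int(k) for k in s.ground_truth.skip_frames}
        # the table starts at frame 2, so earlier injected skips are invisible
        injected = {k for k in injected if k >= 2}
        # the last frame's interval is unobservable
        injected.discard(p.n_frames - 1)
        assert detected == injected


class TestToScreenTime:
    def test_identity_configuration(self):
        cfg = TimingConfig(frame_rate_hz=100.0, pipeline_frames=0, display_delay_ms=0.0)
        frames = [_frame(k * 0.01, k, k * 0.01) for k in range(10)]
        table = build_frame_table(frames)
        assert to_screen_time(0.03, table, cfg) == pytest.approx(0.03, abs=1e-12)

    def test_mid_frame_event_gets_frame_display_time(self, clean_session, default_config):
        s = clean_session
        gt = s.ground_truth
        frames = [r for r in s.records if r.line_type is LineType.FRAME]
        markers = [r for r in s.records if r.line_type is LineType.EVENT_MARKER]
        table = build_frame_table(frames, markers)
        for k in (5, 50, 200):
            mid = gt.marker_game_time[k]  # mid-frame event of frame k
            st = to_screen_time(mid, table, default_config)
            assert st == pytest.approx(gt.display_time[k], abs=1e-7)

    def test_event_in_stuck_frame_is_one_period_late(self):
        cfg = TimingConfig(frame_rate_hz=100.0, pipeline_frames=0, display_delay_ms=0.0)
        period = 0.01
        # identical sessions except frame 5 is stuck
        flips_clean = np.cumsum([0.0] + [period] * 9)
        intervals = [period] * 9
        intervals[5] = 2 * period
        flips_skip = np.cumsum([0.0] + intervals)
        t_clean = build_frame_table([_frame(f, k, f) for k, f in enumerate(flips_clean)])
        t_skip = build_frame_table([_frame(f, k, f) for k, f in enumerate(flips_skip)])
        # an event in (stuck) frame 6's preparation window
        ev_clean = flips_clean[6] + 0.004
        ev_skip = flips_skip[6] + 0.004
        late = to_screen_time(ev_skip, t_skip, cfg) - to_screen_time(ev_clean, t_clean, cfg)
        assert late == pytest.approx(period, abs=1e-12)

    def test_exactness_on_clean_in_memory_table(self, clean_session, default_config):
        """Conversion is exact (<= 1e-9 s) against the simulator's unserialized truth."""
        gt = clean_session.ground_truth
        frames = [
            LogRecord(gt.queue_time[k], 0, LineType.FRAME, (k, gt.queue_time[k]))
            for k in range(gt.queue_time.size)
        ]
        table = build_frame_table(frames)
        screen, exact = convert_times(gt.marker_game_time, table, default_config)
        assert exact.all()
        np.testing.assert_allclose(screen, gt.display_time, atol=1e-9)

    def test_monotone_in_game_time(self, noisy_skip_session, default_config):
        frames = [r for r in noisy_skip_session.records if r.line_type is LineType.FRAME]
        table = build_frame_table(frames)
        t0 = table.prep_game_time[0]
        ts = np.sort(np.random.default_rng(0).uniform(t0, table.prep_game_time[-1], 500))
        screen, _ = convert_times(ts, table, default_config)
        assert np.all(np.diff(screen) >= 0)

    def test_pre_table_event_flagged_approximate(self, clean_session, default_config):
        frames = [r for r in clean_session.records if r.line_type is LineType.FRAME]
        markers = [r for r in clean_session.records if r.line_type is LineType.EVENT_MARKER]
        table = build_frame_table(frames, markers)
        early = table.prep_game_time[0] - 0.02
        value, exact = to_screen_time_checked(early, table, default_config)
        assert not exact
        # the fallback still lands near the truth: delay plus clock map
        assert value == pytest.approx(early + fixed_display_delay(default_config) / 1000.0, abs=0.05)


def test_config_file_round_trip(tmp_path):
    cfg = TimingConfig(59.952, 2, 18.0)
    path = tmp_path / "timing.cfg"
    write_timing_config(cfg, path)
    assert read_timing_config(path) == cfg
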