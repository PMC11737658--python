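"""Game-time to screen-time conversion.

The engine's game thread runs ahead of the display: a frame is prepared,
handed to the swap chain, scanned out ``pipeline_frames`` refresh periods
later, and finally shown by the projector after a further fixed
``display_delay_ms``.  The log records, for each frame, the game-thread
time at which its preparation started and the high-resolution (QPC)
timestamp at which it was handed over; an event logged at game time ``t``
therefore appeared on screen at::

    screen(t) = flip_timestamp(frame whose preparation interval contains t)
                + pipeline_frames / frame_rate + display_delay

Frame skips (stuck frames shown for twice the nominal period) stall the
game thread and the handover together, so the doubled interval is present
in the logged timestamps and converted times follow skips exactly.

Event markers carry both a game-thread time and a QPC timestamp; those
pairs anchor a piecewise-linear monotone map between the two clocks, used
for events logged before frame timing is available (the first two game
frames) and for diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .timedlog import LineType, LogRecord

__all__ = [
    "TimingConfig",
    "FrameTable",
    "fixed_display_delay",
    "build_frame_table",
    "detect_frame_skips",
    "to_screen_time",
    "to_screen_time_checked",
    "convert_times",
    "read_timing_config",
    "write_timing_config",
]


@dataclass(frozen=True)
class TimingConfig:
    """Display-timing model of a setup.

    Defaults describe a 59.952 Hz projector-dome rig with a two-frame
    rendering pipeline (the multi-camera dome capture needs two frames) and
    an 18 ms projector delay.
    """

    frame_rate_hz: float = 59.952
    pipeline_frames: int = 2
    display_delay_ms: float = 18.0

    def __post_init__(self) -> None:
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.pipeline_frames < 0:
            raise ValueError("pipeline_frames must be non-negative")
        if self.display_delay_ms < 0:
            raise ValueError("display_delay_ms must be non-negative")

    @property
    def frame_period_ms(self) -> float:
        return 1000.0 / self.frame_rate_hz

    @property
    def frame_period_s(self) -> float:
        return 1.0 / self.frame_rate_hz


def fixed_display_delay(config: TimingConfig) -> float:
    """The fixed preparation-to-screen delay, milliseconds.

    ``pipeline_frames`` refresh periods plus the projector/display delay;
    e.g. two frames at 59.952 Hz plus 18 ms gives 51.360 ms.
    """
    return config.pipeline_frames * config.frame_period_ms + config.display_delay_ms


@dataclass
class FrameTable:
    """Per-frame preparation times and graphics timestamps.

    ``prep_game_time[k]`` opens frame ``frame_index[k]``'s preparation
    interval (half-open, closed by the next frame's entry);
    ``flip_timestamp[k]`` is that frame's QPC handover timestamp.  Marker
    anchors give the monotone game-clock -> QPC map.
    """

    frame_index: np.ndarray
    prep_game_time: np.ndarray
    flip_timestamp: np.ndarray
    anchor_game: np.ndarray
    anchor_qpc: np.ndarray

    def __post_init__(self) -> None:
        if len(self.frame_index) < 2:
            raise ValueError("a frame table needs at least 2 frames")
        if np.any(np.diff(self.flip_timestamp) <= 0):
            raise ValueError("flip timestamps must be strictly increasing")
        if np.any(np.diff(self.frame_index) != 1):
            raise ValueError("frame indices must be contiguous from the first logged frame")

    @property
    def first_frame(self) -> int:
        return int(self.frame_index[0])

    def flip_intervals(self) -> np.ndarray:
        """On-screen duration of each frame but the last, seconds."""
        return np.diff(self.flip_timestamp)

    def game_to_qpc(self, game_time):
        """Piecewise-linear monotone map between the game and QPC clocks.

        Linear extrapolation beyond the outermost anchors.  With no (or a
        single) anchor the map falls back to the frame records themselves.
        """
        g, q = self.anchor_game, self.anchor_qpc
        if g.size < 2:
            # No usable anchors: fall back to the frame records, which pin
            # the clock offset (prep and handover share it) but not drift.
            g = self.prep_game_time
            q = self.prep_game_time - (self.prep_game_time[0] - self.flip_timestamp[0])
        t = np.asarray(game_time, dtype=float)
        out = np.interp(t, g, q)
        # linear extrapolation at the edges
        lo = t < g[0]
        hi = t > g[-1]
        if np.any(lo):
            slope = (q[1] - q[0]) / (g[1] - g[0])
            out = np.where(lo, q[0] + (t - g[0]) * slope, out)
        if np.any(hi):
            slope = (q[-1] - q[-2]) / (g[-1] - g[-2])
            out = np.where(hi, q[-1] + (t - g[-1]) * slope, out)
        return out if out.ndim else float(out)

    def clock_offset(self) -> float:
        """Median game-clock minus QPC-clock offset over the anchors, s."""
        if self.anchor_game.size == 0:
            return float(np.median(self.prep_game_time - self.flip_timestamp))
        return float(np.median(self.anchor_game - self.anchor_qpc))


def build_frame_table(
    frame_records: Sequence[LogRecord], marker_records: Sequence[LogRecord] = ()
) -> FrameTable:
    """Assemble a :class:`FrameTable` from FRAME and EVENT_MARKER records.

    Frame timing is logged only from the third game frame onward, so the
    table may legitimately start at frame index 2.
    """
    frames = [r for r in frame_records if r.line_type is LineType.FRAME]
    if len(frames) < 2:
        raise ValueError(f"need at least 2 FRAME records, got {len(frames)}")
    frames.sort(key=lambda r: r.payload[0])
    idx = np.array([r.payload[0] for r in frames], dtype=int)
    prep = np.array([r.game_time for r in frames], dtype=float)
    flips = np.array([r.payload[1] for r in frames], dtype=float)
    anchors = [
        (r.game_time, r.payload[1])
        for r in marker_records
        if r.line_type is LineType.EVENT_MARKER
    ]
    anchors.sort()
    ag = np.array([a[0] for a in anchors], dtype=float)
    aq = np.array([a[1] for a in anchors], dtype=float)
    # deduplicate identical game times (np.interp requires increasing x)
    if ag.size:
        keep = np.concatenate([[True], np.diff(ag) > 0])
        ag, aq = ag[keep], aq[keep]
    return FrameTable(idx, prep, flips, ag, aq)


def detect_frame_skips(table: FrameTable, config: TimingConfig) -> np.ndarray:
    """Frame indices of stuck frames.

    A frame whose on-screen interval exceeds 1.5x the nominal period (the
    midpoint between one and two periods, robust to jitter far below half a
    period) is reported; an interval near 2x the period is one skip.
    """
    intervals = table.flip_intervals()
    stuck = intervals > 1.5 * config.frame_period_s
    return table.frame_index[:-1][stuck]


def to_screen_time_checked(game_time: float, table: FrameTable, config: TimingConfig) -> tuple[float, bool]:
    """Screen time plus an exactness flag.

    Events inside the tabulated span inherit their frame's actual handover
    timestamp (so stuck frames carry their events along); the flag is True.
    Events before the first tabulated frame fall back to the anchor map
    plus the fixed delay, flagged False (approximate).
    """
    delay_s = fixed_display_delay(config) / 1000.0
    prep = table.prep_game_time
    if game_time < prep[0]:
        return float(table.game_to_qpc(game_time)) + delay_s, False
    k = int(np.searchsorted(prep, game_time, side="right")) - 1
    return float(table.flip_timestamp[k]) + delay_s, True


def to_screen_time(game_time: float, table: FrameTable, config: TimingConfig) -> float:
    """On-screen time (QPC clock, seconds) of an event at ``game_time``."""
    return to_screen_time_checked(game_time, table, config)[0]


def convert_times(times, table: FrameTable, config: TimingConfig):
    """Vectorized :func:`to_screen_time`; returns ``(screen_times, exact_mask)``."""
    t = np.asarray(times, dtype=float)
    delay_s = fixed_display_delay(config) / 1000.0
    k = np.searchsorted(table.prep_game_time, t, side="right") - 1
    exact = k >= 0
    out = np.empty_like(t)
    out[exact] = table.flip_timestamp[np.maximum(k[exact], 0)] + delay_s
    if np.any(~exact):
        out[~exact] = np.asarray(table.game_to_qpc(t[~exact])) + delay_s
    return out, exact


# --------------------------------------------------------------------------
# Key/value config files (used by the CLI)

_CONFIG_KEYS = ("frame_rate_hz", "pipeline_frames", "display_delay_ms")


def read_timing_config(path) -> TimingConfig:
    """Read a ``key: value`` timing-config file; missing keys keep defaults."""
    values: dict[str, float] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if ":" not in line:
                raise ValueError(f"malformed config line {raw!r}")
            k, v = (s.strip() for s in line.split(":", 1))
            if k not in _CONFIG_KEYS:
                raise ValueError(f"unknown timing config key {k!r}")
            values[k] = float(v)
    if "pipeline_frames" in values:
        values["pipeline_frames"] = int(values["pipeline_frames"])  # type: ignore[assignment]
    return TimingConfig(**values)  # type: ignore[arg-type]


def write_timing_config(config: TimingConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"frame_rate_hz: {config.frame_rate_hz}\n")
        fh.write(f"pipeline_frames: {config.pipeline_frames}\n")
        fh.write(f"display_delay_ms: {config.display_delay_ms}\n")
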