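"""Synthetic session generator.

Produces a complete, hardware-free session: the plain-text log, the
acquisition-side 16-bit marker channel, a 30 kHz photodiode voltage trace,
and the ground-truth display times -- so the whole
parse -> convert -> verify pipeline can be exercised and checked end to end.

Timing model
------------
Frame ``k`` is handed to the swap chain at QPC time ``F_k``; scanout starts
``pipeline_frames`` refresh periods later and the projector shows it after
``true_display_delay_ms`` more, so its true display time is::

    D_k = F_k + pipeline_frames / frame_rate + true_display_delay

Handover ticks are one nominal period apart except at frame skips (stuck
frames: doubled interval; drawn per frame with ``skip_probability`` and
forced after every injected pause) and pauses (the screen is black while
the game is paused and ticks stall for the pause duration).  The game
thread prepares frame ``k`` during ``[F_k, F_{k+1})``, read on a game clock
offset from QPC by ``clock_offset_s``.

A brightness object steps through the flicker pattern 1, 0.3, 1, 0 on each
frame (0.5 while idle, black during pauses) and emits an event marker at
every switch; markers reach the acquisition board with zero latency plus an
optional jitter knob (default 0).  The photodiode converts brightness to
voltage through an affine map (black 0 V, full 2 V) and a first-order rise
(time constant ``rise_tau_ms``), with additive Gaussian noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .photodiode import MarkerChannel, PhotodiodeTrace
from .stimuli import BRIGHTNESS_MARKER_BASE, FLICKER_PATTERN, IDLE_BRIGHTNESS, flicker_sequence
from .timedlog import LineType, LogRecord, SessionHeader, write_log
from .timing import TimingConfig

__all__ = [
    "SimulationParams",
    "GroundTruth",
    "SyntheticSession",
    "simulate_session",
    "synthesize_photodiode",
    "PLAYER_OBJECT_ID",
    "BRIGHTNESS_OBJECT_ID",
    "SESSION_MACHINE_ID",
    "TRIAL_MACHINE_ID",
]

PLAYER_OBJECT_ID = 1
BRIGHTNESS_OBJECT_ID = 2
SESSION_MACHINE_ID = 3
TRIAL_MACHINE_ID = 4


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions of a synthetic session.

    Defaults reproduce the reference dome rig: 59.952 Hz refresh, two-frame
    rendering pipeline, 18 ms projector delay, 30 kHz acquisition, photodiode
    noise 2% of full amplitude with a 0.5 ms rise, and a 2% per-frame skip
    probability; 4400 frames give >= 1000 analyzed 1->0 transitions.
    """

    n_frames: int = 4400
    timing: TimingConfig = field(default_factory=TimingConfig)
    skip_probability: float = 0.02
    pauses: tuple[tuple[int, int], ...] = ()
    clock_offset_s: float = 0.0
    true_display_delay_ms: float = 18.0
    sample_rate_hz: float = 30000.0
    noise_sd_fraction: float = 0.02
    rise_tau_ms: float = 0.5
    marker_jitter_ms: float = 0.0
    amplitude_v: float = 2.0
    lead_in_s: float = 0.25
    seed: int = 0
    outcome_sequence: tuple[str, ...] = ()
    correct_state: str = "CorrectResponse"

    def __post_init__(self) -> None:
        if self.n_frames < 3:
            raise ValueError("n_frames must be >= 3 (frame timing starts at the 3rd frame)")
        if not 0.0 <= self.skip_probability <= 1.0:
            raise ValueError("skip_probability must be in [0, 1]")
        if self.noise_sd_fraction < 0 or self.rise_tau_ms < 0:
            raise ValueError("noise and rise tau must be non-negative")
        for frame, n_pause in self.pauses:
            if not 0 <= frame < self.n_frames - 2:
                raise ValueError(f"pause frame {frame} outside the session")
            if n_pause < 1:
                raise ValueError("pause length must be >= 1 frame")


@dataclass
class GroundTruth:
    """True per-frame timing of a synthetic session (QPC clock, seconds)."""

    queue_time: np.ndarray
    display_time: np.ndarray
    brightness: np.ndarray
    skip_frames: np.ndarray
    pauses: tuple[tuple[int, int], ...]
    marker_game_time: np.ndarray
    marker_qpc: np.ndarray
    marker_sample: np.ndarray
    marker_id: np.ndarray

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("frame\tqueue_time\tdisplay_time\tbrightness\tstuck\n")
            stuck = set(int(s) for s in self.skip_frames)
            for k in range(self.queue_time.size):
                fh.write(
                    f"{k}\t{self.queue_time[k]:.7f}\t{self.display_time[k]:.7f}"
                    f"\t{self.brightness[k]:.7f}\t{1 if k in stuck else 0}\n"
                )


@dataclass
class SyntheticSession:
    params: SimulationParams
    header: SessionHeader
    records: list[LogRecord]
    markers: MarkerChannel
    trace: PhotodiodeTrace
    ground_truth: GroundTruth

    def log_text(self, verbosity: int | None = None) -> str:
        import io

        buf = io.StringIO()
        write_log(buf, self.header, self.records, verbosity=verbosity)
        return buf.getvalue()

    def write(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "session.log", "w", encoding="utf-8") as fh:
            fh.write(self.log_text())
        self.markers.save(out / "markers.tsv")
        self.trace.save(out / "photodiode.tsv")
        self.ground_truth.save(out / "ground_truth.tsv")


def synthesize_photodiode(
    change_times,
    values,
    p: SimulationParams,
    rng: np.random.Generator | None = None,
    duration: float | None = None,
) -> PhotodiodeTrace:
    """Photodiode trace from a piecewise-constant luminance program.

    ``change_times`` (QPC seconds, increasing) and ``values`` (brightness in
    [0, 1]) describe the screen; each change is shifted by
    ``true_display_delay_ms``, converted to volts (0 V black,
    ``amplitude_v`` full), smoothed by a first-order rise of
    ``rise_tau_ms`` and sampled at ``sample_rate_hz`` with additive
    Gaussian noise of sd ``noise_sd_fraction * amplitude_v``.  The trace
    starts at QPC time 0 with the idle brightness.
    """
    change_times = np.asarray(change_times, dtype=float)
    values = np.asarray(values, dtype=float)
    if change_times.size != values.size:
        raise ValueError("change_times and values must have equal length")
    if np.any(np.diff(change_times) <= 0):
        raise ValueError("change times must be strictly increasing")
    if rng is None:
        rng = np.random.default_rng(p.seed)
    fs = p.sample_rate_hz
    shifted = change_times + p.true_display_delay_ms / 1000.0
    if change_times.size and p.rise_tau_ms > 0:
        min_gap = float(np.min(np.diff(shifted))) if change_times.size > 1 else np.inf
        if min_gap < 3 * p.rise_tau_ms / 1000.0:
            warnings.warn(
                f"transitions only {min_gap * 1000:.3f} ms apart overlap the "
                f"{p.rise_tau_ms} ms rise support",
                stacklevel=2,
            )
    if duration is None:
        duration = (shifted[-1] if shifted.size else 0.0) + 0.1
    n = int(np.floor(duration * fs))
    # brightness per sample; a change at time t first affects sample round(t*fs)
    change_samples = np.round(shifted * fs).astype(np.int64)
    levels = np.concatenate([[IDLE_BRIGHTNESS], values])
    idx = np.searchsorted(change_samples, np.arange(n), side="right")
    volts = p.amplitude_v * levels[idx]
    if p.rise_tau_ms > 0:
        alpha = float(np.exp(-1000.0 / (fs * p.rise_tau_ms)))
        zi = np.array([alpha * volts[0]])
        volts, _ = signal.lfilter([1 - alpha], [1, -alpha], volts, zi=zi)
    if p.noise_sd_fraction > 0:
        volts = volts + rng.normal(0.0, p.noise_sd_fraction * p.amplitude_v, size=n)
    return PhotodiodeTrace(volts, sample_rate_hz=fs, start_timestamp=0.0)


def _q(x: float) -> float:
    """Quantize to the log dialect's 7-decimal resolution, so in-memory
    records equal their serialized form exactly."""
    return round(float(x), 7)


def simulate_session(p: SimulationParams) -> SyntheticSession:
    """Generate a full synthetic session (deterministic in ``p.seed``)."""
    rng = np.random.default_rng(p.seed)
    cfg = p.timing
    period = cfg.frame_period_s
    n = p.n_frames

    # -- handover ticks -----------------------------------------------------
    skip = rng.random(n) < p.skip_probability
    pause_extra = np.zeros(n)
    pause_set = dict(p.pauses)
    for frame, n_pause in p.pauses:
        pause_extra[frame] = n_pause * period
        skip[frame + 1] = True  # the resume frame comes out stuck
    intervals = period * np.where(skip, 2.0, 1.0) + pause_extra
    queue = p.lead_in_s + np.concatenate([[0.0], np.cumsum(intervals[:-1])])
    prep = queue + p.clock_offset_s
    display = queue + cfg.pipeline_frames * period + p.true_display_delay_ms / 1000.0

    # -- brightness program and markers ------------------------------------
    brightness = flicker_sequence(n)
    phases = rng.uniform(0.05, 0.85, size=n)
    marker_game = prep + phases * intervals
    marker_qpc = marker_game - p.clock_offset_s
    if p.marker_jitter_ms > 0:
        arrival = marker_qpc + rng.normal(0.0, p.marker_jitter_ms / 1000.0, size=n)
    else:
        arrival = marker_qpc
    marker_sample = np.round(arrival * p.sample_rate_hz).astype(np.int64)
    marker_ids = BRIGHTNESS_MARKER_BASE + (np.arange(n) % len(FLICKER_PATTERN))

    # -- luminance changes seen by the photodiode ---------------------------
    change_t: list[float] = []
    change_v: list[float] = []
    for k in range(n):
        change_t.append(queue[k] + cfg.pipeline_frames * period)
        change_v.append(float(brightness[k]))
        if k in pause_set:
            # one refresh after frame k the pause frame (black) goes up
            change_t.append(queue[k] + period + cfg.pipeline_frames * period)
            change_v.append(0.0)
    end_time = queue[-1] + intervals[-1] + cfg.pipeline_frames * period + p.true_display_delay_ms / 1000.0
    trace = synthesize_photodiode(
        np.array(change_t), np.array(change_v), p, rng=rng, duration=end_time + 0.1
    )

    # -- log records --------------------------------------------------------
    records: list[LogRecord] = []
    records.append(
        LogRecord(_q(prep[0]), SESSION_MACHINE_ID, LineType.STATE_ENTER, ("Running",))
    )
    pos = np.zeros(3)
    heading = 0.0
    steps = rng.normal(0.0, 1.0, size=(n, 3))
    for k in range(n):
        if k >= 2:
            records.append(LogRecord(_q(prep[k]), 0, LineType.FRAME, (k, _q(queue[k]))))
        records.append(
            LogRecord(
                _q(marker_game[k]),
                BRIGHTNESS_OBJECT_ID,
                LineType.EVENT_MARKER,
                (int(marker_ids[k]), _q(marker_qpc[k])),
            )
        )
        fwd, side, drot = steps[k]
        records.append(
            LogRecord(_q(prep[k]), PLAYER_OBJECT_ID, LineType.INPUT, (_q(fwd), _q(side), _q(drot)))
        )
        heading += drot
        pos += np.array([fwd, side, 0.0])
        records.append(
            LogRecord(
                _q(prep[k]),
                PLAYER_OBJECT_ID,
                LineType.POSITION,
                (_q(pos[0]), _q(pos[1]), _q(pos[2]), _q(heading % 360.0)),
            )
        )
        if k in pause_set:
            t_pause = _q(prep[k] + period)
            records.append(LogRecord(t_pause, SESSION_MACHINE_ID, LineType.STATE_EXIT, ("Running",)))
            records.append(LogRecord(t_pause, SESSION_MACHINE_ID, LineType.STATE_ENTER, ("Paused",)))
            records.append(LogRecord(_q(prep[k + 1]), SESSION_MACHINE_ID, LineType.STATE_EXIT, ("Paused",)))
            records.append(LogRecord(_q(prep[k + 1]), SESSION_MACHINE_ID, LineType.STATE_ENTER, ("Running",)))
    if p.outcome_sequence:
        span = (prep[-1] - prep[0]) / len(p.outcome_sequence)
        for i, outcome in enumerate(p.outcome_sequence):
            t0 = prep[0] + i * span
            t1 = t0 + span
            records.append(LogRecord(_q(t0), TRIAL_MACHINE_ID, LineType.STATE_ENTER, ("Trial",)))
            records.append(LogRecord(_q(t0 + 0.25 * span), TRIAL_MACHINE_ID, LineType.STATE_ENTER, (outcome,)))
            records.append(LogRecord(_q(t1 - 0.25 * span), TRIAL_MACHINE_ID, LineType.STATE_EXIT, (outcome,)))
            records.append(LogRecord(_q(t1), TRIAL_MACHINE_ID, LineType.STATE_EXIT, ("Trial",)))
    records.append(
        LogRecord(_q(prep[-1] + intervals[-1]), SESSION_MACHINE_ID, LineType.STATE_EXIT, ("Running",))
    )
    records.sort(key=lambda r: r.game_time)

    header = SessionHeader(
        level_start_time="2025-01-16T00:00:00",
        subject="synthetic",
        experimenter="simulator",
        experiment="timing-verification",
        level_name="FlickerTest",
        verbosity=3,
        extra={
            "seed": str(p.seed),
            "rng": "numpy-PCG64",
            "frame_rate_hz": f"{cfg.frame_rate_hz}",
            "pipeline_frames": f"{cfg.pipeline_frames}",
            "display_delay_ms": f"{cfg.display_delay_ms}",
        },
    )
    markers = MarkerChannel(marker_sample, marker_ids)
    truth = GroundTruth(
        queue_time=queue,
        display_time=display,
        brightness=np.asarray(brightness, dtype=float),
        skip_frames=np.nonzero(skip)[0],
        pauses=p.pauses,
        marker_game_time=marker_game,
        marker_qpc=marker_qpc,
        marker_sample=marker_sample,
        marker_id=marker_ids,
    )
    return SyntheticSession(p, header, records, markers, trace, truth)
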