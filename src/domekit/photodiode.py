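"""Photodiode timing verification.

A photodiode fixed to the screen watches a brightness-switching object
whose every switch also emits an event marker.  Recorded transitions are
aligned to the screen times predicted from the log: for each analyzed
switch the trace is low-pass filtered (500 Hz, 4th-order Butterworth,
applied forward-backward so the filter adds no delay of its own), the time
of the maximum signal change inside a window around the predicted time is
located, and the residual (measured minus predicted, milliseconds) is
summarized by its median, 5th/95th percentiles and the fraction of
transitions within a tolerance.

The max-change statistic carries a small detection latency when the
physical edge is not a step: a first-order (RC) rise smeared by the filter
peaks slightly after the edge onset.  :func:`verify_session` removes this
latency with a noiseless forward model of the same instrument chain
(:func:`edge_detection_latency_ms`), so residuals measure timing, not
photodiode dynamics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import signal

from .stimuli import BRIGHTNESS_MARKER_BASE, FLICKER_PATTERN
from .timedlog import LineType, LogRecord
from .timing import TimingConfig, build_frame_table, convert_times

__all__ = [
    "PhotodiodeTrace",
    "MarkerChannel",
    "AlignmentStats",
    "design_lowpass",
    "lowpass_filter",
    "transition_residual",
    "edge_detection_latency_ms",
    "alignment_stats",
    "verify_session",
    "FALLING_MARKER_IDS",
]

#: Marker ids of switches to pattern value 0 coming from value 1 -- the
#: brightness change the alignment analysis uses.
FALLING_MARKER_IDS = frozenset(
    {
        BRIGHTNESS_MARKER_BASE + i
        for i in range(len(FLICKER_PATTERN))
        if FLICKER_PATTERN[i] == 0.0 and FLICKER_PATTERN[i - 1] == 1.0
    }
)


@dataclass
class PhotodiodeTrace:
    """A sampled photodiode voltage trace."""

    samples: np.ndarray
    sample_rate_hz: float = 30000.0
    start_timestamp: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate_hz

    def times(self) -> np.ndarray:
        return self.start_timestamp + np.arange(self.samples.size) / self.sample_rate_hz

    def save(self, path) -> None:
        """Two-column text: time (s) and voltage."""
        np.savetxt(path, np.column_stack([self.times(), self.samples]), fmt="%.7f")

    @classmethod
    def load(cls, path, sample_rate_hz: float | None = None) -> "PhotodiodeTrace":
        data = np.loadtxt(path)
        t, v = data[:, 0], data[:, 1]
        if sample_rate_hz is None:
            sample_rate_hz = 1.0 / float(np.median(np.diff(t)))
        return cls(v, sample_rate_hz=sample_rate_hz, start_timestamp=float(t[0]))


@dataclass
class MarkerChannel:
    """Event markers on the acquisition clock: sample index + 16-bit id."""

    sample_index: np.ndarray
    marker_id: np.ndarray

    def __post_init__(self) -> None:
        self.sample_index = np.asarray(self.sample_index, dtype=np.int64)
        self.marker_id = np.asarray(self.marker_id, dtype=np.int64)
        if self.sample_index.shape != self.marker_id.shape:
            raise ValueError("sample_index and marker_id must have equal length")
        if np.any(np.diff(self.sample_index) <= 0):
            raise ValueError("marker sample indices must be strictly increasing")
        if np.any((self.marker_id < 0) | (self.marker_id > 0xFFFF)):
            raise ValueError("marker ids must fit in 16 bits")

    def __len__(self) -> int:
        return self.sample_index.size

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("sample_index\tmarker_id\n")
            for s, m in zip(self.sample_index, self.marker_id):
                fh.write(f"{s}\t{m}\n")

    @classmethod
    def load(cls, path) -> "MarkerChannel":
        data = np.loadtxt(path, skiprows=1, dtype=np.int64, ndmin=2)
        return cls(data[:, 0], data[:, 1])


def design_lowpass(cutoff_hz: float, order: int, sample_rate_hz: float) -> np.ndarray:
    """Butterworth low-pass in second-order sections.

    The design has unit DC gain, |H| = 1/sqrt(2) at the cutoff and
    |H(f)| = 1/sqrt(1 + (f/fc)^(2*order)) elsewhere.
    """
    nyq = sample_rate_hz / 2.0
    if cutoff_hz >= nyq:
        raise ValueError(f"cutoff {cutoff_hz} Hz is not below Nyquist ({nyq} Hz)")
    return signal.butter(order, cutoff_hz, btype="low", fs=sample_rate_hz, output="sos")


def lowpass_filter(trace: PhotodiodeTrace, cutoff_hz: float = 500.0, order: int = 4) -> PhotodiodeTrace:
    """Zero-phase (forward-backward) Butterworth low-pass of a trace."""
    sos = design_lowpass(cutoff_hz, order, trace.sample_rate_hz)
    filtered = signal.sosfiltfilt(sos, trace.samples)
    return PhotodiodeTrace(filtered, trace.sample_rate_hz, trace.start_timestamp)


def transition_residual(
    trace: PhotodiodeTrace,
    predicted_time: float,
    window_ms: float = 5.0,
    polarity: str = "falling",
    noise_floor_factor: float = 5.0,
) -> float | None:
    """Residual of one brightness transition, milliseconds.

    Locates the extreme first difference of ``trace`` (pass the filtered
    trace) with the requested polarity inside ``predicted_time +/-
    window_ms`` and returns measured minus predicted time.  Returns None
    (missing) when no difference exceeds ``noise_floor_factor`` times the
    median absolute first difference of the window's outer-quarter flanks.
    """
    if polarity not in ("falling", "rising"):
        raise ValueError("polarity must be 'falling' or 'rising'")
    fs = trace.sample_rate_hz
    n = trace.samples.size
    half = window_ms / 1000.0
    i0 = int(np.ceil((predicted_time - half - trace.start_timestamp) * fs))
    i1 = int(np.floor((predicted_time + half - trace.start_timestamp) * fs))
    if i0 < 1 or i1 >= n:
        raise ValueError(
            f"window {predicted_time}s +/- {window_ms}ms extends outside the trace"
        )
    seg = trace.samples[i0 - 1 : i1 + 1]
    d = np.diff(seg)  # d[j] is the change arriving at sample i0 + j
    quarter = max(1, d.size // 4)
    flanks = np.concatenate([d[:quarter], d[-quarter:]])
    floor = noise_floor_factor * float(np.median(np.abs(flanks)))
    if polarity == "falling":
        j = int(np.argmin(d))
        magnitude = -d[j]
        opposite = float(np.max(d))
    else:
        j = int(np.argmax(d))
        magnitude = d[j]
        opposite = -float(np.min(d))
    # a real transition of the requested polarity must beat the noise floor
    # and dominate the opposite polarity (filter ringing of a wrong-polarity
    # edge never does)
    if magnitude <= floor or magnitude <= 0 or magnitude <= opposite:
        return None
    measured = trace.start_timestamp + (i0 + j) / fs
    return (measured - predicted_time) * 1000.0


@lru_cache(maxsize=32)
def edge_detection_latency_ms(
    sample_rate_hz: float,
    cutoff_hz: float = 500.0,
    order: int = 4,
    rise_tau_ms: float = 0.5,
) -> float:
    """Detection latency of the max-change statistic for a first-order edge.

    Computed from a noiseless forward model: an ideal unit step is passed
    through a discrete RC stage with time constant ``rise_tau_ms`` and the
    same zero-phase Butterworth filter, and the offset of the extreme first
    difference from the true edge sample is returned (ms).  Zero for
    ``rise_tau_ms = 0`` up to the filter's symmetric response.
    """
    fs = sample_rate_hz
    n = int(fs * 0.2)
    m = n // 2
    x = np.zeros(n)
    x[m:] = 1.0
    if rise_tau_ms > 0:
        alpha = float(np.exp(-1000.0 / (fs * rise_tau_ms)))
        y = signal.lfilter([1 - alpha], [1, -alpha], x)
    else:
        y = x
    sos = design_lowpass(cutoff_hz, order, fs)
    f = signal.sosfiltfilt(sos, y)
    d = np.diff(f)
    j = int(np.argmax(d))  # arrival sample of the extreme change is j + 1
    return ((j + 1) - m) / fs * 1000.0


@dataclass
class AlignmentStats:
    """Residual distribution of aligned transitions.

    Percentiles use linear interpolation between order statistics.
    ``n_missing`` counts analyzed markers with no detectable transition.
    """

    residuals: np.ndarray
    n_missing: int = 0
    median: float = field(init=False)
    p05: float = field(init=False)
    p95: float = field(init=False)

    def __post_init__(self) -> None:
        self.residuals = np.asarray(self.residuals, dtype=float)
        if self.residuals.size == 0:
            raise ValueError("alignment statistics need at least one residual")
        self.median = float(np.median(self.residuals))
        self.p05 = float(np.percentile(self.residuals, 5))
        self.p95 = float(np.percentile(self.residuals, 95))

    @property
    def n(self) -> int:
        return self.residuals.size

    def fraction_within(self, tol_ms: float) -> float:
        """Fraction of residuals with magnitude at most ``tol_ms``."""
        return float(np.mean(np.abs(self.residuals) <= tol_ms))

    def report(self) -> str:
        lines = [
            "statistic\tvalue",
            f"n\t{self.n}",
            f"n_missing\t{self.n_missing}",
            f"median_ms\t{self.median:.4f}",
            f"p05_ms\t{self.p05:.4f}",
            f"p95_ms\t{self.p95:.4f}",
            f"fraction_within_0.1667_ms\t{self.fraction_within(0.1667):.4f}",
            f"fraction_within_0.2_ms\t{self.fraction_within(0.2):.4f}",
        ]
        return "\n".join(lines) + "\n"


def alignment_stats(residuals: Iterable[float], n_missing: int = 0) -> AlignmentStats:
    """Summarize per-transition residuals (ms)."""
    return AlignmentStats(np.fromiter((float(r) for r in residuals), dtype=float), n_missing)


def _qpc_to_sample(qpc: np.ndarray, anchor_qpc: np.ndarray, anchor_sample: np.ndarray) -> np.ndarray:
    """Piecewise-linear QPC -> acquisition-sample map with edge extrapolation."""
    out = np.interp(qpc, anchor_qpc, anchor_sample)
    lo = qpc < anchor_qpc[0]
    hi = qpc > anchor_qpc[-1]
    if np.any(lo):
        s = (anchor_sample[1] - anchor_sample[0]) / (anchor_qpc[1] - anchor_qpc[0])
        out = np.where(lo, anchor_sample[0] + (qpc - anchor_qpc[0]) * s, out)
    if np.any(hi):
        s = (anchor_sample[-1] - anchor_sample[-2]) / (anchor_qpc[-1] - anchor_qpc[-2])
        out = np.where(hi, anchor_sample[-1] + (qpc - anchor_qpc[-1]) * s, out)
    return out


def verify_session(
    records: Sequence[LogRecord],
    markers: MarkerChannel,
    trace: PhotodiodeTrace,
    config: TimingConfig | None = None,
    *,
    analyzed_marker_ids: frozenset[int] | set[int] = FALLING_MARKER_IDS,
    polarity: str = "falling",
    window_ms: float = 5.0,
    cutoff_hz: float = 500.0,
    order: int = 4,
    rise_tau_ms: float = 0.5,
) -> AlignmentStats:
    """End-to-end timing verification of a session.

    Parameters
    ----------
    records : unconverted log records (the function performs its own
        screen-time conversion from the FRAME records).
    markers : the acquisition-side marker channel; its brightness-switch
        ids must match the log's EVENT_MARKER records one-to-one.
    trace : the raw photodiode trace (filtered internally).
    rise_tau_ms : photodiode rise time constant used to remove the
        max-change detection latency; 0 disables the correction.

    Markers logged before frame timing is available (the first two game
    frames) are excluded: their screen times would be approximate.
    """
    if config is None:
        config = TimingConfig()
    records = list(records)
    frame_records = [r for r in records if r.line_type is LineType.FRAME]
    marker_records = [r for r in records if r.line_type is LineType.EVENT_MARKER]
    table = build_frame_table(frame_records, marker_records)

    bright = [r for r in marker_records if BRIGHTNESS_MARKER_BASE <= r.payload[0] <= 0xFFFF]
    chan_mask = markers.marker_id >= BRIGHTNESS_MARKER_BASE
    chan_samples = markers.sample_index[chan_mask]
    chan_ids = markers.marker_id[chan_mask]
    log_ids = np.array([r.payload[0] for r in bright], dtype=np.int64)
    if log_ids.size != chan_ids.size or np.any(log_ids != chan_ids):
        raise ValueError(
            "marker channel does not match the log's brightness-switch markers "
            f"({chan_ids.size} recorded vs {log_ids.size} logged)"
        )
    if log_ids.size < 2:
        raise ValueError("need at least two matched markers to align clocks")

    marker_qpc = np.array([r.payload[1] for r in bright], dtype=float)
    game_times = np.array([r.game_time for r in bright], dtype=float)
    screen_qpc, exact = convert_times(game_times, table, config)

    latency = edge_detection_latency_ms(trace.sample_rate_hz, cutoff_hz, order, rise_tau_ms)
    filtered = lowpass_filter(trace, cutoff_hz, order)

    analyzed = np.array([mid in analyzed_marker_ids for mid in log_ids])
    residuals = []
    n_missing = 0
    half_samples = window_ms / 1000.0 * trace.sample_rate_hz
    pred_samples = _qpc_to_sample(screen_qpc, marker_qpc, chan_samples.astype(float))
    for i in np.nonzero(analyzed & exact)[0]:
        ps = pred_samples[i]
        if ps - half_samples < 1 or ps + half_samples >= trace.samples.size:
            n_missing += 1
            continue
        pred_time = trace.start_timestamp + ps / trace.sample_rate_hz
        r = transition_residual(filtered, pred_time, window_ms, polarity)
        if r is None:
            n_missing += 1
        else:
            residuals.append(r - latency)
    if not residuals:
        raise ValueError("no analyzable transitions found")
    return AlignmentStats(np.array(residuals), n_missing)
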