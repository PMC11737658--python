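"""Receptive-field mapping stimulus schedules in dome coordinates.

Three classical mapping paradigms are generated as per-frame schedules:

* a moving bar realized as a great-circle strip swept across the dome,
* Gaussian blobs flashed over a grid of dome locations,
* sparse noise: a few black/white squares per frame at random lattice sites.

Schedules are pure functions of their parameters and seed (NumPy PCG64 via
``numpy.random.default_rng``; the seed is recorded in each schedule) so that
a logged session can be regenerated bit-identically offline.

The module also owns the photodiode flicker convention: a brightness
object that steps through the 4-periodic pattern 1, 0.3, 1, 0 on each
running frame, showing 0.5 while idle, and emits an event marker at every
switch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import THETA_MAX_DEG, DomeDirection, dome_to_cartesian, polar_angle

__all__ = [
    "FLICKER_PATTERN",
    "IDLE_BRIGHTNESS",
    "BRIGHTNESS_MARKER_BASE",
    "flicker_sequence",
    "StimulusElement",
    "StimulusFrameEvent",
    "BarSweepParams",
    "bar_sweep_schedule",
    "FlashGridParams",
    "flash_grid_schedule",
    "SparseNoiseParams",
    "sparse_noise_schedule",
    "schedule_to_table",
]

#: Brightness values cycled by the photodiode flicker object, one per frame.
FLICKER_PATTERN: tuple[float, ...] = (1.0, 0.3, 1.0, 0.0)
#: Brightness shown before the state machine runs (and while it is stopped).
IDLE_BRIGHTNESS: float = 0.5
#: Event-marker id of a switch to pattern element k is BASE + k (16-bit safe).
BRIGHTNESS_MARKER_BASE: int = 40000


def flicker_sequence(n_frames: int) -> np.ndarray:
    """Brightness of the flicker object on each of ``n_frames`` running frames.

    Frame i shows ``FLICKER_PATTERN[i % 4]``; with no running frames the
    object simply stays at :data:`IDLE_BRIGHTNESS`.  Every element of the
    returned sequence is a brightness *switch* (consecutive pattern values
    always differ), each accompanied by marker ``BRIGHTNESS_MARKER_BASE +
    (i % 4)`` in a live session.
    """
    if n_frames < 0:
        raise ValueError("n_frames must be >= 0")
    pattern = np.array(FLICKER_PATTERN)
    return pattern[np.arange(n_frames) % len(pattern)]


@dataclass(frozen=True)
class StimulusElement:
    """One drawable element of a mapping frame.

    ``size`` is the strip width, blob sigma, or square side (degrees);
    ``value`` is an intensity in [0, 1] or a polarity (+1 white, -1 black).
    """

    azimuth: float
    elevation: float
    size: float
    value: float


@dataclass(frozen=True)
class StimulusFrameEvent:
    frame_index: int
    elements: tuple[StimulusElement, ...]


def _check_on_dome(az: float, el: float) -> None:
    theta = polar_angle(dome_to_cartesian(DomeDirection(az, el)))
    if theta > THETA_MAX_DEG + 1e-9:
        raise ValueError(
            f"dome position (az={az}, el={el}) lies {theta:.1f} deg from forward, "
            f"beyond the {THETA_MAX_DEG:.0f} deg dome coverage"
        )


# --------------------------------------------------------------------------
# Moving bar (sphere strip)


@dataclass(frozen=True)
class BarSweepParams:
    """A great-circle strip of fixed angular width swept across the dome.

    ``sweep_direction`` is the direction of motion in the (azimuth,
    elevation) plane (0 = rightward, 90 = upward); the strip is oriented
    orthogonally to its motion unless ``orientation`` says otherwise.  The
    center travels ``extent`` degrees at ``speed`` deg/s, starting at
    -extent/2 along the sweep axis.
    """

    orientation: float = 90.0
    sweep_direction: float = 0.0
    speed: float = 10.0
    strip_width: float = 2.0
    extent: float = 120.0
    frame_rate_hz: float = 59.952

    def __post_init__(self) -> None:
        if self.speed <= 0:
            raise ValueError("speed must be positive")
        if self.strip_width <= 0:
            raise ValueError("strip_width must be positive")
        if self.extent > 2 * THETA_MAX_DEG:
            raise ValueError(f"extent must be <= {2 * THETA_MAX_DEG:.0f} deg")


def bar_sweep_schedule(p: BarSweepParams) -> list[StimulusFrameEvent]:
    """Per-frame strip centers for one sweep.

    The logged quantity of interest is the strip's center point on each
    frame; it advances ``speed / frame_rate_hz`` degrees per frame along the
    sweep direction.
    """
    step = p.speed / p.frame_rate_hz
    n_frames = int(round(p.extent / step)) + 1
    if n_frames < 2:
        raise ValueError("extent and speed imply a sweep shorter than one frame")
    cosd = math.cos(math.radians(p.sweep_direction))
    sind = math.sin(math.radians(p.sweep_direction))
    events = []
    for i in range(n_frames):
        s = -p.extent / 2.0 + i * step
        az = s * cosd
        el = s * sind
        _check_on_dome(az, el)
        events.append(
            StimulusFrameEvent(
                frame_index=i,
                elements=(StimulusElement(az, el, p.strip_width, 1.0),),
            )
        )
    return events


# --------------------------------------------------------------------------
# Flashed Gaussian blobs


@dataclass(frozen=True)
class FlashGridParams:
    """Gaussian blobs flashed over an azimuth x elevation grid.

    The blob profile is a circular Gaussian in angular coordinates,
    truncated at 3 sigma.  Each location is flashed exactly once per
    repetition, in a seed-determined random order, for ``flash_frames``
    frames followed by ``gap_frames`` blank frames.
    """

    azimuths: tuple[float, ...] = (-40.0, -20.0, 0.0, 20.0, 40.0)
    elevations: tuple[float, ...] = (-20.0, 0.0, 20.0)
    sigma_deg: float = 2.0
    flash_frames: int = 6
    gap_frames: int = 6
    seed: int = 0
    repetitions: int = 1

    def __post_init__(self) -> None:
        if not self.azimuths or not self.elevations:
            raise ValueError("grid must be non-empty")
        if self.flash_frames < 1 or self.gap_frames < 0:
            raise ValueError("flash_frames >= 1 and gap_frames >= 0 required")
        for az in self.azimuths:
            for el in self.elevations:
                _check_on_dome(az, el)


def flash_grid_schedule(p: FlashGridParams) -> list[StimulusFrameEvent]:
    """Flash every grid location once per repetition in random order.

    The schedule spans ``len(grid) * repetitions * (flash_frames +
    gap_frames)`` frames; frames inside a gap carry no elements and are
    omitted from the event list.
    """
    rng = np.random.default_rng(p.seed)
    grid = [(az, el) for az in p.azimuths for el in p.elevations]
    slot = p.flash_frames + p.gap_frames
    events = []
    for rep in range(p.repetitions):
        order = rng.permutation(len(grid))
        for k, gi in enumerate(order):
            az, el = grid[gi]
            start = (rep * len(grid) + k) * slot
            for f in range(p.flash_frames):
                events.append(
                    StimulusFrameEvent(
                        frame_index=start + f,
                        elements=(StimulusElement(az, el, p.sigma_deg, 1.0),),
                    )
                )
    return events


# --------------------------------------------------------------------------
# Sparse noise


@dataclass(frozen=True)
class SparseNoiseParams:
    """Black/white squares at random dome-lattice locations.

    The lattice is anchored at (0, 0) with node spacing ``spacing_deg`` in
    azimuth and elevation, restricted to the dome coverage.  Each frame
    draws ``squares_per_frame`` distinct sites (without replacement) and an
    independent polarity per square; the background is intermediate gray.
    """

    square_size_deg: float = 4.0
    spacing_deg: float = 8.0
    squares_per_frame: int = 4
    polarities: tuple[int, ...] = (-1, 1)
    seed: int = 0
    max_eccentricity_deg: float = THETA_MAX_DEG

    def __post_init__(self) -> None:
        if self.squares_per_frame < 1:
            raise ValueError("squares_per_frame must be >= 1")
        if self.spacing_deg <= 0 or self.square_size_deg <= 0:
            raise ValueError("spacing and square size must be positive")
        if not self.polarities:
            raise ValueError("polarity set must be non-empty")

    def lattice(self) -> list[tuple[float, float]]:
        kmax = int(math.floor(self.max_eccentricity_deg / self.spacing_deg))
        sites = []
        for i in range(-kmax, kmax + 1):
            for j in range(-kmax, kmax + 1):
                az = i * self.spacing_deg
                el = j * self.spacing_deg
                if abs(el) > 90.0:
                    continue
                theta = polar_angle(dome_to_cartesian(DomeDirection(az, el)))
                if theta <= self.max_eccentricity_deg + 1e-9:
                    sites.append((az, el))
        return sites


def sparse_noise_schedule(p: SparseNoiseParams, n_frames: int) -> list[StimulusFrameEvent]:
    """Seeded sparse-noise schedule of ``n_frames`` frames."""
    sites = p.lattice()
    if not sites:
        raise ValueError("sparse-noise lattice is empty")
    if p.squares_per_frame > len(sites):
        raise ValueError(
            f"squares_per_frame={p.squares_per_frame} exceeds the {len(sites)}-site lattice"
        )
    rng = np.random.default_rng(p.seed)
    pol = np.array(p.polarities, dtype=float)
    events = []
    for f in range(n_frames):
        chosen = rng.choice(len(sites), size=p.squares_per_frame, replace=False)
        signs = pol[rng.integers(0, len(pol), size=p.squares_per_frame)]
        elements = tuple(
            StimulusElement(sites[c][0], sites[c][1], p.square_size_deg, s)
            for c, s in zip(chosen, signs)
        )
        events.append(StimulusFrameEvent(frame_index=f, elements=elements))
    return events


def schedule_to_table(events: list[StimulusFrameEvent]) -> str:
    """Serialize a schedule as a TSV table (one row per element)."""
    lines = ["frame\tazimuth\televation\tsize\tvalue"]
    for ev in events:
        for el in ev.elements:
            lines.append(
                f"{ev.frame_index}\t{el.azimuth:.7f}\t{el.elevation:.7f}\t{el.size:.7f}\t{el.value:.7f}"
            )
    return "\n".join(lines) + "\n"
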