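"""The plain-text session-log dialect: records, writer, streaming parser,
and behavioral summaries.

File layout
-----------
A log starts with a header block of ``# key: value`` lines (level start
time, subject, experimenter, experiment, level name, verbosity, plus free
extras), followed by one tab-separated line per logged event.  Every line
has at least four columns::

    game_time <TAB> object_id <TAB> LINE_TYPE <TAB> payload...

``game_time`` is seconds on the engine game-thread clock, printed with 7
decimals (the dialect's time resolution is therefore 0.1 microseconds).
``object_id`` is a stable non-negative integer identity.  Payload columns
depend on the line type:

=================  ==========================================================
EVENT_MARKER       marker id, high-resolution (QPC) timestamp  (5 columns)
INPUT              forward, sideways, rotation                 (6 columns)
POSITION           x, y, z, rotation [, dome azimuth, dome elevation]
STATE_ENTER/EXIT   state name
STIMULUS_CREATE/   stimulus type, scale, height, hide, x, y, z,
  DESTROY          then ``key=value`` type parameters
FRAME              frame index, graphics flip timestamp (QPC)
CUSTOM             free text (no tabs)
=================  ==========================================================

Two log flavors exist: the *continuous* log (everything) and an
*abbreviated* log controlled by a verbosity level 0-3.  Level 0 keeps only
state transitions and event markers; level 3 is identical to the continuous
log.

Game-thread times precede actual display; ``parse_log(convert=True)``
replaces them with on-screen times using :mod:`domekit.timing`.
"""

from __future__ import annotations

import enum
import io
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence, TextIO

import numpy as np

__all__ = [
    "LineType",
    "StimulusType",
    "StimulusSettings",
    "SessionHeader",
    "LogRecord",
    "StateInterval",
    "TrajectorySample",
    "PerformanceSummary",
    "LogParseError",
    "LogConversionError",
    "VERBOSITY_MAX",
    "verbosity_types",
    "serialize_record",
    "parse_record",
    "write_log",
    "read_header",
    "parse_log",
    "ParsedLog",
    "extract_trajectory",
    "extract_state_intervals",
    "performance_summary",
]

_TIME_FMT = "{:.7f}"
VERBOSITY_MAX = 3


class LogParseError(ValueError):
    """A malformed line or header; carries the 1-based line number."""

    def __init__(self, message: str, line_no: int | None = None):
        self.line_no = line_no
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)


class LogConversionError(ValueError):
    """Screen-time conversion was requested but is impossible."""


class LineType(enum.Enum):
    EVENT_MARKER = "EVENT_MARKER"
    INPUT = "INPUT"
    POSITION = "POSITION"
    STATE_ENTER = "STATE_ENTER"
    STATE_EXIT = "STATE_EXIT"
    STIMULUS_CREATE = "STIMULUS_CREATE"
    STIMULUS_DESTROY = "STIMULUS_DESTROY"
    FRAME = "FRAME"
    CUSTOM = "CUSTOM"


class StimulusType(enum.Enum):
    IMAGE = "IMAGE"
    MOVIE = "MOVIE"
    GRATING = "GRATING"
    MESH = "MESH"
    MULTIPLE = "MULTIPLE"


#: Legal ``type_params`` keys per stimulus type.
STIMULUS_PARAM_KEYS: dict[StimulusType, frozenset[str]] = {
    StimulusType.IMAGE: frozenset({"image_path"}),
    StimulusType.MOVIE: frozenset({"movie_path", "loop"}),
    StimulusType.GRATING: frozenset({"spatial_frequency", "orientation", "phase", "contrast"}),
    StimulusType.MESH: frozenset({"mesh_path"}),
    StimulusType.MULTIPLE: frozenset({"spacing", "count", "child_type"}),
}


@dataclass(frozen=True)
class StimulusSettings:
    """The master description of one stimulus.

    ``type_params`` holds the per-type parameters as strings (serialized
    verbatim into the log; keys must be legal for the stimulus type and
    neither keys nor values may contain whitespace, tabs, or '=').
    """

    stimulus_type: StimulusType
    scale: float = 1.0
    height: float = 0.0
    hide: bool = False
    type_params: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("stimulus scale must be positive")
        legal = STIMULUS_PARAM_KEYS[self.stimulus_type]
        for k, v in self.type_params:
            if k not in legal:
                raise ValueError(
                    f"parameter {k!r} is not legal for stimulus type {self.stimulus_type.value}"
                )
            for s in (k, v):
                if any(c in s for c in "\t\n ="):
                    raise ValueError(f"illegal character in stimulus parameter {k!r}")


@dataclass
class SessionHeader:
    level_start_time: str
    subject: str
    experimenter: str
    experiment: str
    level_name: str
    verbosity: int = VERBOSITY_MAX
    extra: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("level_start_time", "subject", "experimenter", "experiment", "level_name"):
            if not getattr(self, name):
                raise ValueError(f"header field {name!r} must be non-empty")
        if not 0 <= self.verbosity <= VERBOSITY_MAX:
            raise ValueError(f"verbosity must be in 0..{VERBOSITY_MAX}")


_HEADER_FIELDS = ("level_start_time", "subject", "experimenter", "experiment", "level_name", "verbosity")


@dataclass(frozen=True)
class LogRecord:
    """One typed line of the session log.

    ``payload`` is a tuple whose shape depends on ``line_type`` (see the
    module docstring).  ``time_is_screen``/``time_approx`` flag converted
    records and do not take part in equality or serialization.
    """

    game_time: float
    object_id: int
    line_type: LineType
    payload: tuple
    time_is_screen: bool = field(default=False, compare=False, repr=False)
    time_approx: bool = field(default=False, compare=False, repr=False)


@dataclass
class StateInterval:
    state_name: str
    enter_time: float
    exit_time: float | None
    machine_id: int

    @property
    def duration(self) -> float | None:
        if self.exit_time is None:
            return None
        return self.exit_time - self.enter_time


@dataclass(frozen=True)
class TrajectorySample:
    time: float
    position: tuple[float, float, float]
    rotation: float


def verbosity_types(level: int) -> frozenset[LineType]:
    """Line types kept by an abbreviated log at ``level``.

    0: state transitions + event markers; 1: adds stimuli; 2: adds frame,
    input and custom lines; 3: everything (identical to the continuous log).
    """
    types = {LineType.STATE_ENTER, LineType.STATE_EXIT, LineType.EVENT_MARKER}
    if level >= 1:
        types |= {LineType.STIMULUS_CREATE, LineType.STIMULUS_DESTROY}
    if level >= 2:
        types |= {LineType.FRAME, LineType.INPUT, LineType.CUSTOM}
    if level >= 3:
        types |= {LineType.POSITION}
    return frozenset(types)


# --------------------------------------------------------------------------
# Serialization


def _fmt(x: float) -> str:
    return _TIME_FMT.format(x)


def _serialize_stimulus(s: StimulusSettings, location: tuple[float, float, float]) -> list[str]:
    cols = [
        s.stimulus_type.value,
        _fmt(s.scale),
        _fmt(s.height),
        "1" if s.hide else "0",
        _fmt(location[0]),
        _fmt(location[1]),
        _fmt(location[2]),
    ]
    cols.extend(f"{k}={v}" for k, v in s.type_params)
    return cols


def serialize_record(record: LogRecord) -> str:
    """One tab-separated log line for ``record``; inverse of :func:`parse_record`."""
    if not isinstance(record.line_type, LineType):
        raise ValueError(f"unknown line type: {record.line_type!r}")
    if record.object_id < 0:
        raise ValueError("object_id must be non-negative")
    lt = record.line_type
    p = record.payload
    if lt is LineType.EVENT_MARKER:
        marker_id, ts = p
        if not 0 <= int(marker_id) <= 0xFFFF:
            raise ValueError("event marker id must fit in 16 bits")
        cols = [str(int(marker_id)), _fmt(ts)]
    elif lt is LineType.INPUT:
        fwd, side, rot = p
        cols = [_fmt(fwd), _fmt(side), _fmt(rot)]
    elif lt is LineType.POSITION:
        if len(p) not in (4, 6):
            raise ValueError("POSITION payload must be (x, y, z, rot[, az, el])")
        cols = [_fmt(v) for v in p]
    elif lt in (LineType.STATE_ENTER, LineType.STATE_EXIT):
        (name,) = p
        if not name or any(c in name for c in "\t\n"):
            raise ValueError("state name must be non-empty and tab-free")
        cols = [name]
    elif lt in (LineType.STIMULUS_CREATE, LineType.STIMULUS_DESTROY):
        settings, x, y, z = p
        cols = _serialize_stimulus(settings, (x, y, z))
    elif lt is LineType.FRAME:
        idx, flip = p
        cols = [str(int(idx)), _fmt(flip)]
    elif lt is LineType.CUSTOM:
        (text,) = p
        if "\t" in text or "\n" in text:
            raise ValueError("custom text may not contain tabs or newlines")
        cols = [text]
    else:  # pragma: no cover - enum is closed
        raise ValueError(f"unknown line type: {lt!r}")
    return "\t".join([_fmt(record.game_time), str(record.object_id), lt.value, *cols])


def _parse_stimulus(cols: Sequence[str], line_no: int):
    if len(cols) < 7:
        raise LogParseError("stimulus payload needs at least 7 columns", line_no)
    try:
        stype = StimulusType(cols[0])
    except ValueError:
        raise LogParseError(f"unknown stimulus type {cols[0]!r}", line_no) from None
    params = []
    for tok in cols[7:]:
        if "=" not in tok:
            raise LogParseError(f"malformed stimulus parameter {tok!r}", line_no)
        k, v = tok.split("=", 1)
        params.append((k, v))
    settings = StimulusSettings(
        stimulus_type=stype,
        scale=float(cols[1]),
        height=float(cols[2]),
        hide=cols[3] == "1",
        type_params=tuple(params),
    )
    return settings, float(cols[4]), float(cols[5]), float(cols[6])


def parse_record(line: str, line_no: int = 0) -> LogRecord:
    """Parse one log line; raises :class:`LogParseError` with the line number."""
    cols = line.rstrip("\n").split("\t")
    if len(cols) < 4:
        raise LogParseError(f"expected at least 4 columns, got {len(cols)}", line_no)
    try:
        game_time = float(cols[0])
        object_id = int(cols[1])
    except ValueError as exc:
        raise LogParseError(str(exc), line_no) from None
    try:
        lt = LineType(cols[2])
    except ValueError:
        raise LogParseError(f"unknown line type {cols[2]!r}", line_no) from None
    body = cols[3:]
    try:
        if lt is LineType.EVENT_MARKER:
            if len(body) != 2:
                raise LogParseError("EVENT_MARKER needs exactly 5 columns", line_no)
            payload: tuple = (int(body[0]), float(body[1]))
        elif lt is LineType.INPUT:
            if len(body) != 3:
                raise LogParseError("INPUT needs exactly 6 columns", line_no)
            payload = (float(body[0]), float(body[1]), float(body[2]))
        elif lt is LineType.POSITION:
            if len(body) not in (4, 6):
                raise LogParseError("POSITION needs 7 or 9 columns", line_no)
            payload = tuple(float(v) for v in body)
        elif lt in (LineType.STATE_ENTER, LineType.STATE_EXIT):
            if len(body) != 1:
                raise LogParseError(f"{lt.value} needs exactly 4 columns", line_no)
            payload = (body[0],)
        elif lt in (LineType.STIMULUS_CREATE, LineType.STIMULUS_DESTROY):
            payload = _parse_stimulus(body, line_no)
        elif lt is LineType.FRAME:
            if len(body) != 2:
                raise LogParseError("FRAME needs exactly 5 columns", line_no)
            payload = (int(body[0]), float(body[1]))
        else:  # CUSTOM
            payload = ("\t".join(body),)
    except LogParseError:
        raise
    except ValueError as exc:
        raise LogParseError(str(exc), line_no) from None
    return LogRecord(game_time, object_id, lt, payload)


# --------------------------------------------------------------------------
# Writing


def write_log(dest, header: SessionHeader, records: Iterable[LogRecord], verbosity: int | None = None) -> None:
    """Write a log file (or stream).

    ``verbosity=None`` writes the continuous log; otherwise the abbreviated
    log at that level (the header's stored verbosity is updated to match).
    """
    own = isinstance(dest, (str, Path))
    fh: TextIO = open(dest, "w", encoding="utf-8") if own else dest
    try:
        level = VERBOSITY_MAX if verbosity is None else verbosity
        keep = verbosity_types(level)
        fh.write(f"# level_start_time: {header.level_start_time}\n")
        fh.write(f"# subject: {header.subject}\n")
        fh.write(f"# experimenter: {header.experimenter}\n")
        fh.write(f"# experiment: {header.experiment}\n")
        fh.write(f"# level_name: {header.level_name}\n")
        fh.write(f"# verbosity: {level}\n")
        for k, v in header.extra.items():
            fh.write(f"# {k}: {v}\n")
        last_t = -np.inf
        for rec in records:
            if rec.line_type not in keep:
                continue
            if rec.game_time < last_t:
                raise ValueError(
                    f"records out of order: {rec.game_time} after {last_t} (game_time must be non-decreasing)"
                )
            last_t = rec.game_time
            fh.write(serialize_record(rec))
            fh.write("\n")
    finally:
        if own:
            fh.close()


# --------------------------------------------------------------------------
# Parsing


def _open_source(source):
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="utf-8"), True
    return source, False


def _read_header_lines(fh: TextIO) -> tuple[SessionHeader, int]:
    """Consume the header block; returns (header, lines consumed)."""
    fields: dict[str, str] = {}
    extra: dict[str, str] = {}
    n = 0
    while True:
        pos = fh.tell()
        line = fh.readline()
        if not line:
            break
        if not line.startswith("#"):
            fh.seek(pos)
            break
        n += 1
        body = line[1:].strip()
        if ":" not in body:
            raise LogParseError(f"malformed header line {line!r}", n)
        k, v = body.split(":", 1)
        k = k.strip()
        v = v.strip()
        if k in _HEADER_FIELDS:
            fields[k] = v
        else:
            extra[k] = v
    missing = [f for f in _HEADER_FIELDS if f != "verbosity" and f not in fields]
    if missing:
        raise LogParseError(f"header missing required fields: {missing}", n or 1)
    header = SessionHeader(
        level_start_time=fields["level_start_time"],
        subject=fields["subject"],
        experimenter=fields["experimenter"],
        experiment=fields["experiment"],
        level_name=fields["level_name"],
        verbosity=int(fields.get("verbosity", VERBOSITY_MAX)),
        extra=extra,
    )
    return header, n


def read_header(source) -> SessionHeader:
    """Read only the header block of a log."""
    fh, own = _open_source(source)
    try:
        header, _ = _read_header_lines(fh)
        return header
    finally:
        if own:
            fh.close()


class ParsedLog:
    """Streaming view of a parsed log: iterate to get :class:`LogRecord`s.

    Memory use is constant in the file size (plus, with ``convert=True``,
    one small table row per logged frame); nothing is retained unless the
    caller keeps it.
    """

    def __init__(self, header: SessionHeader, iterator: Iterator[LogRecord]):
        self.header = header
        self._iterator = iterator

    def __iter__(self) -> Iterator[LogRecord]:
        return self._iterator

    def records(self) -> list[LogRecord]:
        """Materialize the remaining records as a list."""
        return list(self._iterator)


def _iter_body(fh: TextIO, first_line_no: int) -> Iterator[tuple[int, str]]:
    n = first_line_no
    for line in fh:
        n += 1
        if line.strip() == "":
            continue
        yield n, line


def parse_log(
    source,
    line_types: Iterable[LineType] | None = None,
    object_ids: Iterable[int] | None = None,
    convert: bool = True,
    config=None,
) -> ParsedLog:
    """Parse a session log, streaming.

    Parameters
    ----------
    source : path or text stream
        With ``convert=True`` the source is read twice (frame table pass,
        then the record pass), so a stream must be seekable.
    line_types, object_ids : optional filters applied while streaming.
    convert : replace every record's game-thread time by its on-screen time
        (the default, since analyses relate events to what the subject saw).
        Requires FRAME records in the log.
    config : :class:`domekit.timing.TimingConfig`, default constructed when
        omitted.

    Returns a :class:`ParsedLog`; malformed lines raise
    :class:`LogParseError` naming the line.
    """
    from . import timing  # deferred to avoid an import cycle

    type_set = frozenset(line_types) if line_types is not None else None
    if type_set is not None:
        for t in type_set:
            if not isinstance(t, LineType):
                raise ValueError(f"unknown line type in filter: {t!r}")
    id_set = frozenset(object_ids) if object_ids is not None else None

    fh, own = _open_source(source)
    header, header_lines = _read_header_lines(fh)

    table = None
    if convert:
        cfg = config if config is not None else timing.TimingConfig()
        frame_records: list[LogRecord] = []
        marker_records: list[LogRecord] = []
        for n, line in _iter_body(fh, header_lines):
            token = line.split("\t", 3)
            if len(token) >= 3:
                if token[2] == LineType.FRAME.value:
                    frame_records.append(parse_record(line, n))
                elif token[2] == LineType.EVENT_MARKER.value:
                    marker_records.append(parse_record(line, n))
        if not frame_records:
            if own:
                fh.close()
            raise LogConversionError(
                "convert=True requires FRAME records to map game time to screen "
                "time, but the log contains none; re-parse with convert=False"
            )
        table = timing.build_frame_table(frame_records, marker_records)
        fh.seek(0)
        _read_header_lines(fh)

    def generate() -> Iterator[LogRecord]:
        try:
            for n, line in _iter_body(fh, header_lines):
                token = line.split("\t", 3)
                if len(token) < 4:
                    # re-parse for a uniform error message
                    parse_record(line, n)
                if type_set is not None and token[2] not in _TYPE_TOKENS:
                    raise LogParseError(f"unknown line type {token[2]!r}", n)
                if type_set is not None and LineType(token[2]) not in type_set:
                    continue
                if id_set is not None:
                    try:
                        oid = int(token[1])
                    except ValueError:
                        raise LogParseError(f"bad object id {token[1]!r}", n) from None
                    if oid not in id_set:
                        continue
                rec = parse_record(line, n)
                if table is not None:
                    screen, exact = timing.to_screen_time_checked(rec.game_time, table, cfg)
                    rec = replace(rec, game_time=screen)
                    object.__setattr__(rec, "time_is_screen", True)
                    object.__setattr__(rec, "time_approx", not exact)
                yield rec
        finally:
            if own:
                fh.close()

    return ParsedLog(header, generate())


_TYPE_TOKENS = frozenset(t.value for t in LineType)


# --------------------------------------------------------------------------
# Extraction helpers


def _as_records(log) -> Iterable[LogRecord]:
    if isinstance(log, ParsedLog):
        return iter(log)
    return log


def extract_trajectory(log, object_id: int) -> list[TrajectorySample]:
    """Time-ordered POSITION samples of one object.

    An object with no POSITION records yields an empty list with a warning.
    """
    samples = []
    for rec in _as_records(log):
        if rec.line_type is LineType.POSITION and rec.object_id == object_id:
            x, y, z, rot = rec.payload[:4]
            samples.append(TrajectorySample(rec.game_time, (x, y, z), rot))
    if not samples:
        warnings.warn(f"no POSITION records for object {object_id}", stacklevel=2)
    samples.sort(key=lambda s: s.time)
    return samples


def extract_state_intervals(log) -> list[StateInterval]:
    """Matched STATE_ENTER/STATE_EXIT pairs, one interval each.

    Each state machine (object id) keeps its own stack, so nested machines
    (a block containing trials) produce properly nested intervals.  An exit
    without a matching entry is an error; entries still open at the end of
    the file (a truncated session) are returned with ``exit_time=None``
    under a warning.
    """
    stacks: dict[int, list[tuple[str, float]]] = {}
    intervals: list[StateInterval] = []
    line_guess = 0
    for rec in _as_records(log):
        line_guess += 1
        if rec.line_type is LineType.STATE_ENTER:
            (name,) = rec.payload
            stacks.setdefault(rec.object_id, []).append((name, rec.game_time))
        elif rec.line_type is LineType.STATE_EXIT:
            (name,) = rec.payload
            stack = stacks.get(rec.object_id, [])
            if not stack or stack[-1][0] != name:
                raise LogParseError(
                    f"STATE_EXIT {name!r} (machine {rec.object_id}) has no matching STATE_ENTER",
                    line_guess,
                )
            ename, etime = stack.pop()
            intervals.append(StateInterval(ename, etime, rec.game_time, rec.object_id))
    open_states = [(oid, name) for oid, st in stacks.items() for name, _ in st]
    if open_states:
        warnings.warn(
            f"log ends inside open states (truncated session?): {open_states}",
            stacklevel=2,
        )
        for oid, stack in stacks.items():
            for name, t in stack:
                intervals.append(StateInterval(name, t, None, oid))
    intervals.sort(key=lambda iv: iv.enter_time)
    return intervals


@dataclass
class PerformanceSummary:
    """Outcome counts and the sliding proportion of correct outcomes."""

    counts: dict[str, int]
    series: np.ndarray
    window: int


def performance_summary(
    intervals: Sequence[StateInterval],
    outcome_states: Iterable[str],
    correct_states: Iterable[str],
    window: int = 20,
) -> PerformanceSummary:
    """Behavioral performance from outcome-state intervals.

    Outcomes are the intervals whose state name is in ``outcome_states``,
    in order of entry time.  ``series[i]`` is the fraction of correct
    outcomes among outcomes ``max(0, i-window+1) .. i`` -- the proportion
    of correct trials in a sliding window (the classic session chart uses
    ``window=20``).
    """
    outcome_set = frozenset(outcome_states)
    correct_set = frozenset(correct_states)
    if window < 1:
        raise ValueError("window must be >= 1")
    if not correct_set <= outcome_set:
        raise ValueError("correct_states must be a subset of outcome_states")
    ordered = sorted(
        (iv for iv in intervals if iv.state_name in outcome_set), key=lambda iv: iv.enter_time
    )
    counts = {name: 0 for name in sorted(outcome_set)}
    flags = np.zeros(len(ordered), dtype=float)
    for i, iv in enumerate(ordered):
        counts[iv.state_name] += 1
        flags[i] = 1.0 if iv.state_name in correct_set else 0.0
    if not ordered:
        return PerformanceSummary(counts, np.array([]), window)
    csum = np.concatenate([[0.0], np.cumsum(flags)])
    idx = np.arange(len(ordered))
    lo = np.maximum(0, idx - window + 1)
    series = (csum[idx + 1] - csum[lo]) / (idx + 1 - lo)
    return PerformanceSummary(counts, series, window)
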