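"""Tachogram I/O, adaptive NN filtering and analysis-segment extraction.

A 24-h Holter recording arrives as a *tachogram*: the sequence of
beat-to-beat intervals in milliseconds, optionally with per-beat
annotations (normal / ventricular / artefact) and the wall-clock start
time of the recording.  Before any heart-rate-variability index can be
computed the tachogram is cleaned into a normal-to-normal (NN) interval
series: ectopic beats and artefacts are replaced by linear interpolation
between accepted neighbours.  Four analysis segments are then carved out
of each record:

* the full 24 h series,
* the first 30 min,
* the most stationary 30 min of the 16:00-20:00 daytime window,
* the most stationary 30 min of the 24:00-04:00 nighttime window,

where "most stationary" means the 30-min window (1-min shift) with the
smallest cvNN30min = sdNN30min / meanNN30min^3 [1/ms^2] computed on the
4-Hz resampled interval function.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import (
    CoverageError,
    EmptyInputError,
    InsufficientDataError,
    ParseError,
    UnusableRecordError,
)

__all__ = [
    "Tachogram",
    "NNSeries",
    "SegmentDescriptor",
    "read_tachogram",
    "write_tachogram",
    "adaptive_nn_filter",
    "exclusion_check",
    "extract_clock_window",
    "most_stationary_30min",
    "first_30min",
    "DAY_WINDOW",
    "NIGHT_WINDOW",
]

#: Daytime clock window, seconds of day (16:00-20:00).
DAY_WINDOW = (16 * 3600, 20 * 3600)
#: Nighttime clock window, seconds of day (24:00-04:00 of the next day).
NIGHT_WINDOW = (24 * 3600, 28 * 3600)

_SECONDS_PER_DAY = 86400


@dataclass
class Tachogram:
    """Raw beat-to-beat interval sequence (ms) with optional annotations."""

    intervals: np.ndarray
    annotations: Optional[Sequence[str]] = None
    start_clock: int = 0  # seconds since midnight

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.intervals.ndim != 1 or self.intervals.size == 0:
            raise EmptyInputError("tachogram holds no intervals")
        if np.any(self.intervals <= 0):
            raise ParseError("tachogram contains non-positive intervals")
        if self.annotations is not None and len(self.annotations) != len(self.intervals):
            raise ParseError("annotation column length differs from interval column")


@dataclass
class NNSeries:
    """Filtered normal-to-normal interval series.

    ``t`` is the cumulative occurrence time in seconds with the first
    beat at t = 0 and t[k] = t[k-1] + nn[k] / 1000.
    """

    nn: np.ndarray
    start_clock: int = 0
    ectopy_fraction: float = 0.0
    t: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.nn = np.asarray(self.nn, dtype=float)
        if self.nn.size == 0:
            raise EmptyInputError("NN series is empty")
        if np.any(self.nn <= 0):
            raise ParseError("NN series contains non-positive intervals")
        if self.t is None:
            t = np.empty_like(self.nn)
            t[0] = 0.0
            np.cumsum(self.nn[1:] / 1000.0, out=t[1:])
            self.t = t
        else:
            self.t = np.asarray(self.t, dtype=float)
            if len(self.t) != len(self.nn):
                raise ParseError("t and nn length mismatch")

    @property
    def duration_s(self) -> float:
        return float(self.t[-1])

    def __len__(self) -> int:
        return len(self.nn)


@dataclass
class SegmentDescriptor:
    """Which slice of a record a feature vector was computed on."""

    label: str  # one of {"h24", "first30", "day30", "night30"}
    start_s: float
    stop_s: float
    window_stats: Optional[dict] = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "label": self.label,
                "start_s": self.start_s,
                "stop_s": self.stop_s,
                "window_stats": self.window_stats,
            }
        )


_START_RE = re.compile(r"^#\s*start\s*=\s*(\d{1,2}):(\d{2}):(\d{2})\s*$")


def _parse_start(line: str) -> Optional[int]:
    m = _START_RE.match(line)
    if m is None:
        return None
    h, mnt, s = (int(g) for g in m.groups())
    return h * 3600 + mnt * 60 + s


def read_tachogram(path, format: str = "plain") -> Tachogram:
    """Read a tachogram file.

    ``plain``: one interval in ms per line; ``#``-prefixed lines are
    headers, of which ``# start=HH:MM:SS`` sets the recording start
    clock (default midnight).  ``csv``: columns ``interval_ms`` and an
    optional ``annotation`` column with labels in {N, V, A}.
    """
    path = Path(path)
    if format not in ("plain", "csv"):
        raise ValueError(f"unknown tachogram format {format!r}")
    start_clock = 0
    intervals: list[float] = []
    annotations: list[str] = []
    have_ann = False
    with open(path) as fh:
        lines = fh.readlines()
    body = 0
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            sc = _parse_start(line)
            if sc is not None:
                start_clock = sc
            continue
        body += 1
        if format == "csv" and body == 1 and line.lower().startswith("interval"):
            continue  # header row
        fields = line.split(",") if format == "csv" else [line]
        try:
            intervals.append(float(fields[0]))
        except ValueError:
            raise ParseError(f"{path}: malformed interval at line {lineno}: {fields[0]!r}")
        if format == "csv" and len(fields) > 1:
            have_ann = True
            annotations.append(fields[1].strip())
        else:
            annotations.append("N")
    if not intervals:
        raise EmptyInputError(f"{path}: no intervals found")
    return Tachogram(
        intervals=np.array(intervals),
        annotations=annotations if have_ann else None,
        start_clock=start_clock,
    )


def write_tachogram(nn: "NNSeries | Tachogram", path) -> None:
    """Serialize an interval sequence back to the plain-text dialect."""
    values = nn.nn if isinstance(nn, NNSeries) else nn.intervals
    sc = int(nn.start_clock)
    h, rem = divmod(sc, 3600)
    m, s = divmod(rem, 60)
    with open(path, "w") as fh:
        fh.write(f"# start={h:02d}:{m:02d}:{s:02d}\n")
        for v in values:
            fh.write(f"{v:.6g}\n")


def adaptive_nn_filter(
    tg: Tachogram,
    rel_tol: float = 0.20,
    abs_tol_ms: float = 50.0,
    smoothing: float = 0.1,
) -> NNSeries:
    """Replace ectopic beats and artefacts, producing an NN series.

    A beat is flagged when its annotation is not normal, or when it
    deviates from an exponentially updated reference mean by more than
    ``max(rel_tol * reference, abs_tol_ms)``.  The reference starts at
    the median interval (robust to early ectopy) and is updated only on
    accepted beats: ``ref <- ref + smoothing * (beat - ref)``.  Flagged
    beats are replaced by linear interpolation between the nearest
    accepted neighbours, so the beat count is preserved.
    """
    x = np.asarray(tg.intervals, dtype=float)
    n = len(x)
    if n < 2:
        raise InsufficientDataError("adaptive filter needs at least 2 intervals")
    ann_bad = np.zeros(n, dtype=bool)
    if tg.annotations is not None:
        ann_bad = np.array([a not in ("N", "n", "", None) for a in tg.annotations])

    flagged = np.zeros(n, dtype=bool)
    ref = float(np.median(x))
    for i in range(n):
        if ann_bad[i] or abs(x[i] - ref) > max(rel_tol * ref, abs_tol_ms):
            flagged[i] = True
        else:
            ref += smoothing * (x[i] - ref)

    if flagged.all():
        raise UnusableRecordError("every beat was flagged; record unusable")

    nn = x.copy()
    if flagged.any():
        ok = np.flatnonzero(~flagged)
        bad = np.flatnonzero(flagged)
        nn[bad] = np.interp(bad, ok, x[ok])
    return NNSeries(
        nn=nn,
        start_clock=tg.start_clock,
        ectopy_fraction=float(flagged.sum()) / n,
    )


def exclusion_check(nn: NNSeries, max_fraction: float = 0.10) -> bool:
    """True when the record must be excluded (ectopy strictly above the cap)."""
    return nn.ectopy_fraction > max_fraction


def _subseries(nn: NNSeries, start_s: float, stop_s: float) -> NNSeries:
    mask = (nn.t >= start_s) & (nn.t < stop_s)
    if not mask.any():
        raise InsufficientDataError(f"no beats in [{start_s}, {stop_s}) s")
    return NNSeries(
        nn=nn.nn[mask],
        start_clock=int(nn.start_clock + start_s) % _SECONDS_PER_DAY,
        ectopy_fraction=nn.ectopy_fraction,
    )


def extract_clock_window(nn: NNSeries, start_clock: int, stop_clock: int) -> NNSeries:
    """Return beats whose occurrence clock time lies in [start, stop).

    Clock times are seconds of day; a window starting before the
    recording's start clock is taken on the following calendar day, so
    24:00-04:00 (passed as 86400-100800 or equivalently 0-14400) rolls
    over midnight correctly.
    """
    elapsed_start = (start_clock - nn.start_clock) % _SECONDS_PER_DAY
    duration = (stop_clock - start_clock) % _SECONDS_PER_DAY
    if duration == 0:
        raise ValueError("empty clock window")
    elapsed_stop = elapsed_start + duration
    if nn.duration_s < elapsed_stop:
        raise CoverageError(
            f"recording ends at {nn.duration_s:.0f} s; window needs "
            f"[{elapsed_start:.0f}, {elapsed_stop:.0f}) s "
            f"(missing {elapsed_stop - nn.duration_s:.0f} s)"
        )
    return _subseries(nn, elapsed_start, elapsed_stop)


def first_30min(nn: NNSeries) -> NNSeries:
    """Beats within the first 1800 s of the record."""
    if nn.duration_s < 1800:
        raise InsufficientDataError(
            f"record spans {nn.duration_s:.0f} s, need at least 1800 s"
        )
    return _subseries(nn, 0.0, 1800.0)


def most_stationary_30min(
    nn4h: NNSeries,
    label: str = "day30",
    fs: float = 4.0,
    window_s: int = 1800,
    shift_s: int = 60,
) -> tuple[NNSeries, SegmentDescriptor]:
    """Select the most stationary 30-min window of a (typically 4-h) series.

    The interval-vs-time function is linearly interpolated and resampled
    at ``fs`` Hz; 30-min windows shifted by 1 min are scored by
    cvNN30min_w = sdNN30min_w / meanNN30min_w**3 and the window with the
    smallest value wins (earliest window on ties).  The returned series
    holds the *original* beats inside the winning window; the resampled
    signal is used only for the window statistics.
    """
    span = nn4h.duration_s
    if span < window_s:
        raise InsufficientDataError(
            f"series spans {span:.0f} s, need at least {window_s} s"
        )
    grid = np.arange(0.0, span, 1.0 / fs)
    sig = np.interp(grid, nn4h.t, nn4h.nn)
    win_n = int(window_s * fs)
    shift_n = int(shift_s * fs)
    starts = np.arange(0, len(grid) - win_n + 1, shift_n)
    best = None
    for s0 in starts:
        w = sig[s0 : s0 + win_n]
        mean_w = float(np.mean(w))
        sd_w = float(np.std(w, ddof=1))
        cv_w = sd_w / mean_w**3
        if best is None or cv_w < best[0]:
            best = (cv_w, s0, mean_w, sd_w)
    cv_w, s0, mean_w, sd_w = best
    start_s = s0 / fs
    stop_s = start_s + window_s
    desc = SegmentDescriptor(
        label=label,
        start_s=start_s,
        stop_s=stop_s,
        window_stats={
            "meanNN30min_w": mean_w,
            "sdNN30min_w": sd_w,
            "cvNN30min_w": cv_w,
        },
    )
    return _subseries(nn4h, start_s, stop_s), desc
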