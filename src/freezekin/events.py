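"""Gait-event detection from the filtered sagittal angular-velocity signal.

Stride cycles are delimited by consecutive dominant swing peaks. Between two
swing peaks the signal shows, in order, the heel-strike (HS) maximum that ends
the earlier swing and the toe-off (TO) maximum that launches the next one (the
classic "second and first maxima" of an HS-to-HS cycle). Toe strike (TS) and
heel off (HO) are the threshold crossings of |omega| bracketing the flat-foot
interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .errors import DataError, NoStridesFound, ParameterError

__all__ = [
    "StrideWindow",
    "GaitEvents",
    "auto_orient",
    "find_stride_windows",
    "detect_events",
    "select_central_strides",
]

log = logging.getLogger(__name__)

#: minimum prominence (deg/s) for a stance-adjacent event maximum
EVENT_PROMINENCE_DPS = 10.0
#: dominant swing peaks must reach this fraction of the signal maximum
SWING_PEAK_REL_HEIGHT = 0.5


@dataclass(frozen=True)
class StrideWindow:
    """Half-open sample range between two consecutive dominant swing peaks."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise DataError(f"window start {self.start} must precede end {self.end}")


@dataclass
class GaitEvents:
    """Per-stride HS/TS/HO/TO sample indices for one foot.

    Invariant: ``hs < ts < ho < to < hs_next`` per stride; strides are ordered
    and non-overlapping.
    """

    hs: np.ndarray
    ts: np.ndarray
    ho: np.ndarray
    to: np.ndarray
    hs_next: np.ndarray
    fs: float
    foot: str = "right"

    def __post_init__(self) -> None:
        for name in ("hs", "ts", "ho", "to", "hs_next"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.int64))
        n = self.hs.size
        for name in ("ts", "ho", "to", "hs_next"):
            if getattr(self, name).size != n:
                raise DataError("event arrays must have equal length")
        if self.fs <= 0:
            raise DataError("fs must be positive")
        ordered = (self.hs < self.ts) & (self.ts < self.ho) & (self.ho < self.to) & (self.to < self.hs_next)
        if not np.all(ordered):
            raise DataError(f"event ordering hs<ts<ho<to<hs_next violated at stride {int(np.argmin(ordered))}")
        if n > 1 and not np.all(self.hs[1:] >= self.hs_next[:-1]):
            raise DataError("strides overlap or are out of order")

    @property
    def n_strides(self) -> int:
        return int(self.hs.size)

    def duration_s(self) -> float:
        """Span from the first HS to the last HS of the analyzed strides."""
        if self.n_strides == 0:
            return 0.0
        return float(self.hs_next[-1] - self.hs[0]) / self.fs

    def take(self, idx: Sequence[int]) -> "GaitEvents":
        idx = np.asarray(idx, dtype=np.int64)
        return GaitEvents(
            hs=self.hs[idx], ts=self.ts[idx], ho=self.ho[idx], to=self.to[idx],
            hs_next=self.hs_next[idx], fs=self.fs, foot=self.foot,
        )

    def flatfoot_intervals(self) -> list[tuple[int, int]]:
        """Closed (ts, ho) index intervals — the flat-foot (midstance) periods."""
        return [(int(a), int(b)) for a, b in zip(self.ts, self.ho)]


def auto_orient(omega_sag: np.ndarray) -> np.ndarray:
    """Flip the sagittal channel sign if its dominant extrema are negative.

    Sensor mounting flips the sagittal sign between feet/devices; the detection
    rules assume the swing peak and stance-adjacent extrema are maxima.
    """
    omega_sag = np.asarray(omega_sag, dtype=float)
    if omega_sag.size and -np.min(omega_sag) > np.max(omega_sag):
        return -omega_sag
    return omega_sag


def find_stride_windows(
    omega_sag: np.ndarray,
    fs: float,
    min_stride_s: float = 0.6,
    max_stride_s: float = 2.5,
    prominence_dps: float = 50.0,
) -> list[StrideWindow]:
    """Delimit gait cycles by consecutive dominant swing peaks.

    Dominant peaks must exceed half the signal maximum, be at least
    ``prominence_dps`` prominent, and be at least ``min_stride_s`` apart.
    Windows longer than ``max_stride_s`` (walking interruptions) are dropped.
    """
    omega_sag = np.asarray(omega_sag, dtype=float)
    if fs <= 0:
        raise ParameterError("fs must be positive")
    if omega_sag.size < 2 or np.max(omega_sag) <= 0:
        raise NoStridesFound("signal has no positive swing peaks")
    height = SWING_PEAK_REL_HEIGHT * float(np.max(omega_sag))
    peaks, _ = find_peaks(
        omega_sag,
        height=height,
        distance=max(int(round(min_stride_s * fs)), 1),
        prominence=prominence_dps,
    )
    if peaks.size < 2:
        raise NoStridesFound(f"found {peaks.size} dominant swing peak(s); need at least 2")
    windows = []
    max_len = max_stride_s * fs
    for a, b in zip(peaks[:-1], peaks[1:]):
        if b - a <= max_len:
            windows.append(StrideWindow(int(a), int(b)))
    if not windows:
        raise NoStridesFound("no swing-peak pair within the stride-duration bounds")
    return windows


def _interior_maxima(omega: np.ndarray, start: int, end: int, threshold_dps: float) -> np.ndarray:
    """Stance-adjacent maxima strictly inside (start, end)."""
    seg = omega[start : end + 1]
    pk, _ = find_peaks(seg, height=threshold_dps, prominence=EVENT_PROMINENCE_DPS)
    pk = pk + start
    return pk[(pk > start) & (pk < end)]


def detect_events(
    omega_sag: np.ndarray,
    windows: Sequence[StrideWindow],
    fs: float,
    threshold_dps: float = 30.0,
    foot: str = "right",
) -> GaitEvents:
    """Detect HS/TS/HO/TO in each stride window.

    Within a window the first interior maximum is the HS terminating the swing
    that opened the window and the last is the TO launching the next swing.
    TS is the first sample after HS where ``|omega|`` drops below the
    threshold; HO is the last sample before TO still below it. Strides failing
    any rule are dropped and logged, never repaired.
    """
    omega_sag = np.asarray(omega_sag, dtype=float)
    if threshold_dps <= 0:
        raise ParameterError("threshold_dps must be positive")
    n = omega_sag.size
    absw = np.abs(omega_sag)

    hs_l, ts_l, ho_l, to_l, nx_l = [], [], [], [], []
    per_window: list[tuple[int, int] | None] = []
    for w in windows:
        maxima = _interior_maxima(omega_sag, w.start, w.end, threshold_dps)
        if maxima.size < 2:
            per_window.append(None)
            continue
        per_window.append((int(maxima[0]), int(maxima[-1])))

    # HS following the final window (needed as hs_next of the last stride)
    tail_hs: int | None = None
    last_end = windows[-1].end
    if last_end + 2 < n:
        tail = _interior_maxima(omega_sag, last_end, n - 1, threshold_dps)
        if tail.size:
            tail_hs = int(tail[0])

    for k, w in enumerate(windows):
        pair = per_window[k]
        if pair is None:
            log.warning("stride %d dropped: fewer than two event maxima in window", k)
            continue
        hs, to = pair
        if k + 1 < len(windows):
            if windows[k + 1].start != w.end or per_window[k + 1] is None:
                log.warning("stride %d dropped: no heel strike after window", k)
                continue
            hs_next = per_window[k + 1][0]
        elif tail_hs is not None:
            hs_next = tail_hs
        else:
            log.warning("stride %d dropped: trailing heel strike not found", k)
            continue
        below = np.flatnonzero(absw[hs + 1 : to] < threshold_dps) + hs + 1
        if below.size == 0:
            log.warning("stride %d dropped: |omega| never below %g deg/s in stance", k, threshold_dps)
            continue
        ts, ho = int(below[0]), int(below[-1])
        if not (hs < ts < ho < to < hs_next):
            log.warning("stride %d dropped: event ordering violated", k)
            continue
        hs_l.append(hs); ts_l.append(ts); ho_l.append(ho); to_l.append(to); nx_l.append(hs_next)

    if not hs_l:
        raise NoStridesFound("no stride satisfied the event-detection rules")
    return GaitEvents(hs=hs_l, ts=ts_l, ho=ho_l, to=to_l, hs_next=nx_l, fs=fs, foot=foot)


def select_central_strides(
    events: GaitEvents,
    segments: Sequence[tuple[int, int]],
    n_per_segment: int = 10,
) -> GaitEvents:
    """Keep the ``n_per_segment`` strides nearest each walking bout's midpoint.

    ``segments`` are (start, end) sample-index boundaries of straight-walk
    bouts (e.g. going and returning); they are an explicit input, not inferred.
    Segments holding fewer strides than requested keep all of them.
    """
    if not segments:
        raise ParameterError("at least one walking-bout segment is required")
    if n_per_segment < 1:
        raise ParameterError("n_per_segment must be >= 1")
    keep: list[int] = []
    centers = (events.hs + events.hs_next) / 2.0
    for start, end in segments:
        if not start < end:
            raise ParameterError(f"segment ({start}, {end}) is empty")
        inside = np.flatnonzero((events.hs >= start) & (events.hs_next <= end))
        if inside.size == 0:
            log.warning("segment (%d, %d) contains no strides", start, end)
            continue
        if inside.size <= n_per_segment:
            if inside.size < n_per_segment:
                log.warning(
                    "segment (%d, %d) has %d strides, fewer than requested %d; keeping all",
                    start, end, inside.size, n_per_segment,
                )
            keep.extend(inside.tolist())
            continue
        mid = (start + end) / 2.0
        order = np.argsort(np.abs(centers[inside] - mid), kind="stable")[:n_per_segment]
        keep.extend(sorted(inside[order].tolist()))
    return events.take(sorted(keep))
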