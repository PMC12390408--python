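"""ZUPT-based stride length, walking speed, and foot-clearance landmarks.

The zero-velocity-update (ZUPT) scheme anchors inertial integration on the
flat-foot (TS..HO) intervals: velocity is forced to zero there, and each
moving span between consecutive flat-foot intervals is integrated cumulatively
(trapezoid by default; Simpson and spline schemes available) and linearly
detrended so its terminal velocity is zero on every axis. Displacement
integrals are likewise computed per span, re-zeroed at each span start.

The leading span (recording start to the first TS) assumes the trial begins at
rest; the trailing span after the last HO has no terminal anchor, is left at
zero, and any landmark falling inside it is flagged invalid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_simpson, cumulative_trapezoid
from scipy.interpolate import CubicSpline
from scipy.signal import find_peaks
from scipy.spatial.transform import Rotation

from .errors import DataError, ZuptImpossible
from .events import GaitEvents
from .io_config import ImuRecording

__all__ = [
    "GlobalAcceleration",
    "SpatialStride",
    "rotate_and_degravitate",
    "zupt_velocity",
    "stride_length",
    "naive_stride_length",
    "speed",
    "clearance",
    "swing_landmarks",
    "spatial_strides",
]

log = logging.getLogger(__name__)

M_TO_MM = 1000.0


@dataclass
class GlobalAcceleration:
    """Global-frame acceleration with gravity removed, plus flat-foot intervals."""

    a_global: np.ndarray
    fs: float
    flatfoot: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.a_global = np.atleast_2d(np.asarray(self.a_global, dtype=float))
        if self.a_global.ndim != 2 or self.a_global.shape[1] != 3:
            raise DataError(f"a_global must be (n, 3), got {self.a_global.shape}")
        n = self.a_global.shape[0]
        prev_end = -1
        for a, b in self.flatfoot:
            if not (0 <= a <= b < n):
                raise DataError(f"flat-foot interval ({a}, {b}) out of bounds")
            if a <= prev_end:
                raise DataError("flat-foot intervals overlap or are unordered")
            prev_end = b

    def __len__(self) -> int:
        return self.a_global.shape[0]

    def anchored_spans(self) -> list[tuple[int, int]]:
        """Integration spans bounded by zero-velocity anchors.

        The leading span runs from sample 0 (assumed at rest) to the first
        flat-foot onset; interior spans run from each flat-foot end (HO) to
        the next flat-foot onset (TS). The unanchored trailing span is
        excluded.
        """
        if not self.flatfoot:
            raise ZuptImpossible("no flat-foot intervals; ZUPT cannot anchor integration")
        spans = []
        first_ts = self.flatfoot[0][0]
        if first_ts > 0:
            spans.append((0, first_ts))
        for (_, ho), (ts_next, _) in zip(self.flatfoot[:-1], self.flatfoot[1:]):
            spans.append((ho, ts_next))
        return spans


@dataclass
class SpatialStride:
    """Per-stride spatial metrics (lengths in m, clearance landmarks in mm)."""

    stride_index: int
    st_s: float
    sl_m: float
    sp_mps: float
    max1_mm: float = np.nan
    min_mm: float = np.nan
    max2_mm: float = np.nan
    idx_max1: int = -1
    idx_min: int = -1
    idx_max2: int = -1
    max1_valid: bool = False
    min_valid: bool = False
    max2_valid: bool = False


def rotate_and_degravitate(
    rec: ImuRecording,
    gravity_mps2: float = 9.80665,
    flatfoot: list[tuple[int, int]] | None = None,
) -> GlobalAcceleration:
    """Rotate specific force into the global frame and remove gravity.

    The rotation comes from the per-sample quaternions (sensor-to-global);
    a constant gravity vector is subtracted from the vertical component.
    """
    rot = Rotation.from_quat(rec.quat, scalar_first=True)
    a_global = rot.apply(rec.acc)
    a_global[:, 2] -= gravity_mps2
    return GlobalAcceleration(a_global=a_global, fs=rec.fs, flatfoot=list(flatfoot or []))


def _span_integrate(
    x: np.ndarray, spans: list[tuple[int, int]], fs: float, detrend: bool,
    scheme: str = "trapezoid",
) -> np.ndarray:
    """Cumulative integral per span, zero at each span start.

    ``scheme`` selects trapezoidal (default), Simpson, or cubic-spline
    cumulative integration. The trapezoid loses ~(omega*dt)^2/12 of amplitude
    on fast swing transients; the spline antiderivative resolves the
    between-sample curvature and is the accurate choice when the swing jerk
    approaches the sampling limit. With ``detrend`` a linear ramp is
    subtracted so the span's terminal value is exactly zero. Samples outside
    spans stay zero.
    """
    if scheme not in ("trapezoid", "simpson", "spline"):
        raise DataError(f"unknown integration scheme {scheme!r}")
    out = np.zeros_like(x)
    for a, b in spans:
        if scheme == "spline":
            tt = np.arange(b - a + 1) / fs
            seg = CubicSpline(tt, x[a : b + 1], axis=0).antiderivative()(tt)
        else:
            integ = cumulative_trapezoid if scheme == "trapezoid" else cumulative_simpson
            seg = integ(x[a : b + 1], dx=1.0 / fs, axis=0, initial=0.0)
        if detrend:
            ramp = np.linspace(0.0, 1.0, b - a + 1)
            seg = seg - np.multiply.outer(ramp, seg[-1])
        out[a : b + 1] = seg
    return out


def zupt_velocity(ga: GlobalAcceleration, fs: float | None = None, scheme: str = "trapezoid") -> np.ndarray:
    """Three-axis velocity with zero-velocity updates on flat-foot intervals.

    Velocity is bit-zero on every flat-foot sample; each anchored span is
    integrated from zero and linearly detrended to land on zero at the next
    flat-foot onset.
    """
    fs = ga.fs if fs is None else fs
    spans = ga.anchored_spans()
    v = _span_integrate(ga.a_global, spans, fs, detrend=True, scheme=scheme)
    for a, b in ga.flatfoot:
        v[a : b + 1] = 0.0
    return v


def stride_length(
    v: np.ndarray,
    ga: GlobalAcceleration,
    events: GaitEvents,
    fs: float | None = None,
    scheme: str = "trapezoid",
) -> np.ndarray:
    """Stride length per stride, m: peak horizontal displacement between HS pairs.

    Horizontal speed is the Euclidean norm of the two horizontal velocity
    components, re-zeroed on flat-foot intervals, and integrated per anchored
    span into a displacement that resets at each span start. Strides whose
    window holds no anchored displacement are reported as NaN and logged.
    """
    fs = ga.fs if fs is None else fs
    vh = np.hypot(v[:, 0], v[:, 1])
    for a, b in ga.flatfoot:
        vh[a : b + 1] = 0.0
    spans = ga.anchored_spans()
    dh = _span_integrate(vh, spans, fs, detrend=False, scheme=scheme)
    covered = np.zeros(len(ga), dtype=bool)
    for a, b in spans:
        covered[a : b + 1] = True
    sl = np.full(events.n_strides, np.nan)
    for k, (hs, nx) in enumerate(zip(events.hs, events.hs_next)):
        if not covered[hs:nx].any():
            log.warning("stride %d dropped from SL: no anchored flat-foot span", k)
            continue
        sl[k] = float(np.max(dh[hs:nx]))
    return sl


def naive_stride_length(ga: GlobalAcceleration, events: GaitEvents, fs: float | None = None) -> np.ndarray:
    """Stride length by naive double integration (no zeroing, no detrend).

    Comparison baseline demonstrating the drift the ZUPT scheme removes.
    """
    fs = ga.fs if fs is None else fs
    v = cumulative_trapezoid(ga.a_global, dx=1.0 / fs, axis=0, initial=0.0)
    vh = np.hypot(v[:, 0], v[:, 1])
    dh = cumulative_trapezoid(vh, dx=1.0 / fs, initial=0.0)
    return np.array([dh[nx] - dh[hs] for hs, nx in zip(events.hs, events.hs_next)])


def speed(sl_m: np.ndarray | float, st_s: np.ndarray | float) -> np.ndarray | float:
    """Walking speed per stride: stride length over stride time."""
    st = np.asarray(st_s, dtype=float)
    if np.any(st <= 0):
        raise DataError("stride time must be positive")
    return np.asarray(sl_m, dtype=float) / st


def swing_landmarks(z_mm: np.ndarray, lo: int, hi: int) -> tuple[float, float, float, int, int, int, bool, bool, bool]:
    """Locate Max1 / Min / Max2 of a clearance series strictly inside (lo, hi).

    Max1 is the first local maximum, Max2 the last, and Min the minimum
    between them. With a single maximum only Max1 is valid; with none, no
    landmark is.
    """
    seg = z_mm[lo + 1 : hi]
    nan = float("nan")
    if seg.size < 3 or not np.all(np.isfinite(seg)):
        return nan, nan, nan, -1, -1, -1, False, False, False
    pk, _ = find_peaks(seg)
    if pk.size == 0:
        return nan, nan, nan, -1, -1, -1, False, False, False
    i1 = int(pk[0]) + lo + 1
    if pk.size == 1:
        return float(z_mm[i1]), nan, nan, i1, -1, -1, True, False, False
    i2 = int(pk[-1]) + lo + 1
    imin = int(np.argmin(z_mm[i1 : i2 + 1])) + i1
    return (
        float(z_mm[i1]), float(z_mm[imin]), float(z_mm[i2]),
        i1, imin, i2, True, True, True,
    )


def clearance(
    ga: GlobalAcceleration, events: GaitEvents, fs: float | None = None,
    scheme: str = "trapezoid", detrend_displacement: bool = False,
) -> tuple[np.ndarray, list[tuple]]:
    """Relative vertical displacement (mm) and per-stride swing landmarks.

    Only the vertical axis is integrated; displacement is re-zeroed on each
    anchored span so the flat-foot plateau defines the zero baseline.
    ``detrend_displacement`` additionally anchors the displacement to zero at
    the span's terminal flat-foot onset (the baseline holds at both ends of a
    span), spreading any residual integration drift linearly — a
    displacement-level analogue of the velocity ZUPT detrend.
    Landmarks are searched strictly within each stride's swing (TO, next HS).

    Returns
    -------
    z_mm : per-sample relative vertical displacement, mm
    landmarks : per stride, the 9-tuple of :func:`swing_landmarks`
    """
    fs = ga.fs if fs is None else fs
    v = zupt_velocity(ga, fs, scheme=scheme)
    spans = ga.anchored_spans()
    z = _span_integrate(v[:, 2], spans, fs, detrend=detrend_displacement, scheme=scheme) * M_TO_MM
    covered = np.zeros(len(ga), dtype=bool)
    for a, b in spans:
        covered[a : b + 1] = True
    out = []
    for k, (to, nx) in enumerate(zip(events.to, events.hs_next)):
        if not covered[to:nx].all():
            log.warning("stride %d clearance invalid: swing outside anchored spans", k)
            out.append((np.nan,) * 3 + (-1,) * 3 + (False,) * 3)
            continue
        out.append(swing_landmarks(z, int(to), int(nx)))
    return z, out


def spatial_strides(
    rec: ImuRecording,
    events: GaitEvents,
    gravity_mps2: float = 9.80665,
    scheme: str = "trapezoid",
    detrend_displacement: bool = False,
) -> list[SpatialStride]:
    """Convenience wrapper: full spatial analysis of one trial."""
    ga = rotate_and_degravitate(rec, gravity_mps2, flatfoot=events.flatfoot_intervals())
    v = zupt_velocity(ga, scheme=scheme)
    sl = stride_length(v, ga, events, scheme=scheme)
    st = (events.hs_next - events.hs) / events.fs
    _, marks = clearance(ga, events, scheme=scheme, detrend_displacement=detrend_displacement)
    strides = []
    for k in range(events.n_strides):
        m1, mn, m2, i1, imn, i2, v1, vmn, v2 = marks[k]
        sp = float(sl[k] / st[k]) if np.isfinite(sl[k]) else np.nan
        strides.append(
            SpatialStride(
                stride_index=k, st_s=float(st[k]), sl_m=float(sl[k]), sp_mps=sp,
                max1_mm=m1, min_mm=mn, max2_mm=m2,
                idx_max1=i1, idx_min=imn, idx_max2=i2,
                max1_valid=v1, min_valid=vmn, max2_valid=v2,
            )
        )
    return strides
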