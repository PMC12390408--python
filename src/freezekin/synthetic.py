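"""Ground-truthed synthetic gait: foot trajectories, IMU signals, marker tracks, cohorts.

Construction
------------
A trial is a lead-in flat-foot rest, then ``n_strides + 1`` moving spans
(heel-off to the next toe-strike) separated by flat-foot holds, then a flat
tail. Each moving span advances the foot by one stride length with a quintic
smootherstep (C^2, zero velocity/acceleration at both ends) and lifts it
through a C^2 double-hump vertical profile whose knots are exactly the Max1 /
Min / Max2 clearance landmarks (zero first and second derivatives at every
knot, so pieces are monotone and the landmarks are exact local extrema).

The sagittal angular-velocity channel is a stylized cubic-Hermite template
with the canonical morphology: a dominant mid-swing peak, stance-adjacent
heel-strike and toe-off maxima, and |omega| crossing the toe-strike/heel-off
threshold exactly at the constructed TS/HO instants. It is *not* the
derivative of the emitted orientation (a template whose maxima are all
positive cannot integrate to a periodic angle); the pipeline only uses the
gyroscope for event detection, so the two are decoupled by design.

All randomness flows from the seed in :class:`GaitModelParams` /
:class:`CohortSpec`; identical seeds give bit-identical artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.interpolate import BPoly
from scipy.spatial.transform import Rotation

from .errors import ParameterError
from .io_config import ImuRecording, ReferenceTrajectory

__all__ = [
    "analysis_config",
    "GaitModelParams",
    "FootTrajectory",
    "GroundTruth",
    "CohortGroup",
    "CohortSpec",
    "generate_trajectory",
    "simulate_imu",
    "simulate_markers",
    "generate_cohort",
]

#: |omega| threshold (deg/s) at which the template crosses at TS and HO
EVENT_THRESHOLD_DPS = 30.0


def analysis_config(**overrides):
    """Pipeline configuration matched to the synthetic template's bandwidth.

    The stylized angular-velocity template packs the stance-adjacent maxima and
    mid-swing peak into tighter time intervals than real slow gait, so the
    field-default 3 Hz gyroscope cutoff would merge them; a 10 Hz cutoff
    preserves the morphology while still suppressing added white noise. The
    accelerometer cutoff is likewise raised to 20 Hz so the short vertical
    push-off transients survive filtering.
    """
    from .io_config import PipelineConfig

    kw = {"gyro_cutoff_hz": 10.0, "accel_cutoff_hz": 20.0,
          "integrator": "spline", "clearance_detrend": True}
    kw.update(overrides)
    return PipelineConfig(**kw)
_FLAT_OMEGA_DPS = 8.0
_LEAD_FLAT_S = 0.45
_TAIL_FLAT_S = 0.45


@dataclass
class GaitModelParams:
    """Parameters of one synthetic trial."""

    stride_time_s: float = 1.2
    phase_fractions: tuple[float, float, float, float] = (0.11, 0.41, 0.12, 0.36)
    stride_length_m: float = 1.30
    max1_mm: float = 150.0
    min_mm: float = 90.0
    max2_mm: float = 120.0
    swing_peak_dps: float = 350.0
    hs_peak_dps: float = 90.0
    to_peak_dps: float = 100.0
    pitch_amplitude_deg: float = 15.0
    gyro_noise_dps: float = 0.0
    accel_noise_mps2: float = 0.0
    accel_bias_mps2: tuple[float, float, float] = (0.0, 0.0, 0.0)
    marker_noise_mm: float = 0.0
    n_strides: int = 10
    fs: float = 100.0
    gravity_mps2: float = 9.80665
    foot: str = "right"
    seed: int = 0

    def __post_init__(self) -> None:
        fr = np.asarray(self.phase_fractions, dtype=float)
        if fr.size != 4 or np.any(fr <= 0):
            raise ParameterError("phase_fractions must be four positive numbers")
        if abs(float(fr.sum()) - 1.0) > 1e-9:
            raise ParameterError(f"phase_fractions must sum to 1, got {fr.sum()!r}")
        for name in ("stride_time_s", "stride_length_m", "fs", "swing_peak_dps",
                     "hs_peak_dps", "to_peak_dps"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.n_strides < 1:
            raise ParameterError("n_strides must be >= 1")
        if not (self.min_mm <= self.max1_mm and self.min_mm <= self.max2_mm):
            raise ParameterError("min_mm must not exceed max1_mm or max2_mm")
        if self.gyro_noise_dps < 0 or self.accel_noise_mps2 < 0 or self.marker_noise_mm < 0:
            raise ParameterError("noise magnitudes must be non-negative")
        if min(self.hs_peak_dps, self.to_peak_dps) <= EVENT_THRESHOLD_DPS:
            raise ParameterError("stance-adjacent peaks must exceed the 30 deg/s threshold")


@dataclass
class FootTrajectory:
    """Dense sampled foot kinematics in the global frame (plus orientation)."""

    t: np.ndarray
    pos: np.ndarray  # (n, 3), m
    vel: np.ndarray  # (n, 3), m/s
    acc: np.ndarray  # (n, 3), m/s^2
    pitch_rad: np.ndarray  # rotation about the global/sensor y axis
    omega_dps: np.ndarray  # clean sagittal angular-velocity template, deg/s
    fs: float

    def __len__(self) -> int:
        return self.t.size


@dataclass
class GroundTruth:
    """Per-stride truth of one synthetic trial."""

    hs: np.ndarray
    ts: np.ndarray
    ho: np.ndarray
    to: np.ndarray
    hs_next: np.ndarray
    stride_time_s: np.ndarray
    stride_length_m: np.ndarray
    max1_mm: np.ndarray
    min_mm: np.ndarray
    max2_mm: np.ndarray
    phases_pct: np.ndarray  # (n_strides, 4): LR, MS, PS, SW
    clearance_mm: np.ndarray  # per-sample vertical displacement above baseline

    @property
    def n_strides(self) -> int:
        return int(self.hs.size)


def _smootherstep() -> tuple[Callable, Callable, Callable]:
    s = lambda u: u**3 * (10.0 - 15.0 * u + 6.0 * u**2)
    d1 = lambda u: 30.0 * u**2 * (1.0 - u) ** 2
    d2 = lambda u: 60.0 * u * (1.0 - 3.0 * u + 2.0 * u**2)
    return s, d1, d2


def _first_below(absw: np.ndarray, start: int, stop: int, thr: float) -> int:
    idx = np.flatnonzero(absw[start + 1 : stop] < thr)
    if idx.size == 0:
        raise ParameterError("template never falls below threshold in stance")
    return int(idx[0]) + start + 1


def _local_argmax(x: np.ndarray, i: int, half: int = 4) -> int:
    lo, hi = max(i - half, 0), min(i + half + 1, x.size)
    return int(np.argmax(x[lo:hi])) + lo


def generate_trajectory(params: GaitModelParams) -> tuple[GroundTruth, FootTrajectory]:
    """Build the continuous foot kinematics and its per-stride ground truth.

    Deterministic (no randomness): the same parameters always return
    bit-identical arrays.
    """
    lr, ms, ps, sw = params.phase_fractions
    T, fs = params.stride_time_s, params.fs
    t_move = (ps + sw + lr) * T  # heel-off .. next toe-strike
    t_flat = ms * T
    n_spans = params.n_strides + 1
    total = _LEAD_FLAT_S + n_spans * t_move + (n_spans - 1) * t_flat + _TAIL_FLAT_S
    n = int(round(total * fs)) + 1
    t = np.arange(n) / fs

    span_starts = _LEAD_FLAT_S + np.arange(n_spans) * (t_move + t_flat)
    # event times within a moving span (relative to span start = HO)
    rel_to = ps * T
    rel_hs = (ps + sw) * T
    rel_ts = t_move

    pos = np.zeros((n, 3))
    vel = np.zeros((n, 3))
    acc = np.zeros((n, 3))
    pitch = np.zeros(n)
    s_f, s_d1, s_d2 = _smootherstep()

    # vertical profile knots (relative time, mm) with zero 1st/2nd derivatives:
    # quintic pieces are monotone between knots, so each knot is an exact extremum
    z_knots_rel = np.array([0.0, rel_to + 0.25 * sw * T, rel_to + 0.55 * sw * T,
                            rel_to + 0.85 * sw * T, t_move])
    z_vals = np.array([0.0, params.max1_mm, params.min_mm, params.max2_mm, 0.0]) / 1000.0
    zpoly = BPoly.from_derivatives(z_knots_rel, [[v, 0.0, 0.0] for v in z_vals])
    zp1, zp2 = zpoly.derivative(1), zpoly.derivative(2)

    amp = np.deg2rad(params.pitch_amplitude_deg)
    for j, s0 in enumerate(span_starts):
        m = (t >= s0) & (t <= s0 + t_move)
        u = (t[m] - s0) / t_move
        pos[m, 0] = j * params.stride_length_m + params.stride_length_m * s_f(u)
        vel[m, 0] = params.stride_length_m / t_move * s_d1(u)
        acc[m, 0] = params.stride_length_m / t_move**2 * s_d2(u)
        rel = t[m] - s0
        pos[m, 2] = zpoly(rel)
        vel[m, 2] = zp1(rel)
        acc[m, 2] = zp2(rel)
        pitch[m] = amp * np.sin(2.0 * np.pi * u) * np.sin(np.pi * u) ** 2
        mflat = t > s0 + t_move
        pos[mflat, 0] = (j + 1) * params.stride_length_m

    omega = _omega_template(params, span_starts, rel_to, rel_hs, t_move, t_flat, t)

    # --- per-stride truth from the sampled clean template -------------------
    absw = np.abs(omega)
    hs_i, ts_i, ho_i, to_i, nx_i = [], [], [], [], []
    for k in range(params.n_strides):
        hs = _local_argmax(omega, int(round((span_starts[k] + rel_hs) * fs)))
        ho = int(round((span_starts[k + 1]) * fs))
        to = _local_argmax(omega, int(round((span_starts[k + 1] + rel_to) * fs)))
        nx = _local_argmax(omega, int(round((span_starts[k + 1] + rel_hs) * fs)))
        ts = _first_below(absw, hs, to, EVENT_THRESHOLD_DPS)
        # HO truth: last below-threshold sample before the TO rise
        below = np.flatnonzero(absw[ts : to] < EVENT_THRESHOLD_DPS) + ts
        ho = int(below[-1])
        hs_i.append(hs); ts_i.append(ts); ho_i.append(ho); to_i.append(to); nx_i.append(nx)

    hs_a = np.array(hs_i); nx_a = np.array(nx_i)
    phases = np.tile(np.array([lr, ms, ps, sw]) * 100.0, (params.n_strides, 1))
    truth = GroundTruth(
        hs=hs_a, ts=np.array(ts_i), ho=np.array(ho_i), to=np.array(to_i), hs_next=nx_a,
        stride_time_s=(nx_a - hs_a) / fs,
        stride_length_m=np.full(params.n_strides, params.stride_length_m),
        max1_mm=np.full(params.n_strides, params.max1_mm),
        min_mm=np.full(params.n_strides, params.min_mm),
        max2_mm=np.full(params.n_strides, params.max2_mm),
        phases_pct=phases,
        clearance_mm=pos[:, 2] * 1000.0,
    )
    traj = FootTrajectory(t=t, pos=pos, vel=vel, acc=acc, pitch_rad=pitch, omega_dps=omega, fs=fs)
    return truth, traj


def _omega_template(
    params: GaitModelParams,
    span_starts: np.ndarray,
    rel_to: float,
    rel_hs: float,
    t_move: float,
    t_flat: float,
    t: np.ndarray,
) -> np.ndarray:
    """Cubic-Hermite sagittal angular-velocity template, deg/s."""
    _, _, ps, sw = params.phase_fractions
    T = params.stride_time_s
    edge_slope = 300.0  # deg/s^2 at the TS/HO threshold crossings
    gap = min(0.16, 0.35 * t_flat, 0.3 * _LEAD_FLAT_S)
    # symmetric flank knots around each stance-adjacent peak keep the local
    # maximum in place under zero-phase low-pass filtering
    d = min(0.04, 0.35 * ps * T, 0.08 * sw * T)
    fl_hs = max(0.45 * params.hs_peak_dps, EVENT_THRESHOLD_DPS + 8.0)
    fl_to = max(0.45 * params.to_peak_dps, EVENT_THRESHOLD_DPS + 8.0)
    # flank slopes match the crossing slope so every piece stays monotone and
    # |omega| first crosses the threshold exactly at the TS/HO knots
    sl_hs = sl_to = edge_slope
    knots: list[tuple[float, float, float]] = [(t[0], _FLAT_OMEGA_DPS, 0.0)]
    for j, s0 in enumerate(span_starts):
        knots.append((s0 - gap, _FLAT_OMEGA_DPS, 0.0))
        knots.append((s0, EVENT_THRESHOLD_DPS, edge_slope))
        knots.append((s0 + rel_to - d, fl_to, sl_to))
        knots.append((s0 + rel_to, params.to_peak_dps, 0.0))
        knots.append((s0 + rel_to + d, fl_to, -sl_to))
        knots.append((s0 + rel_to + 0.25 * sw * T, -40.0, 0.0))
        knots.append((s0 + rel_to + 0.5 * sw * T, params.swing_peak_dps, 0.0))
        knots.append((s0 + rel_to + 0.72 * sw * T, -40.0, 0.0))
        knots.append((s0 + rel_hs - d, fl_hs, sl_hs))
        knots.append((s0 + rel_hs, params.hs_peak_dps, 0.0))
        knots.append((s0 + rel_hs + d, fl_hs, -sl_hs))
        knots.append((s0 + t_move, EVENT_THRESHOLD_DPS, -edge_slope))
        knots.append((s0 + t_move + gap, _FLAT_OMEGA_DPS, 0.0))
    knots.append((t[-1], _FLAT_OMEGA_DPS, 0.0))
    xs = np.array([k[0] for k in knots])
    if np.any(np.diff(xs) <= 0):
        raise ParameterError("phase/stride timing too tight for the angular-velocity template")
    poly = BPoly.from_derivatives(xs, [[k[1], k[2]] for k in knots])
    return poly(t)


def simulate_imu(traj: FootTrajectory, params: GaitModelParams) -> ImuRecording:
    """Synthesize the sensor streams for a trajectory.

    Specific force is the true global acceleration plus gravity, rotated into
    the sensor frame by the (exact) orientation, plus bias and white noise.
    The gyroscope's sagittal (y) channel carries the event template.
    """
    rng = np.random.default_rng(params.seed)
    n = len(traj)
    rot = Rotation.from_euler("y", traj.pitch_rad[:, None])
    a_with_g = traj.acc + np.array([0.0, 0.0, params.gravity_mps2])
    acc_sensor = rot.apply(a_with_g, inverse=True)
    acc_sensor += np.asarray(params.accel_bias_mps2, dtype=float)
    if params.accel_noise_mps2 > 0:
        acc_sensor = acc_sensor + rng.normal(0.0, params.accel_noise_mps2, (n, 3))
    gyr = np.zeros((n, 3))
    gyr[:, 1] = traj.omega_dps
    if params.gyro_noise_dps > 0:
        gyr = gyr + rng.normal(0.0, params.gyro_noise_dps, (n, 3))
    q_xyzw = rot.as_quat()
    quat = np.column_stack([q_xyzw[:, 3], q_xyzw[:, 0], q_xyzw[:, 1], q_xyzw[:, 2]])
    return ImuRecording(t=traj.t.copy(), acc=acc_sensor, gyr=gyr, quat=quat,
                        fs=traj.fs, foot=params.foot)


def simulate_markers(
    traj: FootTrajectory,
    marker_noise_mm: float = 0.0,
    seed: int | None = None,
    offset_mm: tuple[float, float, float] = (0.0, 35.0, 55.0),
) -> ReferenceTrajectory:
    """Reflective-marker track: true positions (mm) plus offset and white noise.

    The constant offset stands in for the marker's mounting position; the
    agreement stage removes the vertical part by min-subtraction.
    """
    if marker_noise_mm < 0:
        raise ParameterError("marker_noise_mm must be non-negative")
    pos_mm = traj.pos * 1000.0 + np.asarray(offset_mm, dtype=float)
    if marker_noise_mm > 0:
        rng = np.random.default_rng(seed)
        pos_mm = pos_mm + rng.normal(0.0, marker_noise_mm, pos_mm.shape)
    return ReferenceTrajectory(t=traj.t.copy(), pos=pos_mm, vertical_axis="z")


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class CohortGroup:
    """Between-subject parameter distributions (mean, SD) for one group."""

    n_subjects: int
    stride_time_s: tuple[float, float] = (1.2, 0.08)
    stride_length_m: tuple[float, float] = (1.30, 0.15)
    lr_pct: tuple[float, float] = (11.0, 1.5)
    ms_pct: tuple[float, float] = (42.0, 3.0)
    ps_pct: tuple[float, float] = (12.0, 1.5)
    max1_mm: tuple[float, float] = (150.0, 15.0)
    min_mm: tuple[float, float] = (90.0, 12.0)
    max2_mm: tuple[float, float] = (120.0, 12.0)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ParameterError("n_subjects must be >= 1")
        for name in ("stride_time_s", "stride_length_m", "lr_pct", "ms_pct",
                     "ps_pct", "max1_mm", "min_mm", "max2_mm"):
            mean, sd = getattr(self, name)
            if sd < 0:
                raise ParameterError(f"{name} SD must be non-negative")


@dataclass
class CohortSpec:
    """Group structure of a synthetic cohort."""

    groups: dict[str, CohortGroup] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ParameterError("cohort must contain at least one group")


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, dict[str, GaitModelParams]]:
    """Draw subject-level gait parameters for every group.

    Returns a tidy per-subject table and, per subject, the
    :class:`GaitModelParams` that realize those parameters in a full trial
    simulation. Draws are clipped to physiologic floors so every subject's
    parameters remain valid.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    subject_params: dict[str, GaitModelParams] = {}
    for group, g in spec.groups.items():
        for i in range(g.n_subjects):
            sid = f"{group}_{i:03d}"
            st = max(rng.normal(*g.stride_time_s), 0.6)
            sl = max(rng.normal(*g.stride_length_m), 0.2)
            lr = float(np.clip(rng.normal(*g.lr_pct), 4.0, 25.0))
            ms = float(np.clip(rng.normal(*g.ms_pct), 25.0, 65.0))
            ps = float(np.clip(rng.normal(*g.ps_pct), 4.0, 25.0))
            sw = 100.0 - lr - ms - ps
            if sw < 15.0:  # keep a plausible swing share
                scale = (100.0 - 15.0) / (lr + ms + ps)
                lr, ms, ps, sw = lr * scale, ms * scale, ps * scale, 15.0
            mn = max(rng.normal(*g.min_mm), 20.0)
            m1 = max(rng.normal(*g.max1_mm), mn + 5.0)
            m2 = max(rng.normal(*g.max2_mm), mn + 5.0)
            rows.append({
                "subject": sid, "group": group,
                "st_s": st, "sl_m": sl, "sp_mps": sl / st,
                "lr_pct": lr, "ms_pct": ms, "ps_pct": ps, "sw_pct": sw,
                "max1_mm": m1, "min_mm": mn, "max2_mm": m2,
            })
            subject_params[sid] = GaitModelParams(
                stride_time_s=st,
                phase_fractions=(lr / 100.0, ms / 100.0, ps / 100.0, sw / 100.0),
                stride_length_m=sl,
                max1_mm=m1, min_mm=mn, max2_mm=m2,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
    return pd.DataFrame(rows), subject_params
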