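"""Sensor/reference file I/O, run configuration, and signal preconditioning.

Conventions
-----------
* Quaternions are scalar-first ``(w, x, y, z)`` Hamilton quaternions encoding
  the sensor-to-global rotation.
* Accelerometer streams are specific force in m/s^2 (gravity included),
  gyroscope streams are angular velocity in deg/s.
* All low-pass filtering is zero-phase (forward-backward), so the effective
  attenuation order is twice the design order but events suffer no phase lag.
"""

from __future__ import annotations

import dataclasses
import io as _stdio
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import signal

from .errors import DataError, FormatError, ParameterError

__all__ = [
    "ImuRecording",
    "ReferenceTrajectory",
    "PipelineConfig",
    "load_imu_recording",
    "write_imu_recording",
    "load_reference_trajectory",
    "write_reference_trajectory",
    "butterworth_lowpass",
]

#: column roles an IMU trial file must provide (time is optional when fs is given)
IMU_ROLES = ("ax", "ay", "az", "gx", "gy", "gz", "qw", "qx", "qy", "qz")

_QUAT_NORM_TOL = 1e-6
_TIME_STEP_TOL = 1e-9


@dataclass
class ImuRecording:
    """One trial's synchronized accelerometer/gyroscope/quaternion streams.

    Attributes
    ----------
    t : (n,) float array, seconds, uniformly sampled
    acc : (n, 3) float array, specific force in m/s^2, sensor frame
    gyr : (n, 3) float array, angular velocity in deg/s, sensor frame
    quat : (n, 4) float array, unit quaternions, scalar-first, sensor-to-global
    fs : sampling rate, Hz
    foot : 'left' or 'right'
    """

    t: np.ndarray
    acc: np.ndarray
    gyr: np.ndarray
    quat: np.ndarray
    fs: float
    foot: str = "right"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.acc = np.atleast_2d(np.asarray(self.acc, dtype=float))
        self.gyr = np.atleast_2d(np.asarray(self.gyr, dtype=float))
        self.quat = np.atleast_2d(np.asarray(self.quat, dtype=float))
        n = self.t.size
        if n < 2:
            raise DataError("recording must contain at least 2 samples")
        for name, arr, width in (("acc", self.acc, 3), ("gyr", self.gyr, 3), ("quat", self.quat, 4)):
            if arr.shape != (n, width):
                raise DataError(f"{name} must have shape ({n}, {width}), got {arr.shape}")
            if not np.all(np.isfinite(arr)):
                raise DataError(f"{name} contains non-finite values")
        if not self.fs > 0:
            raise DataError(f"sampling rate must be positive, got {self.fs}")
        if self.foot not in ("left", "right"):
            raise DataError(f"foot must be 'left' or 'right', got {self.foot!r}")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise DataError("time vector is not strictly increasing")
        if np.max(np.abs(dt - 1.0 / self.fs)) > _TIME_STEP_TOL:
            raise DataError("time vector is not uniform at 1/fs")
        norms = np.linalg.norm(self.quat, axis=1)
        bad = np.abs(norms - 1.0) > _QUAT_NORM_TOL
        if np.any(bad):
            i = int(np.argmax(bad))
            raise DataError(f"quaternion at sample {i} has norm {norms[i]:.6g} (expected 1)")

    def __len__(self) -> int:
        return self.t.size


@dataclass
class ReferenceTrajectory:
    """Time-stamped 3-D marker positions (mm, lab frame) used for validation."""

    t: np.ndarray
    pos: np.ndarray
    vertical_axis: str = "z"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.pos = np.atleast_2d(np.asarray(self.pos, dtype=float))
        if self.pos.shape != (self.t.size, 3):
            raise DataError(f"pos must have shape ({self.t.size}, 3), got {self.pos.shape}")
        if not np.all(np.isfinite(self.pos)):
            raise DataError("reference trajectory contains non-finite coordinates")
        if self.t.size and np.any(np.diff(self.t) <= 0):
            raise DataError("time vector is not strictly increasing")
        if self.vertical_axis not in ("x", "y", "z"):
            raise DataError(f"vertical_axis must be x, y or z, got {self.vertical_axis!r}")

    @property
    def vertical(self) -> np.ndarray:
        """Vertical coordinate series in mm."""
        return self.pos[:, "xyz".index(self.vertical_axis)]

    def __len__(self) -> int:
        return self.t.size


@dataclass
class PipelineConfig:
    """Run configuration; defaults follow the published processing choices."""

    gyro_cutoff_hz: float = 3.0
    accel_cutoff_hz: float = 10.0
    filter_order: int = 2
    ts_ho_threshold_dps: float = 30.0
    n_central_strides: int = 10
    gravity_mps2: float = 9.80665
    gpqi_variant: str = "as_printed"
    min_stride_s: float = 0.6
    max_stride_s: float = 2.5
    swing_peak_prominence_dps: float = 50.0
    integrator: str = "trapezoid"
    clearance_detrend: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ts_ho_threshold_dps <= 0:
            raise ParameterError("ts_ho_threshold_dps must be > 0")
        if self.n_central_strides < 1:
            raise ParameterError("n_central_strides must be >= 1")
        if self.gpqi_variant not in ("as_printed", "per_foot_sqrt"):
            raise ParameterError(f"unknown gpqi_variant {self.gpqi_variant!r}")
        if self.gyro_cutoff_hz <= 0 or self.accel_cutoff_hz <= 0:
            raise ParameterError("filter cutoffs must be positive")
        if self.integrator not in ("trapezoid", "simpson", "spline"):
            raise ParameterError(f"unknown integrator {self.integrator!r}")

    def validate_against_fs(self, fs: float) -> None:
        for cut in (self.gyro_cutoff_hz, self.accel_cutoff_hz):
            if cut >= fs / 2:
                raise ParameterError(f"cutoff {cut} Hz is not below Nyquist for fs={fs} Hz")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise FormatError(f"config file {path} must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# file I/O


def _read_table(path: str | Path) -> pd.DataFrame:
    # comma-, semicolon- or tab-delimited with header; the delimiter is sniffed
    # from the header line and floats are parsed with exact round-tripping
    try:
        with open(path) as fh:
            header = fh.readline()
        sep = max(",;\t", key=header.count)
        if header.count(sep) == 0:
            sep = r"\s+"
        return pd.read_csv(path, sep=sep, float_precision="round_trip")
    except OSError as exc:
        raise FormatError(f"could not read {path}: {exc}") from exc
    except Exception as exc:  # pragma: no cover - pandas error wording varies
        raise FormatError(f"could not parse {path}: {exc}") from exc


def load_imu_recording(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    fs: float | None = None,
    foot: str = "right",
) -> ImuRecording:
    """Read a delimited-text IMU trial.

    Parameters
    ----------
    column_map : mapping from role (``t``, ``ax`` ... ``qz``) to the column
        name used in the file. Roles absent from the map default to their own
        name. This keeps the reader robust to vendor export naming.
    fs : sampling rate in Hz; required when the file has no time column,
        otherwise inferred from the time column.
    """
    df = _read_table(path)
    cmap = dict(column_map or {})

    def col(role: str, required: bool = True) -> np.ndarray | None:
        name = cmap.get(role, role)
        if name not in df.columns:
            if required:
                raise FormatError(f"missing column {name!r} for role {role!r}")
            return None
        return df[name].to_numpy(dtype=float)

    t = col("t", required=False)
    data = {role: col(role) for role in IMU_ROLES}
    n = len(df)
    if t is not None:
        if n < 2 or np.any(np.diff(t) <= 0):
            raise DataError("time column is not strictly increasing")
        inferred = 1.0 / float(np.median(np.diff(t)))
        fs = inferred if fs is None else fs
    elif fs is None:
        raise ParameterError("file has no time column; sampling rate fs must be supplied")
    else:
        t = np.arange(n) / fs
    acc = np.column_stack([data["ax"], data["ay"], data["az"]])
    gyr = np.column_stack([data["gx"], data["gy"], data["gz"]])
    quat = np.column_stack([data["qw"], data["qx"], data["qy"], data["qz"]])
    return ImuRecording(t=t, acc=acc, gyr=gyr, quat=quat, fs=float(fs), foot=foot)


def write_imu_recording(rec: ImuRecording, path: str | Path) -> None:
    """Write a trial as comma-delimited text; numeric payloads round-trip exactly."""
    cols = {"t": rec.t}
    for i, role in enumerate(("ax", "ay", "az")):
        cols[role] = rec.acc[:, i]
    for i, role in enumerate(("gx", "gy", "gz")):
        cols[role] = rec.gyr[:, i]
    for i, role in enumerate(("qw", "qx", "qy", "qz")):
        cols[role] = rec.quat[:, i]
    _write_exact(cols, path)


def load_reference_trajectory(path: str | Path, vertical_axis: str = "z") -> ReferenceTrajectory:
    """Read a delimited-text reference marker track (t in s, x/y/z in mm)."""
    df = _read_table(path)
    for name in ("t", "x", "y", "z"):
        if name not in df.columns:
            raise FormatError(f"missing column {name!r} in reference trajectory")
    arr = df[["x", "y", "z"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(arr)):
        raise DataError("reference trajectory contains non-finite coordinates")
    return ReferenceTrajectory(t=df["t"].to_numpy(dtype=float), pos=arr, vertical_axis=vertical_axis)


def write_reference_trajectory(traj: ReferenceTrajectory, path: str | Path) -> None:
    cols = {"t": traj.t, "x": traj.pos[:, 0], "y": traj.pos[:, 1], "z": traj.pos[:, 2]}
    _write_exact(cols, path)


def _write_exact(cols: Mapping[str, np.ndarray], path: str | Path) -> None:
    # %.17g preserves float64 exactly through text round-trips
    buf = _stdio.StringIO()
    names = list(cols)
    buf.write(",".join(names) + "\n")
    mat = np.column_stack([cols[n] for n in names])
    np.savetxt(buf, mat, fmt="%.17g", delimiter=",")
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# preconditioning


def butterworth_lowpass(
    x: np.ndarray, cutoff: float, order: int, fs: float, axis: int = 0
) -> np.ndarray:
    """Zero-phase Butterworth low-pass (effective order ``2 * order``).

    Raises
    ------
    ParameterError
        If ``cutoff`` is at or above the Nyquist frequency.
    """
    if not 0 < cutoff < fs / 2:
        raise ParameterError(f"cutoff must lie in (0, fs/2)={fs / 2}, got {cutoff}")
    x = np.asarray(x, dtype=float)
    sos = signal.butter(order, cutoff, btype="low", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x, axis=axis)
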