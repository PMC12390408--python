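"""High-level per-trial analysis used by the CLI and tests."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import agreement as agr
from . import events as ev
from . import spatial as sp
from . import temporal as tp
from .io_config import ImuRecording, PipelineConfig, ReferenceTrajectory, butterworth_lowpass

__all__ = ["TrialResult", "run_trial", "validate_against_reference"]

#: sensor axis carrying the sagittal angular velocity (body frontal axis)
SAGITTAL_AXIS = 1


@dataclass
class TrialResult:
    events: ev.GaitEvents
    temporal: tp.TemporalSummary
    strides: list[sp.SpatialStride]

    def to_frame(self, subject: str = "", state: str = "") -> pd.DataFrame:
        rows = []
        for k, s in enumerate(self.strides):
            ph = self.temporal.phases[k]
            rows.append({
                "subject": subject, "state": state, "foot": self.events.foot,
                "stride_index": k,
                "st_s": s.st_s, "sl_m": s.sl_m, "sp_mps": s.sp_mps,
                "lr_pct": ph.lr_pct, "ms_pct": ph.ms_pct,
                "ps_pct": ph.ps_pct, "sw_pct": ph.sw_pct,
                "cadence_spm": self.temporal.cadence,
                "max1_mm": s.max1_mm, "min_mm": s.min_mm, "max2_mm": s.max2_mm,
                "max1_valid": s.max1_valid, "min_valid": s.min_valid,
                "max2_valid": s.max2_valid,
            })
        return pd.DataFrame(rows)


def detect_trial_events(rec: ImuRecording, config: PipelineConfig | None = None) -> ev.GaitEvents:
    """Filter, orient, window and detect gait events for one trial."""
    config = config or PipelineConfig()
    config.validate_against_fs(rec.fs)
    omega = butterworth_lowpass(rec.gyr[:, SAGITTAL_AXIS], config.gyro_cutoff_hz,
                                config.filter_order, rec.fs)
    omega = ev.auto_orient(omega)
    windows = ev.find_stride_windows(
        omega, rec.fs,
        min_stride_s=config.min_stride_s, max_stride_s=config.max_stride_s,
        prominence_dps=config.swing_peak_prominence_dps,
    )
    return ev.detect_events(omega, windows, rec.fs,
                            threshold_dps=config.ts_ho_threshold_dps, foot=rec.foot)


def run_trial(
    rec: ImuRecording,
    config: PipelineConfig | None = None,
    segments: list[tuple[int, int]] | None = None,
    reference_phases: tp.GaitPhaseProfile | None = None,
) -> TrialResult:
    """Full single-trial analysis: events, temporal and spatial parameters.

    ``segments`` are walking-bout boundaries for central-stride selection;
    when omitted, all detected strides are analyzed.
    """
    config = config or PipelineConfig()
    events = detect_trial_events(rec, config)
    if segments:
        events = ev.select_central_strides(events, segments, config.n_central_strides)

    phases = tp.gait_phases(events)
    mean_ph = tp.mean_phase_profile(phases)
    gpqi_val = None
    if reference_phases is not None:
        # single-foot trial: both feet of the index collapse onto this foot
        gpqi_val = tp.gpqi(mean_ph, mean_ph, reference_phases, config.gpqi_variant)
    summary = tp.TemporalSummary(
        stride_times=tp.stride_time(events),
        cadence=tp.cadence(events),
        phases=phases,
        mean_phases=mean_ph,
        gpqi=gpqi_val,
    )
    # accelerometer preconditioning before inertial integration
    acc_f = butterworth_lowpass(rec.acc, config.accel_cutoff_hz, config.filter_order, rec.fs)
    rec_f = ImuRecording(t=rec.t, acc=acc_f, gyr=rec.gyr, quat=rec.quat, fs=rec.fs, foot=rec.foot)
    strides = sp.spatial_strides(rec_f, events, gravity_mps2=config.gravity_mps2,
                                 scheme=config.integrator,
                                 detrend_displacement=config.clearance_detrend)
    return TrialResult(events=events, temporal=summary, strides=strides)


def validate_against_reference(
    rec: ImuRecording,
    ref: ReferenceTrajectory,
    config: PipelineConfig | None = None,
    robust: bool = True,
) -> agr.AgreementReport:
    """Agreement stage: IMU clearance landmarks vs a synchronized marker track.

    ``robust`` enables the noise-tolerant reference baseline and landmark
    extraction (identical to the direct rules on noise-free tracks).
    """
    result = run_trial(rec, config)
    ref_clear = agr.normalize_reference(ref, robust=robust)
    pairs, n_excl = agr.pair_landmarks(result.strides, ref_clear, result.events, robust=robust)
    return agr.build_report(pairs, n_excluded=n_excl)
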