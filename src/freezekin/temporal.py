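"""Temporal gait parameters: stride time, phase percentages, cadence, GPQI."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import DataError, ParameterError
from .events import GaitEvents

__all__ = [
    "GaitPhaseProfile",
    "TemporalSummary",
    "stride_time",
    "gait_phases",
    "mean_phase_profile",
    "cadence",
    "gpqi",
    "reference_profile",
]

GPQI_VARIANTS = ("as_printed", "per_foot_sqrt")


@dataclass(frozen=True)
class GaitPhaseProfile:
    """Loading response / midstance / pre-swing / swing as % of stride time."""

    lr_pct: float
    ms_pct: float
    ps_pct: float
    sw_pct: float

    def __post_init__(self) -> None:
        vals = self.as_array()
        if np.any(vals < 0) or np.any(vals > 100):
            raise DataError(f"phase percentages must lie in [0, 100]: {vals}")
        if abs(float(vals.sum()) - 100.0) > 1e-9:
            raise DataError(f"phase percentages must sum to 100, got {vals.sum()!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.lr_pct, self.ms_pct, self.ps_pct, self.sw_pct], dtype=float)


@dataclass
class TemporalSummary:
    """Per-trial temporal metrics for one foot."""

    stride_times: np.ndarray
    cadence: int
    phases: list[GaitPhaseProfile]
    mean_phases: GaitPhaseProfile
    gpqi: float | None = None


def stride_time(events: GaitEvents) -> np.ndarray:
    """Seconds between consecutive heel strikes, per stride."""
    if events.n_strides < 1:
        raise DataError("at least one stride is required")
    return (events.hs_next - events.hs) / events.fs


def gait_phases(events: GaitEvents) -> list[GaitPhaseProfile]:
    """Phase durations as percentages of each stride's total time.

    LR = HS..TS, MS = TS..HO, PS = HO..TO, SW = TO..next HS; the four values
    sum to 100 exactly by construction.
    """
    out = []
    for hs, ts, ho, to, nx in zip(events.hs, events.ts, events.ho, events.to, events.hs_next):
        total = nx - hs
        if total <= 0:
            raise DataError("zero-length stride")
        lr = (ts - hs) / total * 100.0
        ms = (ho - ts) / total * 100.0
        ps = (to - ho) / total * 100.0
        sw = 100.0 - lr - ms - ps
        out.append(GaitPhaseProfile(lr, ms, ps, sw))
    return out


def mean_phase_profile(profiles: Sequence[GaitPhaseProfile]) -> GaitPhaseProfile:
    """Componentwise mean of phase profiles, renormalized to sum to 100."""
    if not profiles:
        raise ParameterError("at least one phase profile is required")
    m = np.mean([p.as_array() for p in profiles], axis=0)
    m = m / m.sum() * 100.0
    sw = 100.0 - m[0] - m[1] - m[2]
    return GaitPhaseProfile(float(m[0]), float(m[1]), float(m[2]), float(sw))


def reference_profile(profiles: Iterable[GaitPhaseProfile]) -> GaitPhaseProfile:
    """Reference phase sequence: mean profile of a healthy-control cohort."""
    return mean_phase_profile(list(profiles))


def cadence(events: GaitEvents, duration_s: float | None = None) -> int:
    """Strides per minute, rounded down to the nearest integer.

    The gait duration defaults to the span from the first to the last heel
    strike of the analyzed strides, matching the counted strides.
    """
    if events.n_strides == 0:
        return 0
    if duration_s is None:
        duration_s = events.duration_s()
    if duration_s <= 0:
        raise ParameterError("duration_s must be positive")
    return int(math.floor(events.n_strides / (duration_s / 60.0)))


def gpqi(
    subject_left: GaitPhaseProfile,
    subject_right: GaitPhaseProfile,
    reference: GaitPhaseProfile,
    variant: str = "as_printed",
) -> float:
    """Gait Phase Quality Index: squared discrepancy from the reference profile.

    ``as_printed`` sums the squared phase deviations over both feet;
    ``per_foot_sqrt`` sums the per-foot Euclidean distances instead. Lower is
    closer to the reference.
    """
    if variant not in GPQI_VARIANTS:
        raise ParameterError(f"unknown GPQI variant {variant!r}; choose from {GPQI_VARIANTS}")
    ref = reference.as_array()
    total = 0.0
    for foot in (subject_left, subject_right):
        ss = float(np.sum((foot.as_array() - ref) ** 2))
        total += math.sqrt(ss) if variant == "per_foot_sqrt" else ss
    return total
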