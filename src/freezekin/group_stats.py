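"""Two-group comparison machinery: Shapiro-Wilk gating, then Mann-Whitney U or t-test.

A parameter is classified non-normal if *any* compared group rejects
Shapiro-Wilk at alpha = 0.05, which yields a single test choice per parameter.
Raw p-values are reported per comparison; no multiple-testing correction is
applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import GateError, ParameterError

__all__ = [
    "GROUPS",
    "COMPARISON_PAIRS",
    "GroupSample",
    "ComparisonResult",
    "normality_gate",
    "compare",
    "run_comparison_grid",
    "significance_stars",
]

log = logging.getLogger(__name__)

GROUPS = ("HC", "PDoff", "PDon", "NOFOGoff", "NOFOGon", "FOGoff", "FOGon")

#: the eight comparisons run per parameter
COMPARISON_PAIRS = (
    ("HC", "PDoff"),
    ("HC", "PDon"),
    ("HC", "NOFOGoff"),
    ("HC", "NOFOGon"),
    ("HC", "FOGoff"),
    ("HC", "FOGon"),
    ("NOFOGoff", "FOGoff"),
    ("NOFOGon", "FOGon"),
)

SHAPIRO_ALPHA = 0.05
#: largest per-group n for which the exact Mann-Whitney null is used (no ties)
EXACT_MW_MAX_N = 20


@dataclass
class GroupSample:
    """One parameter's per-subject values for one group."""

    group: str
    parameter: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ParameterError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ParameterError("values must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("values must be finite")


@dataclass(frozen=True)
class ComparisonResult:
    group_a: str
    group_b: str
    parameter: str
    test: str  # 'mann_whitney_u' | 't_test'
    p_value: float
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    median_a: float
    median_b: float

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


def significance_stars(p: float) -> str:
    """Annotation thresholds 0.05 / 0.01 / 0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def normality_gate(samples: Sequence[GroupSample], alpha: float = SHAPIRO_ALPHA) -> str:
    """Shapiro-Wilk gate: 'non_normal' if any group rejects at ``alpha``."""
    if not samples:
        raise GateError("no groups supplied to the normality gate")
    for s in samples:
        if s.values.size < 3:
            raise GateError(f"group {s.group} has {s.values.size} values; Shapiro-Wilk needs >= 3")
        if np.ptp(s.values) == 0:
            raise GateError(f"group {s.group} is constant; normality is undefined")
        _, p = stats.shapiro(s.values)
        if p < alpha:
            return "non_normal"
    return "normal"


def compare(a: GroupSample, b: GroupSample, gate: str, equal_var: bool = True) -> ComparisonResult:
    """Two-sided Mann-Whitney U (non_normal) or independent-samples t-test (normal)."""
    if a.parameter != b.parameter:
        raise ParameterError(f"parameter mismatch: {a.parameter!r} vs {b.parameter!r}")
    if gate == "non_normal":
        x, y = a.values, b.values
        no_ties = np.unique(np.concatenate([x, y])).size == x.size + y.size
        method = "exact" if (no_ties and max(x.size, y.size) <= EXACT_MW_MAX_N) else "asymptotic"
        _, p = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        test = "mann_whitney_u"
    elif gate == "normal":
        _, p = stats.ttest_ind(a.values, b.values, equal_var=equal_var)
        test = "t_test"
    else:
        raise ParameterError(f"gate must be 'normal' or 'non_normal', got {gate!r}")
    sd = lambda v: float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    return ComparisonResult(
        group_a=a.group, group_b=b.group, parameter=a.parameter, test=test,
        p_value=float(p),
        mean_a=float(np.mean(a.values)), sd_a=sd(a.values),
        mean_b=float(np.mean(b.values)), sd_b=sd(b.values),
        median_a=float(np.median(a.values)), median_b=float(np.median(b.values)),
    )


def run_comparison_grid(samples: Iterable[GroupSample], equal_var: bool = True) -> list[ComparisonResult]:
    """Run the eight standard comparisons for every parameter present.

    Each parameter is first gated across all its supplied groups; pairs with a
    missing group are skipped with a warning.
    """
    by_param: dict[str, dict[str, GroupSample]] = {}
    for s in samples:
        by_param.setdefault(s.parameter, {})[s.group] = s
    results: list[ComparisonResult] = []
    for param in sorted(by_param):
        groups = by_param[param]
        gate = normality_gate(list(groups.values()))
        for ga, gb in COMPARISON_PAIRS:
            if ga not in groups or gb not in groups:
                missing = [g for g in (ga, gb) if g not in groups]
                log.warning("parameter %s: comparison %s vs %s skipped, missing %s", param, ga, gb, missing)
                continue
            results.append(compare(groups[ga], groups[gb], gate, equal_var=equal_var))
    return results
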