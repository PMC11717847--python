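"""Readout statistics for sensorgram traces.

Two relative-change statistics summarize each experiment step:

* **instantaneous change** — the abrupt baseline shift right at reagent
  addition: 100 * (V(t_after) - V(t_before)) / V(t_before), signed.
* **gradual change** — the slow shift attributed to binding kinetics,
  measured between two fixed reference instants: the value 400 s after
  the start of the step's recording window versus the value 50 s after
  sample addition, normalized by the latter.  The asymmetry of the two
  reference frames (window start vs. addition instant) is deliberate and
  preserved exactly.

Triplicate experiments are summarized by mean and sample SD, and group
differences are assessed with a classical pooled one-way ANOVA (for two
groups, F equals the squared pooled two-sample t statistic).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .trace import Trace

#: reference offsets of the gradual-change statistic, seconds
GRADUAL_LATE_OFFSET = 400.0  # after the start of the step's recording window
GRADUAL_EARLY_OFFSET = 50.0  # after sample addition


class InsufficientDataError(ValueError):
    """Too few observations for the requested statistic."""


class UndefinedRatioError(ZeroDivisionError):
    """The reference voltage of a relative change is zero."""


@dataclass(frozen=True)
class StepStats:
    """Both change statistics of one experiment step, with the instants used."""

    instantaneous_change_pct: float
    gradual_change_pct: float
    t_before: float
    t_after: float

    def __post_init__(self) -> None:
        if self.t_after <= self.t_before:
            raise ValueError("t_after must exceed t_before")


@dataclass(frozen=True)
class GroupSummary:
    """Mean, sample SD (n-1 denominator) and size of one group of changes (%)."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise InsufficientDataError("a group summary needs n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


def instantaneous_change_pct(trace: Trace, t_before: float, t_after: float) -> float:
    """Signed percent baseline step between two instants (nearest samples).

    100 * (V(t_after) - V(t_before)) / V(t_before); negative means the
    output dropped.
    """
    v_before = trace.value_at(t_before)
    v_after = trace.value_at(t_after)
    if v_before == 0.0:
        raise UndefinedRatioError(f"trace value at t_before={t_before:g} s is zero")
    return 100.0 * (v_after - v_before) / v_before


def gradual_change_pct(trace: Trace, step_record_start: float,
                       addition_time: float) -> float:
    """Signed percent gradual change of one step.

    100 * (V(step_record_start + 400 s) - V(addition_time + 50 s))
        / V(addition_time + 50 s).
    """
    if step_record_start > addition_time:
        raise ValueError("step_record_start must not exceed addition_time")
    v_early = trace.value_at(addition_time + GRADUAL_EARLY_OFFSET)
    v_late = trace.value_at(step_record_start + GRADUAL_LATE_OFFSET)
    if v_early == 0.0:
        raise UndefinedRatioError("trace value at the early reference instant is zero")
    return 100.0 * (v_late - v_early) / v_early


def step_stats(trace: Trace, step_record_start: float, addition_time: float,
               pre_offset: float = 2.0, post_offset: float = 0.0) -> StepStats:
    """Both statistics of one step from its window start and addition instant.

    The instantaneous change is read between ``addition_time - pre_offset``
    and ``addition_time + post_offset``.  The default post offset of 0
    reads the first sample at/after the addition — the step is already
    applied there while the exponential component is still exactly zero.
    """
    t_before = addition_time - pre_offset
    t_after = addition_time + post_offset
    return StepStats(
        instantaneous_change_pct=instantaneous_change_pct(trace, t_before, t_after),
        gradual_change_pct=gradual_change_pct(trace, step_record_start, addition_time),
        t_before=t_before,
        t_after=t_after,
    )


def triplicate_summary(values) -> GroupSummary:
    """Mean and sample SD of a group of percent changes."""
    arr = np.asarray(list(values), dtype=float)
    if len(arr) < 2:
        raise InsufficientDataError(f"need at least 2 values, got {len(arr)}")
    return GroupSummary(mean=float(np.mean(arr)), sd=float(np.std(arr, ddof=1)),
                        n=len(arr))


def anova_oneway(groups) -> tuple[float, float]:
    """Classical fixed-effects one-way ANOVA across groups of percent changes.

    Returns (F, p).  Uses the pooled-variance form; for two groups F is
    the square of the pooled two-sample t statistic.  Two identical
    groups give F = 0, p = 1.
    """
    groups = [np.asarray(list(g), dtype=float) for g in groups]
    if len(groups) < 2:
        raise InsufficientDataError("need at least 2 groups")
    for g in groups:
        if len(g) < 2:
            raise InsufficientDataError("every group needs n >= 2")
    f, p = stats.f_oneway(*groups)
    if np.isnan(f):  # all observations identical: no variance anywhere
        return 0.0, 1.0
    return float(f), float(p)


def detect_step(trace: Trace, threshold: float = 0.05) -> float:
    """Time of the largest single-sample relative jump exceeding ``threshold``.

    Convenience only: annotated event times, when present, are
    authoritative and are never overridden by this detector.
    """
    v = trace.values
    prev = v[:-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(np.diff(v)) / np.abs(prev)
    rel[~np.isfinite(rel)] = 0.0
    i = int(np.argmax(rel))
    if rel[i] < threshold:
        raise ValueError(
            f"no single-sample relative jump exceeds the threshold {threshold:g}"
        )
    return float(trace.times[i + 1])
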