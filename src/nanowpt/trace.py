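"""Time-series container for lock-in amplifier output traces.

A :class:`Trace` is a uniformly sampled voltage record with event
annotations (reagent-addition instants).  All readout statistics read
trace values at stated instants as the *nearest sample* — at the default
225 samples/s this rounds reference instants by at most ~2.2 ms, well
below any time scale of the binding response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class TraceRangeError(ValueError):
    """A reference instant falls outside the recorded time span."""


@dataclass
class Trace:
    """Sampled output voltage vs. time with event annotations.

    Parameters
    ----------
    times : ndarray of float
        Sample instants in seconds, strictly increasing, nominally
        uniform at 1/sampling_rate spacing.
    values : ndarray of float
        Output voltage at each sample, in volts.
    annotations : list of (float, str)
        ``(event_time_s, label)`` pairs marking reagent additions.
    """

    times: np.ndarray
    values: np.ndarray
    annotations: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.values.ndim != 1:
            raise ValueError("times and values must be 1-D arrays")
        if len(self.times) != len(self.values):
            raise ValueError(
                f"times ({len(self.times)}) and values ({len(self.values)}) "
                "must have the same length"
            )
        if len(self.times) >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        self.annotations = [(float(t), str(lab)) for t, lab in self.annotations]

    def __len__(self) -> int:
        return len(self.times)

    @property
    def duration(self) -> float:
        """Recorded span in seconds."""
        return float(self.times[-1] - self.times[0])

    @property
    def sampling_rate(self) -> float:
        """Nominal sampling rate (1 / median sample spacing), in S/s."""
        if len(self.times) < 2:
            raise ValueError("sampling rate undefined for a single-sample trace")
        return 1.0 / float(np.median(np.diff(self.times)))

    def index_at(self, t: float) -> int:
        """Index of the sample nearest to instant ``t`` (seconds)."""
        if not (self.times[0] <= t <= self.times[-1]):
            raise TraceRangeError(
                f"instant t={t:g} s outside recorded span "
                f"[{self.times[0]:g}, {self.times[-1]:g}] s"
            )
        return int(np.argmin(np.abs(self.times - t)))

    def value_at(self, t: float) -> float:
        """Voltage of the sample nearest to instant ``t``."""
        return float(self.values[self.index_at(t)])

    def scaled(self, factor: float) -> "Trace":
        """Return a copy with all values multiplied by ``factor``."""
        return Trace(self.times.copy(), self.values * factor, list(self.annotations))
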