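"""Time-domain model of the sensor output under reagent-addition events.

Each reagent addition produces (a) an instantaneous fractional step of
the output baseline (the bulk impedance of the added liquid) and (b) a
gradual first-order exponential component (surface binding of antibody
or protein), saturating within 10-15 min at the default time constant.
Steps compose multiplicatively — all readout statistics are relative
changes — and the exponential components add on top of the stepped
baseline:

    V(t) = B * prod_i (1 + s_i)            for events with t_i <= t
             * (1 + sum_i a_i (1 - exp(-(t - t_i)/tau_i)))
             * (1 + drift * t)
             + white noise

The model parameterizes the *output-voltage level* directly: that is the
level at which all the readout statistics are defined, and the mapping
from well impedance to output is monotone and locally linear for the
small relative changes involved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trace import Trace

#: reagent-addition kinds understood by the protocol layer
EVENT_KINDS = (
    "buffer_fill",
    "negative_control",
    "antibody",
    "protein",
    "patient_serum",
    "healthy_serum",
    "refill",
)


@dataclass(frozen=True)
class ReagentEvent:
    """One reagent addition: instantaneous step plus exponential response.

    ``step_fraction`` is the instantaneous fractional change of the output
    baseline (−0.5 halves the output); ``gradual_amplitude`` is the
    asymptotic fractional change of the exponential component after the
    step; ``time_constant`` its first-order time constant in seconds.
    """

    time: float  # s
    kind: str
    step_fraction: float = 0.0
    gradual_amplitude: float = 0.0
    time_constant: float = 240.0  # s

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("event time must be >= 0")
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}; one of {EVENT_KINDS}")
        if self.gradual_amplitude != 0 and self.time_constant <= 0:
            raise ValueError("time_constant must be > 0 when gradual_amplitude != 0")


@dataclass(frozen=True)
class NoiseModel:
    """Measurement imperfections: white noise and linear drift.

    ``white_noise_sd`` and ``drift_rate`` are fractions of the baseline
    (per second for the drift).  These are calibration knobs emulating
    the recorded traces, not physics.

    The simulated trace stands for the output of a lock-in amplifier
    whose demodulation bandwidth is far below the sampling rate, so the
    white-noise process is band-limited by the instrument's own one-pole
    filter at ``noise_bandwidth`` (Hz) before it reaches the record;
    ``white_noise_sd`` is the sd of the unfiltered process.  Set
    ``noise_bandwidth=None`` for raw iid noise per sample.
    """

    white_noise_sd: float = 0.002
    drift_rate: float = 0.0  # fraction of baseline per second
    seed: int = 0
    noise_bandwidth: float | None = 2.0  # Hz; None = iid per sample

    def __post_init__(self) -> None:
        if self.white_noise_sd < 0:
            raise ValueError("white_noise_sd must be >= 0")
        if self.noise_bandwidth is not None and self.noise_bandwidth <= 0:
            raise ValueError("noise_bandwidth must be > 0 (or None)")

    def marginal_sd(self, sampling_rate: float) -> float:
        """Stationary per-sample sd of the noise on the record (fraction of
        baseline), after the instrument's band limit."""
        if self.noise_bandwidth is None:
            return self.white_noise_sd
        alpha = 1.0 - np.exp(-2.0 * np.pi * self.noise_bandwidth / sampling_rate)
        return self.white_noise_sd * float(np.sqrt(alpha / (2.0 - alpha)))


@dataclass(frozen=True)
class ExperimentProtocol:
    """Ordered reagent events over a recording of ``duration`` seconds."""

    events: tuple[ReagentEvent, ...]
    duration: float  # s
    baseline_output: float = 1.0  # V

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(self.events))
        times = [e.time for e in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")
        if times and times[-1] >= self.duration:
            raise ValueError("all event times must fall before the end of the recording")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")


def binding_response(t_since_event: float, amplitude: float, tau: float):
    """First-order (Langmuir-like) fractional binding response.

    amplitude * (1 - exp(-t/tau)); zero at the addition instant,
    saturating to ``amplitude``.  At the default tau = 240 s the response
    reaches 95% of its asymptote at ~719 s (~12 min), matching the
    observed 10-15 min saturation window.  Accepts scalar or array ``t``.
    """
    t = np.asarray(t_since_event, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_since_event must be >= 0")
    out = amplitude * (1.0 - np.exp(-t / tau))
    return float(out) if np.isscalar(t_since_event) else out


def _one_pole(x: np.ndarray, alpha: float) -> np.ndarray:
    """First-order recursive low-pass y[n] = y[n-1] + alpha (x[n] - y[n-1])."""
    from scipy.signal import lfilter

    return lfilter([alpha], [1.0, alpha - 1.0], x)


def simulate_trace(protocol: ExperimentProtocol, noise: NoiseModel | None = None,
                   sampling_rate: float = 225.0) -> Trace:
    """Simulate the lock-in output trace for a reagent protocol.

    Deterministic given ``noise.seed``; with ``noise=None`` the trace is
    noiseless and drift-free.  Event times are recorded as trace
    annotations labelled with the event kind.
    """
    if sampling_rate <= 0:
        raise ValueError(f"sampling_rate must be > 0, got {sampling_rate}")
    dt = 1.0 / sampling_rate
    times = np.arange(0.0, protocol.duration, dt)
    level = np.full(len(times), protocol.baseline_output)
    gradual = np.zeros(len(times))
    for event in protocol.events:
        active = times >= event.time
        level[active] *= 1.0 + event.step_fraction
        if event.gradual_amplitude != 0.0:
            gradual[active] += binding_response(
                times[active] - event.time, event.gradual_amplitude, event.time_constant
            )
    values = level * (1.0 + gradual)
    if noise is not None:
        values = values * (1.0 + noise.drift_rate * times)
        if noise.white_noise_sd > 0:
            rng = np.random.default_rng(noise.seed)
            eps = rng.normal(
                0.0, noise.white_noise_sd * protocol.baseline_output, len(times)
            )
            if noise.noise_bandwidth is not None:
                # the record is the output of the instrument's one-pole filter
                alpha = 1.0 - np.exp(-dt * 2.0 * np.pi * noise.noise_bandwidth)
                eps = _one_pole(eps, alpha)
            values = values + eps
    annotations = [(e.time, e.kind) for e in protocol.events]
    return Trace(times, values, annotations)
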