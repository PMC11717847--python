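"""Synthetic experiment generator with the published per-condition statistics.

Generates every input the analysis pipeline consumes: single-step and
six-step protocols, triplicate groups per condition, and the
54-experiment labelled dataset (one third protein, two thirds negative
control).  Per-trace step and gradual *targets* are drawn
Normal(mean, sd) around the per-condition table values; the gradual
target is then converted to the exponential's asymptote through the
closed-form inverse of the gradual-change statistic, so that the
analysis statistic recovers the drawn target exactly in the noiseless
limit.

With the addition at ``EVENT_TIME`` = 100 s into a 600 s window and time
constant tau, the statistic reads the exponential at 50 s and at
400 - EVENT_TIME = 300 s after the addition:

    g = a (E2 - E1) / (1 + a E1),   E1 = 1 - exp(-50/tau),
                                    E2 = 1 - exp(-300/tau)

whose inverse a(g) the generator applies to each drawn target g.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import analysis
from .binding import ExperimentProtocol, NoiseModel, ReagentEvent, simulate_trace
from .classification import LabelledDataset, extract_features
from .trace import Trace

#: recording-window layout shared by every generated step, seconds
STEP_DURATION = 600.0  # each experiment step lasts 10 minutes
EVENT_TIME = 100.0  # reagent addition, relative to the window start

#: default time constant of the exponential binding response, seconds
DEFAULT_TAU = 240.0


@dataclass(frozen=True)
class ConditionParams:
    """Published per-condition statistics (% changes, triplicate mean/SD)."""

    condition: str
    step_mean: float  # % instantaneous change
    step_sd: float
    gradual_mean: float  # % gradual change
    gradual_sd: float
    tau: float = DEFAULT_TAU  # s

    def __post_init__(self) -> None:
        if self.step_sd < 0 or self.gradual_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")


@dataclass(frozen=True)
class DatasetSpec:
    """Size, class mix and seed of the labelled dataset."""

    n_experiments: int = 54
    protein_fraction: float = 1.0 / 3.0
    seed: int = 42

    def __post_init__(self) -> None:
        if not 0.0 < self.protein_fraction < 1.0:
            raise ValueError("protein_fraction must be in (0, 1)")
        if self.n_experiments < 2:
            raise ValueError("need at least 2 experiments")


#: event kind used when simulating each condition
_CONDITION_KIND = {
    "pbs_fill": "buffer_fill",
    "nc_blank": "negative_control",
    "antibody": "antibody",
    "hmgb1": "protein",
    "patient_serum": "patient_serum",
    "healthy_serum": "healthy_serum",
}


def default_condition_table() -> dict[str, ConditionParams]:
    """Published per-condition change statistics, signed (% units).

    Instantaneous changes were reported only for the buffer-fill and
    first blank-PBS negative-control steps; conditions without a reported
    instantaneous change carry 0 +/- 0 for the step entry.  The blank-PBS
    negative control stores the gradual statistics of the NC step paired
    with the protein comparison (-1.2 +/- 0.43).
    """
    rows = [
        ConditionParams("pbs_fill", step_mean=-54.433, step_sd=3.37,
                        gradual_mean=0.0, gradual_sd=0.0),
        ConditionParams("nc_blank", step_mean=-2.43, step_sd=1.42,
                        gradual_mean=-1.2, gradual_sd=0.43),
        ConditionParams("antibody", step_mean=0.0, step_sd=0.0,
                        gradual_mean=2.87, gradual_sd=1.19),
        ConditionParams("hmgb1", step_mean=0.0, step_sd=0.0,
                        gradual_mean=0.96, gradual_sd=0.62),
        ConditionParams("patient_serum", step_mean=0.0, step_sd=0.0,
                        gradual_mean=1.61, gradual_sd=1.17),
        ConditionParams("healthy_serum", step_mean=0.0, step_sd=0.0,
                        gradual_mean=-3.5, gradual_sd=0.28),
    ]
    return {row.condition: row for row in rows}


def gradual_exponent_fractions(tau: float, event_time: float = EVENT_TIME,
                               record_start: float = 0.0) -> tuple[float, float]:
    """(E1, E2): the exponential's completed fractions at the two
    reference instants of the gradual-change statistic."""
    t_early = analysis.GRADUAL_EARLY_OFFSET
    t_late = record_start + analysis.GRADUAL_LATE_OFFSET - event_time
    if t_late <= t_early:
        raise ValueError("late reference instant must follow the early one")
    e1 = 1.0 - math.exp(-t_early / tau)
    e2 = 1.0 - math.exp(-t_late / tau)
    return e1, e2


def amplitude_for_gradual_target(target_pct: float, tau: float,
                                 event_time: float = EVENT_TIME,
                                 record_start: float = 0.0) -> float:
    """Exponential asymptote a such that the gradual statistic returns
    ``target_pct`` exactly on a noiseless trace (closed-form inverse)."""
    g = target_pct / 100.0
    e1, e2 = gradual_exponent_fractions(tau, event_time, record_start)
    denom = e2 - e1 - g * e1
    if denom <= 0:
        raise ValueError(
            f"gradual target {target_pct:g}% unreachable with tau={tau:g} s"
        )
    return g / denom


def gradual_target_from_amplitude(amplitude: float, tau: float,
                                  event_time: float = EVENT_TIME,
                                  record_start: float = 0.0) -> float:
    """Forward map: the gradual statistic (%) a noiseless trace with
    exponential asymptote ``amplitude`` produces."""
    e1, e2 = gradual_exponent_fractions(tau, event_time, record_start)
    return 100.0 * amplitude * (e2 - e1) / (1.0 + amplitude * e1)


def sample_experiment(params: ConditionParams, seed,
                      baseline_output: float = 1.0) -> ExperimentProtocol:
    """Draw one single-step experiment protocol for a condition.

    The per-trace step and gradual targets are Normal(mean, sd) draws;
    the gradual target is mapped to the exponential asymptote with
    :func:`amplitude_for_gradual_target`.  Deterministic given ``seed``
    (an int or a :class:`numpy.random.SeedSequence`).
    """
    rng = np.random.default_rng(seed)
    step_pct = rng.normal(params.step_mean, params.step_sd) if params.step_sd > 0 \
        else params.step_mean
    gradual_pct = rng.normal(params.gradual_mean, params.gradual_sd) \
        if params.gradual_sd > 0 else params.gradual_mean
    amplitude = 0.0 if gradual_pct == 0.0 else amplitude_for_gradual_target(
        gradual_pct, params.tau
    )
    event = ReagentEvent(
        time=EVENT_TIME,
        kind=_CONDITION_KIND[params.condition],
        step_fraction=step_pct / 100.0,
        gradual_amplitude=amplitude,
        time_constant=params.tau,
    )
    return ExperimentProtocol(events=(event,), duration=STEP_DURATION,
                              baseline_output=baseline_output)


def simulate_condition_triplicate(params: ConditionParams, seeds,
                                  noise_sd: float = 0.002,
                                  sampling_rate: float = 225.0) -> list[Trace]:
    """Three (or ``len(seeds)``) seeded single-step traces of one condition."""
    traces = []
    for s in seeds:
        ss = s if isinstance(s, np.random.SeedSequence) else np.random.SeedSequence(s)
        child = ss.spawn(2)
        proto = sample_experiment(params, child[0])
        noise = NoiseModel(white_noise_sd=noise_sd, seed=child[1])
        traces.append(simulate_trace(proto, noise, sampling_rate))
    return traces


def analyze_condition_traces(traces) -> list[analysis.StepStats]:
    """Step statistics of generated single-step traces (annotations drive
    the reference instants)."""
    out = []
    for trace in traces:
        (event_time, _), = trace.annotations
        out.append(analysis.step_stats(trace, step_record_start=0.0,
                                       addition_time=event_time))
    return out


def six_step_protocol(table: dict[str, ConditionParams] | None = None,
                      seed=0, baseline_output: float = 1.0) -> ExperimentProtocol:
    """The canonical six-step protocol: PBS fill, blank-PBS NC, antibody,
    PBS refill, blank-PBS NC, target protein; 600 s per step."""
    table = table or default_condition_table()
    order = ["pbs_fill", "nc_blank", "antibody", "refill", "nc_blank", "hmgb1"]
    ss = np.random.SeedSequence(seed).spawn(len(order))
    events = []
    for i, name in enumerate(order):
        t = i * STEP_DURATION + EVENT_TIME
        if name == "refill":
            events.append(ReagentEvent(time=t, kind="refill"))
            continue
        proto = sample_experiment(table[name], ss[i])
        e = proto.events[0]
        events.append(ReagentEvent(time=t, kind=e.kind, step_fraction=e.step_fraction,
                                   gradual_amplitude=e.gradual_amplitude,
                                   time_constant=e.time_constant))
    return ExperimentProtocol(events=tuple(events),
                              duration=len(order) * STEP_DURATION,
                              baseline_output=baseline_output)


#: which conditions each class cycles through in the labelled dataset
PROTEIN_CONDITIONS = ("hmgb1", "patient_serum")
NEGATIVE_CONDITIONS = ("nc_blank", "healthy_serum")


def generate_dataset(spec: DatasetSpec,
                     condition_table: dict[str, ConditionParams] | None = None,
                     noise_sd: float = 0.002,
                     sampling_rate: float = 225.0,
                     ) -> tuple[list[Trace], LabelledDataset]:
    """Simulate the labelled dataset of single-step experiments.

    round(n * protein_fraction) protein traces (alternating purified-HMGB1
    and patient-serum parameters) and the remainder negative-control
    traces (alternating blank-PBS and healthy-serum parameters), each run
    through the trace simulator and the 4-feature extractor.  Fully
    seeded: the spec seed spawns independent streams per trace and for
    the train/test split.
    """
    table = condition_table or default_condition_table()
    n_protein = round(spec.n_experiments * spec.protein_fraction)
    n_negative = spec.n_experiments - n_protein
    if n_protein < 1 or n_negative < 1:
        raise ValueError("both classes must be present in the dataset")

    root = np.random.SeedSequence(spec.seed)
    split_stream, *trace_streams = root.spawn(spec.n_experiments + 1)

    plan = [("protein", PROTEIN_CONDITIONS[i % len(PROTEIN_CONDITIONS)])
            for i in range(n_protein)]
    plan += [("negative_control", NEGATIVE_CONDITIONS[i % len(NEGATIVE_CONDITIONS)])
             for i in range(n_negative)]

    traces: list[Trace] = []
    features = np.empty((spec.n_experiments, 4))
    labels = []
    for i, ((label, cond), stream) in enumerate(zip(plan, trace_streams)):
        proto_stream, noise_stream = stream.spawn(2)
        proto = sample_experiment(table[cond], proto_stream)
        noise = NoiseModel(white_noise_sd=noise_sd, seed=noise_stream)
        trace = simulate_trace(proto, noise, sampling_rate)
        traces.append(trace)
        features[i] = extract_features(trace, step_time=EVENT_TIME)
        labels.append(label)

    split_seed = int(split_stream.generate_state(1)[0] % (2**31))
    dataset = LabelledDataset(features=features, labels=np.array(labels),
                              split_seed=split_seed,
                              conditions=[cond for _, cond in plan])
    return traces, dataset
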