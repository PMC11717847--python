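"""File formats and configuration parsing.

All tabular outputs are CSV with units spelled out in the column names
(``time_s``, ``v_out_v``, ``frequency_hz`` ...).  Trace files carry
their event annotations as comment lines prefixed ``#`` ahead of the
header, so a trace round-trips losslessly through a single file.
Configuration is YAML with engineering-suffixed quantities ("29.84 fF",
"10.5 MHz", "2 cm^2") parsed into strict SI at the boundary.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .binding import NoiseModel
from .circuit import CoilSpec, ImpedanceSpectrum, LockInConfig, SensorImpedanceModel, WptCircuit
from .synthetic import DatasetSpec
from .trace import Trace


class TraceParseError(ValueError):
    """A trace CSV is malformed; the message names the offending line."""


_SI_PREFIXES = {
    "f": 1e-15, "p": 1e-12, "n": 1e-9, "u": 1e-6, "µ": 1e-6,
    "m": 1e-3, "c": 1e-2, "k": 1e3, "M": 1e6, "G": 1e9,
}
_BASE_UNITS = {"", "V", "A", "H", "F", "Hz", "ohm", "Ohm", "Ω", "S", "s", "m", "T",
               "m^2", "m2"}


def parse_si_value(value) -> float:
    """Parse a number or an engineering-suffixed quantity string to SI.

    Examples: ``"29.84 fF"`` -> 2.984e-14, ``"10.5 MHz"`` -> 1.05e7,
    ``"0.6 mm"`` -> 6e-4, ``"2 cm^2"`` -> 2e-4 (area prefixes square),
    ``500`` -> 500.0, ``"inf"`` -> inf.
    """
    if isinstance(value, (int, float)):
        return float(value)
    text = str(value).strip()
    m = re.fullmatch(r"([+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?|inf)\s*(\S*)", text)
    if not m:
        raise ValueError(f"cannot parse quantity {value!r}")
    number = float(m.group(1))
    unit = m.group(2)
    if unit in _BASE_UNITS:
        return number
    prefix, rest = unit[0], unit[1:]
    if prefix not in _SI_PREFIXES or rest not in _BASE_UNITS:
        raise ValueError(f"unknown unit {unit!r} in {value!r}")
    factor = _SI_PREFIXES[prefix]
    if rest.endswith(("^2", "2")) and rest.startswith("m"):
        factor = factor**2  # area: the prefix applies to the length
    return number * factor


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """Validated full-pipeline configuration (strict SI internally)."""

    circuit: WptCircuit
    lockin: LockInConfig
    dataset: DatasetSpec
    noise: NoiseModel
    raw: dict = field(default_factory=dict)


def default_config_dict() -> dict:
    """The built-in configuration: the published hardware operating point."""
    return {
        "circuit": {
            "source_amplitude": "400 mV",
            "drive_frequency": "10.5 MHz",
            "primary_resistor": 500,
            "secondary_resistor": 26,
            "coupling_coefficient": 0.3,
        },
        "coil": {
            "n_turns": 35,
            "wire_diameter": "0.6 mm",
            "cross_section_area": "2 cm^2",
            "self_inductance": "7.7 mH",
        },
        "sensor": {
            "capacitance": "29.84 fF",
            "solution_resistance": "inf",
            "access_resistance": "1 kohm",
        },
        "lockin": {
            "gain": 1000,
            "bandwidth": 2,
            "sampling_rate": 225,
            "input_impedance": 50,
        },
        "dataset": {
            "n_experiments": 54,
            "protein_fraction": 1.0 / 3.0,
            "seed": 42,
        },
        "noise": {
            "white_noise_sd": 0.002,
            "drift_rate": 0.0,
        },
    }


_REQUIRED_SECTIONS = ("circuit", "coil", "sensor", "lockin", "dataset", "noise")


def build_config(overrides: dict | None = None) -> PipelineConfig:
    """Merge overrides into the default configuration and validate."""
    raw = default_config_dict()
    for section, entries in (overrides or {}).items():
        if section not in raw:
            raise ValueError(f"unknown config section {section!r}")
        if not isinstance(entries, dict):
            raise ValueError(f"config section {section!r} must be a mapping")
        raw[section].update(entries)
    missing = [s for s in _REQUIRED_SECTIONS if s not in raw]
    if missing:
        raise ValueError(f"missing config sections: {missing}")

    coil_cfg, circ, sens, lock = raw["coil"], raw["circuit"], raw["sensor"], raw["lockin"]
    coil = CoilSpec(
        n_turns=int(coil_cfg["n_turns"]),
        wire_diameter=parse_si_value(coil_cfg["wire_diameter"]),
        cross_section_area=parse_si_value(coil_cfg["cross_section_area"]),
        self_inductance=parse_si_value(coil_cfg["self_inductance"]),
    )
    sensor = SensorImpedanceModel(
        capacitance=parse_si_value(sens["capacitance"]),
        solution_resistance=parse_si_value(sens["solution_resistance"]),
        access_resistance=parse_si_value(sens["access_resistance"]),
    )
    kwargs: dict = {}
    if "coupling_coefficient" in circ and circ.get("coupling_coefficient") is not None:
        kwargs["coupling_coefficient"] = float(circ["coupling_coefficient"])
    if "mutual_inductance" in circ and circ.get("mutual_inductance") is not None:
        kwargs["mutual_inductance"] = parse_si_value(circ["mutual_inductance"])
    circuit = WptCircuit(
        source_amplitude=parse_si_value(circ["source_amplitude"]),
        drive_frequency=parse_si_value(circ["drive_frequency"]),
        primary_resistor=parse_si_value(circ["primary_resistor"]),
        secondary_resistor=parse_si_value(circ["secondary_resistor"]),
        primary_coil=coil,
        secondary_coil=coil,
        sensor=sensor,
        **kwargs,
    )
    lockin = LockInConfig(
        gain=float(lock["gain"]),
        bandwidth=parse_si_value(lock["bandwidth"]),
        sampling_rate=float(lock["sampling_rate"]),
        reference_frequency=circuit.drive_frequency,
        input_impedance=parse_si_value(lock.get("input_impedance", 50)),
    )
    ds = raw["dataset"]
    dataset = DatasetSpec(n_experiments=int(ds["n_experiments"]),
                          protein_fraction=float(ds["protein_fraction"]),
                          seed=int(ds["seed"]))
    nz = raw["noise"]
    noise = NoiseModel(white_noise_sd=float(nz["white_noise_sd"]),
                       drift_rate=float(nz["drift_rate"]))
    return PipelineConfig(circuit=circuit, lockin=lockin, dataset=dataset,
                          noise=noise, raw=raw)


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML config file (``None`` -> all defaults) and validate."""
    overrides = None
    if path is not None:
        with open(path) as fh:
            overrides = yaml.safe_load(fh) or {}
        if not isinstance(overrides, dict):
            raise ValueError(f"config file {path} must contain a mapping")
    return build_config(overrides)


# ---------------------------------------------------------------------------
# trace CSV


def write_trace_csv(trace: Trace, path: str | Path) -> None:
    """Write a trace with its annotations to one CSV file.

    Annotations are comment lines ``# event,<time_s>,<label>`` ahead of
    the ``time_s,v_out_v`` header; values are written at full float
    precision.
    """
    path = Path(path)
    with open(path, "w") as fh:
        for t, label in trace.annotations:
            fh.write(f"# event,{float(t)!r},{label}\n")
        fh.write("time_s,v_out_v\n")
        for t, v in zip(trace.times.tolist(), trace.values.tolist()):
            fh.write(f"{t!r},{v!r}\n")


def read_trace_csv(path: str | Path) -> Trace:
    """Read a trace CSV written by :func:`write_trace_csv` (lossless)."""
    path = Path(path)
    annotations: list[tuple[float, str]] = []
    times: list[float] = []
    values: list[float] = []
    with open(path) as fh:
        lines = fh.readlines()
    if not any(line.strip() and not line.startswith("#") for line in lines):
        raise TraceParseError(f"{path}: no data rows")
    header_seen = False
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            parts = body.split(",", 2)
            if parts[0].strip() == "event":
                if len(parts) != 3:
                    raise TraceParseError(f"{path}:{lineno}: malformed annotation")
                annotations.append((float(parts[1]), parts[2]))
            continue
        if not header_seen:
            if line.split(",")[:2] != ["time_s", "v_out_v"]:
                raise TraceParseError(f"{path}:{lineno}: expected header time_s,v_out_v")
            header_seen = True
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise TraceParseError(f"{path}:{lineno}: expected 2 fields, got {len(parts)}")
        try:
            times.append(float(parts[0]))
            values.append(float(parts[1]))
        except ValueError as err:
            raise TraceParseError(f"{path}:{lineno}: {err}") from None
        if len(times) >= 2 and times[-1] <= times[-2]:
            raise TraceParseError(f"{path}:{lineno}: non-monotone time")
    return Trace(np.array(times), np.array(values), annotations)


def write_spectrum_csv(spectrum: ImpedanceSpectrum, path: str | Path) -> None:
    """Frequency sweep as CSV: frequency_hz, z_real_ohm, z_imag_ohm, z_abs_ohm."""
    df = pd.DataFrame({
        "frequency_hz": spectrum.frequencies,
        "z_real_ohm": spectrum.impedance.real,
        "z_imag_ohm": spectrum.impedance.imag,
        "z_abs_ohm": np.abs(spectrum.impedance),
    })
    df.to_csv(path, index=False)
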