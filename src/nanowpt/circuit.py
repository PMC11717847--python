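"""Phasor-domain model of the resonant inductive-coupling readout link.

The wireless readout chain is a two-loop circuit: an AC source drives the
primary loop (source resistor R_p in series with the transmitter coil and
the lock-in input), which couples magnetically (mutual inductance M) into
the secondary loop (receiver coil, series resistor, and the nanowell
sensor).  Both sides are tuned to a common resonance so that the
reflected impedance

    Z_refl(omega) = omega^2 M^2 / Z_sec(omega)

— the term the secondary contributes to the impedance seen from the
transmitter — is maximally sensitive to the sensor.  Any change of the
nanowell impedance (buffer filling, antibody or protein binding) moves
Z_sec, hence Z_refl, hence the current through the primary and the
voltage at the lock-in input.

Coil magnetics are modelled at the filamentary-loop level: each turn is a
circular filament, fields follow the Biot–Savart law, and the mutual
inductance of two coaxial windings is the Neumann double integration over
all turn pairs.  The lock-in is modelled quasi-statically: at each sample
instant the circuit is solved at the drive frequency and the demodulated
amplitude is low-passed with a one-pole filter at the configured
bandwidth.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import IntegrationWarning, quad

from .trace import Trace

MU_0 = 4e-7 * math.pi  # permeability of free space, H/m


class InvalidGeometryError(ValueError):
    """A geometric parameter (radius, area, gap) is non-physical."""


class InvalidParameterError(ValueError):
    """An electrical parameter is outside its physical domain."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class CoilSpec:
    """Geometry and electrical parameters of one wound coil.

    ``radius`` is derived from ``cross_section_area`` (area = pi r^2) when
    not given explicitly.  ``self_inductance`` is a stated design value,
    not recomputed from geometry.
    """

    n_turns: int
    wire_diameter: float  # m
    cross_section_area: float  # m^2
    self_inductance: float  # H
    radius: float | None = None  # m

    def __post_init__(self) -> None:
        if self.n_turns < 1:
            raise InvalidGeometryError(f"n_turns must be >= 1, got {self.n_turns}")
        if self.wire_diameter <= 0 or self.cross_section_area <= 0:
            raise InvalidGeometryError("wire_diameter and cross_section_area must be > 0")
        if self.self_inductance <= 0:
            raise InvalidParameterError("self_inductance must be > 0")
        if self.radius is None:
            object.__setattr__(
                self, "radius", math.sqrt(self.cross_section_area / math.pi)
            )
        elif self.radius <= 0:
            raise InvalidGeometryError("radius must be > 0")

    def turn_positions(self, z0: float = 0.0, direction: float = 1.0) -> np.ndarray:
        """Axial positions of the turn filaments, stacked at wire-diameter pitch."""
        return z0 + direction * self.wire_diameter * np.arange(self.n_turns)


@dataclass(frozen=True)
class MagneticConfig:
    """Magnetic-path parameters: permeability, air gap, coil separation, drive current."""

    permeability: float = MU_0  # H/m
    gap_length: float = 0.0  # m
    coil_separation: float = 0.0  # m
    drive_current: float = 1.0  # A

    def __post_init__(self) -> None:
        if self.permeability <= 0:
            raise InvalidParameterError("permeability must be > 0")
        if self.gap_length < 0 or self.coil_separation < 0:
            raise InvalidGeometryError("gap_length and coil_separation must be >= 0")


@dataclass(frozen=True)
class SensorImpedanceModel:
    """Equivalent circuit of the nanowell sensor.

    Access resistance in series with (solution resistance || oxide
    capacitance) — the standard reduction of a well whose ionic path is
    shunted by the interelectrode dielectric.  A dry sensor is represented
    by ``solution_resistance = inf`` (purely capacitive well).
    """

    capacitance: float  # F
    solution_resistance: float = math.inf  # ohm; inf = dry sensor
    access_resistance: float = 0.0  # ohm
    topology: str = "parallel_rc_plus_series_r"

    def __post_init__(self) -> None:
        if self.capacitance <= 0:
            raise InvalidParameterError("capacitance must be > 0")
        if self.solution_resistance < 0 or self.access_resistance < 0:
            raise InvalidParameterError("resistances must be >= 0")
        if self.topology != "parallel_rc_plus_series_r":
            raise InvalidParameterError(f"unknown sensor topology {self.topology!r}")


def _default_coil() -> CoilSpec:
    # 35 aligned turns, 0.6 mm wire, 2 cm^2 cross-section; design inductance 7.7 mH
    return CoilSpec(
        n_turns=35,
        wire_diameter=0.6e-3,
        cross_section_area=2e-4,
        self_inductance=7.7e-3,
    )


@dataclass(frozen=True)
class WptCircuit:
    """Full two-sided circuit: source, primary loop, coupling, secondary loop.

    Exactly one of ``mutual_inductance`` / ``coupling_coefficient`` is
    given; the other is derived from M = k sqrt(L_p L_r).
    """

    source_amplitude: float = 0.4  # V peak
    drive_frequency: float = 10.5e6  # Hz
    primary_resistor: float = 500.0  # ohm
    secondary_resistor: float = 26.0  # ohm
    primary_coil: CoilSpec = field(default_factory=_default_coil)
    secondary_coil: CoilSpec = field(default_factory=_default_coil)
    sensor: SensorImpedanceModel = field(
        default_factory=lambda: SensorImpedanceModel(capacitance=29.84e-15)
    )
    primary_parasitic_resistance: float = 0.0  # ohm, not printed on any schematic
    mutual_inductance: float | None = None  # H
    coupling_coefficient: float | None = None  # k in [0, 1]

    def __post_init__(self) -> None:
        if (self.mutual_inductance is None) == (self.coupling_coefficient is None):
            raise InvalidParameterError(
                "give exactly one of mutual_inductance / coupling_coefficient"
            )
        lp = self.primary_coil.self_inductance
        lr = self.secondary_coil.self_inductance
        if self.coupling_coefficient is not None:
            k = self.coupling_coefficient
            if not 0.0 <= k <= 1.0:
                raise InvalidParameterError(f"coupling coefficient k={k} outside [0, 1]")
            object.__setattr__(self, "mutual_inductance", k * math.sqrt(lp * lr))
        else:
            m = self.mutual_inductance
            if m < 0 or m * m > lp * lr * (1 + 1e-12):
                raise InvalidParameterError(
                    f"mutual inductance M={m} violates M^2 <= L_p L_r"
                )
            object.__setattr__(self, "coupling_coefficient", m / math.sqrt(lp * lr))
        if self.source_amplitude <= 0 or self.drive_frequency <= 0:
            raise InvalidParameterError("source amplitude and drive frequency must be > 0")
        if self.primary_resistor < 0 or self.secondary_resistor < 0:
            raise InvalidParameterError("loop resistors must be >= 0")


@dataclass(frozen=True)
class LockInConfig:
    """Lock-in amplifier settings.

    ``input_impedance`` models the instrument's input termination; the
    measured node voltage is I * R_in with I the loop current through the
    series chain source -> R_p -> coil -> lock-in input.
    """

    gain: float = 1000.0
    bandwidth: float = 2.0  # Hz
    sampling_rate: float = 225.0  # S/s
    reference_frequency: float = 10.5e6  # Hz
    input_impedance: float = 50.0  # ohm

    def __post_init__(self) -> None:
        if min(self.gain, self.bandwidth, self.sampling_rate,
               self.reference_frequency, self.input_impedance) <= 0:
            raise InvalidParameterError("all lock-in parameters must be > 0")
        if self.bandwidth >= self.reference_frequency:
            raise InvalidParameterError("bandwidth must be below the reference frequency")


@dataclass
class ImpedanceSpectrum:
    """Frequency-resolved equivalent impedance seen from the transmitter."""

    frequencies: np.ndarray  # Hz, strictly increasing
    impedance: np.ndarray  # complex ohm

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.impedance = np.asarray(self.impedance, dtype=complex)
        if len(self.frequencies) != len(self.impedance):
            raise ValueError("frequency and impedance arrays must match in length")
        if not np.all(np.diff(self.frequencies) > 0):
            raise ValueError("frequencies must be strictly increasing")

    def peak(self) -> tuple[float, float]:
        """(f_peak, |Z|_peak) of the maximum |Z|; ties break to the lowest frequency."""
        mag = np.abs(self.impedance)
        i = int(np.argmax(mag))  # argmax returns the first maximum
        return float(self.frequencies[i]), float(mag[i])


# ---------------------------------------------------------------------------
# magnetics


def loop_field_on_axis(radius: float, current: float, axial_distance: float,
                       n_segments: int = 720) -> float:
    """Axial magnetic flux density (T) of a circular current loop, by Biot-Savart.

    The loop sits in the z=0 plane centred on the axis; the field point is
    on the axis at ``axial_distance``.  The line integral
    mu0 I / (4 pi) * loop_integral(dl x r / |r|^3) is evaluated numerically
    by midpoint quadrature over the loop.
    """
    if radius <= 0:
        raise InvalidGeometryError(f"loop radius must be > 0, got {radius}")
    phi = (np.arange(n_segments) + 0.5) * (2 * math.pi / n_segments)
    dphi = 2 * math.pi / n_segments
    # dl x r, z-component: dl = a(-sin, cos, 0) dphi, r = (0,0,z) - a(cos, sin, 0)
    # (dl x r)_z = a^2 dphi  (independent of phi); |r|^3 = (a^2 + z^2)^{3/2}
    r3 = (radius**2 + axial_distance**2) ** 1.5
    integrand_z = radius**2 / r3
    return MU_0 * current / (4 * math.pi) * float(np.sum(integrand_z * np.ones_like(phi))) * dphi


def _loop_pair_mutual(radius_a: float, radius_b: float, axial_gap: float) -> float:
    """Neumann integral for two coaxial circular filaments (H), numeric quadrature."""
    a, b, d = radius_a, radius_b, axial_gap

    def integrand(psi: float) -> float:
        return math.cos(psi) / math.sqrt(a * a + b * b - 2 * a * b * math.cos(psi) + d * d)

    # epsabs floor keeps the far-field regime (near-cancelling integrand)
    # from triggering spurious round-off reports
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=IntegrationWarning)
        val, _ = quad(integrand, 0.0, 2 * math.pi, epsabs=1e-30, epsrel=1e-11,
                      limit=400)
    return MU_0 * a * b / 2.0 * val


def mutual_inductance(primary: CoilSpec, secondary: CoilSpec, separation: float) -> float:
    """Mutual inductance (H) of two coaxial, aligned multi-turn coils.

    Each turn is a filamentary circular loop; windings stack axially at
    wire-diameter pitch on opposite sides of a face-to-face ``separation``.
    The result is the Neumann-type double integration over both windings
    (sum over all turn pairs of the numerically integrated loop-pair
    mutual).
    """
    if separation < 0:
        raise InvalidGeometryError("separation must be >= 0")
    min_gap = max(primary.wire_diameter, secondary.wire_diameter)
    if separation < min_gap:
        warnings.warn(
            f"separation {separation:g} m below the wire diameter {min_gap:g} m: "
            "windings overlap; filamentary model is inaccurate here",
            stacklevel=2,
        )
    z_primary = primary.turn_positions(z0=0.0, direction=-1.0)
    z_secondary = secondary.turn_positions(z0=separation, direction=+1.0)
    total = 0.0
    for zp in z_primary:
        for zs in z_secondary:
            total += _loop_pair_mutual(primary.radius, secondary.radius, zs - zp)
    return total


def gap_reluctance(gap_length: float, permeability: float, area: float) -> float:
    """Reluctance (1/H) of a uniform air gap: l_g / (mu * A_g)."""
    if area <= 0:
        raise InvalidGeometryError(f"gap cross-section area must be > 0, got {area}")
    if permeability <= 0:
        raise InvalidParameterError("permeability must be > 0")
    if gap_length < 0:
        raise InvalidGeometryError("gap length must be >= 0")
    return gap_length / (permeability * area)


def induced_voltage(mutual: float, primary_current_phasor: complex,
                    angular_frequency: float) -> complex:
    """Sinusoidal steady-state induced voltage phasor: -j omega M I_p (V)."""
    if angular_frequency < 0:
        raise InvalidParameterError("angular frequency must be >= 0")
    return -1j * angular_frequency * mutual * primary_current_phasor


def resonant_inductance(capacitance: float, angular_frequency: float) -> float:
    """Receiver inductance (H) resonating with C_s at omega: L_r = 1/(omega^2 C_s)."""
    if capacitance <= 0 or angular_frequency <= 0:
        raise InvalidParameterError("capacitance and angular frequency must be > 0")
    return 1.0 / (angular_frequency**2 * capacitance)


def resonant_frequency(inductance: float, capacitance: float) -> float:
    """Angular resonance frequency (rad/s) of a series LC: 1/sqrt(L C)."""
    if inductance <= 0 or capacitance <= 0:
        raise InvalidParameterError("inductance and capacitance must be > 0")
    return 1.0 / math.sqrt(inductance * capacitance)


# ---------------------------------------------------------------------------
# circuit solution


def sensor_impedance(sensor: SensorImpedanceModel, frequency) -> complex:
    """Complex impedance (ohm) of the nanowell sensor at ``frequency`` (Hz).

    Z = R_access + (R_solution || 1/(j omega C_s)); a dry sensor
    (R_solution = inf) reduces to R_access + 1/(j omega C_s).  Accepts a
    scalar or an array of frequencies.
    """
    f = np.asarray(frequency, dtype=float)
    if np.any(f <= 0):
        raise InvalidParameterError("frequency must be > 0")
    omega = 2 * np.pi * f
    y_well = 1j * omega * sensor.capacitance  # admittance of the oxide capacitance
    if math.isfinite(sensor.solution_resistance):
        if sensor.solution_resistance == 0.0:
            z = np.zeros_like(omega, dtype=complex)
        else:
            z = 1.0 / (y_well + 1.0 / sensor.solution_resistance)
    else:
        z = 1.0 / y_well
    out = sensor.access_resistance + z
    return complex(out) if np.isscalar(frequency) else out


def secondary_impedance(circuit: WptCircuit, frequency) -> complex:
    """Series impedance of the secondary loop: j omega L_r + R_sec + Z_sensor."""
    omega = 2 * np.pi * np.asarray(frequency, dtype=float)
    z = (1j * omega * circuit.secondary_coil.self_inductance
         + circuit.secondary_resistor
         + sensor_impedance(circuit.sensor, frequency))
    return complex(z) if np.isscalar(frequency) else z


def equivalent_impedance(circuit: WptCircuit, frequency) -> complex:
    """Impedance seen from the transmitter (ohm) at ``frequency`` (Hz).

    Z_eq = R_p + j omega L_p + omega^2 M^2 / Z_sec.  A secondary at exact
    series resonance with a vanishing total resistance makes the reflected
    term singular; that is reported as an infinite impedance, not an error.
    """
    scalar = np.isscalar(frequency)
    f = np.atleast_1d(np.asarray(frequency, dtype=float))
    omega = 2 * np.pi * f
    m = circuit.mutual_inductance
    z_sec = np.atleast_1d(secondary_impedance(circuit, f))
    with np.errstate(divide="ignore", invalid="ignore"):
        reflected = np.where(
            z_sec == 0, complex(np.inf), (omega**2) * (m**2) / z_sec
        )
    z = (circuit.primary_resistor
         + circuit.primary_parasitic_resistance
         + 1j * omega * circuit.primary_coil.self_inductance
         + reflected)
    return complex(z[0]) if scalar else z


def frequency_sweep(circuit: WptCircuit, f_min: float, f_max: float,
                    n_points: int) -> ImpedanceSpectrum:
    """Equivalent-impedance spectrum on a log-spaced grid of ``n_points``."""
    if not (0 < f_min < f_max):
        raise InvalidParameterError("need 0 < f_min < f_max")
    if n_points < 2:
        raise InvalidParameterError("n_points must be >= 2")
    freqs = np.logspace(math.log10(f_min), math.log10(f_max), n_points)
    return ImpedanceSpectrum(freqs, equivalent_impedance(circuit, freqs))


# ---------------------------------------------------------------------------
# lock-in readout


@dataclass
class DemodTrace:
    """Demodulated lock-in output: real and imaginary channels vs. time."""

    times: np.ndarray
    real: np.ndarray
    imag: np.ndarray

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.real, self.imag)

    def to_trace(self, annotations: list[tuple[float, str]] | None = None) -> Trace:
        """Magnitude channel as a :class:`Trace`."""
        return Trace(self.times, self.magnitude, annotations or [])


def _one_pole_lowpass(x: np.ndarray, dt: float, bandwidth: float) -> np.ndarray:
    """First-order low-pass, cutoff = bandwidth (Hz), settled initial state."""
    tau = 1.0 / (2 * math.pi * bandwidth)
    alpha = 1.0 - math.exp(-dt / tau)
    y = np.empty_like(x)
    y[0] = x[0]
    for i in range(1, len(x)):
        y[i] = y[i - 1] + alpha * (x[i] - y[i - 1])
    return y


def lock_in_output(circuit: WptCircuit, lockin: LockInConfig,
                   sensor_trajectory: Callable[[float], SensorImpedanceModel],
                   duration: float) -> DemodTrace:
    """Quasi-static lock-in output for a time-varying sensor.

    At each sample instant the circuit is solved at the drive frequency
    with the sensor returned by ``sensor_trajectory(t)``:
    I = V_src / (Z_eq + R_in), measured node voltage V = I * R_in, output
    channels gain * Re(V), gain * Im(V).  Both channels are then low-passed
    with a one-pole filter at the configured bandwidth (time constant
    1/(2 pi BW), ~0.08 s at the 2 Hz default).
    """
    if duration <= 0:
        raise InvalidParameterError("duration must be > 0")
    dt = 1.0 / lockin.sampling_rate
    times = np.arange(0.0, duration, dt)
    v = np.empty(len(times), dtype=complex)
    for i, t in enumerate(times):
        sensor = sensor_trajectory(t)
        if sensor is None:
            raise InvalidParameterError(f"sensor trajectory undefined at t={t:g} s")
        c = WptCircuit(
            source_amplitude=circuit.source_amplitude,
            drive_frequency=circuit.drive_frequency,
            primary_resistor=circuit.primary_resistor,
            secondary_resistor=circuit.secondary_resistor,
            primary_coil=circuit.primary_coil,
            secondary_coil=circuit.secondary_coil,
            sensor=sensor,
            primary_parasitic_resistance=circuit.primary_parasitic_resistance,
            mutual_inductance=circuit.mutual_inductance,
        )
        z_eq = equivalent_impedance(c, circuit.drive_frequency)
        current = circuit.source_amplitude / (z_eq + lockin.input_impedance)
        v[i] = lockin.gain * current * lockin.input_impedance
    real = _one_pole_lowpass(v.real.copy(), dt, lockin.bandwidth)
    imag = _one_pole_lowpass(v.imag.copy(), dt, lockin.bandwidth)
    return DemodTrace(times, real, imag)


def calibrate_coupling(circuit: WptCircuit, loaded_sensor: SensorImpedanceModel,
                       target_drop: float, lockin: LockInConfig | None = None,
                       k_bounds: tuple[float, float] = (1e-4, 0.999)) -> float:
    """Coupling coefficient k for which loading the sensor drops the output
    magnitude by ``target_drop`` (fraction of the dry-sensor output).

    Solved by bisection on k; raises if the target is outside the
    achievable range at the given bounds.
    """
    from scipy.optimize import brentq

    lockin = lockin or LockInConfig(reference_frequency=circuit.drive_frequency)

    def drop(k: float) -> float:
        base = dict(
            source_amplitude=circuit.source_amplitude,
            drive_frequency=circuit.drive_frequency,
            primary_resistor=circuit.primary_resistor,
            secondary_resistor=circuit.secondary_resistor,
            primary_coil=circuit.primary_coil,
            secondary_coil=circuit.secondary_coil,
            primary_parasitic_resistance=circuit.primary_parasitic_resistance,
            coupling_coefficient=k,
        )
        out = []
        for sensor in (circuit.sensor, loaded_sensor):
            c = WptCircuit(sensor=sensor, **base)
            z = equivalent_impedance(c, circuit.drive_frequency)
            out.append(abs(circuit.source_amplitude * lockin.input_impedance
                           / (z + lockin.input_impedance)))
        dry, loaded = out
        return 1.0 - loaded / dry

    f = lambda k: drop(k) - target_drop
    lo, hi = k_bounds
    if f(lo) * f(hi) > 0:
        raise InvalidParameterError(
            f"target drop {target_drop:g} not bracketed by k in {k_bounds}"
        )
    return float(brentq(f, lo, hi, xtol=1e-9))
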