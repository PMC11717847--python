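import numpy as np
import pytest

from nanowpt.circuit import SensorImpedanceModel, WptCircuit
from nanowpt.synthetic import default_condition_table


@pytest.fixture(scope="session")
def condition_table():
    return default_condition_table()


@pytest.fixture()
def dry_circuit():
    """Default operating point with a dry (purely capacitive) sensor."""
    return WptCircuit(
        coupling_coefficient=0.3,
        sensor=SensorImpedanceModel(capacitance=29.84e-15, access_resistance=1e3),
    )


@pytest.fixture()
def loaded_circuit():
    """Same link with a conductive (buffer-filled) sensor."""
    return WptCircuit(
        coupling_coefficient=0.3,
        sensor=SensorImpedanceModel(
            capacitance=29.84e-15, solution_resistance=1e4, access_resistance=1e3
        ),
    )


def mesh_equivalent_impedance(circuit: WptCircuit, frequency: float) -> complex:
    """Independent 2x2 complex mesh-equation solution of the two-loop link."""
    from nanowpt.circuit import sensor_impedance

    w = 2 * np.pi * frequency
    m = circuit.mutual_inductance
    z11 = (circuit.primary_resistor + circuit.primary_parasitic_resistance
           + 1j * w * circuit.primary_coil.self_inductance)
    z22 = (1j * w * circuit.secondary_coil.self_inductance
           + circuit.secondary_resistor
           + sensor_impedance(circuit.sensor, frequency))
    a = np.array([[z11, -1j * w * m], [-1j * w * m, z22]])
    currents = np.linalg.solve(a, np.array([circuit.source_amplitude, 0.0]))
    return circuit.source_amplitude / currents[0]


def elliptic_loop_mutual(radius_a: float, radius_b: float, separation: float) -> float:
    """Maxwell's closed form for coaxial filamentary loops (elliptic integrals)."""
    from scipy.special import ellipe, ellipk

    mu0 = 4e-7 * np.pi
    k2 = 4 * radius_a * radius_b / ((radius_a + radius_b) ** 2 + separation**2)
    k = np.sqrt(k2)
    return mu0 * np.sqrt(radius_a * radius_b) * (
        (2 / k - k) * ellipk(k2) - (2 / k) * ellipe(k2)
    )


def pooled_two_group_t(group_a, group_b) -> tuple[float, float]:
    """Pooled two-sample t test (statistic, two-sided p); oracle for the ANOVA."""
    from scipy import stats

    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * stats.t.sf(abs(t), na + nb - 2)
    return float(t), float(p)
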