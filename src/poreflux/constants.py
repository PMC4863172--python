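"""Physical constants and unit conversions.

Units are fixed project-wide: rates in ns^-1, voltage in mV, current in pA,
time in ns, temperature in K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["PhysicalConstants", "DEFAULT_CONSTANTS", "voltage_to_energy_kcal_mol"]

_ELEMENTARY_CHARGE = 1.602176634e-19  # C (exact, SI 2019)
_BOLTZMANN = 1.380649e-23  # J/K (exact, SI 2019)
_AVOGADRO = 6.02214076e23  # 1/mol (exact, SI 2019)


@dataclass(frozen=True)
class PhysicalConstants:
    """Constants entering the voltage-dependent rate law and current conversion.

    Attributes
    ----------
    elementary_charge : float
        Charge transported per permeation event, in coulombs.
    boltzmann : float
        Boltzmann constant in J/K.
    temperature : float
        Absolute temperature in kelvin; 300 K by default.
    """

    elementary_charge: float = _ELEMENTARY_CHARGE
    boltzmann: float = _BOLTZMANN
    temperature: float = 300.0

    def __post_init__(self) -> None:
        if not (self.temperature > 0 and math.isfinite(self.temperature)):
            raise ValueError(f"temperature must be positive and finite, got {self.temperature}")
        if self.elementary_charge <= 0 or self.boltzmann <= 0:
            raise ValueError("elementary_charge and boltzmann must be positive")

    @property
    def thermal_voltage(self) -> float:
        """k_B*T/e in mV (25.852 mV at 300 K)."""
        return self.boltzmann * self.temperature / self.elementary_charge * 1e3

    @property
    def current_per_rate(self) -> float:
        """Current in pA produced by one elementary charge per ns (160.218 pA)."""
        # e [C] / 1 ns = e * 1e9 A = e * 1e21 pA
        return self.elementary_charge * 1e21


DEFAULT_CONSTANTS = PhysicalConstants()


def voltage_to_energy_kcal_mol(
    voltage_mv: float, constants: PhysicalConstants = DEFAULT_CONSTANTS
) -> float:
    """Energy in kcal/mol gained by a monovalent ion crossing ``voltage_mv``.

    200 mV corresponds to 4.6 kcal/mol — the scale against which permeation
    barriers are judged.
    """
    if not math.isfinite(voltage_mv):
        raise ValueError(f"voltage must be finite, got {voltage_mv}")
    joules = constants.elementary_charge * voltage_mv * 1e-3
    return joules * _AVOGADRO / 4184.0
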