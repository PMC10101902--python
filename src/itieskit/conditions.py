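"""Physical conditions shared by every potential <-> energy conversion.

All modules convert between Galvani potential differences and free energies
through a single :class:`Conditions` object so that the temperature used for a
logP, a boundary line and a simulated voltammogram is always the same one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InvalidInputError

#: Molar gas constant, J mol^-1 K^-1.
GAS_CONSTANT = 8.314

#: Faraday constant, C mol^-1.
FARADAY = 96485.0

LN10 = math.log(10.0)


@dataclass(frozen=True)
class Conditions:
    """Temperature and the physical constants entering Nernstian factors.

    Parameters
    ----------
    temperature:
        Absolute temperature in kelvin. The default, 293.15 K (20 degC),
        is a typical unthermostatted-lab value and is the temperature at
        which the package's worked logP examples were computed; it is
        configurable and is reported alongside every derived quantity.

    Notes
    -----
    ``R`` and ``F`` are fixed class-level constants: they are not free
    parameters of any model in this package.
    """

    temperature: float = 293.15
    gas_constant: float = GAS_CONSTANT
    faraday: float = FARADAY

    def __post_init__(self) -> None:
        if not (270.0 <= self.temperature <= 330.0):
            raise InvalidInputError(
                f"temperature {self.temperature!r} K outside the supported "
                "range [270, 330] K"
            )

    @property
    def thermal_voltage(self) -> float:
        """R*T/F in volts (~25.3 mV at 293.15 K)."""
        return self.gas_constant * self.temperature / self.faraday

    @property
    def nernst_slope(self) -> float:
        """ln(10)*R*T/F in volts per decade (~58.2 mV at 293.15 K)."""
        return LN10 * self.thermal_voltage
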