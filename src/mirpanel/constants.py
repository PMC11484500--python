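"""Physical constants and the built-in sensor calibration table.

The MIX.miR readout is the voltage shift of an ion-exchange membrane's
current-voltage characteristic.  In the linear region of the Langmuir
isotherm the shift follows

    dV = A * (R*T/F) * log10(C / C_r)

with a dimensionless slope coefficient ``A`` (theoretically 2*ln(10) for an
ideal over-limiting membrane response, i.e. ~118 mV per decade at room
temperature) and a per-analyte reference concentration ``C_r`` in pM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: Theoretical slope coefficient of an ideal membrane sensor, 2 ln(10).
THEORETICAL_SLOPE = 2.0 * math.log(10.0)


@dataclass(frozen=True)
class PhysicalConstants:
    """Faraday constant, gas constant and temperature used by the isotherm.

    ``thermal_voltage`` (R*T/F, in volts) is derived, never stored.
    """

    F: float = 9.648e4  # C mol^-1
    R: float = 8.314    # J mol^-1 K^-1
    T: float = 298.0    # K

    def __post_init__(self) -> None:
        if self.F <= 0 or self.R <= 0 or self.T <= 0:
            raise ValueError("physical constants must be positive")

    @property
    def thermal_voltage(self) -> float:
        return self.R * self.T / self.F


DEFAULT_CONSTANTS = PhysicalConstants()

#: The nine-marker panel, in calibration-table order.
PANEL_9 = (
    "miR-200b",
    "miR-543",
    "miR-331",
    "miR-3605",
    "miR-301a",
    "miR-18a",
    "miR-423",
    "miR-142",
    "miR-132",
)

#: Built-in per-analyte isotherm constants (A, C_r in pM), version 1.
BUILTIN_ISOTHERM_CONSTANTS = {
    "miR-200b": (4.1745, 0.0493),
    "miR-543": (4.4899, 0.0702),
    "miR-331": (4.1706, 0.0614),
    "miR-3605": (4.0927, 0.0326),
    "miR-301a": (5.5452, 0.2778),
    "miR-18a": (4.4159, 0.0922),
    "miR-423": (5.9386, 0.1390),
    "miR-142": (5.3700, 0.1403),
    "miR-132": (4.2641, 0.0836),
}
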