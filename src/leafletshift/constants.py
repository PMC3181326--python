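"""Physical constants and unit conversion factors (SI, CODATA 2018)."""

ELEMENTARY_CHARGE = 1.602176634e-19  # C
BOLTZMANN = 1.380649e-23  # J/K
AVOGADRO = 6.02214076e23  # 1/mol
VACUUM_PERMITTIVITY = 8.8541878128e-12  # F/m
DEBYE = 3.33564e-30  # C·m per Debye unit

# Default aqueous-phase parameters for a symmetric 1:1 electrolyte at room
# temperature; the recordings being emulated were taken at 25 °C.
DEFAULT_TEMPERATURE_K = 298.15
DEFAULT_RELATIVE_PERMITTIVITY = 78.5


def thermal_voltage_mV(temperature_K: float = DEFAULT_TEMPERATURE_K) -> float:
    """kT/e in millivolts (~25.7 mV at 25 °C)."""
    return BOLTZMANN * temperature_K / ELEMENTARY_CHARGE * 1e3
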