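"""Thermal constants and state.

All mechanics in this package are expressed in the single-molecule unit
system: lengths in nm, forces in pN, energies in pN·nm, spring constants in
pN/nm.  Note 1 pN/nm ≡ 1e-3 N/m, so an effective stiffness of 8.0e-3 N/m is
8.0 pN/nm.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Boltzmann constant in pN·nm/K.
K_B = 0.0138065

#: Default experimental temperature, 23 °C.
DEFAULT_TEMPERATURE_K = 296.15


@dataclass(frozen=True)
class ThermalState:
    """Temperature of the bath, with the thermal energy scale derived.

    Parameters
    ----------
    temperature : float
        Absolute temperature in kelvin.  Defaults to 296.15 K (23 °C), the
        condition the device was characterized at.
    """

    temperature: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError(f"temperature must be > 0 K, got {self.temperature}")

    @property
    def kBT(self) -> float:
        """Thermal energy k_B·T in pN·nm (≈ 4.09 pN·nm at 23 °C)."""
        return K_B * self.temperature
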