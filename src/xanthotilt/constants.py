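"""Physical constants and the thermodynamic context shared by both routes."""

from __future__ import annotations

from dataclasses import dataclass

#: Gas constant in kcal mol^-1 K^-1.
R_KCAL_PER_MOL_K: float = 1.98720425e-3

#: Simulation temperature of the bilayer systems (K).
DEFAULT_TEMPERATURE_K: float = 320.0

#: Instrumental polarization correction factor of the two-channel detection.
DEFAULT_G_FACTOR: float = 0.99

#: Length of the distance->angle mapping lever arm (Å): the bilayer-normal
#: projection of the chromophore-half separation at fully vertical orientation.
DEFAULT_ELL_ANGSTROM: float = 11.8


def rt_kcal_per_mol(temperature: float = DEFAULT_TEMPERATURE_K) -> float:
    """Thermal energy RT in kcal/mol at ``temperature`` (K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return R_KCAL_PER_MOL_K * temperature


@dataclass(frozen=True)
class ThermoContext:
    """Temperature and the derived thermal energy.

    Attributes
    ----------
    temperature : float
        Absolute temperature in K.
    """

    temperature: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def rt(self) -> float:
        """RT in kcal/mol."""
        return R_KCAL_PER_MOL_K * self.temperature
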