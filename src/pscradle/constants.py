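"""Physical constants used throughout the model.

All values are SI except volumes, which the model keeps in litres so that
current / (z F Vol) directly yields a molar concentration rate (M/s).
"""

from dataclasses import dataclass


@dataclass(frozen=True)
class PhysicalConstants:
    """Fundamental constants at brain temperature.

    ``RT/F`` evaluates to ~26.7 mV at 310 K, the thermal voltage that scales
    every Nernst-type potential in the model.
    """

    R: float = 8.31          # gas constant, J/(mol K)
    T: float = 310.0         # absolute temperature, K
    F: float = 96485.0       # Faraday constant, C/mol
    k_B: float = 1.38e-23    # Boltzmann constant, J/K
    Q: float = 1.6022e-19    # elementary charge, C
    eps0: float = 8.85e-12   # vacuum permittivity, F/m
    eps_r: float = 0.82      # relative permittivity of cytoplasm (dimensionless)

    @property
    def RTF(self) -> float:
        """Thermal voltage RT/F in volts (~0.0267 V at 310 K)."""
        return self.R * self.T / self.F

    @property
    def kBT(self) -> float:
        """Thermal energy k_B*T in joules."""
        return self.k_B * self.T

    @property
    def eps(self) -> float:
        """Dynamic permittivity eps0*eps_r in F/m."""
        return self.eps0 * self.eps_r


CONSTANTS = PhysicalConstants()
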