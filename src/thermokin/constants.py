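"""Physical constants used by the Eyring and Arrhenius machinery.

Two immutable presets are provided:

``CODATA``
    Exact SI (2019 redefinition) values; default everywhere.
``COMPAT``
    The three-significant-figure values commonly used in printed
    biochemical thermodynamics tables (kB = 1.38e-23 J/K,
    h = 6.63e-34 J s, R = 8.314 J/(K mol)).  Used when reproducing
    reference tables computed at that precision.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class PhysicalConstants:
    kB: float  # Boltzmann constant, J/K
    h: float  # Planck constant, J*s
    R: float  # molar gas constant, J/(K*mol)
    N_A: float  # Avogadro constant, 1/mol

    @property
    def R_kJ(self) -> float:
        """Gas constant in kJ/(K*mol)."""
        return self.R / 1000.0


CODATA = PhysicalConstants(
    kB=1.380649e-23,
    h=6.62607015e-34,
    R=8.314462618,
    N_A=6.02214076e23,
)

COMPAT = PhysicalConstants(
    kB=1.38e-23,
    h=6.63e-34,
    R=8.314,
    N_A=6.022e23,
)
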