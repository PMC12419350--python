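"""Physical constants (CODATA 2018) used by the thermodynamic analysis."""

from dataclasses import dataclass

#: molar gas constant, J K^-1 mol^-1
R = 8.314462618
#: Boltzmann constant, J K^-1
K_B = 1.380649e-23
#: Planck constant, J s
H = 6.62607015e-34


@dataclass(frozen=True)
class PhysicalConstants:
    """Immutable bundle of the constants entering the Eyring equation."""

    r: float = R
    k_b: float = K_B
    h: float = H


CODATA2018 = PhysicalConstants()
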