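"""Unit conversions for iodometric titration kinetics.

Concentrations are mol dm^-3 throughout (identical to the printed mol l^-1),
time is seconds, temperature is kelvin.

Residual oxidant in an aliquot liberates one mole of I2 per mole of
chloramine-T from acidified KI; the iodine consumes two equivalents of
thiosulfate ("hypo"), so

    [CAT] = N_thio * V_titre / (2 * V_aliquot)

with N_thio in equivalents dm^-3 and volumes in cm^3 (the cm^3 cancel).
"""

from __future__ import annotations

import numpy as np

from .exceptions import KineticsDomainError

__all__ = [
    "celsius_to_kelvin",
    "kelvin_to_celsius",
    "titre_to_concentration",
    "concentration_to_titre",
]


def celsius_to_kelvin(t_celsius: float) -> float:
    """Convert a Celsius temperature to kelvin (T[K] = t[degC] + 273.15)."""
    return t_celsius + 273.15


def kelvin_to_celsius(t_kelvin: float) -> float:
    return t_kelvin - 273.15


def titre_to_concentration(titre, thio_normality: float, aliquot_volume: float):
    """Oxidant concentration (mol dm^-3) from a thiosulfate titre.

    Parameters
    ----------
    titre : float or array
        Thiosulfate volume at the end point, cm^3. Must be >= 0.
    thio_normality : float
        Thiosulfate normality, equivalents dm^-3. Must be >= 0.
    aliquot_volume : float
        Volume of the reaction aliquot quenched into KI, cm^3. Must be > 0.
    """
    if aliquot_volume <= 0:
        raise KineticsDomainError("aliquot_volume must be positive")
    if thio_normality < 0:
        raise KineticsDomainError("thio_normality must be non-negative")
    titre = np.asarray(titre, dtype=float)
    if np.any(titre < 0):
        raise KineticsDomainError("titre volumes must be non-negative")
    conc = thio_normality * titre / (2.0 * aliquot_volume)
    return float(conc) if conc.ndim == 0 else conc


def concentration_to_titre(conc, thio_normality: float, aliquot_volume: float):
    """Inverse of :func:`titre_to_concentration` (exact to machine precision)."""
    if aliquot_volume <= 0:
        raise KineticsDomainError("aliquot_volume must be positive")
    if thio_normality <= 0:
        raise KineticsDomainError("thio_normality must be positive to express a titre")
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise KineticsDomainError("concentrations must be non-negative")
    titre = 2.0 * aliquot_volume * conc / thio_normality
    return float(titre) if titre.ndim == 0 else titre
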