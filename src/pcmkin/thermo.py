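"""Eyring and Arrhenius analysis of rate constants versus temperature.

The Eyring equation (transmission coefficient 1)

    k = (k_B T / h) exp(dS/R) exp(-dH/(R T))

linearises as ln(k/T) = [ln(k_B/h) + dS/R] - (dH/R)(1/T), so an OLS fit of
ln(k/T) on 1/T yields the activation enthalpy dH (kJ mol^-1) from the slope
and entropy dS (J K^-1 mol^-1) from the intercept. Derived quantities:

    Ea  = dH + R T            (Arrhenius activation energy)
    dG  = dH - T dS           (Gibbs activation energy)
    lnA = dS/R + 1 + ln(k_B T / h)

Ea and lnA are quoted at a reference temperature (default the median
experimental temperature; 313.15 K for the standard 30-50 degC grid) while
dG is quoted at the analysis temperature (default 308.15 K); both are
configurable and stored explicitly because the two conventions differ.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .constants import H, K_B, R
from .exceptions import FitError, KineticsDomainError, ValidationError

__all__ = [
    "ActivationParameters",
    "ArrheniusFit",
    "eyring_rate_constant",
    "eyring_fit",
    "arrhenius_fit",
    "activation_derived",
]

IDENTITY_RTOL = 1e-6


def eyring_rate_constant(dH_kJ: float, dS_J: float, temperature):
    """Rate constant from the Eyring equation; dH in kJ mol^-1, dS in J K^-1 mol^-1."""
    T = np.asarray(temperature, dtype=float)
    k = (K_B * T / H) * np.exp(dS_J / R) * np.exp(-dH_kJ * 1000.0 / (R * T))
    return float(k) if k.ndim == 0 else k


def activation_derived(dH_kJ: float, dS_J: float, temperature: float) -> tuple[float, float, float]:
    """(Ea [kJ mol^-1], dG [kJ mol^-1], lnA) at the given temperature."""
    if temperature <= 0:
        raise KineticsDomainError("temperature must be positive")
    ea = dH_kJ + R * temperature / 1000.0
    dg = dH_kJ - temperature * dS_J / 1000.0
    ln_a = dS_J / R + 1.0 + np.log(K_B * temperature / H)
    return float(ea), float(dg), float(ln_a)


@dataclass(frozen=True)
class ActivationParameters:
    """Activation thermodynamics with their derivation temperatures.

    ``reference_T`` is the temperature at which Ea and lnA are quoted,
    ``gibbs_T`` the one for dG. The three derived identities are enforced to
    1e-6 relative at construction.
    """

    dH: float  # kJ mol^-1
    dS: float  # J K^-1 mol^-1
    Ea: float  # kJ mol^-1, at reference_T
    dG: float  # kJ mol^-1, at gibbs_T
    lnA: float  # dimensionless, at reference_T
    reference_T: float
    gibbs_T: float
    dH_se: float = float("nan")
    dS_se: float = float("nan")

    def __post_init__(self) -> None:
        if self.reference_T <= 0 or self.gibbs_T <= 0:
            raise ValidationError("temperatures must be positive")
        ea, _, ln_a = activation_derived(self.dH, self.dS, self.reference_T)
        _, dg, _ = activation_derived(self.dH, self.dS, self.gibbs_T)
        for name, stored, expect in (("Ea", self.Ea, ea), ("dG", self.dG, dg), ("lnA", self.lnA, ln_a)):
            scale = max(abs(expect), 1.0)
            if abs(stored - expect) > IDENTITY_RTOL * scale:
                raise ValidationError(
                    f"{name} inconsistent with (dH, dS) at its stated temperature: "
                    f"stored {stored!r}, derived {expect!r}"
                )

    @classmethod
    def from_enthalpy_entropy(
        cls,
        dH: float,
        dS: float,
        reference_T: float,
        gibbs_T: float | None = None,
        dH_se: float = float("nan"),
        dS_se: float = float("nan"),
    ) -> "ActivationParameters":
        gibbs_T = reference_T if gibbs_T is None else gibbs_T
        ea, _, ln_a = activation_derived(dH, dS, reference_T)
        _, dg, _ = activation_derived(dH, dS, gibbs_T)
        return cls(dH=dH, dS=dS, Ea=ea, dG=dg, lnA=ln_a,
                   reference_T=reference_T, gibbs_T=gibbs_T, dH_se=dH_se, dS_se=dS_se)


@dataclass(frozen=True)
class ArrheniusFit:
    Ea: float  # kJ mol^-1
    lnA: float
    Ea_se: float
    lnA_se: float
    r_squared: float


def _check_pairs(temperatures: np.ndarray, rate_constants: np.ndarray) -> None:
    if temperatures.shape != rate_constants.shape or temperatures.ndim != 1:
        raise KineticsDomainError("temperatures and rate constants must be 1-D, equal length")
    if np.unique(temperatures).size < 2:
        raise FitError("at least 2 distinct temperatures are required")
    if np.any(temperatures <= 0):
        raise KineticsDomainError("temperatures must be positive kelvin")
    if np.any(rate_constants <= 0):
        raise FitError("all rate constants must be positive for a log-linear fit")


def eyring_fit(
    temperatures: Sequence[float],
    rate_constants: Sequence[float],
    reference_T: float | None = None,
    gibbs_T: float = 308.15,
) -> ActivationParameters:
    """OLS of ln(k/T) on 1/T -> (dH, dS) with standard errors.

    ``reference_T`` (for Ea and lnA) defaults to the median experimental
    temperature; dG is derived at ``gibbs_T``.
    """
    T = np.asarray(temperatures, dtype=float)
    k = np.asarray(rate_constants, dtype=float)
    _check_pairs(T, k)
    res = stats.linregress(1.0 / T, np.log(k / T))
    dH = -res.slope * R / 1000.0
    dS = R * (res.intercept - np.log(K_B / H))
    dH_se = (res.stderr if np.isfinite(res.stderr) else 0.0) * R / 1000.0
    dS_se = (res.intercept_stderr if np.isfinite(res.intercept_stderr) else 0.0) * R
    if reference_T is None:
        reference_T = float(np.median(T))
    return ActivationParameters.from_enthalpy_entropy(
        float(dH), float(dS), reference_T, gibbs_T, dH_se=float(dH_se), dS_se=float(dS_se)
    )


def arrhenius_fit(
    temperatures: Sequence[float],
    rate_constants: Sequence[float],
) -> ArrheniusFit:
    """OLS of ln k on 1/T -> Ea = -slope*R (kJ mol^-1) and lnA = intercept.

    Over a narrow temperature window this satisfies Ea ~= dH + R*T_mean
    against :func:`eyring_fit` on the same data.
    """
    T = np.asarray(temperatures, dtype=float)
    k = np.asarray(rate_constants, dtype=float)
    _check_pairs(T, k)
    res = stats.linregress(1.0 / T, np.log(k))
    ea = -res.slope * R / 1000.0
    ea_se = (res.stderr if np.isfinite(res.stderr) else 0.0) * R / 1000.0
    ln_a_se = res.intercept_stderr if np.isfinite(res.intercept_stderr) else 0.0
    return ArrheniusFit(
        Ea=float(ea), lnA=float(res.intercept),
        Ea_se=float(ea_se), lnA_se=float(ln_a_se), r_squared=float(res.rvalue**2),
    )
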