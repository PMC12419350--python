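"""Oxidant:substrate consumption ratio from an excess-oxidant experiment.

The substrate is allowed to react to completion in the presence of excess
chloramine-T; the residual oxidant is estimated iodometrically, and the
consumption ratio is (cat0 - cat_final)/pcm0. For this system two moles of
oxidant are consumed per mole of paracetamol (the product is quinone oxime).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .core import ReactionConditions
from .exceptions import IntegrationError, KineticsDomainError, NoReactionError, ValidationError
from .mechanism import MechanismParameters, catalytic_rate_law, effective_second_order_constant

__all__ = ["StoichiometryResult", "determine_stoichiometry", "react_to_completion"]

#: accepted determinations must sit within this distance of the rounding grid
ACCEPTANCE_DISTANCE = 0.25
#: substrate conversion that operationalises "complete reaction"
COMPLETE_CONVERSION = 0.9999


@dataclass(frozen=True)
class StoichiometryResult:
    """Consumed-oxidant : consumed-substrate ratio.

    ``rounded`` snaps to the nearest half-integer so non-integer mechanistic
    ratios stay representable; ``accepted`` is True when the raw ratio falls
    within 0.25 of that grid point.
    """

    ratio: float
    rounded: float
    residual_oxidant: float
    accepted: bool

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise ValidationError("consumption ratio must be positive")


def determine_stoichiometry(cat0: float, pcm0: float, cat_final: float) -> StoichiometryResult:
    """Back-titration arithmetic: ratio = (cat0 - cat_final)/pcm0.

    ``cat_final >= cat0`` means no oxidant was consumed and raises; a
    vanishing residual means the oxidant may have been limiting, so the
    ratio is only a lower bound (warning). The ratio is invariant to a
    common dilution of all three inputs.
    """
    if pcm0 <= 0:
        raise KineticsDomainError("pcm0 must be positive")
    if cat_final < 0 or cat0 <= 0:
        raise KineticsDomainError("concentrations must be non-negative, cat0 positive")
    if cat_final >= cat0:
        raise NoReactionError(
            f"no oxidant consumed (cat_final {cat_final!r} >= cat0 {cat0!r})"
        )
    if cat_final == 0:
        warnings.warn(
            "residual oxidant is zero: the oxidant may have been limiting and the "
            "ratio is only a lower bound", stacklevel=2,
        )
    ratio = (cat0 - cat_final) / pcm0
    rounded = round(ratio * 2.0) / 2.0
    return StoichiometryResult(
        ratio=float(ratio),
        rounded=float(rounded),
        residual_oxidant=float(cat_final),
        accepted=bool(abs(ratio - rounded) <= ACCEPTANCE_DISTANCE),
    )


def react_to_completion(
    conditions: ReactionConditions,
    params: MechanismParameters,
    conversion: float = COMPLETE_CONVERSION,
) -> tuple[float, float, float]:
    """Integrate the full coupled scheme until the substrate conversion
    reaches ``conversion``; returns (cat_final, pcm_final, t_final).

    Emulates letting the mixture stand until the reaction is complete.
    Requires excess oxidant (cat0 > 2 pcm0) so the substrate can actually be
    exhausted under the 2:1 scheme.
    """
    cat0, pcm0 = conditions.cat0, conditions.pcm0
    if pcm0 <= 0 or cat0 <= 0:
        raise KineticsDomainError("cat0 and pcm0 must be positive")
    excess = cat0 - 2.0 * pcm0
    if excess <= 0:
        raise KineticsDomainError(
            "react_to_completion requires excess oxidant (cat0 > 2*pcm0)"
        )
    k2 = effective_second_order_constant(conditions, params)
    if k2 <= 0:
        raise KineticsDomainError("zero-rate system never completes")
    # pseudo-first-order bound for the substrate against the residual oxidant
    t_max = 40.0 * np.log(1.0 / (1.0 - conversion)) / (k2 * excess / 2.0)
    target = (1.0 - conversion) * pcm0

    def rhs(_t: float, y):
        rate = catalytic_rate_law(conditions, params, max(y[0], 0.0), max(y[1], 0.0))
        return [-rate, -rate / 2.0]

    def done(_t: float, y):
        return y[1] - target

    done.terminal = True
    done.direction = -1

    sol = solve_ivp(rhs, (0.0, t_max), [cat0, pcm0], method="LSODA",
                    rtol=1e-10, atol=1e-14, events=done)
    if not sol.success:
        raise IntegrationError(f"stoichiometry integration failed: {sol.message}")
    if sol.t_events[0].size == 0:
        warnings.warn("target conversion not reached within the integration horizon",
                      stacklevel=2)
        cat_f, pcm_f, t_f = sol.y[0][-1], sol.y[1][-1], sol.t[-1]
    else:
        cat_f, pcm_f = sol.y_events[0][0]
        t_f = sol.t_events[0][0]
    return float(cat_f), float(pcm_f), float(t_f)
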