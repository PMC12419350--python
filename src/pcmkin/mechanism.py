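"""Speciation logic, the hydroxide-inhibited catalytic rate law, and the
forward simulator.

Model
-----
In alkaline solution the oxidant's reactive species is the anion RNCl^-
(R = p-CH3C6H4SO2) and the catalyst's is [OsO3(OH)3]^- , formed from the
predominant [OsO4(OH)2]^2- by loss of hydroxide; binding of OH^- back onto
the catalyst (equilibrium constant K1, dm^3 mol^-1) removes the active form,
which is the origin of the observed rate inhibition by hydroxide. With a
weak (K2, default 0) substrate-complexation step folded in, the loss of
oxidant follows

    -d[CAT]/dt = ( k_u + k_cat [Os]_T / (1 + K1 [OH-] + K2 [PCM]) ) [PCM][CAT]

where k_cat (dm^6 mol^-2 s^-1) is the rate-determining constant of the
catalysed path on the k_obs scale, and k_u (dm^3 mol^-1 s^-1) is a parallel
uncatalysed bimolecular path with no hydroxide dependence. The observed
third-order constant is k_obs = k' / ([Os]_T [PCM]0); under K2 = 0 and
k_u = 0 it obeys k_obs = k_cat / (1 + K1 [OH-]), whose double reciprocal
1/k_obs vs [OH-] is a straight line: k_cat = 1/intercept and
K1 = slope/intercept (the only direction consistent with evaluating the
rate-determining constant from the intercept).

Two moles of oxidant are consumed per mole of substrate, so the simulator
integrates d[PCM]/dt = -rate/2 alongside d[CAT]/dt = -rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats
from scipy.integrate import solve_ivp

from .core import ReactionConditions, TitrationTimeSeries
from .exceptions import (
    FitError,
    IntegrationError,
    KineticsDomainError,
    SpeciesDecisionError,
    ValidationError,
)
from .units import concentration_to_titre

__all__ = [
    "MechanismParameters",
    "HydroxideFit",
    "SpeciesDecision",
    "select_reactive_species",
    "catalytic_rate_law",
    "effective_second_order_constant",
    "k_obs_from_pseudo",
    "fit_hydroxide_inhibition",
    "simulate_scheme",
    "default_time_grid",
]

#: default number of aliquots per simulated run
DEFAULT_N_POINTS = 10
#: default first-order log-decay of the oxidant at the final aliquot
#: (0.63 ~= 47% conversion ~= 0.91 half-lives; see docs/methods.md)
DEFAULT_DECAY_EXTENT = 0.63

RTOL, ATOL = 1e-9, 1e-12


@dataclass(frozen=True)
class MechanismParameters:
    """Parameters of the folded rate law (all non-negative).

    k_cat : dm^6 mol^-2 s^-1, rate-determining constant of the catalysed
        path on the k_obs scale
    K1 : dm^3 mol^-1, hydroxide-binding equilibrium constant
    K2 : dm^3 mol^-1, substrate-complexation constant; 0 by default, its
        effect being folded into k_cat (it is insignificant for this system)
    k_u : dm^3 mol^-1 s^-1, parallel uncatalysed second-order constant
    """

    k_cat: float
    K1: float
    K2: float = 0.0
    k_u: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k_cat", "K1", "K2", "k_u"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


# ---------------------------------------------------------------------------
# Speciation
# ---------------------------------------------------------------------------

ALKALINE_OXIDANTS = ("RNCl-", "OCl-")
ACIDIC_OXIDANTS = ("RNHCl", "HOCl", "RNCl2")
CATALYST_ACTIVE = "[OsO3(OH)3]-"
CATALYST_PREDOMINANT = "[OsO4(OH)2]2-"


@dataclass(frozen=True)
class SpeciesDecision:
    medium: str
    diagnostics: dict
    reactive_oxidant: str
    reactive_catalyst: str
    retained: tuple[str, ...]
    eliminated: tuple[tuple[str, str], ...]


def select_reactive_species(
    medium: str,
    *,
    oh_inhibition: bool,
    chloride_catalysis: bool,
    pts_retardation: bool,
    base_catalysis: bool,
) -> SpeciesDecision:
    """Elimination table assigning the kinetically active oxidant and
    catalyst species from the medium and four qualitative diagnostics.

    In alkaline medium the candidates are RNCl- and OCl-; OCl- survives only
    for base-catalysed reactions, RNHCl only when chloride catalysis is
    observed (and chloride catalysis together with retardation by the
    reduced sulfonamide PTS is contradictory). The catalyst's active form is
    [OsO3(OH)3]- when hydroxide inhibits the rate, else [OsO4(OH)2]2-.
    """
    if medium not in ("acidic", "alkaline"):
        raise SpeciesDecisionError(f"medium must be 'acidic' or 'alkaline', got {medium!r}")
    diagnostics = {
        "oh_inhibition": oh_inhibition,
        "chloride_catalysis": chloride_catalysis,
        "pts_retardation": pts_retardation,
        "base_catalysis": base_catalysis,
    }
    catalyst = CATALYST_ACTIVE if oh_inhibition else CATALYST_PREDOMINANT
    eliminated: list[tuple[str, str]] = []

    if medium == "alkaline":
        if chloride_catalysis and pts_retardation:
            raise SpeciesDecisionError(
                "contradictory diagnostics in alkaline medium: chloride catalysis implicates "
                "RNHCl, but retardation by the reduced sulfonamide (PTS) rules the acidic "
                "pathway out"
            )
        for species in ACIDIC_OXIDANTS:
            if species == "RNHCl" and chloride_catalysis:
                continue
            eliminated.append((species, "reactive only in an acidic medium"))
        if base_catalysis:
            oxidant = "OCl-"
            eliminated.append(("RNCl-", "OCl- is implicated for a base-catalysed reaction"))
        elif chloride_catalysis:
            oxidant = "RNHCl"
            eliminated.append(("RNCl-", "chloride catalysis implicates RNHCl"))
            eliminated.append(("OCl-", "effective only in base-catalysed reactions"))
        else:
            oxidant = "RNCl-"
            eliminated.append(("OCl-", "effective only in base-catalysed reactions"))
        retained = (oxidant,)
    else:
        retained = ACIDIC_OXIDANTS
        oxidant = "RNHCl"
        for species in ALKALINE_OXIDANTS:
            eliminated.append((species, "alkaline-medium species"))

    return SpeciesDecision(
        medium=medium,
        diagnostics=diagnostics,
        reactive_oxidant=oxidant,
        reactive_catalyst=catalyst,
        retained=retained,
        eliminated=tuple(eliminated),
    )


# ---------------------------------------------------------------------------
# Rate law
# ---------------------------------------------------------------------------

def effective_second_order_constant(
    conditions: ReactionConditions, params: MechanismParameters, pcm: float | None = None
) -> float:
    """k2_eff = k_u + k_cat [Os]_T / (1 + K1 [OH-] + K2 [PCM]), dm^3 mol^-1 s^-1."""
    pcm = conditions.pcm0 if pcm is None else pcm
    denom = 1.0 + params.K1 * conditions.oh + params.K2 * pcm
    return params.k_u + params.k_cat * conditions.os_total / denom


def catalytic_rate_law(
    conditions: ReactionConditions,
    params: MechanismParameters,
    cat,
    pcm,
):
    """Instantaneous rate of oxidant loss, mol dm^-3 s^-1.

    Bilinear in cat and pcm at K2 = 0; independent of ionic strength; the
    catalysed component is first order in the gross catalyst concentration.
    """
    cat = np.asarray(cat, dtype=float)
    pcm = np.asarray(pcm, dtype=float)
    denom = 1.0 + params.K1 * conditions.oh + params.K2 * pcm
    rate = (params.k_u + params.k_cat * conditions.os_total / denom) * pcm * cat
    return float(rate) if rate.ndim == 0 else rate


def k_obs_from_pseudo(k_psi: float, conditions: ReactionConditions) -> float:
    """Observed third-order constant k_obs = k' / ([Os]_T [PCM]0), dm^6 mol^-2 s^-1."""
    divisor = conditions.os_total * conditions.pcm0
    if divisor <= 0:
        raise KineticsDomainError("k_obs requires os_total > 0 and pcm0 > 0")
    if k_psi < 0:
        raise KineticsDomainError("k_psi must be non-negative")
    return k_psi / divisor


# ---------------------------------------------------------------------------
# Hydroxide-inhibition (double-reciprocal) fit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HydroxideFit:
    """Result of the 1/k_obs vs [OH-] line at one temperature.

    k_cat = 1/intercept; K1 = slope/intercept. A nonlinear least-squares
    refit of k_obs = k_cat/(1 + K1 [OH-]) is stored for consistency; a
    discrepancy beyond 2 SE triggers a warning at fit time.
    """

    k_cat: float
    K1: float
    k_cat_se: float
    K1_se: float
    intercept: float
    slope: float
    intercept_se: float
    slope_se: float
    r_squared: float
    temperature: float
    k_cat_nonlinear: float = field(default=float("nan"))
    K1_nonlinear: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if self.intercept <= 0:
            raise FitError("a valid hydroxide-inhibition fit requires intercept > 0")


def fit_hydroxide_inhibition(
    oh: Sequence[float],
    k_obs: Sequence[float],
    temperature: float = 308.15,
) -> HydroxideFit:
    """OLS of 1/k_obs against [OH-], with a nonlinear refit as cross-check.

    Requires at least 3 distinct hydroxide levels and positive k_obs; an
    intercept <= 0 means the inhibition model is inconsistent with the data
    and raises :class:`FitError`.
    """
    oh = np.asarray(oh, dtype=float)
    k_obs = np.asarray(k_obs, dtype=float)
    if oh.shape != k_obs.shape or oh.ndim != 1:
        raise KineticsDomainError("oh and k_obs must be 1-D arrays of equal length")
    if np.unique(oh).size < 3:
        raise FitError("fit_hydroxide_inhibition needs at least 3 distinct [OH-] values")
    if np.any(k_obs <= 0):
        raise FitError("all k_obs must be positive")

    y = 1.0 / k_obs
    res = stats.linregress(oh, y)
    slope, intercept = res.slope, res.intercept
    slope_se, intercept_se = res.stderr, res.intercept_stderr
    if intercept <= 0:
        raise FitError(
            f"double-reciprocal intercept is {intercept:.3g} <= 0: "
            "the inhibition model is inconsistent with the data"
        )
    k_cat = 1.0 / intercept
    K1 = max(slope, 0.0) / intercept
    if slope < 0:
        warnings.warn("negative double-reciprocal slope; K1 clamped to 0", stacklevel=2)

    # delta-method SEs, including the slope/intercept covariance of OLS
    k_cat_se = intercept_se / intercept**2
    cov_si = -np.mean(oh) * slope_se**2
    var_K1 = (
        (slope_se / intercept) ** 2
        + (slope * intercept_se / intercept**2) ** 2
        - 2.0 * slope * cov_si / intercept**3
    )
    K1_se = float(np.sqrt(max(var_K1, 0.0)))

    # nonlinear refit of the same model, seeded from the OLS estimates
    try:
        with warnings.catch_warnings():
            # the covariance of the refit is unused; flat data make it singular
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(
                lambda x, a, b: a / (1.0 + b * x), oh, k_obs,
                p0=[k_cat, max(K1, 1e-12)], maxfev=10000,
            )
        kc_nl, K1_nl = float(popt[0]), float(popt[1])
    except RuntimeError:  # pragma: no cover - pathological data
        kc_nl, K1_nl = float("nan"), float("nan")
    if np.isfinite(kc_nl) and k_cat_se > 0 and abs(kc_nl - k_cat) > 2.0 * k_cat_se:
        warnings.warn(
            "nonlinear refit of k_cat departs from the double-reciprocal estimate by "
            "more than 2 SE; the inhibition model may be strained", stacklevel=2,
        )
    if np.isfinite(K1_nl) and K1_se > 0 and abs(K1_nl - K1) > 2.0 * K1_se:
        warnings.warn(
            "nonlinear refit of K1 departs from the double-reciprocal estimate by "
            "more than 2 SE", stacklevel=2,
        )

    return HydroxideFit(
        k_cat=float(k_cat), K1=float(K1), k_cat_se=float(k_cat_se), K1_se=K1_se,
        intercept=float(intercept), slope=float(slope),
        intercept_se=float(intercept_se), slope_se=float(slope_se),
        r_squared=float(res.rvalue**2), temperature=float(temperature),
        k_cat_nonlinear=kc_nl, K1_nonlinear=K1_nl,
    )


# ---------------------------------------------------------------------------
# Forward simulation
# ---------------------------------------------------------------------------

def default_time_grid(
    conditions: ReactionConditions,
    params: MechanismParameters,
    n_points: int = DEFAULT_N_POINTS,
    decay_extent: float = DEFAULT_DECAY_EXTENT,
) -> np.ndarray:
    """Equally spaced aliquot times covering ``decay_extent`` units of
    first-order log-decay of the oxidant (predicted from the rate law)."""
    k_psi = effective_second_order_constant(conditions, params) * conditions.pcm0
    if k_psi <= 0:
        raise KineticsDomainError("cannot scale a time grid for a zero-rate run")
    return np.linspace(0.0, decay_extent / k_psi, n_points)


def simulate_scheme(
    conditions: ReactionConditions,
    params: MechanismParameters,
    time_grid: Sequence[float],
    noise_sd_frac: float = 0.0,
    seed: int | None = None,
    *,
    hold_substrate: bool = False,
    run_id: str = "sim",
    replicate_id: int = 1,
    value_unit: str = "cm3_titre",
    aliquot_volume: float = 10.0,
    thio_normality: float = 0.01,
    rng: np.random.Generator | None = None,
) -> TitrationTimeSeries:
    """Integrate the mechanism forward and emit a titration time series.

    The coupled system d[CAT]/dt = -rate, d[PCM]/dt = -rate/2 is integrated
    with LSODA (rtol 1e-9, atol 1e-12) so the stoichiometric invariant
    [CAT] - 2[PCM] + 2 pcm0 - cat0 = 0 holds to test precision along
    noise-free trajectories. With ``hold_substrate`` the substrate is kept
    at pcm0 (the buffered-substrate idealisation used for pseudo-first-order
    design grids); at K2 = 0 that reduces to an exact exponential, which is
    used directly.

    Concentrations are converted to titres through the inverse of the
    iodometric conversion, then multiplicative Gaussian noise of relative SD
    ``noise_sd_frac`` is applied (truncated at zero) using ``seed``/``rng``.
    """
    time_grid = np.asarray(time_grid, dtype=float)
    if time_grid.size == 0:
        raise KineticsDomainError("time_grid must be non-empty")
    if time_grid[0] < 0 or np.any(np.diff(time_grid) <= 0):
        raise KineticsDomainError("time_grid must be non-negative and strictly increasing")
    if noise_sd_frac < 0:
        raise KineticsDomainError("noise_sd_frac must be >= 0")

    cat0, pcm0 = conditions.cat0, conditions.pcm0

    if hold_substrate and params.K2 == 0.0:
        k_psi = effective_second_order_constant(conditions, params) * pcm0
        cat = cat0 * np.exp(-k_psi * time_grid)
        pcm = np.full_like(cat, pcm0)
    else:
        def rhs(_t: float, y: np.ndarray) -> list[float]:
            cat_now = max(y[0], 0.0)
            pcm_now = pcm0 if hold_substrate else max(y[1], 0.0)
            rate = catalytic_rate_law(conditions, params, cat_now, pcm_now)
            return [-rate, 0.0 if hold_substrate else -rate / 2.0]

        t_end = float(time_grid[-1])
        sol = solve_ivp(
            rhs, (0.0, t_end if t_end > 0 else 1.0), [cat0, pcm0],
            t_eval=time_grid, method="LSODA", rtol=RTOL, atol=ATOL,
        )
        if not sol.success:
            raise IntegrationError(f"ODE integration failed: {sol.message}")
        cat, pcm = sol.y[0], sol.y[1]
        if np.any(cat < 0) or np.any(pcm < 0):
            warnings.warn("negative state clipped at 0", stacklevel=2)
            cat, pcm = np.clip(cat, 0.0, None), np.clip(pcm, 0.0, None)

    if value_unit == "cm3_titre":
        values = concentration_to_titre(cat, thio_normality, aliquot_volume)
    elif value_unit == "mol_per_dm3":
        values = cat.copy()
    else:
        raise KineticsDomainError(f"unknown value_unit {value_unit!r}")

    if noise_sd_frac > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        values = values * rng.normal(1.0, noise_sd_frac, size=values.shape)
        values = np.clip(values, 0.0, None)

    with warnings.catch_warnings():
        # flat zero-rate runs legitimately do not decay
        warnings.simplefilter("ignore")
        return TitrationTimeSeries(
            run_id=run_id,
            replicate_id=replicate_id,
            times=time_grid,
            values=values,
            value_unit=value_unit,
            conditions=conditions,
            aliquot_volume=aliquot_volume,
            thio_normality=thio_normality,
        )
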