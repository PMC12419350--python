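"""Rate-constant estimation from titration time courses.

The oxidant (chloramine-T) decays exponentially when the substrate is held
in large excess; the pseudo-first-order constant k' (s^-1) is the negative
slope of ln[CAT]_t against t. When the two concentrations are comparable the
2:1 stoichiometric coupling d[PCM]/dt = (1/2) d[CAT]/dt makes
ln([PCM]_t/[CAT]_t) exactly linear in t with slope k2*([PCM]0 - [CAT]0/2),
which is the linearisation used for the mixed second-order fit.

Reported constants come from ordinary least squares on the linearised form
(matching graphical practice for titration kinetics); an exponential
nonlinear refit is available as a cross-check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .core import KineticDataset, TitrationTimeSeries
from .exceptions import FitError, KineticsDomainError
from .units import titre_to_concentration  # re-exported: spec'd here

__all__ = [
    "MAX_CONVERSION",
    "RateFitResult",
    "OrderEstimate",
    "ReplicateStats",
    "titre_to_concentration",
    "fit_pseudo_first_order",
    "fit_second_order_mixed",
    "second_order_from_pseudo",
    "estimate_order",
    "replicate_agreement",
]

#: points beyond this conversion of the limiting reagent are excluded from
#: linearised fits (logs blow up near exhaustion)
MAX_CONVERSION = 0.90

#: relative spread of k' below which the oxidant order is declared 1 by
#: condition-independence
INVARIANCE_SPREAD = 0.03


@dataclass(frozen=True)
class RateFitResult:
    """A fitted rate constant.

    ``unit`` is ``"s^-1"`` for pseudo-first-order constants and
    ``"dm3 mol^-1 s^-1"`` for second-order constants. ``window`` holds the
    (first, last) indices of the samples used. ``flags`` records degenerate
    or warning states instead of raising.
    """

    constant: float
    standard_error: float
    r_squared: float
    n_points: int
    window: tuple[int, int]
    unit: str
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.constant < 0:
            raise FitError("rate constants must be non-negative")
        if not (0.0 <= self.r_squared <= 1.0):
            raise FitError(f"r_squared out of [0, 1]: {self.r_squared}")
        if self.n_points < 3 and "degenerate" not in " ".join(self.flags):
            raise FitError("a rate fit needs at least 3 points")


@dataclass(frozen=True)
class OrderEstimate:
    order: float
    standard_error: float
    through_origin: bool
    method: str  # "log-log" or "invariance"
    n_runs: int


@dataclass(frozen=True)
class ReplicateStats:
    """Replicate-agreement statistics: per-group CV (%) and one-way ICC(1,1)."""

    cv_percent: tuple[float, ...]
    icc: float

    def __post_init__(self) -> None:
        if any(cv < 0 for cv in self.cv_percent):
            raise FitError("CV must be non-negative")
        if not (-1.0 <= self.icc <= 1.0):
            raise FitError(f"ICC out of [-1, 1]: {self.icc}")


def _fit_window(conc: np.ndarray, reference: float) -> np.ndarray:
    """Boolean mask of usable points: positive concentration and conversion
    (relative to ``reference``) at most :data:`MAX_CONVERSION`."""
    mask = conc > 0
    if reference > 0:
        mask &= (1.0 - conc / reference) <= MAX_CONVERSION
    return mask


def _ols(x: np.ndarray, y: np.ndarray):
    result = stats.linregress(x, y)
    r2 = result.rvalue**2 if np.isfinite(result.rvalue) else 0.0
    return result.slope, result.intercept, result.stderr, result.intercept_stderr, r2


def fit_pseudo_first_order(run: TitrationTimeSeries) -> RateFitResult:
    """OLS of ln[CAT]_t vs t; the constant is the negative slope (s^-1).

    Non-positive concentrations and points beyond 90% conversion are
    excluded (with a warning if any were dropped); a constant series is
    reported as zero slope with a ``degenerate-constant-series`` flag rather
    than an error. The estimate is invariant to scaling of [CAT]0, as
    required for a reaction first order in the oxidant.
    """
    conc = run.concentrations()
    flags: list[str] = []
    if not run.conditions.is_pseudo_first_order:
        flags.append("excess-substrate-condition-violated")

    mask = _fit_window(conc, run.conditions.cat0 if run.conditions.cat0 > 0 else conc[0] if conc[0] > 0 else 0.0)
    n_used = int(mask.sum())
    if n_used < run.n_points:
        warnings.warn(
            f"run {run.run_id!r}: excluded {run.n_points - n_used} point(s) outside the fit window",
            stacklevel=2,
        )
    if np.allclose(conc, conc[0], rtol=1e-15, atol=0.0):
        # no decay at all (e.g. cat0 = 0 or zero rate): report zero slope
        flags.append("degenerate-constant-series")
        return RateFitResult(0.0, 0.0, 0.0, run.n_points, (0, run.n_points - 1), "s^-1",
                             tuple(flags))
    if n_used < 3:
        raise FitError(f"run {run.run_id!r}: fewer than 3 usable points for a pseudo-first-order fit")

    t, y = run.times[mask], np.log(conc[mask])
    slope, _, stderr, _, r2 = _ols(t, y)
    if slope > 0:
        flags.append("positive-slope-clamped-to-zero")
        constant = 0.0
    else:
        constant = -slope
    used = np.flatnonzero(mask)
    return RateFitResult(constant, stderr, r2, n_used, (int(used[0]), int(used[-1])),
                         "s^-1", tuple(flags))


def fit_second_order_mixed(run: TitrationTimeSeries) -> RateFitResult:
    """Second-order fit with 2:1 stoichiometric coupling.

    [PCM]_t is reconstructed as pcm0 - ([CAT]0 - [CAT]_t)/2 and
    ln([PCM]_t/[CAT]_t) is regressed on t; the constant is
    slope / (pcm0 - cat0/2) in dm^3 mol^-1 s^-1.
    """
    a0, b0 = run.conditions.cat0, run.conditions.pcm0
    delta = b0 - a0 / 2.0
    if delta <= 0:
        raise KineticsDomainError(
            "fit_second_order_mixed requires pcm0 > cat0/2 (substrate not exhausted)"
        )
    a = run.concentrations()
    flags: list[str] = []
    if a0 == 0 or np.allclose(a, a[0], rtol=1e-15, atol=0.0):
        flags.append("degenerate-constant-series")
        return RateFitResult(0.0, 0.0, 0.0, run.n_points, (0, run.n_points - 1),
                             "dm3 mol^-1 s^-1", tuple(flags))
    b = b0 - (a0 - a) / 2.0
    mask = _fit_window(a, a0) & (b > 0)
    if int(mask.sum()) < 3:
        raise FitError(f"run {run.run_id!r}: fewer than 3 usable points for a second-order fit")
    t, y = run.times[mask], np.log(b[mask] / a[mask])
    slope, _, stderr, _, r2 = _ols(t, y)
    if slope <= 0:
        warnings.warn(f"run {run.run_id!r}: non-positive second-order slope; constant reported as 0",
                      stacklevel=2)
        constant, flags = 0.0, flags + ["non-positive-slope"]
    else:
        constant = slope / delta
    used = np.flatnonzero(mask)
    return RateFitResult(constant, stderr / delta, r2, int(mask.sum()),
                         (int(used[0]), int(used[-1])), "dm3 mol^-1 s^-1", tuple(flags))


def second_order_from_pseudo(k_psi: float, pcm0: float) -> float:
    """k'' = k'/[PCM]0 (dm^3 mol^-1 s^-1), the Table-style 'calculated'
    second-order constant."""
    if pcm0 <= 0:
        raise KineticsDomainError("pcm0 must be positive to normalise k'")
    if k_psi < 0:
        raise KineticsDomainError("k_psi must be non-negative")
    return k_psi / pcm0


def refit_exponential(run: TitrationTimeSeries) -> tuple[float, float]:
    """Nonlinear cross-check: fit c0*exp(-k t) directly; returns (k, se)."""
    conc = run.concentrations()
    ols = fit_pseudo_first_order(run)
    p0 = [max(conc[0], 1e-30), max(ols.constant, 1e-12)]
    popt, pcov = optimize.curve_fit(lambda t, c0, k: c0 * np.exp(-k * t),
                                    run.times, conc, p0=p0, maxfev=10000)
    return float(popt[1]), float(np.sqrt(pcov[1, 1]))


_SPECIES_FIELD = {"cat": "cat0", "pcm": "pcm0", "os": "os_total", "oh": "oh"}


def estimate_order(dataset: KineticDataset, varied: str) -> OrderEstimate:
    """Reaction order with respect to one varied species.

    The order is the slope of ln k' against ln(concentration) over runs that
    vary only the named species. Two special declarations mirror graphical
    practice:

    * the through-origin flag is true when the direct linear fit of k'
      against concentration has |intercept| < 2 SE(intercept);
    * for the varied-oxidant design, the order is declared 1 by
      condition-independence when the k' spread is below 3% of the mean
      (k' does not depend on [CAT]0 for a first-order oxidant).
    """
    if varied not in _SPECIES_FIELD:
        raise KineticsDomainError(f"unknown species {varied!r}; expected one of {sorted(_SPECIES_FIELD)}")
    field_name = _SPECIES_FIELD[varied]
    runs = dataset.runs
    if len(runs) < 4:
        raise KineticsDomainError("estimate_order needs at least 4 runs")
    from .core import conditions_vary

    others = conditions_vary(runs, ignore=(field_name,))
    if others:
        raise KineticsDomainError(
            f"runs vary more than the requested species: also varying {', '.join(others)}"
        )
    k = np.array([fit_pseudo_first_order(run).constant for run in runs])
    x = np.array([getattr(run.conditions, field_name) for run in runs])
    if np.any(k <= 0) or np.any(x <= 0):
        raise FitError("order estimation needs positive k' and concentrations")

    # through-origin diagnostic on the direct k' vs concentration line
    _, intercept, _, intercept_se, _ = _ols(x, k)
    through_origin = abs(intercept) < 2.0 * intercept_se if intercept_se > 0 else True

    if varied == "cat":
        spread = (k.max() - k.min()) / k.mean()
        if spread < INVARIANCE_SPREAD:
            return OrderEstimate(1.0, 0.0, through_origin, "invariance", len(runs))
    slope, _, stderr, _, _ = _ols(np.log(x), np.log(k))
    return OrderEstimate(float(slope), float(stderr), through_origin, "log-log", len(runs))


def replicate_agreement(groups: Sequence[Sequence[float]]) -> ReplicateStats:
    """CV per group and one-way random-effects ICC(1,1) across groups.

    CV is 100 * sample SD / mean within each group of replicate rate
    constants. The ICC uses the one-way ANOVA decomposition with g groups of
    k replicates each:

        ICC = (MSB - MSW) / (MSB + (k - 1) MSW)

    Groups must share a replicate count; a group with zero mean has no CV
    and raises.
    """
    if len(groups) < 2:
        raise KineticsDomainError("replicate_agreement needs at least 2 groups")
    sizes = {len(g) for g in groups}
    if len(sizes) != 1:
        raise KineticsDomainError("ICC(1,1) requires equal replicate counts per group")
    k = sizes.pop()
    if k < 2:
        raise KineticsDomainError("each group needs at least 2 replicates")
    data = np.asarray(groups, dtype=float)
    means = data.mean(axis=1)
    for index, mean in enumerate(means):
        if mean == 0:
            raise KineticsDomainError(f"group {index} has zero mean; CV undefined")
    # bitwise-identical replicates have exactly zero spread; avoid the
    # rounding residue of mean subtraction
    identical = np.all(data == data[:, :1], axis=1)
    cv = 100.0 * data.std(axis=1, ddof=1) / np.abs(means)
    cv[identical] = 0.0

    g = data.shape[0]
    grand = data.mean()
    within = data - means[:, None]
    within[identical, :] = 0.0
    msb = k * np.sum((means - grand) ** 2) / (g - 1)
    msw = np.sum(within**2) / (g * (k - 1))
    denom = msb + (k - 1) * msw
    icc = 1.0 if denom == 0 else (msb - msw) / denom
    return ReplicateStats(tuple(float(v) for v in cv), float(icc))
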