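"""End-to-end analyses over a KineticDataset.

These functions are the computational core behind the analysis scripts, the
CLI and the acceptance checks: per-run rate tables, the hydroxide-inhibition
fit, the temperature study, reproducibility statistics and the assembled
report.
"""

from __future__ import annotations

from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .core import AnalysisReport, KineticDataset
from .exceptions import KineticsDomainError
from .mechanism import HydroxideFit, fit_hydroxide_inhibition, k_obs_from_pseudo
from .rates import (
    ReplicateStats,
    fit_pseudo_first_order,
    fit_second_order_mixed,
    replicate_agreement,
    second_order_from_pseudo,
)
from .stoichiometry import determine_stoichiometry, react_to_completion
from .synthetic import ReferenceParameters, reference_parameters, scenario, generate_design
from .thermo import ActivationParameters, arrhenius_fit, eyring_fit

__all__ = [
    "rate_table",
    "hydroxide_analysis",
    "activation_analysis",
    "reproducibility_analysis",
    "stoichiometry_analysis",
    "full_report",
]


def rate_table(dataset: KineticDataset) -> pd.DataFrame:
    """Per-run pseudo-first-order and second-order constants.

    Columns mirror how titration studies tabulate their runs: conditions,
    k' (s^-1) with SE and R^2, k'' = k'/[PCM]0, and the mixed
    second-order constant where the run permits it.
    """
    rows = []
    for run in dataset.runs:
        fit = fit_pseudo_first_order(run)
        cond = run.conditions
        row: dict[str, Any] = {
            "run_id": run.run_id,
            "replicate_id": run.replicate_id,
            **cond.to_dict(),
            "k_psi": fit.constant,
            "k_psi_se": fit.standard_error,
            "r_squared": fit.r_squared,
            "n_points": fit.n_points,
            "k2_from_pseudo": (
                second_order_from_pseudo(fit.constant, cond.pcm0) if cond.pcm0 > 0 else np.nan
            ),
        }
        try:
            row["k2_mixed"] = fit_second_order_mixed(run).constant
        except KineticsDomainError:
            row["k2_mixed"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def _mean_k_psi_per_run(dataset: KineticDataset) -> pd.DataFrame:
    table = rate_table(dataset)
    grouped = table.groupby("run_id", sort=True).agg(
        k_psi=("k_psi", "mean"),
        oh=("oh", "first"),
        temperature=("temperature", "first"),
        os_total=("os_total", "first"),
        pcm0=("pcm0", "first"),
        cat0=("cat0", "first"),
    )
    return grouped.reset_index()


def hydroxide_analysis(dataset: KineticDataset) -> dict[float, HydroxideFit]:
    """k_obs vs [OH-] double-reciprocal fit, one per temperature present."""
    table = _mean_k_psi_per_run(dataset)
    fits: dict[float, HydroxideFit] = {}
    for temperature, group in table.groupby("temperature", sort=True):
        if group["oh"].nunique() < 3:
            continue
        k_obs = [
            k_obs_from_pseudo(
                row.k_psi,
                dataset.runs[0].conditions.replace(
                    os_total=row.os_total, pcm0=row.pcm0, oh=row.oh, temperature=temperature
                ),
            )
            for row in group.itertuples()
        ]
        fits[float(temperature)] = fit_hydroxide_inhibition(
            group["oh"].to_numpy(), np.asarray(k_obs), temperature=float(temperature)
        )
    if not fits:
        raise KineticsDomainError("dataset has no temperature with >= 3 hydroxide levels")
    return fits


def activation_analysis(
    dataset: KineticDataset,
    reference_T: float | None = None,
    gibbs_T: float = 308.15,
) -> tuple[ActivationParameters, Any]:
    """Eyring + Arrhenius fits of the per-temperature k' values."""
    table = _mean_k_psi_per_run(dataset)
    temps = table["temperature"].to_numpy()
    ks = table["k_psi"].to_numpy()
    return (
        eyring_fit(temps, ks, reference_T=reference_T, gibbs_T=gibbs_T),
        arrhenius_fit(temps, ks),
    )


def reproducibility_analysis(dataset: KineticDataset) -> ReplicateStats:
    """Triplicate agreement: per-run CV of fitted k' and one-way ICC(1,1)."""
    groups = []
    for _run_id, runs in sorted(dataset.replicate_groups().items()):
        if len(runs) < 2:
            continue
        groups.append([fit_pseudo_first_order(run).constant for run in runs])
    if len(groups) < 2:
        raise KineticsDomainError("reproducibility analysis needs >= 2 replicated runs")
    return replicate_agreement(groups)


def stoichiometry_analysis(reference: ReferenceParameters | None = None):
    """Simulated excess-oxidant determination run to completion."""
    ref = reference or reference_parameters()
    cond = ref.reference_conditions().replace(cat0=5.0e-3, pcm0=2.0e-3)
    cat_final, _pcm_final, _t = react_to_completion(cond, ref.mechanism_table())
    return determine_stoichiometry(cond.cat0, cond.pcm0, cat_final)


def full_report(seed: int, noise_sd_frac: float = 0.0) -> AnalysisReport:
    """Run every standard design and assemble an AnalysisReport."""
    ref = reference_parameters()
    report = AnalysisReport(provenance={
        "seed": int(seed),
        "noise_sd_frac": float(noise_sd_frac),
        "package_version": __version__,
        "generator": "pcmkin.synthetic reference designs",
    })

    seeds = np.random.SeedSequence(seed).generate_state(8) % (2**31)

    cat = generate_design(scenario("cat_grid", int(seeds[0]), noise_sd_frac=noise_sd_frac))
    pcm = generate_design(scenario("pcm_grid", int(seeds[1]), noise_sd_frac=noise_sd_frac))
    table = pd.concat([rate_table(cat), rate_table(pcm)], ignore_index=True)
    report.rate_fits = table.to_dict(orient="records")
    anchor = table[np.isclose(table["pcm0"], ref.pcm_ref)]
    report.derived_constants = {
        "k_psi_reference_s^-1": float(anchor["k_psi"].mean()),
        "k2_from_pseudo_dm3_mol^-1_s^-1": float(anchor["k2_from_pseudo"].mean()),
        "conditions": ref.reference_conditions().to_dict(),
    }

    oh = generate_design(scenario("oh_grid", int(seeds[2]), noise_sd_frac=noise_sd_frac))
    hyd = hydroxide_analysis(oh)[308.15]
    report.mechanism = {
        "k_cat_dm6_mol^-2_s^-1": hyd.k_cat,
        "K1_dm3_mol^-1": hyd.K1,
        "intercept": hyd.intercept,
        "slope": hyd.slope,
        "temperature_K": hyd.temperature,
    }

    temp = generate_design(scenario("temp_grid", int(seeds[3]), noise_sd_frac=noise_sd_frac))
    act, arr = activation_analysis(temp, reference_T=313.15)
    report.activation = {
        "dH_kJ_mol^-1": act.dH, "dS_J_K^-1_mol^-1": act.dS,
        "Ea_kJ_mol^-1": act.Ea, "dG_kJ_mol^-1": act.dG, "lnA": act.lnA,
        "reference_T_K": act.reference_T, "gibbs_T_K": act.gibbs_T,
        "Ea_arrhenius_kJ_mol^-1": arr.Ea, "lnA_arrhenius": arr.lnA,
    }

    stoich = stoichiometry_analysis(ref)
    report.stoichiometry = {
        "ratio": stoich.ratio, "rounded": stoich.rounded,
        "residual_oxidant_mol_dm^-3": stoich.residual_oxidant,
        "accepted": stoich.accepted,
    }

    reps = generate_design(
        scenario("pcm_grid", int(seeds[4]),
                 noise_sd_frac=noise_sd_frac if noise_sd_frac > 0 else 0.01,
                 n_replicates=3)
    )
    stats = reproducibility_analysis(reps)
    report.reproducibility = {
        "cv_percent": list(stats.cv_percent),
        "icc": stats.icc,
    }
    return report
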