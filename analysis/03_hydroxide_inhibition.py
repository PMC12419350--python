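#!/usr/bin/env python
"""Hydroxide-inhibition analysis: double-reciprocal fits at 35/40/45 degC.

Finding (noise-free defaults): 1/k_obs is linear in [OH-] with positive
intercept at each temperature; the rate-determining constant k_cat
(intercept^-1) and hydroxide-binding constant K1 (slope/intercept) recover
the generator truths (0.65, 0.72) at 35 degC exactly.
"""

import argparse
from pathlib import Path

import pandas as pd

from pcmkin.synthetic import generate_design, scenario
from pcmkin.workflows import hydroxide_analysis


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--noise", type=float, default=0.0)
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    rows = []
    for offset, temperature in enumerate((308.15, 313.15, 318.15)):
        dataset = generate_design(
            scenario("oh_grid", args.seed + offset, noise_sd_frac=args.noise,
                     temperature=temperature))
        fit = hydroxide_analysis(dataset)[temperature]
        rows.append({
            "temperature_K": temperature,
            "k_cat": fit.k_cat, "k_cat_se": fit.k_cat_se,
            "K1": fit.K1, "K1_se": fit.K1_se,
            "intercept": fit.intercept, "slope": fit.slope,
            "r_squared": fit.r_squared,
            "k_cat_nonlinear": fit.k_cat_nonlinear, "K1_nonlinear": fit.K1_nonlinear,
        })
        print(f"T = {temperature:.2f} K: k_cat = {fit.k_cat:.4g}, K1 = {fit.K1:.4g} "
              f"(R^2 = {fit.r_squared:.6f})")
    table = pd.DataFrame(rows)
    out = args.outdir / "hydroxide_fits.csv"
    table.to_csv(out, index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
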