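#!/usr/bin/env python
"""Generate every reference experimental design as CSV + manifest.

Emulated campaigns: the oxidant/substrate concentration grids, the catalyst
grid, the hydroxide-variation series at 35/40/45 degC, the 30-50 degC
temperature series, and the excess-oxidant stoichiometry mixture. Noise-free
by default; pass --noise 0.025 for the calibrated titre-noise model.
"""

import argparse
from pathlib import Path

from pcmkin.core import write_runs
from pcmkin.synthetic import generate_design, scenario


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--noise", type=float, default=0.0)
    parser.add_argument("--outdir", type=Path, default=Path("results/data"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    designs = ["cat_grid", "pcm_grid", "os_grid", "temp_grid", "stoichiometry"]
    seed = args.seed
    for design in designs:
        dataset = generate_design(scenario(design, seed, noise_sd_frac=args.noise))
        write_runs(dataset, args.outdir / f"{design}.csv",
                   args.outdir / f"{design}.manifest.yaml")
        print(f"{design}: {len(dataset)} runs")
        seed += 1
    for temperature in (308.15, 313.15, 318.15):
        dataset = generate_design(
            scenario("oh_grid", seed, noise_sd_frac=args.noise, temperature=temperature))
        tag = f"oh_grid_{temperature - 273.15:.0f}C"
        write_runs(dataset, args.outdir / f"{tag}.csv", args.outdir / f"{tag}.manifest.yaml")
        print(f"{tag}: {len(dataset)} runs")
        seed += 1


if __name__ == "__main__":
    main()
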