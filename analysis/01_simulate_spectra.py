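#!/usr/bin/env python
"""Simulate the measurement campaign: six-level calibration design plus
sintered test discs, for both NIR and Raman, and write them as CSV spectra
with JSON metadata sidecars under results/spectra/.

Run:  python analysis/01_simulate_spectra.py [--seed 1]
"""

import argparse
from pathlib import Path

import numpy as np

import amorphquant as aq

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results/spectra"))
args = parser.parse_args()

args.out.mkdir(parents=True, exist_ok=True)

for modality in (aq.Modality.NIR, aq.Modality.RAMAN):
    cfg = aq.SimulationConfig(modality=modality, seed=args.seed)
    rng = np.random.default_rng(args.seed)
    cal, val, comps = aq.generate_calibration_design(cfg, rng=rng)
    discs = aq.generate_disc_set(cfg, rng=np.random.default_rng(args.seed + 500_000))
    tag = modality.value
    for name, sset in (("calibration", cal), ("validation", val), ("discs", discs)):
        csv_path = aq.write_spectra_csv(sset, args.out / f"{tag}_{name}.csv")
        aq.write_metadata_json(
            args.out / f"{tag}_{name}_meta.json",
            {sid: sset.compositions[sid] for sid in sset.sample_ids},
            {s.sample_id: s.presentation for s in sset})
        print(f"{tag:>5} {name:<11} {len(sset):>2} spectra "
              f"({sset.axis.size} points) -> {csv_path}")

print(f"\nDesign: 6 levels x 3 preparations, 14 calibration + 4 validation "
      f"samples; discs at conversions "
      f"{ {g.value: c for g, c in aq.DEFAULT_DISC_CONVERSIONS.items()} } "
      f"of the 20% w/w drug load. Seed {args.seed}.")
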