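#!/usr/bin/env python
"""Spatial spread of photoinhibition: relative spike rate vs lateral
distance and the half-max radius.

Simulates pyramidal units at 0-2.5 mm from the photostimulus with 90%
spike-rate reduction at the center (lateral sigma 0.68 mm), classifies
them by waveform, bins the population relative rate by distance, and
locates the half-max radius with a 2000-resample unit bootstrap.
Writes results/spatial_profile.csv and results/spatial_summary.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from optospread import studies


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=4)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    res = studies.spatial_spread_study(seed=args.seed)
    prof = res["profile"]
    df = pd.DataFrame({"distance_mm": prof.bin_centers_mm,
                       "relative_rate": prof.relative_rate,
                       "sem": prof.sem, "n_units": prof.n_units})
    df.to_csv(args.outdir / "spatial_profile.csv", index=False)
    boot = res["bootstrap"]
    summary = pd.DataFrame([{
        "half_max_radius_mm": res["half_max_radius_mm"],
        "ci90_lo_mm": boot.ci_lo, "ci90_hi_mm": boot.ci_hi,
        "sem_mm": boot.sem, "n_resamples": boot.n_resamples,
        "n_units": res["dataset"].n_units,
    }])
    summary.to_csv(args.outdir / "spatial_summary.csv", index=False)
    print(df.round(3).to_string(index=False))
    print(f"\nHalf-max radius of photoinhibition: "
          f"{res['half_max_radius_mm']:.3f} mm "
          f"(90% CI [{boot.ci_lo:.3f}, {boot.ci_hi:.3f}]); the GtACR1-style "
          f"benchmark at 90% center reduction is ~0.8 mm.")


if __name__ == "__main__":
    main()
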