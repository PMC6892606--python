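#!/usr/bin/env python
"""Recover the spatial profile of blue and orange light in tissue from
synthetic photobleaching volumes.

Simulates nuclear-fluorescence volumes bleached under separable light
fields (blue: 433 µm axial e-folding, 114.7 µm lateral sigma; orange:
1221 µm and 400 µm), runs the dF/F0 -> exponential-inversion chain, and
summarizes the half-max depth and lateral half-width of each recovered
field.  Writes results/light_profile.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from optospread import studies


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    rows = []
    blue = studies.light_profile_study(seed=args.seed)
    rows.append({"wavelength": "blue_473nm", "true_axial_um": 433.0,
                 "true_lateral_half_um": 135.0, **{
                     k: blue[k] for k in ("half_max_depth_um",
                                          "lateral_half_width_um", "n_rois")}})
    orange = studies.light_profile_study(
        axial_um=1221.0, lateral_sigma_um=400.0,
        volume_dims=(2500.0, 2500.0, 2500.0), distance_mode="lateral",
        seed=args.seed + 1)
    rows.append({"wavelength": "orange_594nm", "true_axial_um": 1221.0,
                 "true_lateral_half_um": 471.0, **{
                     k: orange[k] for k in ("half_max_depth_um",
                                            "lateral_half_width_um", "n_rois")}})
    df = pd.DataFrame(rows)
    df.to_csv(args.outdir / "light_profile.csv", index=False)
    print(df.round(1).to_string(index=False))
    print(f"\nBlue light is confined: half-max depth "
          f"{blue['half_max_depth_um']:.0f} µm (paper-style benchmark ~300 µm), "
          f"lateral 50% at {blue['lateral_half_width_um']:.0f} µm (~135 µm).")
    print(f"Orange light penetrates ~{orange['half_max_depth_um'] / blue['half_max_depth_um']:.1f}x "
          f"deeper (half-max depth {orange['half_max_depth_um']:.0f} µm, ~846 µm).")


if __name__ == "__main__":
    main()
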