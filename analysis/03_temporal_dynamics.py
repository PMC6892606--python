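#!/usr/bin/env python
"""Temporal profile of photoinhibition: onset latency, earliest detectable
change, and rebound after stimulus offset.

Simulates suppressed pyramidal populations, estimates (i) the onset
latency by the 90%-of-average-reduction rule on the 1 ms population PSTH,
(ii) the earliest significant change via 10-ms-bin t-tests against
baseline, and (iii) the rebound index over the 500 ms after offset for a
range of generated rebound amplitudes.  Writes results/temporal.csv and
results/rebound.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from optospread import inactmetrics, studies, synthgen
from optospread.core import PhotostimProtocol


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=3)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    onset = studies.onset_latency_study(seed=args.seed)

    # earliest detectable change on the same kind of population
    cfg = synthgen.SuppressionConfig(
        center_reduction=0.9, onset_tau_ms=8.0, n_units_per_distance=100,
        n_fs_per_distance=0, distances_mm=(0.0,), n_trials=100,
        stim_duration_s=1.3, baseline_cv=0.0, seed=args.seed + 1)
    ds = synthgen.simulate_suppression_dataset(
        cfg, PhotostimProtocol(duration_s=1.3, ramp_ms=0.0))
    earliest = inactmetrics.earliest_significant_change(ds, label=None)

    pd.DataFrame([{
        "onset_latency_ms": onset["onset_latency_ms"],
        "earliest_change_ms": earliest,
        "n_units": onset["n_units"], "n_trials": onset["n_trials"],
    }]).to_csv(args.outdir / "temporal.csv", index=False)
    print(f"Photoinhibition onset (90% of average reduction): "
          f"{onset['onset_latency_ms']:.1f} ms (benchmark ~18.4 ms for an "
          f"8 ms decay constant).")
    print(f"Earliest significant change (10 ms bins, t-test): "
          f"{earliest} ms bin start.")

    # rebound scales with the generated amplitude
    rows = []
    for amp in (0.0, 0.1, 0.3, 0.5):
        cfg = synthgen.SuppressionConfig(
            center_reduction=0.9, rebound_amplitude=amp,
            rebound_tau_ms=2000.0, n_units_per_distance=50,
            n_fs_per_distance=0, distances_mm=(0.0,), n_trials=40,
            stim_duration_s=1.0, baseline_cv=0.0, seed=args.seed + 10)
        ds = synthgen.simulate_suppression_dataset(
            cfg, PhotostimProtocol(duration_s=1.0, ramp_ms=0.0))
        reb = inactmetrics.rebound_index(ds, label=None)
        rows.append({"generated_amplitude": amp, "rebound_index": reb})
    df = pd.DataFrame(rows)
    df.to_csv(args.outdir / "rebound.csv", index=False)
    print("\nRebound index vs generated amplitude:")
    print(df.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
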