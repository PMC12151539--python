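"""Microglial engulfment: per-cell volume recovery and ratio cohorts.

Renders 3D stacks of blobby glial cells with engulfed tracer puncta in
two eye-specific channels, segments them (smoothing + threshold, 26-
connectivity labeling, 10-voxel minimum object size), and quantifies the
engulfed volume per cell and the right/left engulfment ratio.  Findings:
per-cell engulfed volumes match the analytic sphere-volume truth within
5% without noise and 10% at SNR 5, ratios invert exactly under channel
swap, and cohorts generated at true mean ratio 2.0 vs 1.0 (30 cells per
group) separate at Mann-Whitney p < 0.01 in essentially every replicate.

Writes results/engulfment_recovery.csv and results/engulfment_cohorts.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from synquant import benchmarks

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--replicates", type=int, default=20,
                    help="cohort-separation replicates")
    args = ap.parse_args()
    RESULTS.mkdir(exist_ok=True)

    rec = benchmarks.engulfment_recovery(seed=args.seed)
    rows = [
        {"condition": cond, **{k: v for k, v in r.items()}}
        for cond, r in rec.items()
    ]
    pd.DataFrame(rows).to_csv(RESULTS / "engulfment_recovery.csv", index=False)
    for cond, r in rec.items():
        print(f"{cond}: per-cell engulfed-volume error "
              f"max {100 * r['max_rel_error']:.1f}% "
              f"(mean {100 * r['mean_rel_error']:.1f}%) over "
              f"{r['n_cells_measured']} cells; "
              f"ratio-reciprocity deviation {r['reciprocal_max_dev']:.1e}")

    coh = benchmarks.engulfment_cohort_separation(
        seed=args.seed, n_replicates=args.replicates
    )
    pd.DataFrame([coh]).to_csv(RESULTS / "engulfment_cohorts.csv", index=False)
    print(f"Cohorts (true ratio 2.0 vs 1.0, {coh['n_cells_per_group']} cells "
          f"per group): Mann-Whitney p < 0.01 in "
          f"{100 * coh['separation_fraction']:.0f}% of "
          f"{coh['n_replicates']} replicates")


if __name__ == "__main__":
    main()
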