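#!/usr/bin/env python
"""Two-epoch recovery experiment: does the pipeline see an early burst?

Simulates replicate datasets whose clock runs 5x faster before 28 Ma,
then checks (i) that binned lineage-averaged rates are >2x higher in the
fast epoch and (ii) that the disparity peak predates the diversity peak.
Writes results/recovery.tsv.
"""

import argparse
import os

import numpy as np
import pandas as pd

from disparitree.experiments import two_epoch_recovery

RESULTS = os.path.join(os.path.dirname(os.path.dirname(os.path.abspath(__file__))), "results")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--replicates", type=int, default=20)
    args = parser.parse_args()

    reps = two_epoch_recovery(args.seed, args.replicates, n_boot=100)
    df = pd.DataFrame(
        {
            "seed": [r.seed for r in reps],
            "n_tips": [r.n_tips for r in reps],
            "rate_ratio_early_late": [r.rate_ratio_early_late for r in reps],
            "disparity_peak_age": [r.disparity_peak_age for r in reps],
            "diversity_peak_age": [r.diversity_peak_age for r in reps],
            "disparity_precedes": [r.disparity_precedes_diversity for r in reps],
        }
    )
    os.makedirs(RESULTS, exist_ok=True)
    out = os.path.join(RESULTS, "recovery.tsv")
    df.to_csv(out, sep="\t", index=False)
    n = len(df)
    print(
        f"rate ratio > 2 in {(df.rate_ratio_early_late > 2).sum()}/{n} replicates "
        f"(median {df.rate_ratio_early_late.median():.2f})"
    )
    print(f"disparity peak precedes diversity peak in {df.disparity_precedes.sum()}/{n}")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
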