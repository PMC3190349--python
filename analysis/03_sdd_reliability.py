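#!/usr/bin/env python
"""Derive the smallest detectable difference from the simulated
test–retest set and show how it responds to measurement error.

Reads results/retest.csv (from 01_simulate_inputs.py), derives the SDD
by both the order-statistic median CI and the 1000-resample bootstrap,
then sweeps the injected reading error over three levels to confirm the
threshold tracks measurement noise. Writes results/sdd_estimates.csv.
"""

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from oamq import io as oio
from oamq import synthetic as syn
from oamq.bml import bootstrap_sdd, change_differences, derive_sdd

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def _pairs(df: pd.DataFrame):
    return [
        ((r.baseline_1, r.followup_1), (r.baseline_2, r.followup_2))
        for r in df.itertuples()
    ]


def main() -> None:
    retest = pd.read_csv(RESULTS / "retest.csv", comment="#")
    pairs = _pairs(retest)
    order = derive_sdd(pairs)
    boot = bootstrap_sdd(change_differences(pairs), n_resamples=1000, seed=SEED)
    df = pd.DataFrame([dataclasses.asdict(order), dataclasses.asdict(boot)])
    oio.write_table(df, RESULTS / "sdd_estimates.csv")
    for est in (order, boot):
        print(
            f"{est.method}: median {est.median_diff_cm3:+.2f} cm^3, "
            f"95% CI ({est.ci_lo_cm3:+.2f}, {est.ci_hi_cm3:+.2f}), "
            f"SDD threshold {est.threshold_cm3:.2f} cm^3"
        )

    print("\nthreshold vs injected reading error (200 replicates each):")
    for i, sd in enumerate((1.0, 3.0, 6.0)):
        thresholds = [
            derive_sdd(_pairs(syn.make_test_retest(
                n_lesions=16, true_change_mean=0.0, true_change_sd=0.0,
                error_sd=sd, seed=SEED + 10_000 * (i + 1) + rep,
            ))).threshold_cm3
            for rep in range(200)
        ]
        print(f"  error_sd {sd:.0f} cm^3 -> mean SDD {np.mean(thresholds):.2f} cm^3")


if __name__ == "__main__":
    main()
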