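#!/usr/bin/env python
"""Behavioral analysis and brain-behavior contrast correlations.

Summarizes the cohort's behavioral records (accuracy and step-wise RTs per
condition), runs the behavioral test battery (paired accuracy t-test,
reward-by-step RT ANOVA with per-step Tukey comparisons, one-sample BIS
test), then correlates each subject's BIS contrast with their behavioral
and neural reward contrasts (ROI distance and beta contrasts from stage
05).  Writes the summary, test results and correlation table under
results/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from rctrsa import behavior, roi


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    records = pd.read_csv(args.out / "cohort_behavior.csv")
    summaries = behavior.summarize(records)
    summaries.to_csv(args.out / "behavior_summary.csv", index=False)
    print("group means per condition:")
    print(summaries.groupby("condition")[["accuracy", "mean_rt"]]
          .mean().round(3).to_string())

    tests = behavior.behavior_tests(records)
    print(
        f"\naccuracy paired t: t={tests['accuracy_ttest']['t']:.2f}, "
        f"p={tests['accuracy_ttest']['p']:.4f}"
    )
    print("RT reward-by-step ANOVA:")
    print(tests["rt_anova"].round(4).to_string())
    print("per-step Tukey reward contrasts (rewarded - non-rewarded):")
    print(tests["rt_tukey"].to_string(index=False))
    print(
        f"BIS contrast: mean={tests['bis_ttest']['mean']:.3f}, "
        f"t={tests['bis_ttest']['t']:.2f}, p={tests['bis_ttest']['p']:.4f}"
    )
    tests["rt_tukey"].to_csv(args.out / "behavior_rt_tukey.csv", index=False)
    with open(args.out / "behavior_tests.json", "w") as fh:
        json.dump(
            {k: tests[k] for k in ("accuracy_ttest", "bis_ttest")}, fh, indent=2
        )

    bis_table = behavior.bis(summaries)
    wide_acc = summaries.pivot(index="subject", columns="condition",
                               values="accuracy")
    wide_rt = summaries.pivot(index="subject", columns="condition",
                              values="mean_rt")
    contrasts = bis_table[["subject", "bis_contrast"]].copy()
    contrasts["accuracy_contrast"] = (
        wide_acc["rewarded"] - wide_acc["non-rewarded"]
    ).to_numpy()
    contrasts["rt_contrast"] = (
        wide_rt["rewarded"] - wide_rt["non-rewarded"]
    ).to_numpy()
    neural = pd.read_csv(args.out / "roi_neural_contrasts.csv")
    contrasts = contrasts.merge(neural, on="subject")
    contrasts.to_csv(args.out / "contrast_table.csv", index=False)

    correlations = roi.contrast_correlations(contrasts)
    correlations.to_csv(args.out / "contrast_correlations.csv", index=False)
    print("\nPearson correlations with the BIS contrast:")
    print(correlations.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
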