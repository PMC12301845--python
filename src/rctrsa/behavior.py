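"""Behavioral summaries and the Balanced Integration Score (BIS).

Accuracy is the fraction of correct trials per condition (all trials
count); mean RT is computed over the decision steps 2-6 of correct trials
only.  The BIS combines the two on a common scale: accuracy and RT are
z-scored across all subject-by-condition cells jointly (sample-sd
convention), and BIS = z(accuracy) - z(RT), so positive values mean fast
and accurate.  The BIS contrast (rewarded minus non-rewarded) is the
per-subject summary of the behavioral reward benefit.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

RT_STEPS = tuple(range(2, 7))


def summarize(records: pd.DataFrame) -> pd.DataFrame:
    """Per-subject, per-condition mean accuracy and mean RT (steps 2-6).

    ``records`` is trial-level with columns ``subject, condition, correct,
    rt_step2..rt_step6``.  RT means use correct trials only; accuracy uses
    all trials.  Conditions with no correct trial get a missing RT with a
    warning.
    """
    rt_cols = [f"rt_step{s}" for s in RT_STEPS]
    rows = []
    for (subject, condition), cell in records.groupby(
        ["subject", "condition"], sort=True
    ):
        accuracy = cell["correct"].mean()
        correct = cell[cell["correct"]]
        if len(correct) == 0:
            warnings.warn(f"no correct trials for {subject}/{condition}")
            mean_rt = np.nan
        else:
            mean_rt = correct[rt_cols].to_numpy().mean()
        rows.append(
            {
                "subject": subject,
                "condition": condition,
                "accuracy": accuracy,
                "mean_rt": mean_rt,
            }
        )
    return pd.DataFrame(rows)


def bis(summaries: pd.DataFrame) -> pd.DataFrame:
    """Balanced Integration Scores per subject and condition.

    Standardization pools all subject-by-condition cells (so condition
    differences survive); returns one row per subject with ``bis_rewarded``,
    ``bis_nonrewarded`` and ``bis_contrast`` (rewarded minus non-rewarded).
    """
    if summaries["subject"].nunique() < 2:
        raise ValueError("BIS standardization needs at least 2 subjects")
    acc = summaries["accuracy"].to_numpy(dtype=float)
    rt = summaries["mean_rt"].to_numpy(dtype=float)
    for name, v in (("accuracy", acc), ("mean RT", rt)):
        if np.std(v, ddof=1) == 0:
            raise ValueError(f"zero variance in {name}; BIS undefined")
    z = summaries.copy()
    z["bis"] = (acc - acc.mean()) / acc.std(ddof=1) - (rt - rt.mean()) / rt.std(
        ddof=1
    )
    wide = z.pivot(index="subject", columns="condition", values="bis")
    out = pd.DataFrame(
        {
            "subject": wide.index,
            "bis_rewarded": wide["rewarded"].to_numpy(),
            "bis_nonrewarded": wide["non-rewarded"].to_numpy(),
        }
    ).reset_index(drop=True)
    out["bis_contrast"] = out["bis_rewarded"] - out["bis_nonrewarded"]
    return out


def behavior_tests(records: pd.DataFrame) -> dict:
    """The behavioral test battery.

    - paired t-test on accuracy between conditions (across subjects);
    - two-way ANOVA on trial-level RTs with reward condition and step
      (correct trials, steps 2-6) and their interaction;
    - Tukey HSD over the condition-by-step cell means, reporting the
      within-step rewarded vs non-rewarded comparisons;
    - one-sample t-test of the BIS contrast against zero.

    Returns a dict with ``accuracy_ttest``, ``rt_anova``, ``rt_tukey`` and
    ``bis_ttest``.
    """
    if records["subject"].nunique() < 3:
        raise ValueError("need at least 3 subjects")
    summaries = summarize(records)
    wide_acc = summaries.pivot(index="subject", columns="condition",
                               values="accuracy")
    t_acc, p_acc = stats.ttest_rel(wide_acc["rewarded"], wide_acc["non-rewarded"])

    rt_cols = [f"rt_step{s}" for s in RT_STEPS]
    correct = records[records["correct"]]
    long = correct.melt(
        id_vars=["subject", "condition"],
        value_vars=rt_cols,
        var_name="step",
        value_name="rt",
    )
    long["step"] = long["step"].str.removeprefix("rt_step").astype(int)
    if long["rt"].std() == 0:
        raise ValueError("constant RTs; ANOVA undefined")
    model = ols("rt ~ C(condition) * C(step)", data=long).fit()
    anova = anova_lm(model, typ=2)

    tukey = pairwise_tukeyhsd(
        long["rt"].to_numpy(),
        (long["condition"] + "|" + long["step"].astype(str)).to_numpy(),
    )
    tuk = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )
    g1 = tuk["group1"].str.split("|", expand=True)
    g2 = tuk["group2"].str.split("|", expand=True)
    within = (g1[1] == g2[1]) & (g1[0] != g2[0])
    rt_tukey = tuk[within].copy()
    rt_tukey["step"] = g1[1][within].astype(int)
    # orient the difference as rewarded minus non-rewarded
    flip = g1[0][within] == "non-rewarded"
    rt_tukey["meandiff"] = np.where(flip, rt_tukey["meandiff"], -rt_tukey["meandiff"])
    rt_tukey = rt_tukey[["step", "meandiff", "p-adj", "reject"]].sort_values(
        "step", ignore_index=True
    )

    bis_table = bis(summaries)
    t_bis, p_bis = stats.ttest_1samp(bis_table["bis_contrast"], 0.0)

    return {
        "accuracy_ttest": {"t": float(t_acc), "p": float(p_acc),
                           "n": int(len(wide_acc))},
        "rt_anova": anova,
        "rt_tukey": rt_tukey,
        "bis_ttest": {"t": float(t_bis), "p": float(p_bis),
                      "mean": float(bis_table["bis_contrast"].mean()),
                      "n": int(len(bis_table))},
    }
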