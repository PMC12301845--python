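"""ROI-level representational analysis and brain-behavior correlations.

From each subject's run-wise state patterns in a region of interest: the
24x24 cross-validated Euclidean RDM; the two within-condition 6x6 distance
subsets (sequence A step i vs sequence B step j for the two rewarded and
the two non-rewarded sequences -- 72 distances per subject); a mixed-model
ANOVA on those distances with reward condition, step pair and task as fixed
effects and subject as a random intercept; post-hoc per-cell reward
contrasts; and Pearson correlations between behavioral and neural
reward contrasts across subjects.

The step-progression factor is the 36 step-pair cells (i, j), i, j in 1..6,
not the 6 steps: with two conditions this yields exactly 72 distances per
subject and a 35-df step term.  The condition-by-task interaction is not
estimable within subject (a subject's rewarded block is always their
rewarded drink; across subjects it is absorbed by the subject intercepts),
so the fixed-effects structure omits it; with reward assignment
counterbalanced across subjects all remaining terms are identified.  F
statistics use the within-subject residual, so the balanced case reproduces
a repeated-measures ANOVA.
"""

from __future__ import annotations

import warnings
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from rctrsa.rdm import RDM, cv_euclidean_rdm
from rctrsa.task import TaskSpec

ANOVA_TERMS = (
    "condition",
    "step_pair",
    "task",
    "condition:step_pair",
    "step_pair:task",
    "condition:step_pair:task",
)


def roi_rdm(betas: np.ndarray, roi_mask: np.ndarray) -> RDM:
    """Cross-validated Euclidean RDM over the ROI voxels.

    ``betas`` is (runs, 24, X, Y, Z) (or (runs, 24, V) with a flat mask).
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise ValueError("ROI mask is empty")
    folds = betas[:, :, roi_mask]
    return cv_euclidean_rdm(folds)


def extract_condition_subsets(
    rdm: RDM, spec: TaskSpec, subject: str = "sub-01"
) -> pd.DataFrame:
    """The 72 within-condition between-sequence step-pair distances.

    For each condition the 6x6 block of distances between the condition's
    two sequences (first sequence step i vs second sequence step j, all 36
    cells) is extracted from the canonically ordered 24x24 RDM.  The task
    factor codes the drink shared by the block's sequences.
    """
    if rdm.n != 24:
        raise ValueError("expected a 24x24 RDM in canonical ordering")
    expected = [f"{s.sequence_id}_s{s.step}" for s in spec.states()]
    if rdm.labels != expected:
        raise ValueError("RDM labels do not match the canonical state ordering")
    rows = []
    blocks = {
        "rewarded": (0, 6, spec.sequences[0].drink),
        "non-rewarded": (12, 18, spec.sequences[2].drink),
    }
    for condition, (a, b, drink) in blocks.items():
        for i, j in product(range(1, 7), range(1, 7)):
            rows.append(
                {
                    "subject": subject,
                    "condition": condition,
                    "step_pair": f"{i}-{j}",
                    "step_i": i,
                    "step_j": j,
                    "task": drink,
                    "distance": rdm.matrix[a + i - 1, b + j - 1],
                }
            )
    return pd.DataFrame(rows)


def _check_balance(subsets: pd.DataFrame) -> None:
    cells = subsets.groupby(["subject", "condition", "step_pair"]).size()
    n_expected = subsets["subject"].nunique() * 72
    if (cells != 1).any() or len(cells) != n_expected or len(subsets) != n_expected:
        bad = cells[cells != 1]
        raise ValueError(
            f"unbalanced design: {len(subsets)} rows for "
            f"{subsets['subject'].nunique()} subjects (expected {n_expected}); "
            f"offending cells:\n{bad}"
        )


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[float, int]:
    """Residual sum of squares and rank of an OLS fit."""
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid), int(rank)


def _sum_coded(values: pd.Series) -> tuple[np.ndarray, list]:
    """Sum-to-zero (deviation) coding: k levels -> k-1 columns."""
    levels = sorted(values.unique())
    k = len(levels)
    cols = np.zeros((len(values), k - 1))
    index = {lv: i for i, lv in enumerate(levels)}
    codes = values.map(index).to_numpy()
    for j in range(k - 1):
        cols[codes == j, j] = 1.0
        cols[codes == k - 1, j] = -1.0
    return cols, levels


def _anova_design(subsets: pd.DataFrame) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Sum-coded design blocks per term, plus the subject-intercept block.

    Explicit construction (rather than a formula engine) keeps the
    non-hierarchical term set -- the three-way interaction is present while
    condition-by-task is excluded as subject-confounded -- from being
    silently re-expanded.
    """
    subj = pd.get_dummies(subsets["subject"]).to_numpy(dtype=float)
    c, _ = _sum_coded(subsets["condition"])
    s, _ = _sum_coded(subsets["step_pair"])
    t, _ = _sum_coded(subsets["task"])
    blocks = {
        "condition": c,
        "step_pair": s,
        "task": t,
        "condition:step_pair": c * s,
        "step_pair:task": s * t,
        "condition:step_pair:task": c * s * t,
    }
    return blocks, subj


def distance_anova(subsets: pd.DataFrame) -> pd.DataFrame:
    """Mixed-model ANOVA on the within-condition distances.

    Fixed effects: condition (1 df), step pair (35 df), task (1 df),
    condition-by-step (35), step-by-task (35) and the three-way interaction
    (35); subjects enter as a random intercept, absorbed here as fixed
    dummies so that every F uses the within-subject residual (the balanced
    special case of the mixed model).  Each term is tested by a partial F:
    its sum-coded columns are dropped from the full model.
    """
    if subsets["subject"].nunique() < 5:
        raise ValueError("need at least 5 subjects")
    _check_balance(subsets)
    y = subsets["distance"].to_numpy(dtype=float)
    blocks, subj = _anova_design(subsets)
    X_full = np.column_stack([subj, *blocks.values()])
    rss_full, rank_full = _ols(y, X_full)
    df_resid = len(y) - rank_full
    mse = rss_full / df_resid

    rows = []
    for name in ANOVA_TERMS:
        X_red = np.column_stack(
            [subj, *(b for k, b in blocks.items() if k != name)]
        )
        rss_red, rank_red = _ols(y, X_red)
        df_term = rank_full - rank_red
        if df_term == 0:
            warnings.warn(f"term {name} not estimable in this design")
            continue
        F = ((rss_red - rss_full) / df_term) / mse
        p = stats.f.sf(F, df_term, df_resid)
        rows.append({"term": name, "df": df_term, "F": F, "p": p})
    rows.append(
        {"term": "residual", "df": df_resid, "F": np.nan, "p": np.nan}
    )
    return pd.DataFrame(rows)


def posthoc_pairwise(subsets: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Reward contrasts of the estimated marginal means per step-pair cell.

    For each of the 36 step-pair cells: the rewarded minus non-rewarded
    difference of cell means (averaged over subjects and task), its t
    statistic against the full-model within-subject residual, the raw
    two-sided p, and a Sidak family adjustment over the 36 contrasts (the
    single-contrast-per-cell family to which the Tukey adjustment of a
    marginal-means engine degenerates).
    """
    _check_balance(subsets)
    y = subsets["distance"].to_numpy(dtype=float)
    blocks, subj = _anova_design(subsets)
    X_full = np.column_stack([subj, *blocks.values()])
    rss_full, rank_full = _ols(y, X_full)
    df_resid = len(y) - rank_full
    mse = rss_full / df_resid

    rows = []
    for sp, cell in subsets.groupby("step_pair"):
        rw = cell.loc[cell["condition"] == "rewarded", "distance"]
        nr = cell.loc[cell["condition"] == "non-rewarded", "distance"]
        est = rw.mean() - nr.mean()
        se = np.sqrt(mse * (1.0 / len(rw) + 1.0 / len(nr)))
        t = est / se
        p = 2.0 * stats.t.sf(abs(t), df_resid)
        rows.append({"step_pair": sp, "estimate": est, "se": se, "t": t, "p": p})
    out = pd.DataFrame(rows)
    k = len(out)
    out["p_adj"] = 1.0 - (1.0 - out["p"]) ** k
    out["significant"] = out["p_adj"] <= alpha
    i_j = out["step_pair"].str.split("-", expand=True).astype(int)
    out.insert(1, "step_i", i_j[0])
    out.insert(2, "step_j", i_j[1])
    return out.sort_values(["step_i", "step_j"], ignore_index=True)


def condition_contrasts(
    rdm: RDM, spec: TaskSpec, betas: np.ndarray | None = None,
    roi_mask: np.ndarray | None = None,
) -> dict[str, float]:
    """Per-subject neural reward contrasts from a canonical 24x24 ROI RDM.

    ``distance_contrast``: mean within-condition between-sequence distance,
    rewarded minus non-rewarded, over all 36 step-pair cells;
    ``distance_contrast_step1``: the same over the 11 cells involving step 1.
    With ``betas`` and ``roi_mask`` the mean-activation (beta) contrasts are
    added: mean ROI beta over rewarded minus non-rewarded states, for all
    steps and for step 1 only.
    """
    subsets = extract_condition_subsets(rdm, spec)
    out = {}
    rw = subsets[subsets["condition"] == "rewarded"]
    nr = subsets[subsets["condition"] == "non-rewarded"]
    out["distance_contrast"] = rw["distance"].mean() - nr["distance"].mean()
    s1 = (subsets["step_i"] == 1) | (subsets["step_j"] == 1)
    out["distance_contrast_step1"] = (
        rw[s1[rw.index]]["distance"].mean() - nr[s1[nr.index]]["distance"].mean()
    )
    if betas is not None and roi_mask is not None:
        roi_betas = betas[:, :, np.asarray(roi_mask, dtype=bool)].mean(axis=(0, 2))
        rewarded_states = np.arange(24) < 12
        step1 = np.arange(24) % 6 == 0
        out["beta_contrast"] = float(
            roi_betas[rewarded_states].mean() - roi_betas[~rewarded_states].mean()
        )
        out["beta_contrast_step1"] = float(
            roi_betas[rewarded_states & step1].mean()
            - roi_betas[~rewarded_states & step1].mean()
        )
    return out


def contrast_correlations(contrasts: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations of the BIS contrast with the other contrasts.

    For each column other than ``bis_contrast`` (e.g. ``rt_contrast``,
    ``accuracy_contrast``, ``distance_contrast``, ``beta_contrast`` and
    their step-1 variants): Pearson r, the t statistic
    ``r * sqrt((n - 2) / (1 - r^2))`` and its two-sided p.  Zero-variance
    columns yield NaN with a warning.
    """
    if "bis_contrast" not in contrasts.columns:
        raise ValueError("contrast table must include a bis_contrast column")
    n = len(contrasts)
    if n < 3:
        raise ValueError("need at least 3 subjects")
    x = contrasts["bis_contrast"].to_numpy(dtype=float)
    rows = []
    others = [c for c in contrasts.columns if c not in ("subject", "bis_contrast")]
    for col in others:
        yv = contrasts[col].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(yv) == 0:
            warnings.warn(f"zero variance in correlation pair bis_contrast~{col}")
            rows.append({"pair": f"bis_contrast~{col}", "r": np.nan, "t": np.nan,
                         "p": np.nan, "n": n})
            continue
        r = float(np.corrcoef(x, yv)[0, 1])
        if abs(r) == 1.0:
            t, p = np.inf * np.sign(r), 0.0
        else:
            t = r * np.sqrt((n - 2) / (1.0 - r**2))
            p = 2.0 * stats.t.sf(abs(t), n - 2)
        rows.append({"pair": f"bis_contrast~{col}", "r": r, "t": t, "p": p, "n": n})
    return pd.DataFrame(rows)
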