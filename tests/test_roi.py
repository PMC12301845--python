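"""ROI RDMs, distance subsets, the mixed-model ANOVA, post-hoc contrasts and
brain-behavior correlations."""

import numpy as np
import pandas as pd
import pytest

from rctrsa import behavior, rdm, roi, task
from rctrsa.roi import (
    condition_contrasts,
    contrast_correlations,
    distance_anova,
    extract_condition_subsets,
    posthoc_pairwise,
    roi_rdm,
)
from conftest import iid_distance_subsets


def constant_rdm(spec, value=2.0):
    mat = np.full((24, 24), value)
    np.fill_diagonal(mat, 0.0)
    return rdm.RDM(mat, spec.state_labels())


class TestRoiRDM:
    def test_shape_and_symmetry(self, noise_free_subject):
        dataset, betas, _ = noise_free_subject
        r = roi_rdm(betas, dataset.truth["plant"].roi_mask)
        assert r.matrix.shape == (24, 24)
        assert np.allclose(r.matrix, r.matrix.T)

    def test_noise_free_matches_target(self, noise_free_subject):
        dataset, betas, target = noise_free_subject
        r = roi_rdm(betas, dataset.truth["plant"].roi_mask)
        assert rdm.spearman(r.vector(), target.vector()) > 0.99

    def test_disjoint_rois_with_identical_patterns_agree(self):
        rng = np.random.default_rng(0)
        patterns = rng.standard_normal((24, 30))
        folds = np.stack([np.concatenate([patterns, patterns], axis=1)] * 4)
        betas = folds.reshape(4, 24, 60, 1, 1)
        mask_a = np.zeros((60, 1, 1), dtype=bool)
        mask_a[:30] = True
        mask_b = ~mask_a
        a = roi_rdm(betas, mask_a)
        b = roi_rdm(betas, mask_b)
        assert np.allclose(a.matrix, b.matrix, atol=1e-10)

    def test_empty_roi_rejected(self, noise_free_subject):
        _, betas, _ = noise_free_subject
        with pytest.raises(ValueError):
            roi_rdm(betas, np.zeros(betas.shape[2:], dtype=bool))


class TestSubsets:
    def test_72_rows_with_36_step_pair_levels(self, coffee_spec):
        rng = np.random.default_rng(1)
        mat = rng.standard_normal((24, 24))
        mat = (mat + mat.T) / 2
        np.fill_diagonal(mat, 0.0)
        subsets = extract_condition_subsets(
            rdm.RDM(mat, coffee_spec.state_labels()), coffee_spec
        )
        assert len(subsets) == 72
        assert subsets["step_pair"].nunique() == 36
        assert (subsets.groupby("condition").size() == 36).all()

    def test_constant_rdm_gives_constant_distances(self, coffee_spec):
        subsets = extract_condition_subsets(constant_rdm(coffee_spec), coffee_spec)
        assert np.allclose(subsets["distance"], 2.0)

    def test_values_are_a_submultiset_of_the_rdm(self, tea_spec):
        rng = np.random.default_rng(2)
        mat = rng.standard_normal((24, 24))
        mat = (mat + mat.T) / 2
        np.fill_diagonal(mat, 0.0)
        r = rdm.RDM(mat, tea_spec.state_labels())
        subsets = extract_condition_subsets(r, tea_spec)
        entries = set(np.round(mat.ravel(), 12))
        assert all(np.round(d, 12) in entries for d in subsets["distance"])

    def test_task_factor_codes_the_block_drink(self, coffee_spec, tea_spec):
        for spec in (coffee_spec, tea_spec):
            subsets = extract_condition_subsets(constant_rdm(spec), spec)
            rewarded_drinks = subsets.loc[
                subsets["condition"] == "rewarded", "task"
            ].unique()
            assert list(rewarded_drinks) == [spec.reward_task]

    def test_wrong_ordering_rejected(self, coffee_spec):
        r = constant_rdm(coffee_spec)
        r.labels = r.labels[::-1]
        with pytest.raises(ValueError):
            extract_condition_subsets(r, coffee_spec)


class TestDistanceANOVA:
    def test_degrees_of_freedom_structure(self):
        rng = np.random.default_rng(3)
        table = distance_anova(iid_distance_subsets(rng, 10))
        df = dict(zip(table["term"], table["df"]))
        assert df["condition"] == 1
        assert df["step_pair"] == 35
        assert df["task"] == 1
        assert df["condition:step_pair"] == 35
        assert df["step_pair:task"] == 35
        assert df["condition:step_pair:task"] == 35
        assert df["residual"] == 10 * 72 - 10 - 142

    def test_null_type_one_rate_near_nominal(self, anova_null_rates):
        rate, n_rep = anova_null_rates
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert rate == pytest.approx(0.05, abs=3.5 * se)

    def test_power_for_planted_condition_effect(self):
        # additive rewarded effect of 2 residual sds at n=20 subjects
        rng = np.random.default_rng(4)
        hits = 0
        n_rep = 60
        for _ in range(n_rep):
            subsets = iid_distance_subsets(rng, 20, condition_effect=2.0)
            table = distance_anova(subsets)
            hits += table.loc[table["term"] == "condition", "p"].item() < 0.05
        assert hits / n_rep > 0.9

    def test_planted_effect_recovered_without_bias(self):
        rng = np.random.default_rng(5)
        effect = 1.5
        ests = []
        for _ in range(30):
            subsets = iid_distance_subsets(rng, 50, condition_effect=effect)
            rw = subsets.loc[subsets["condition"] == "rewarded", "distance"].mean()
            nr = subsets.loc[subsets["condition"] == "non-rewarded",
                             "distance"].mean()
            ests.append(rw - nr)
        assert np.mean(ests) == pytest.approx(effect, rel=0.05)

    def test_unbalanced_design_rejected(self):
        rng = np.random.default_rng(6)
        subsets = iid_distance_subsets(rng, 6)
        with pytest.raises(ValueError, match="unbalanced"):
            distance_anova(subsets.iloc[:-1])

    def test_too_few_subjects_rejected(self):
        rng = np.random.default_rng(7)
        with pytest.raises(ValueError, match="at least 5"):
            distance_anova(iid_distance_subsets(rng, 3))


class TestPosthoc:
    def test_null_raw_significance_near_alpha_per_cell(self):
        rng = np.random.default_rng(8)
        counts = []
        for _ in range(40):
            out = posthoc_pairwise(iid_distance_subsets(rng, 10))
            counts.append((out["p"] < 0.05).sum())
        # ~alpha * 36 raw flags per replicate on average
        assert np.mean(counts) == pytest.approx(1.8, abs=1.0)

    def test_step1_only_effect_flags_step1_cells(self):
        rng = np.random.default_rng(9)
        subsets = iid_distance_subsets(rng, 20)
        step1 = (subsets["step_i"] == 1) | (subsets["step_j"] == 1)
        rewarded = subsets["condition"] == "rewarded"
        subsets.loc[step1 & rewarded, "distance"] += 2.0
        out = posthoc_pairwise(subsets)
        flagged = out[out["significant"]]
        assert len(flagged) > 0
        assert ((flagged["step_i"] == 1) | (flagged["step_j"] == 1)).all()
        unaffected = out[(out["step_i"] != 1) & (out["step_j"] != 1)]
        assert not unaffected["significant"].any()

    def test_equal_means_give_zero_estimates(self, coffee_spec):
        frames = []
        for i in range(6):
            sub = extract_condition_subsets(
                constant_rdm(coffee_spec), coffee_spec, subject=f"s{i}"
            )
            frames.append(sub)
        out = posthoc_pairwise(pd.concat(frames, ignore_index=True))
        assert np.allclose(out["estimate"], 0.0, atol=1e-12)


class TestContrasts:
    def test_perfect_linear_relation(self):
        table = pd.DataFrame(
            {
                "subject": list("abcde"),
                "bis_contrast": [1.0, 2.0, 3.0, 4.0, 5.0],
                "distance_contrast": [2.0, 4.0, 6.0, 8.0, 10.0],
            }
        )
        out = contrast_correlations(table)
        assert out["r"].item() == pytest.approx(1.0)

    def test_anticorrelation(self):
        table = pd.DataFrame(
            {
                "subject": list("abc"),
                "bis_contrast": [1.0, 2.0, 3.0],
                "rt_contrast": [3.0, 2.0, 1.0],
            }
        )
        assert contrast_correlations(table)["r"].item() == pytest.approx(-1.0)

    def test_simulation_recovery_of_true_correlation(self):
        rng = np.random.default_rng(10)
        true_r = 0.6
        estimates = []
        for _ in range(200):
            x = rng.standard_normal(50)
            y = true_r * x + np.sqrt(1 - true_r**2) * rng.standard_normal(50)
            table = pd.DataFrame(
                {"subject": range(50), "bis_contrast": x, "distance_contrast": y}
            )
            estimates.append(contrast_correlations(table)["r"].item())
        se = np.std(estimates) / np.sqrt(len(estimates))
        assert np.mean(estimates) == pytest.approx(true_r, abs=4 * se + 0.01)

    def test_zero_variance_warns(self):
        table = pd.DataFrame(
            {
                "subject": list("abc"),
                "bis_contrast": [1.0, 2.0, 3.0],
                "distance_contrast": [1.0, 1.0, 1.0],
            }
        )
        with pytest.warns(UserWarning):
            out = contrast_correlations(table)
        assert np.isnan(out["r"].item())

    def test_cohort_brain_behavior_coupling_positive(self, cohort10,
                                                     cohort10_analysis):
        # the generator couples behavioral reward benefits with rewarded-
        # block distance boosts; the recovered correlation must be positive
        records = []
        for ds in cohort10:
            rec = ds.behavior.copy()
            rec.insert(0, "subject", ds.subject)
            records.append(rec)
        records = pd.concat(records, ignore_index=True)
        summaries = behavior.summarize(records)
        bis_table = behavior.bis(summaries)
        table = cohort10_analysis["contrasts"].merge(
            bis_table[["subject", "bis_contrast"]], on="subject"
        )
        out = contrast_correlations(
            table[["subject", "bis_contrast", "distance_contrast"]]
        )
        assert out["r"].item() > 0

    def test_step1_contrast_uses_step1_cells_only(self, coffee_spec):
        mat = np.full((24, 24), 1.0)
        np.fill_diagonal(mat, 0.0)
        # raise only rewarded-block entries involving step 1 of either sequence
        mat[0, 6:12] += 1.0
        mat[6:12, 0] += 1.0
        mat[6, 0:6] += 1.0
        mat[0:6, 6] += 1.0
        r = rdm.RDM(mat, coffee_spec.state_labels())
        out = condition_contrasts(r, coffee_spec)
        assert out["distance_contrast_step1"] > out["distance_contrast"] > 0
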