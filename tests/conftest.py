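"""Shared fixtures.

The expensive study-scale computations (the 25-network ensemble, the
10-subject planted cohort and its searchlight maps, the Monte-Carlo
calibration runs) are session-scoped so that every test that needs them
shares one computation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from rctrsa import behavior, glm, rdm, rnn, roi, searchlight, simulate, task

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def fit_subject_betas(dataset: simulate.SubjectDataset) -> np.ndarray:
    """Run-wise GLM state patterns for a synthetic subject: (4, 24, X, Y, Z)."""
    betas = []
    for i, run in enumerate(dataset.runs):
        events = dataset.events[dataset.events["run"] == i + 1]
        design = glm.build_design(
            events, dataset.tr, run.shape[-1], nuisance=dataset.nuisance[i]
        )
        betas.append(glm.fit_glm(run, design))
    return np.stack(betas)


@pytest.fixture(scope="session")
def coffee_spec():
    return task.build_task_spec("coffee")


@pytest.fixture(scope="session")
def tea_spec():
    return task.build_task_spec("tea")


@pytest.fixture(scope="session")
def small_ensemble(coffee_spec):
    """Five quickly trained networks for structure tests."""
    ensemble, logs = rnn.train_ensemble(
        rnn.TrainConfig(seed=101, episodes=2000, n_networks=5), coffee_spec
    )
    return ensemble, logs


@pytest.fixture(scope="session")
def model_rdms(small_ensemble):
    ensemble, _ = small_ensemble
    return rnn.build_model_rdms(ensemble)


@pytest.fixture(scope="session")
def full_ensemble(coffee_spec):
    """The study-scale ensemble: 25 networks, 5000 episodes, seeds 1..25."""
    ensemble, logs = rnn.train_ensemble(
        rnn.TrainConfig(seed=1, episodes=5000, n_networks=25), coffee_spec
    )
    return ensemble, logs


@pytest.fixture(scope="session")
def model_rdms_full(full_ensemble):
    ensemble, _ = full_ensemble
    return rnn.build_model_rdms(ensemble)


@pytest.fixture(scope="session")
def noise_free_subject(coffee_spec):
    """A noise-free planted subject on a desk-scale grid, with its betas.

    The ROI is exactly one searchlight footprint (33 voxels), so the sphere
    at its centre observes the complete planted geometry.
    """
    grid = (12, 12, 12)
    roi_mask = simulate.ball_roi((6, 6, 6), 33, grid)
    rng = np.random.default_rng(7)
    target = rdm.euclidean_rdm(
        rng.standard_normal((24, 40)),
        task.build_task_spec("coffee").state_labels(),
    )
    plant = simulate.PlantSpec(roi_mask=roi_mask, target_rdm=target, snr=np.inf,
                               seed=7)
    events = task.generate_session(coffee_spec, seed=7)
    dataset = simulate.simulate_subject(
        plant, events, seed=7, grid=grid, subject="sub-nf"
    )
    betas = fit_subject_betas(dataset)
    return dataset, betas, target


@pytest.fixture(scope="session")
def cohort10(model_rdms):
    """Ten planted subjects at snr=1 on the default 20x24x20 grid."""
    return simulate.simulate_cohort(model_rdms, 10, snr=1.0, seed=11)


@pytest.fixture(scope="session")
def cohort10_analysis(cohort10, model_rdms):
    """Betas, searchlight z-maps, ROI RDMs and group inference for the cohort."""
    zmaps, roi_rdms, contrast_rows, all_betas = [], [], [], []
    for ds in cohort10:
        betas = fit_subject_betas(ds)
        all_betas.append(betas)
        model = model_rdms.for_reward_task(ds.reward_task)
        zmaps.append(
            searchlight.subject_rsa_map(betas, model, subject=ds.subject)
        )
        spec = task.build_task_spec(ds.reward_task)
        r = roi.roi_rdm(betas, ds.truth["plant"].roi_mask)
        r.labels = spec.state_labels()
        roi_rdms.append(r)
        row = {"subject": ds.subject}
        row.update(
            roi.condition_contrasts(r, spec, betas, ds.truth["plant"].roi_mask)
        )
        contrast_rows.append(row)
    group_map, clusters = searchlight.group_inference(
        [m.values for m in zmaps], n_perm=500, seed=3
    )
    return {
        "betas": all_betas,
        "zmaps": zmaps,
        "roi_rdms": roi_rdms,
        "contrasts": pd.DataFrame(contrast_rows),
        "group_map": group_map,
        "clusters": clusters,
    }


def iid_distance_subsets(rng, n_subjects, condition_effect=0.0):
    """Distance subsets with i.i.d. normal distances (optionally a planted
    additive rewarded-condition effect), counterbalanced reward tasks."""
    frames = []
    for i in range(n_subjects):
        reward_task = "coffee" if i % 2 == 0 else "tea"
        spec = task.build_task_spec(reward_task)
        mat = rng.standard_normal((24, 24))
        mat = (mat + mat.T) / 2
        np.fill_diagonal(mat, 0.0)
        r = rdm.RDM(mat, spec.state_labels())
        sub = roi.extract_condition_subsets(r, spec, subject=f"s{i:02d}")
        sub.loc[sub["condition"] == "rewarded", "distance"] += condition_effect
        frames.append(sub)
    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="session")
def anova_null_rates():
    """Monte-Carlo type-I rate of the distance-ANOVA condition term
    (10 subjects, i.i.d. normal distances, 300 replicates)."""
    rng = np.random.default_rng(42)
    hits = 0
    n_rep = 300
    for _ in range(n_rep):
        subsets = iid_distance_subsets(rng, 10)
        table = roi.distance_anova(subsets)
        p = table.loc[table["term"] == "condition", "p"].item()
        hits += p < 0.05
    return hits / n_rep, n_rep


def simulate_behavior_cohort(config, n_subjects, seed):
    """Trial-level behavioral records for a cohort under one config."""
    rng = np.random.default_rng(seed)
    frames = []
    for i in range(n_subjects):
        rec = simulate.simulate_behavior(config, seed=int(rng.integers(2**31)))
        rec.insert(0, "subject", f"s{i:02d}")
        frames.append(rec)
    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="session")
def tukey_power_run():
    """Monte-Carlo power of the per-step Tukey comparisons at n=50 under the
    generator's default reward benefits (steps 2, 4, 6; 60 replicates)."""
    config = simulate.BehaviorConfig()
    n_rep = 60
    flags = {step: 0 for step in range(2, 7)}
    for rep in range(n_rep):
        records = simulate_behavior_cohort(config, 50, seed=1000 + rep)
        res = behavior.behavior_tests(records)
        tuk = res["rt_tukey"]
        for step in flags:
            row = tuk[tuk["step"] == step]
            flags[step] += bool(row["reject"].item())
    return {step: flags[step] / n_rep for step in flags}, n_rep
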