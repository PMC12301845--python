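"""Synthetic subjects: BOLD runs with a planted representational geometry.

Every downstream stage of the pipeline is testable without any scanner data:
a subject is four runs of volumetric "BOLD" (default 20 x 24 x 20 voxels at
2.5 mm, 362 volumes at TR 1.72 s) generated from the first-level design of a
jittered session, in which one region (the planted ROI, default 310 voxels
-- the size of the medial-frontal cluster the real analysis centres on)
carries multivoxel patterns whose pairwise geometry realizes a target RDM,
at a configurable signal-to-noise ratio.  Voxels outside the ROI carry
unstructured (but run-stable) random patterns, optional decoy regions carry
alternative geometries, and per-trial behavioral records carry configurable
reward effects on accuracy and response times.

SNR convention: the planted pattern matrix is scaled so that the standard
deviation of its entries across voxels equals ``snr`` times the noise
standard deviation (which is fixed at 1); ``snr=inf`` switches the noise
off entirely.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from rctrsa.glm import build_design
from rctrsa.rdm import RDM, spearman, vectorize_upper
from rctrsa.task import (
    N_RUNS,
    N_STATES,
    N_VOLUMES,
    SEQUENCE_LABELS,
    TR,
    build_task_spec,
    generate_session,
)

GRID = (20, 24, 20)
VOXEL_SIZE = 2.5
DEFAULT_ROI_VOXELS = 310


@dataclass
class BehaviorConfig:
    """Reward-effect structure of the behavioral generator.

    Accuracy defaults follow the observed group means (0.95 rewarded, 0.92
    non-rewarded).  RT means (s) are per decision step 2-6; the rewarded
    benefit is concentrated on steps 2, 4 and 6 (strongest at step 2) so
    that the condition means land near 0.65 vs 0.67 s.  RTs are log-normal
    with trial-level sd ``rt_sd``; the default 0.11 s is the residual
    dispersion implied by the reported trial-level F statistics (the
    marginal RT sd of ~0.28 s is not compatible with those tests).
    ``effect_scale`` multiplies both reward benefits and is the hook
    through which cohort-level brain-behavior coupling is expressed.
    """

    acc_rewarded: float = 0.95
    acc_nonrewarded: float = 0.92
    rt_nonrewarded: tuple[float, ...] = (0.78, 0.60, 0.68, 0.58, 0.71)
    rt_benefit: tuple[float, ...] = (0.05, 0.0, 0.025, 0.0, 0.025)
    rt_sd: float = 0.11
    n_trials: int = 72
    effect_scale: float = 1.0

    def rt_mean(self, condition: str, step: int) -> float:
        base = self.rt_nonrewarded[step - 2]
        if condition == "rewarded":
            return base - self.effect_scale * self.rt_benefit[step - 2]
        return base

    def accuracy(self, condition: str) -> float:
        if condition == "rewarded":
            benefit = self.acc_rewarded - self.acc_nonrewarded
            return min(self.acc_nonrewarded + self.effect_scale * benefit, 1.0)
        return self.acc_nonrewarded


@dataclass
class PlantSpec:
    """Ground truth of a synthetic subject's structured signal."""

    roi_mask: np.ndarray  # boolean grid
    target_rdm: RDM
    snr: float
    decoy_rois: list[tuple[np.ndarray, RDM]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if not self.roi_mask.any():
            raise ValueError("roi_mask is empty")
        if self.snr < 0:
            raise ValueError("snr must be >= 0")


@dataclass
class SubjectDataset:
    """One synthetic subject: 4 BOLD runs, events, nuisance, behavior, truth."""

    subject: str
    reward_task: str
    runs: list[np.ndarray]  # each (X, Y, Z, T)
    events: pd.DataFrame
    nuisance: list[np.ndarray]  # each (T, 6)
    behavior: pd.DataFrame
    truth: dict
    tr: float = TR
    voxel_size: float = VOXEL_SIZE

    @property
    def grid(self) -> tuple[int, int, int]:
        return self.runs[0].shape[:3]


def ball_roi(
    center: tuple[int, int, int] | None = None,
    n_voxels: int = DEFAULT_ROI_VOXELS,
    grid: tuple[int, int, int] = GRID,
) -> np.ndarray:
    """Compact quasi-spherical ROI of exactly ``n_voxels`` voxels.

    Voxels are taken in order of distance from the centre (lexicographic
    tie-break) so the mask is deterministic.
    """
    if center is None:
        center = tuple(g // 2 for g in grid)
    idx = np.indices(grid).reshape(3, -1).T
    d2 = ((idx - np.array(center)) ** 2).sum(axis=1)
    order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0], d2))
    mask = np.zeros(grid, dtype=bool)
    chosen = idx[order[:n_voxels]]
    mask[chosen[:, 0], chosen[:, 1], chosen[:, 2]] = True
    return mask


def drink_identity_rdm(reward_task: str = "coffee") -> RDM:
    """A decoy geometry dominated by task (drink) identity: distance 0
    between states of the same drink, 1 across drinks."""
    spec = build_task_spec(reward_task)
    drinks = np.array([spec.sequence(s.sequence_id).drink for s in spec.states()])
    mat = (drinks[:, None] != drinks[None, :]).astype(float)
    return RDM(mat, spec.state_labels(), metric="plain-euclidean")


def embed_geometry(
    target_rdm: RDM, n_voxels: int, seed: int
) -> tuple[np.ndarray, float]:
    """Voxel patterns whose pairwise Euclidean distances realize a target RDM.

    Classical (Torgerson) scaling of the target distances gives coordinates
    in at most n-1 dimensions; a random orthonormal rotation lifts them into
    voxel space (an isometry, so the geometry is unchanged).  Strongly
    non-Euclidean targets are embedded with truncation of the negative
    eigenvalues.  The pattern matrix is normalized to unit entry-sd.
    Returns ``(patterns, achieved)`` where ``achieved`` is the Spearman
    correlation between realized and target distances.
    """
    n = target_rdm.n
    if n_voxels < n - 1:
        raise ValueError(f"need at least {n - 1} voxels to embed {n} conditions")
    if target_rdm.metric == "cv-euclidean-squared":
        d2 = np.maximum(target_rdm.matrix, 0.0)
    else:
        d2 = target_rdm.matrix**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    w, V = np.linalg.eigh(B)
    keep = w > max(w.max(), 0) * 1e-12
    coords = V[:, keep] * np.sqrt(w[keep])
    rng = np.random.default_rng(seed)
    Q, _ = np.linalg.qr(rng.standard_normal((n_voxels, coords.shape[1])))
    patterns = coords @ Q.T
    patterns = patterns / patterns.std()
    from rctrsa.rdm import euclidean_rdm  # local import to keep module load light

    achieved = spearman(
        vectorize_upper(euclidean_rdm(patterns).matrix),
        vectorize_upper(target_rdm.matrix),
    )
    return patterns, achieved


def simulate_behavior(
    config: BehaviorConfig, events: pd.DataFrame | None = None, seed: int = 0
) -> pd.DataFrame:
    """Per-trial correctness and per-step RTs for one subject's session.

    Correctness is Bernoulli at the condition's configured rate; RTs for
    decision steps 2-6 are log-normal with the configured means and sd.
    Without an event table a balanced session of ``config.n_trials`` trials
    (equal sequence counts) is generated directly.
    """
    for rate in (config.acc_rewarded, config.acc_nonrewarded):
        if not 0.0 <= rate <= 1.0:
            raise ValueError("accuracy rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    if events is not None:
        trials = events.drop_duplicates(["run", "trial"])[
            ["run", "trial", "sequence", "condition"]
        ].reset_index(drop=True)
    else:
        n = config.n_trials
        seqs = np.tile(SEQUENCE_LABELS, n // 4 + 1)[:n]
        rng.shuffle(seqs)
        trials = pd.DataFrame(
            {
                "run": np.repeat(np.arange(1, N_RUNS + 1), -(-n // N_RUNS))[:n],
                "trial": np.arange(n) % -(-n // N_RUNS) + 1,
                "sequence": seqs,
                "condition": np.where(
                    np.char.startswith(seqs.astype(str), "n"),
                    "non-rewarded",
                    "rewarded",
                ),
            }
        )
    out = trials.copy()
    rates = out["condition"].map(config.accuracy).to_numpy(dtype=float)
    out["correct"] = rng.random(len(out)) < rates
    rewarded = (out["condition"] == "rewarded").to_numpy()
    for step in range(2, 7):
        m = np.where(
            rewarded, config.rt_mean("rewarded", step),
            config.rt_mean("non-rewarded", step),
        )
        sigma2 = np.log1p((config.rt_sd / m) ** 2)
        mu = np.log(m) - sigma2 / 2
        out[f"rt_step{step}"] = rng.lognormal(mu, np.sqrt(sigma2))
    return out


def simulate_subject(
    plant: PlantSpec,
    events: pd.DataFrame,
    behavior_config: BehaviorConfig | None = None,
    seed: int = 0,
    reward_task: str = "coffee",
    subject: str = "sub-01",
    grid: tuple[int, int, int] = GRID,
    tr: float = TR,
    n_volumes: int = N_VOLUMES,
) -> SubjectDataset:
    """Generate one subject's full dataset from a plant specification.

    Per run: BOLD = task design x true patterns + nuisance random walks x
    random loadings + white Gaussian noise (sd 1, scaled off at snr=inf).
    The planted ROI carries the embedded target geometry, decoys their own
    geometries, background voxels unstructured run-stable patterns of the
    same amplitude.  The full ground truth is stored under ``truth``.
    """
    if behavior_config is None:
        behavior_config = BehaviorConfig()
    rng = np.random.default_rng(seed)
    n_vox = int(np.prod(grid))
    flat_roi = plant.roi_mask.reshape(-1)

    amplitude = 1.0 if np.isinf(plant.snr) else plant.snr
    noise_sd = 0.0 if np.isinf(plant.snr) else 1.0

    patterns = np.zeros((N_STATES, n_vox))
    patterns[:, ~flat_roi] = rng.standard_normal((N_STATES, int((~flat_roi).sum())))
    roi_patterns, achieved = embed_geometry(
        plant.target_rdm, int(flat_roi.sum()), seed=int(rng.integers(2**31))
    )
    patterns[:, flat_roi] = roi_patterns
    for mask, rdm_target in plant.decoy_rois:
        fm = mask.reshape(-1)
        decoy_patterns, _ = embed_geometry(
            rdm_target, int(fm.sum()), seed=int(rng.integers(2**31))
        )
        patterns[:, fm] = decoy_patterns
    patterns *= amplitude

    runs, nuisances = [], []
    for run in range(1, N_RUNS + 1):
        ev = events[events["run"] == run]
        nuis = np.cumsum(rng.normal(0, 1, (n_volumes, 6)), axis=0)
        nuis = (nuis - nuis.mean(0)) / nuis.std(0)
        design = build_design(ev, tr, n_volumes, nuisance=nuis)
        X_task = design.state_columns()
        loadings = rng.normal(0, 0.5 * amplitude, (6, n_vox))
        Y = X_task @ patterns + nuis @ loadings
        if noise_sd > 0:
            Y += rng.normal(0, noise_sd, Y.shape)
        runs.append(np.moveaxis(Y.reshape(n_volumes, *grid), 0, -1))
        nuisances.append(nuis)

    behavior = simulate_behavior(
        behavior_config, events, seed=int(rng.integers(2**31))
    )
    truth = {
        "plant": plant,
        "patterns": patterns,
        "amplitude": amplitude,
        "achieved_geometry_spearman": achieved,
        "behavior_config": behavior_config,
    }
    return SubjectDataset(
        subject=subject,
        reward_task=reward_task,
        runs=runs,
        events=events,
        nuisance=nuisances,
        behavior=behavior,
        truth=truth,
        tr=tr,
    )


def simulate_cohort(
    model_rdms,
    n_subjects: int,
    snr: float,
    seed: int,
    behavior_config: BehaviorConfig | None = None,
    coupling: float = 0.5,
    grid: tuple[int, int, int] = GRID,
    roi_voxels: int = DEFAULT_ROI_VOXELS,
    decoys: bool = False,
    tr: float = TR,
    n_volumes: int = N_VOLUMES,
) -> list[SubjectDataset]:
    """A cohort of synthetic subjects sharing one planted ROI.

    The rewarded drink alternates across subjects (counterbalancing), and
    each subject uses the model RDM matching their assignment.  A per-
    subject effect magnitude ``g ~ N(1, 0.3)`` (clipped at 0.1) jointly
    scales the behavioral reward benefits and -- via ``coupling`` -- the
    rewarded-block distances of the planted geometry, so that brain-behavior
    contrast correlations have a planted positive truth.
    """
    if behavior_config is None:
        behavior_config = BehaviorConfig()
    rng = np.random.default_rng(seed)
    roi = ball_roi(n_voxels=roi_voxels, grid=grid)
    decoy_center = (grid[0] // 4, grid[1] // 4, grid[2] // 4)
    subjects = []
    for i in range(n_subjects):
        reward_task = "coffee" if i % 2 == 0 else "tea"
        spec = build_task_spec(reward_task)
        g = max(float(rng.normal(1.0, 0.3)), 0.1)
        target = model_rdms.for_reward_task(reward_task)
        mat = target.matrix.copy()
        boost = 1.0 + coupling * (g - 1.0)
        mat[:12, :12] *= boost  # rewarded-state block, canonical ordering
        target_s = RDM(mat, target.labels, metric=target.metric)
        decoy_list = []
        if decoys:
            decoy_mask = ball_roi(decoy_center, n_voxels=roi_voxels, grid=grid)
            decoy_list = [(decoy_mask, drink_identity_rdm(reward_task))]
        plant = PlantSpec(
            roi_mask=roi,
            target_rdm=target_s,
            snr=snr,
            decoy_rois=decoy_list,
            seed=seed + i,
        )
        events = generate_session(spec, seed=int(rng.integers(2**31)))
        subjects.append(
            simulate_subject(
                plant,
                events,
                behavior_config=replace(behavior_config, effect_scale=g),
                seed=int(rng.integers(2**31)),
                reward_task=reward_task,
                subject=f"sub-{i + 1:02d}",
                grid=grid,
                tr=tr,
                n_volumes=n_volumes,
            )
        )
    return subjects


def write_subject(dataset: SubjectDataset, out_dir) -> None:
    """Write a subject as a BIDS-like tree (NIfTI runs, TSV events, CSVs)."""
    import nibabel as nib
    from pathlib import Path

    from rctrsa.task import events_to_tsv

    root = Path(out_dir) / dataset.subject
    func = root / "func"
    func.mkdir(parents=True, exist_ok=True)
    affine = np.diag([dataset.voxel_size] * 3 + [1.0])
    for i, run in enumerate(dataset.runs, start=1):
        nib.save(
            nib.Nifti1Image(run.astype(np.float32), affine),
            func / f"run-{i:02d}_bold.nii.gz",
        )
        np.savetxt(func / f"run-{i:02d}_nuisance.tsv", dataset.nuisance[i - 1])
    events_to_tsv(dataset.events, func / "events.tsv")
    dataset.behavior.to_csv(root / "behavior.csv", index=False)
    truth = {
        "reward_task": dataset.reward_task,
        "snr": float(dataset.truth["plant"].snr),
        "roi_voxels": int(dataset.truth["plant"].roi_mask.sum()),
        "achieved_geometry_spearman": float(
            dataset.truth["achieved_geometry_spearman"]
        ),
    }
    (root / "truth.json").write_text(json.dumps(truth, indent=2))
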