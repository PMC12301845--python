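"""Whole-volume searchlight RSA and group inference.

For every voxel, the multivoxel pattern of its 6 mm spherical neighborhood
is summarized as a leave-one-run-out cross-validated Euclidean RDM, rank-
correlated with the model RDM, z-scored against the subject's whole-volume
distribution of correlations, and smoothed (6 mm FWHM).  Group inference is
a voxel-wise one-sided Wilcoxon signed-rank test across subjects with a
cluster-extent familywise-error correction by sign-flipping permutation.

Because both the cross-validated squared distance and the nearest-centroid
discriminant are sums of per-voxel contributions, the searchlight is
computed by accumulating one contribution volume per state pair (or test
state) and summing it over the spherical footprint with a single volumetric
correlation filter -- exactly equivalent to looping over spheres, which the
tests verify against a direct per-sphere implementation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import rankdata

from rctrsa.rdm import RDM, zscore_within

RADIUS_MM = 6.0
FWHM_MM = 6.0
MIN_SPHERE_VOXELS = 10


@dataclass
class Sphere:
    center: tuple[int, int, int]
    members: np.ndarray  # (k, 3) voxel indices, center included


@dataclass
class StatMap:
    """A voxel grid of statistic values (NaN outside the valid mask)."""

    values: np.ndarray
    kind: str  # "r" | "z" | "accuracy" | "signed-rank-W"
    subject: str | None = None
    stages: dict = field(default_factory=dict)

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.values)


def ball_offsets(voxel_size: float = 2.5, radius: float = RADIUS_MM) -> np.ndarray:
    """Integer voxel offsets of a spherical searchlight footprint.

    The radius is converted to whole voxels (``floor(radius / voxel_size)``)
    and membership is centre-to-centre Euclidean distance within that voxel
    radius -- the convention of the common searchlight toolboxes.  A 6 mm
    sphere on a 2.5 mm grid therefore spans 2 voxels and 33 members.
    """
    r = int(np.floor(radius / voxel_size))
    rng = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(rng, rng, rng, indexing="ij")
    offs = np.column_stack([dx.ravel(), dy.ravel(), dz.ravel()])
    keep = (offs**2).sum(axis=1) <= r**2 + 1e-9
    return offs[keep]


def _ball_kernel(voxel_size: float, radius: float) -> np.ndarray:
    offs = ball_offsets(voxel_size, radius)
    r = int(np.abs(offs).max())
    kernel = np.zeros((2 * r + 1,) * 3)
    kernel[offs[:, 0] + r, offs[:, 1] + r, offs[:, 2] + r] = 1.0
    return kernel


def make_spheres(
    mask: np.ndarray, voxel_size: float = 2.5, radius: float = RADIUS_MM
) -> list[Sphere]:
    """One sphere per in-mask voxel; members are the in-mask neighbors
    within ``radius`` (truncated at mask edges)."""
    if not mask.any():
        raise ValueError("mask is empty")
    offs = ball_offsets(voxel_size, radius)
    shape = np.array(mask.shape)
    spheres = []
    for center in np.argwhere(mask):
        pts = center + offs
        inside = np.all((pts >= 0) & (pts < shape), axis=1)
        pts = pts[inside]
        in_mask = mask[pts[:, 0], pts[:, 1], pts[:, 2]]
        spheres.append(Sphere(tuple(int(c) for c in center), pts[in_mask]))
    return spheres


def _ball_sum(volumes: np.ndarray, mask: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Sum each volume over the spherical footprint, restricted to the mask.

    ``volumes`` is (P, X, Y, Z); out-of-mask voxels contribute zero.
    """
    out = np.empty_like(volumes)
    for p in range(volumes.shape[0]):
        out[p] = ndimage.correlate(
            np.where(mask, volumes[p], 0.0), kernel, mode="constant"
        )
    return out


def _pair_contributions(folds: np.ndarray) -> np.ndarray:
    """Per-voxel contributions to the cv squared distance of each pair.

    ``folds`` is (F, n, V); returns (n(n-1)/2, V): the fold-averaged product
    of training-mean and held-out pattern differences, whose sum over a
    sphere's voxels is that sphere's cv distance for the pair.
    """
    F, n, _ = folds.shape
    iu0, iu1 = np.triu_indices(n, k=1)
    fold_sum = folds.sum(axis=0)
    U = np.zeros((len(iu0), folds.shape[2]))
    for f in range(F):
        train = (fold_sum - folds[f]) / (F - 1)
        dtr = train[iu0] - train[iu1]
        dte = folds[f][iu0] - folds[f][iu1]
        U += dtr * dte
    return U / F


def smooth_map(
    values: np.ndarray, fwhm: float, voxel_size: float
) -> np.ndarray:
    """Gaussian smoothing (FWHM in mm) with NaN-aware normalization."""
    if fwhm <= 0:
        return values.copy()
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size
    valid = np.isfinite(values)
    num = ndimage.gaussian_filter(np.where(valid, values, 0.0), sigma)
    den = ndimage.gaussian_filter(valid.astype(float), sigma)
    out = np.full(values.shape, np.nan)
    out[valid] = num[valid] / den[valid]
    return out


def subject_rsa_map(
    betas: np.ndarray,
    model_rdm: RDM,
    mask: np.ndarray | None = None,
    voxel_size: float = 2.5,
    radius: float = RADIUS_MM,
    fwhm: float = FWHM_MM,
    min_voxels: int = MIN_SPHERE_VOXELS,
    subject: str | None = None,
) -> StatMap:
    """Model-based searchlight RSA map for one subject.

    ``betas`` is (runs, 24, X, Y, Z).  Per sphere: cv Euclidean RDM over the
    member voxels, upper triangle rank-correlated (Spearman) with the model
    RDM; the correlation map is z-scored within the subject's valid voxels
    and then smoothed.  Spheres with fewer than ``min_voxels`` in-mask
    members are left undefined.  ``stages`` carries the unsmoothed ``r`` and
    ``z`` maps.
    """
    if betas.ndim != 5:
        raise ValueError("betas must be (runs, states, X, Y, Z)")
    F, n_states = betas.shape[:2]
    if F < 2:
        raise ValueError("need at least 2 runs")
    if n_states != model_rdm.n:
        raise ValueError("state count does not match the model RDM")
    grid = betas.shape[2:]
    if mask is None:
        mask = np.ones(grid, dtype=bool)
    finite = np.isfinite(betas).all(axis=(0, 1))
    mask = mask & finite

    flat = betas[:, :, mask]  # (F, n, V)
    kernel = _ball_kernel(voxel_size, radius)
    counts = _ball_sum(mask[None].astype(float), mask, kernel)[0]
    valid = mask & (counts >= min_voxels)

    U = _pair_contributions(flat)  # (P, V)
    vols = np.zeros((U.shape[0], *grid))
    vols[:, mask] = U
    sphere_d = _ball_sum(vols, mask, kernel)[:, valid]  # (P, n_valid)

    model_ranks = rankdata(model_rdm.vector())
    ranks = rankdata(sphere_d, axis=0)
    mr = model_ranks - model_ranks.mean()
    rr = ranks - ranks.mean(axis=0)
    denom = np.sqrt((rr**2).sum(axis=0) * (mr**2).sum())
    with np.errstate(invalid="ignore"):
        r = (mr @ rr) / denom

    r_map = np.full(grid, np.nan)
    r_map[valid] = r
    z_map = np.full(grid, np.nan)
    z_map[valid] = zscore_within(r)
    smoothed = smooth_map(z_map, fwhm, voxel_size)
    return StatMap(
        smoothed, kind="z", subject=subject, stages={"r": r_map, "z": z_map}
    )


# ---------------------------------------------------------------------------
# group inference


def signed_rank_null_tail(n: int) -> np.ndarray:
    """Exact null tail P(W+ >= w), w = 0..n(n+1)/2, of the one-sample
    Wilcoxon signed-rank statistic for ``n`` continuous observations."""
    total = n * (n + 1) // 2
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for k in range(1, n + 1):
        counts[k:] += counts[:-k].copy()
    probs = counts / 2.0**n
    return probs[::-1].cumsum()[::-1]


def signed_rank_p(values: np.ndarray) -> float:
    """Exact one-sided (greater) signed-rank p for one sample."""
    values = np.asarray(values, dtype=float)
    ranks = rankdata(np.abs(values))
    w = ranks[values > 0].sum()
    tail = signed_rank_null_tail(values.size)
    return float(tail[int(round(w))])


def group_inference(
    z_maps: list[StatMap] | list[np.ndarray],
    alpha_voxel: float = 0.001,
    alpha_cluster: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[StatMap, pd.DataFrame]:
    """Voxel-wise one-sided signed-rank group test with cluster-extent FWE
    control by sign-flipping permutation.

    Clusters are formed from voxels whose exact signed-rank p falls below
    ``alpha_voxel`` (26-connectivity); the null distribution of the maximum
    cluster extent is built by randomly flipping each subject's map sign,
    and clusters larger than the (1 - ``alpha_cluster``) null quantile are
    flagged significant.  Returns the group W-statistic map and the cluster
    table (size, peak statistic, peak voxel, corrected p, significance).
    """
    maps = [m.values if isinstance(m, StatMap) else m for m in z_maps]
    stack = np.stack(maps)  # (N, X, Y, Z)
    n_sub = stack.shape[0]
    if n_sub < 5:
        raise ValueError("group inference needs at least 5 subjects")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse cluster-extent null")
    valid = np.isfinite(stack).all(axis=0)
    X = stack[:, valid]  # (N, V)
    if np.all(X == X[:1]):
        raise ValueError("all subject maps identical; signed-rank undefined")

    ranks = rankdata(np.abs(X), axis=0)
    W = (ranks * (X > 0)).sum(axis=0)
    tail = signed_rank_null_tail(n_sub)
    passing = np.where(tail <= alpha_voxel)[0]
    w_map = np.full(valid.shape, np.nan)
    w_map[valid] = W
    stat_map = StatMap(w_map, kind="signed-rank-W")

    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    if passing.size == 0:
        warnings.warn(
            f"no attainable voxel threshold at alpha={alpha_voxel} with "
            f"{n_sub} subjects"
        )
        return stat_map, pd.DataFrame(
            columns=["size", "peak_stat", "peak_x", "peak_y", "peak_z", "p_fwe",
                     "significant"]
        )
    w_crit = passing[0]

    supra = np.zeros(valid.shape, dtype=bool)
    supra[valid] = W >= w_crit
    labels, n_clusters = ndimage.label(supra, structure=structure)

    # permutation null of the maximum cluster extent
    rng = np.random.default_rng(seed)
    pos = X > 0
    A = ranks * pos
    B = ranks * ~pos
    signs = rng.integers(0, 2, size=(n_perm, n_sub)).astype(float)
    Wp = signs @ A + (1.0 - signs) @ B  # (n_perm, V)
    null_max = np.zeros(n_perm, dtype=int)
    perm_vol = np.zeros(valid.shape, dtype=bool)
    for p in range(n_perm):
        perm_vol[valid] = Wp[p] >= w_crit
        lab, k = ndimage.label(perm_vol, structure=structure)
        if k:
            null_max[p] = np.bincount(lab.ravel())[1:].max()

    mean_map = np.nanmean(stack, axis=0)
    rows = []
    for c in range(1, n_clusters + 1):
        members = labels == c
        size = int(members.sum())
        vals = np.where(members, mean_map, -np.inf)
        peak = np.unravel_index(np.argmax(vals), vals.shape)
        p_fwe = float((1 + (null_max >= size).sum()) / (n_perm + 1))
        rows.append(
            {
                "size": size,
                "peak_stat": float(mean_map[peak]),
                "peak_x": peak[0],
                "peak_y": peak[1],
                "peak_z": peak[2],
                "p_fwe": p_fwe,
                "significant": p_fwe <= alpha_cluster,
            }
        )
    clusters = pd.DataFrame(
        rows, columns=["size", "peak_stat", "peak_x", "peak_y", "peak_z", "p_fwe",
                       "significant"]
    ).sort_values("size", ascending=False, ignore_index=True)
    return stat_map, clusters


def reward_classification_map(
    betas: np.ndarray,
    rewarded: np.ndarray,
    mask: np.ndarray | None = None,
    voxel_size: float = 2.5,
    radius: float = RADIUS_MM,
    min_voxels: int = MIN_SPHERE_VOXELS,
) -> StatMap:
    """Leave-one-run-out searchlight decoding of rewarded vs non-rewarded.

    Per sphere and fold, a nearest-class-centroid classifier (Euclidean) is
    trained on the remaining runs and applied to the held-out run's 24 state
    patterns; accuracies are averaged over folds and test states.  Ties
    count one half.
    """
    rewarded = np.asarray(rewarded, dtype=bool)
    if rewarded.all() or not rewarded.any():
        raise ValueError("need both rewarded and non-rewarded states")
    F, n_states = betas.shape[:2]
    grid = betas.shape[2:]
    if mask is None:
        mask = np.ones(grid, dtype=bool)
    mask = mask & np.isfinite(betas).all(axis=(0, 1))
    flat = betas[:, :, mask]
    kernel = _ball_kernel(voxel_size, radius)
    counts = _ball_sum(mask[None].astype(float), mask, kernel)[0]
    valid = mask & (counts >= min_voxels)

    acc = np.zeros(grid)
    fold_idx = np.arange(F)
    for f in range(F):
        train = flat[fold_idx != f]
        c_r = train[:, rewarded].mean(axis=(0, 1))
        c_n = train[:, ~rewarded].mean(axis=(0, 1))
        # per-voxel discriminant contribution for each test state
        diffs = (flat[f] - c_r) ** 2 - (flat[f] - c_n) ** 2  # (n, V)
        vols = np.zeros((n_states, *grid))
        vols[:, mask] = diffs
        delta = _ball_sum(vols, mask, kernel)  # <0 -> closer to rewarded centroid
        pred_r = delta < 0
        correct = np.where(
            delta == 0, 0.5, pred_r == rewarded[:, None, None, None]
        )
        acc += correct.mean(axis=0)
    values = np.where(valid, acc / F, np.nan)
    return StatMap(values, kind="accuracy")
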