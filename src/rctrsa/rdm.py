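"""Dissimilarity primitives shared by the model and brain analyses.

Distances, RDM containers, upper-triangle vectorization, Spearman rank
correlation, within-subject standardization and nonmetric MDS.  The
cross-validated distance is the unbiased leave-one-run-out *squared*
Euclidean estimator (pattern differences from the training folds multiplied
by the same differences in the held-out fold, averaged over folds); under
the null it is centred on zero, so negative entries are retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from sklearn.manifold import MDS


@dataclass
class RDM:
    """A labelled square matrix of pairwise pattern dissimilarities."""

    matrix: np.ndarray
    labels: list[str] = field(default_factory=list)
    metric: str = "plain-euclidean"  # or "cv-euclidean-squared"

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.n
        if self.matrix.ndim != 2 or self.matrix.shape[1] != n:
            raise ValueError("RDM matrix must be square")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("RDM matrix must be symmetric")
        if not self.labels:
            self.labels = [f"c{i}" for i in range(n)]
        if len(self.labels) != n:
            raise ValueError("label count does not match matrix size")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def vector(self) -> np.ndarray:
        return vectorize_upper(self.matrix)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.matrix, index=self.labels, columns=self.labels).to_csv(path)

    @classmethod
    def from_csv(cls, path, metric: str = "plain-euclidean") -> "RDM":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(), list(df.index), metric=metric)


def euclidean_rdm(patterns: np.ndarray, labels: list[str] | None = None) -> RDM:
    """Plain Euclidean distances between the rows of ``patterns`` (n x v)."""
    patterns = np.asarray(patterns, dtype=float)
    if patterns.ndim != 2 or patterns.shape[0] < 2:
        raise ValueError("patterns must be a 2-D array with at least two rows")
    if not np.all(np.isfinite(patterns)):
        raise ValueError("patterns contain non-finite values")
    sq = np.sum(patterns**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * patterns @ patterns.T
    np.maximum(d2, 0.0, out=d2)
    mat = np.sqrt(d2)
    np.fill_diagonal(mat, 0.0)
    mat = (mat + mat.T) / 2.0
    return RDM(mat, labels or [], metric="plain-euclidean")


def cv_euclidean_rdm(folds: np.ndarray, labels: list[str] | None = None) -> RDM:
    """Leave-one-run-out cross-validated squared Euclidean RDM.

    ``folds`` is (F, n, v): F runs of n condition patterns over v features.
    For each held-out fold f the pairwise difference of the training-fold
    mean patterns is multiplied elementwise by the difference in fold f and
    summed over features; the final entry is the mean over folds.  Noise
    that is independent across folds cancels in expectation, so the
    estimator is unbiased (and exactly the squared true distance when the
    folds are noise-free); single-draw entries may be negative.
    """
    folds = np.asarray(folds, dtype=float)
    if folds.ndim != 3:
        raise ValueError("folds must be (F, n_conditions, n_features)")
    F = folds.shape[0]
    if F < 2:
        raise ValueError("cross-validated distances need at least 2 folds")
    if not np.all(np.isfinite(folds)):
        raise ValueError("folds contain non-finite values")
    n = folds.shape[1]
    total = np.zeros((n, n))
    fold_sum = folds.sum(axis=0)
    for f in range(F):
        train = (fold_sum - folds[f]) / (F - 1)
        test = folds[f]
        # d2(i,j) = (t_i - t_j) . (y_i - y_j) via the cross-Gram matrix
        G = train @ test.T
        d2 = np.diag(G)[:, None] + np.diag(G)[None, :] - G - G.T
        total += d2
    mat = total / F
    mat = (mat + mat.T) / 2.0
    np.fill_diagonal(mat, 0.0)
    return RDM(mat, labels or [], metric="cv-euclidean-squared")


def vectorize_upper(rdm: RDM | np.ndarray) -> np.ndarray:
    """Row-major upper triangle excluding the diagonal; length n(n-1)/2."""
    mat = rdm.matrix if isinstance(rdm, RDM) else np.asarray(rdm, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("input must be a square matrix")
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def unvectorize(vector: np.ndarray) -> np.ndarray:
    """Refold an upper-triangle vector into a symmetric zero-diagonal matrix."""
    return squareform(np.asarray(vector, dtype=float), checks=False)


def spearman(v1: np.ndarray, v2: np.ndarray) -> float:
    """Spearman's rho: Pearson correlation of mid-ranks (ties averaged).

    Returns NaN (with a warning) when either argument has zero rank
    variance.
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.shape != v2.shape or v1.ndim != 1:
        raise ValueError("inputs must be 1-D arrays of equal length")
    if v1.size < 3:
        raise ValueError("need at least 3 observations")
    r1 = rankdata(v1)
    r2 = rankdata(v2)
    if np.ptp(r1) == 0 or np.ptp(r2) == 0:
        warnings.warn("zero rank variance; Spearman correlation undefined")
        return float("nan")
    r1 = r1 - r1.mean()
    r2 = r2 - r2.mean()
    return float(r1 @ r2 / np.sqrt((r1 @ r1) * (r2 @ r2)))


def zscore_within(values: np.ndarray) -> np.ndarray:
    """Standardize a subject's map values (sample sd, n-1 denominator)."""
    values = np.asarray(values, dtype=float)
    finite = values[np.isfinite(values)]
    if finite.size < 2:
        raise ValueError("need at least 2 finite values to z-score")
    sd = finite.std(ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation; z-score undefined")
    return (values - finite.mean()) / sd


def nonmetric_mds(
    rdm: RDM | np.ndarray,
    dim: int = 2,
    seed: int = 0,
    n_init: int = 20,
) -> tuple[np.ndarray, float]:
    """Nonmetric (Kruskal) MDS embedding of a dissimilarity matrix.

    Minimizes normalized stress-1 with monotone regression from ``n_init``
    random starts; returns the best coordinates and their stress.
    """
    mat = rdm.matrix if isinstance(rdm, RDM) else np.asarray(rdm, dtype=float)
    n = mat.shape[0]
    if n < dim + 1:
        raise ValueError("need at least dim+1 conditions")
    mds = MDS(
        n_components=dim,
        metric=False,
        dissimilarity="precomputed",
        n_init=n_init,
        random_state=seed,
        normalized_stress=True,
        max_iter=500,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coords = mds.fit_transform(mat)
    return coords, float(mds.stress_)
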