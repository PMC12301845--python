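"""First-level GLM: design matrices and run-wise pattern estimation.

One GLM per run, with a regressor per task state (1 s boxcar at each step
onset convolved with the canonical double-gamma HRF), optional nuisance
columns passed through unmodified, and an intercept.  Run-separable
estimation supplies the run-wise condition patterns that the leave-one-run-
out cross-validated distances require.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from rctrsa.task import N_STATES

#: conventional double-gamma parameters: response delay 6 s, undershoot
#: delay 16 s, unit dispersions, undershoot ratio 1/6, 32 s support
HRF_PEAK_DELAY = 6.0
HRF_UNDERSHOOT_DELAY = 16.0
HRF_UNDERSHOOT_RATIO = 1.0 / 6.0
HRF_LENGTH = 32.0

_DT = 0.1  # convolution grid resolution (s)


@dataclass
class DesignMatrix:
    matrix: np.ndarray  # volumes x regressors
    names: list[str]
    tr: float

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    def state_columns(self) -> np.ndarray:
        idx = [i for i, n in enumerate(self.names) if n.startswith("state_")]
        return self.matrix[:, idx]


def canonical_hrf(tr: float, oversampling: int = 1) -> np.ndarray:
    """Canonical double-gamma HRF sampled at ``tr / oversampling``.

    Peak-normalized to 1; the kernel spans 0..32 s (peak near 5 s, undershoot
    near 15 s).
    """
    if tr <= 0:
        raise ValueError("TR must be positive")
    dt = tr / oversampling
    t = np.arange(0.0, HRF_LENGTH + dt / 2, dt)
    h = gamma_dist.pdf(t, HRF_PEAK_DELAY) - HRF_UNDERSHOOT_RATIO * gamma_dist.pdf(
        t, HRF_UNDERSHOOT_DELAY
    )
    return h / h.max()


def build_design(
    events: pd.DataFrame,
    tr: float,
    n_volumes: int,
    nuisance: np.ndarray | None = None,
) -> DesignMatrix:
    """Design matrix for one run of an event table.

    Each of the 24 task states contributes a boxcar (its onsets, 1 s
    duration) convolved with the canonical HRF on a 0.1 s grid and sampled
    at the volume acquisition times; step-7 feedback events (no state index)
    are not modelled.  Nuisance columns (volumes x k) are appended
    unmodified, then an intercept.
    """
    run_end = n_volumes * tr
    task = events[events["state_index"].notna()]
    late = task[task["onset"] + task["duration"] > run_end]
    if len(late):
        raise ValueError(
            "events extend beyond the run end: "
            + ", ".join(
                f"(trial {r.trial}, step {r.step}, onset {r.onset:.2f})"
                for r in late.itertuples()
            )
        )
    oversampling = max(int(round(tr / _DT)), 1)
    dt = tr / oversampling
    n_fine = int(np.ceil(run_end / dt)) + 1
    kernel = canonical_hrf(tr, oversampling)
    vol_idx = (np.arange(n_volumes) * oversampling).astype(int)

    cols, names = [], []
    for state in range(N_STATES):
        sel = task[task["state_index"] == state]
        boxcar = np.zeros(n_fine)
        for r in sel.itertuples():
            a = int(round(r.onset / dt))
            b = min(int(round((r.onset + r.duration) / dt)), n_fine)
            boxcar[a:b] = 1.0
        reg = np.convolve(boxcar, kernel)[:n_fine]
        cols.append(reg[vol_idx])
        names.append(f"state_{state:02d}")
    X = np.column_stack(cols)
    if nuisance is not None:
        nuisance = np.asarray(nuisance, dtype=float)
        if nuisance.shape[0] != n_volumes:
            raise ValueError("nuisance rows must match n_volumes")
        X = np.column_stack([X, nuisance])
        names += [f"nuisance_{i}" for i in range(nuisance.shape[1])]
    X = np.column_stack([X, np.ones(n_volumes)])
    names.append("intercept")
    return DesignMatrix(X, names, tr)


def fit_glm(
    data: np.ndarray,
    design: DesignMatrix,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Ordinary least squares per voxel; returns the 24 state coefficients.

    ``data`` is either (T, V) or a 4-D volume (X, Y, Z, T); with a 4-D input
    and a boolean ``mask`` the result is (24, X, Y, Z) with NaN outside the
    mask, otherwise (24, V).
    """
    X = design.matrix
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns involved in the deficiency via QR pivoting
        _, r = np.linalg.qr(X)
        bad = [design.names[i] for i in np.where(np.abs(np.diag(r)) < 1e-8)[0]]
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"suspect columns: {bad}"
        )
    volumetric = data.ndim == 4
    if volumetric:
        if mask is None:
            mask = np.ones(data.shape[:3], dtype=bool)
        Y = data[mask].T  # T x V
    else:
        Y = data
    if Y.shape[0] != X.shape[0]:
        raise ValueError("data time dimension does not match the design")
    coefs, *_ = np.linalg.lstsq(X, Y, rcond=None)
    state_idx = [i for i, n in enumerate(design.names) if n.startswith("state_")]
    betas = coefs[state_idx]
    if volumetric:
        out = np.full((len(state_idx), *mask.shape), np.nan)
        out[:, mask] = betas
        return out
    return betas
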