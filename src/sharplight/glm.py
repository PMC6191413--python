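"""First-level GLM: HRF-convolved design matrices and OLS beta volumes.

One event regressor per stimulus × condition present in a run, locked to
observed-stimulus onset and modelled as a zero-duration impulse convolved
with the canonical double-gamma haemodynamic response function, plus a
linear drift and a constant. Ordinary least squares per voxel; no
temporal prewhitening (point estimates stay unbiased, and recovery — not
efficiency — is what downstream analyses consume).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import STIMULI
from .simulate import BetaSet, TimeSeriesDataset

# canonical double-gamma parameters: response gamma peaking near 5 s,
# undershoot gamma near 16 s weighted 1/6
_PEAK_SHAPE = 6.0
_UNDERSHOOT_SHAPE = 16.0
_RATE = 1.0
_UNDERSHOOT_RATIO = 1.0 / 6.0


def hrf(t: np.ndarray | float) -> np.ndarray:
    """Canonical double-gamma HRF evaluated in continuous time (s).

    Zero for t ≤ 0; peaks a little after 5 s; small negative undershoot
    that has essentially vanished by 30 s.
    """
    t = np.asarray(t, dtype=float)
    out = stats.gamma.pdf(t, _PEAK_SHAPE, scale=1.0 / _RATE) - _UNDERSHOOT_RATIO * stats.gamma.pdf(
        t, _UNDERSHOOT_SHAPE, scale=1.0 / _RATE
    )
    return np.where(t > 0, out, 0.0)


def hrf_kernel(tr_s: float, duration_s: float = 32.0) -> np.ndarray:
    """The HRF sampled at the scan interval, for discrete convolution."""
    if tr_s <= 0:
        raise ValueError("tr_s must be positive")
    return hrf(np.arange(0.0, duration_s, tr_s))


@dataclass
class DesignMatrix:
    """A run's design: scans × regressors with labelled columns.

    Event columns are labelled ``(run, condition, stimulus)``; nuisance
    columns are labelled by name (``"drift"``, ``"constant"`` plus any
    user-supplied extras).
    """

    matrix: np.ndarray
    labels: list[tuple[int, str, str] | str]
    run: int

    @property
    def event_labels(self) -> list[tuple[int, str, str]]:
        return [l for l in self.labels if isinstance(l, tuple)]


def build_design_matrix(
    events: pd.DataFrame,
    n_scans: int,
    tr_s: float,
    nuisance: np.ndarray | None = None,
) -> DesignMatrix:
    """Design matrix for one run of an events table.

    ``nuisance`` may supply extra columns (n_scans × k), e.g. motion
    parameters in real-data mode; a centred linear drift and a constant
    are always appended.
    """
    runs = sorted(events["run"].unique())
    if len(runs) != 1:
        raise ValueError(f"events span runs {runs}; build one design matrix per run")
    run = int(runs[0])
    t = np.arange(n_scans) * tr_s
    last = events["onset_s"].max()
    if last >= n_scans * tr_s:
        raise ValueError(f"last onset {last:.1f}s falls outside the run ({n_scans} scans × {tr_s}s)")

    cols, labels = [], []
    for (cond, stim), grp in events.groupby(["condition", "observed"], sort=True):
        reg = np.zeros(n_scans)
        for onset in grp["onset_s"].to_numpy(float):
            reg += hrf(t - onset)
        cols.append(reg)
        labels.append((run, cond, stim))
    if nuisance is not None:
        nuisance = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if nuisance.shape[0] != n_scans:
            raise ValueError("nuisance columns must have n_scans rows")
        for j in range(nuisance.shape[1]):
            cols.append(nuisance[:, j])
            labels.append(f"nuisance_{j}")
    cols.append(t - t.mean())
    labels.append("drift")
    cols.append(np.ones(n_scans))
    labels.append("constant")

    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"design matrix is rank deficient: {_collinear_columns(X, labels)}")
    return DesignMatrix(matrix=X, labels=labels, run=run)


def _collinear_columns(X: np.ndarray, labels: list) -> str:
    """Name columns implicated in a rank deficiency via pivoted QR."""
    from scipy.linalg import qr

    _, R, piv = qr(X, pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    bad = [labels[piv[i]] for i in range(len(diag)) if diag[i] < tol]
    bad += [labels[p] for p in piv[len(diag):]]
    return f"collinear columns {bad}"


def fit_glm(data: TimeSeriesDataset, designs: dict[int, DesignMatrix] | list[DesignMatrix]) -> BetaSet:
    """OLS per voxel per run; event coefficients become a BetaSet.

    Nuisance coefficients (drift, constant, extras) are estimated jointly
    but discarded from the returned set.
    """
    if not isinstance(designs, dict):
        designs = {d.run: d for d in designs}
    grid = data.grid
    mask = grid.mask
    out: dict[tuple[int, str, str], np.ndarray] = {}
    for run, vol in sorted(data.runs.items()):
        design = designs[run]
        X = design.matrix
        ns = vol.shape[-1]
        if X.shape[0] != ns:
            raise ValueError(f"run {run}: design has {X.shape[0]} rows but data has {ns} scans")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(f"run {run}: {_collinear_columns(X, design.labels)}")
        Y = vol[mask].T  # scans × voxels
        coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
        for j, label in enumerate(design.labels):
            if isinstance(label, tuple):
                beta = np.zeros(grid.shape)
                beta[mask] = coef[j]
                out[label] = beta
    return BetaSet(grid=grid, data=out, subject_id=data.subject_id)
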