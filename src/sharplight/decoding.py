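"""Searchlight decoding of observed-stimulus identity from beta patterns.

For every masked voxel, the beta values inside a sphere of configurable
radius (default 3 voxels, i.e. 9 mm at 3 mm resolution) form the feature
vectors of a linear soft-margin SVM (C = 1, no feature scaling) trained
to discriminate which stimulus — index or little finger movement — was
observed. Cross-validation is leave-one-run-out: with 8 runs each of the
8 folds trains on the 14 beta images from the other seven runs and tests
on the held-out run's two, so 16 images enter each condition-specific
analysis. The sphere-centre voxel receives the accuracy minus chance
(50%), yielding a per-subject, per-condition accuracy map.

The SVM is solved by scikit-learn's libsvm binding, called at the
low level (``sklearn.svm._libsvm``) so that the millions of tiny fits a
searchlight needs skip the estimator-API validation overhead; the
decision values are identical to ``SVC(kernel="linear", C=C)``. With a
zero decision value the tie breaks to the first stimulus label in sorted
order ("index"), matching the estimator's convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import _libsvm as libsvm

from .design import STIMULI
from .simulate import BetaSet, VolumeGrid

libsvm.set_verbosity_wrap(0)

CHANCE = 0.5


@dataclass
class Fold:
    """One leave-one-run-out split over (run, stimulus) items."""

    train_items: list[tuple[int, str]]
    test_items: list[tuple[int, str]]


@dataclass
class AccuracyMap:
    """Per-voxel decoding accuracy minus chance, for one condition."""

    grid: VolumeGrid
    volume: np.ndarray  # accuracy − chance; NaN outside the mask
    condition: str
    subject_id: str = "sub-01"
    chance: float = CHANCE

    def __post_init__(self) -> None:
        inside = self.volume[self.grid.mask]
        if inside.size and (np.nanmin(inside) < -self.chance - 1e-9 or np.nanmax(inside) > 1 - self.chance + 1e-9):
            raise ValueError("accuracy-minus-chance values fall outside [-0.5, 0.5]")


def sphere_offsets(radius_voxels: float) -> list[tuple[int, int, int]]:
    """Integer offsets (di, dj, dk) with ‖d‖ ≤ radius, centre included."""
    if radius_voxels < 0:
        raise ValueError("radius must be >= 0")
    r = int(np.floor(radius_voxels))
    r2 = radius_voxels**2
    return [
        (di, dj, dk)
        for di in range(-r, r + 1)
        for dj in range(-r, r + 1)
        for dk in range(-r, r + 1)
        if di * di + dj * dj + dk * dk <= r2
    ]


def make_folds(runs: list[int], stimuli: tuple[str, ...] = STIMULI) -> list[Fold]:
    """One fold per run: test on that run's items, train on all others."""
    runs = sorted(runs)
    if len(runs) < 2:
        raise ValueError(f"leave-one-run-out needs at least 2 runs, got {len(runs)}")
    folds = []
    for r in runs:
        folds.append(
            Fold(
                train_items=[(q, s) for q in runs if q != r for s in stimuli],
                test_items=[(r, s) for s in stimuli],
            )
        )
    return folds


def _svm_decision(X_train: np.ndarray, y01: np.ndarray, X_test: np.ndarray, C: float) -> np.ndarray:
    """Decision values matching SVC(kernel='linear', C=C): > 0 ⇒ class 1."""
    model = libsvm.fit(np.ascontiguousarray(X_train), y01, svm_type=0, kernel="linear", C=C)
    w = model[3] @ model[1]
    return -(X_test @ w.ravel()) - model[4][0]


def _decode_items(
    X: np.ndarray,
    y01: np.ndarray,
    fold_indices: list[tuple[np.ndarray, np.ndarray]],
    C: float,
) -> float:
    """Cross-validated accuracy over precomputed fold row indices."""
    correct = 0
    total = 0
    for train_idx, test_idx in fold_indices:
        dec = _svm_decision(X[train_idx], y01[train_idx], X[test_idx], C)
        pred = (dec > 0).astype(float)
        correct += int(np.sum(pred == y01[test_idx]))
        total += len(test_idx)
    return correct / total


def decode_neighbourhood(
    patterns: dict[tuple[int, str], np.ndarray],
    folds: list[Fold],
    C: float = 1.0,
) -> float:
    """Leave-one-run-out SVM accuracy for one set of item patterns.

    ``patterns`` maps (run, stimulus) to a feature vector; all vectors
    must be finite and of one length. Returns the fraction of correctly
    classified test items pooled over folds.
    """
    keys = sorted(patterns)
    X = np.asarray([patterns[k] for k in keys], dtype=float)
    if X.ndim != 2:
        raise ValueError("patterns must share a common feature length")
    if not np.all(np.isfinite(X)):
        raise ValueError("patterns contain non-finite features")
    labels = sorted({s for _, s in keys})
    y01 = np.asarray([float(labels.index(s)) for _, s in keys])
    row = {k: i for i, k in enumerate(keys)}
    fold_indices = [
        (
            np.asarray([row[k] for k in f.train_items]),
            np.asarray([row[k] for k in f.test_items]),
        )
        for f in folds
    ]
    return _decode_items(X, y01, fold_indices, C)


def searchlight_map(
    betas: BetaSet,
    condition: str,
    radius_voxels: float = 3.0,
    C: float = 1.0,
) -> AccuracyMap:
    """Accuracy-minus-chance map for one condition of a BetaSet.

    Spheres are truncated at the mask boundary (available voxels only).
    """
    grid = betas.grid
    patterns, keys = betas.stack(condition)  # items × masked voxels
    if not np.all(np.isfinite(patterns)):
        raise ValueError("beta patterns contain non-finite values")
    runs = sorted({r for r, _ in keys})
    folds = make_folds(runs)
    labels = sorted({s for _, s in keys})
    y01 = np.asarray([float(labels.index(s)) for _, s in keys])
    row = {k: i for i, k in enumerate(keys)}
    fold_indices = [
        (
            np.asarray([row[k] for k in f.train_items]),
            np.asarray([row[k] for k in f.test_items]),
        )
        for f in folds
    ]

    mask = grid.mask
    coords = np.argwhere(mask)
    col_of = -np.ones(grid.shape, dtype=int)
    col_of[mask] = np.arange(coords.shape[0])
    offsets = np.asarray(sphere_offsets(radius_voxels))

    volume = np.full(grid.shape, np.nan)
    shape = np.asarray(grid.shape)
    for v, (i, j, k) in enumerate(coords):
        nbr = offsets + (i, j, k)
        ok = np.all((nbr >= 0) & (nbr < shape), axis=1)
        nbr = nbr[ok]
        cols = col_of[nbr[:, 0], nbr[:, 1], nbr[:, 2]]
        cols = cols[cols >= 0]
        X = np.ascontiguousarray(patterns[:, cols])
        acc = _decode_items(X, y01, fold_indices, C)
        volume[i, j, k] = acc - CHANCE
    return AccuracyMap(grid=grid, volume=volume, condition=condition, subject_id=betas.subject_id)
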