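"""Synthetic voxel responses under sharpening, cancellation or null codes.

The generative model follows the population-code cartoon that motivates
the analysis: a voxel belongs to the *informative region* and prefers one
stimulus (index or little), responding with ``amp_preferred`` to its
preferred stimulus and ``amp_nonpreferred`` to the other, on top of a
``baseline``. Expectation (a congruent, i.e. expected, action outcome)
scales the evoked amplitude by ``gain`` ∈ (0, 1]:

* sharpening — gain applies when the observed stimulus is *not* the
  voxel's preferred one (suppression of units tuned away from the
  expected stimulus);
* cancellation — gain applies when the observed stimulus *is* preferred
  (suppression of units tuned toward the expected outcome);
* null — no congruency modulation.

Incongruent and no-move trials are never modulated: only the contrast
between congruent and incongruent is meaningful (a congruent suppression
is equivalent to an incongruent facilitation), and no-move trials carry
tuning signal only, so regions of interest can be defined from them
independently of any congruency effect.

Responses can be emitted directly as run-wise GLM coefficients
(:func:`simulate_betas`, noise shrinking with trials per cell as 1/√m) or
as HRF-convolved BOLD-like time series (:func:`simulate_timeseries`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import CONDITIONS, STIMULI

HYPOTHESES = ("sharpening", "cancellation", "null")


@dataclass
class VolumeGrid:
    """A small volumetric grid of isotropic voxels with an analysis mask."""

    shape: tuple[int, int, int]
    voxel_size_mm: float = 3.0
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.shape) != 3 or any(s <= 0 for s in self.shape):
            raise ValueError(f"shape must be three positive integers, got {self.shape}")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if self.mask is None:
            self.mask = np.ones(self.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.shape:
                raise ValueError("mask shape does not match grid shape")
        if not self.mask.any():
            raise ValueError("mask must contain at least one voxel")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def blob(center: tuple[int, int, int], radius: int, shape: tuple[int, int, int]) -> list[tuple[int, int, int]]:
    """Voxel coordinates of a compact cube-clipped ball, for informative regions."""
    cx, cy, cz = center
    out = []
    for i in range(max(0, cx - radius), min(shape[0], cx + radius + 1)):
        for j in range(max(0, cy - radius), min(shape[1], cy + radius + 1)):
            for k in range(max(0, cz - radius), min(shape[2], cz + radius + 1)):
                if (i - cx) ** 2 + (j - cy) ** 2 + (k - cz) ** 2 <= radius**2:
                    out.append((i, j, k))
    return out


@dataclass
class PopulationSpec:
    """Population code: who is tuned to what, and how expectation modulates it.

    ``preference_assignment`` maps informative voxel coordinates to their
    preferred stimulus; every other masked voxel responds at baseline to
    everything. Amplitudes are in arbitrary signal units.
    """

    informative_region: list[tuple[int, int, int]] = field(default_factory=list)
    preference_assignment: dict[tuple[int, int, int], str] = field(default_factory=dict)
    baseline: float = 100.0
    amp_preferred: float = 2.0
    amp_nonpreferred: float = 1.0
    gain: float = 0.7
    hypothesis: str = "sharpening"
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.hypothesis not in HYPOTHESES:
            raise ValueError(f"hypothesis must be one of {HYPOTHESES}, got {self.hypothesis!r}")
        if not self.amp_preferred > self.amp_nonpreferred:
            raise ValueError("amp_preferred must exceed amp_nonpreferred (voxels respond more to their preferred stimulus)")
        if self.amp_nonpreferred < 0:
            raise ValueError("amp_nonpreferred must be >= 0")
        if not 0 < self.gain <= 1:
            raise ValueError("gain must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        self.informative_region = [tuple(v) for v in self.informative_region]
        self.preference_assignment = {tuple(k): v for k, v in self.preference_assignment.items()}
        missing = [v for v in self.informative_region if v not in self.preference_assignment]
        if missing:
            raise ValueError(f"informative voxels without a preference assignment: {missing[:5]}")

    @classmethod
    def two_blobs(
        cls,
        grid: VolumeGrid,
        centers: tuple[tuple[int, int, int], tuple[int, int, int]] | None = None,
        radius: int = 2,
        seed: int = 0,
        **kwargs,
    ) -> "PopulationSpec":
        """Default spec: two compact informative blobs with 50/50 preference mix.

        Compact blobs give the group cluster inference a spatial target;
        the alternating preference assignment within each blob yields the
        mixed population that the tuning analysis classifies voxel by voxel.
        """
        nx, ny, nz = grid.shape
        if centers is None:
            centers = (
                (nx // 4, ny // 4, nz // 2),
                (3 * nx // 4, 3 * ny // 4, nz // 2),
            )
        voxels: list[tuple[int, int, int]] = []
        for c in centers:
            voxels.extend(v for v in blob(c, radius, grid.shape) if grid.mask[v])
        rng = np.random.default_rng(seed)
        prefs = {}
        for c in centers:
            bvox = [v for v in blob(c, radius, grid.shape) if grid.mask[v]]
            half = len(bvox) // 2
            labels = np.array(["index"] * half + ["little"] * (len(bvox) - half))
            rng.shuffle(labels)
            prefs.update(dict(zip(bvox, labels)))
        return cls(informative_region=voxels, preference_assignment=prefs, **kwargs)


def mean_response(pref: str | None, observed: str, condition: str, spec: PopulationSpec) -> float:
    """Noise-free voxel response for one trial type.

    ``pref`` is the voxel's preferred stimulus, or ``None`` for a
    non-informative voxel (which returns baseline for every input). The
    gain is applied only on congruent trials, to the tuned-away amplitude
    under sharpening and to the tuned-toward amplitude under cancellation.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if observed not in STIMULI:
        raise ValueError(f"unknown stimulus {observed!r}")
    if pref is None:
        return spec.baseline
    amp = spec.amp_preferred if observed == pref else spec.amp_nonpreferred
    g = 1.0
    if condition == "congruent" and spec.hypothesis == "sharpening" and observed != pref:
        g = spec.gain
    elif condition == "congruent" and spec.hypothesis == "cancellation" and observed == pref:
        g = spec.gain
    return spec.baseline + amp * g


def mean_response_volume(grid: VolumeGrid, spec: PopulationSpec, observed: str, condition: str) -> np.ndarray:
    """Vectorised :func:`mean_response` over the grid (masked-out voxels = 0)."""
    vol = np.zeros(grid.shape, dtype=float)
    vol[grid.mask] = spec.baseline
    for vox in spec.informative_region:
        if grid.mask[vox]:
            vol[vox] = mean_response(spec.preference_assignment[vox], observed, condition, spec)
    return vol


@dataclass
class BetaSet:
    """Run-wise coefficient volumes keyed by (run, condition, stimulus)."""

    grid: VolumeGrid
    data: dict[tuple[int, str, str], np.ndarray]
    subject_id: str = "sub-01"

    @property
    def runs(self) -> list[int]:
        return sorted({k[0] for k in self.data})

    @property
    def conditions(self) -> list[str]:
        return sorted({k[1] for k in self.data})

    def __getitem__(self, key: tuple[int, str, str]) -> np.ndarray:
        return self.data[key]

    def stack(self, condition: str, runs: list[int] | None = None) -> tuple[np.ndarray, list[tuple[int, str]]]:
        """Masked patterns for one condition: (items × voxels, item keys).

        Items are ordered (run, stimulus) with runs ascending and stimuli
        in canonical order, so an 8-run set yields 16 rows.
        """
        runs = self.runs if runs is None else runs
        keys = [(r, s) for r in runs for s in STIMULI]
        try:
            rows = [self.data[(r, condition, s)][self.grid.mask] for r, s in keys]
        except KeyError as e:
            raise KeyError(f"condition {condition!r} missing cell {e.args[0]} in BetaSet") from e
        return np.asarray(rows), keys


@dataclass
class TimeSeriesDataset:
    """Per-run 4D data (x, y, z, scan) with a fixed TR, on one grid."""

    grid: VolumeGrid
    runs: dict[int, np.ndarray]
    tr_s: float
    subject_id: str = "sub-01"

    def __post_init__(self) -> None:
        for run, vol in self.runs.items():
            if vol.shape[:3] != self.grid.shape:
                raise ValueError(f"run {run} data shape {vol.shape} does not match grid {self.grid.shape}")
            if not np.all(np.isfinite(vol)):
                raise ValueError(f"run {run} contains non-finite values")


def _cells_of(design_run: pd.DataFrame) -> dict[tuple[str, str], pd.DataFrame]:
    return {
        (cond, stim): grp
        for (cond, stim), grp in design_run.groupby(["condition", "observed"], sort=True)
    }


def simulate_betas(
    design: pd.DataFrame,
    grid: VolumeGrid,
    spec: PopulationSpec,
    seed: int = 0,
    conditions: tuple[str, ...] = CONDITIONS,
) -> BetaSet:
    """Draw run-wise betas directly: cell mean response plus Normal noise.

    The noise SD per beta is ``noise_sd / sqrt(m)`` with ``m`` the number
    of trials in that run × condition × stimulus cell, emulating the
    variance reduction a GLM gains from averaging over within-run
    repetitions. A run with an empty requested cell is an error.
    """
    rng = np.random.default_rng(seed)
    data: dict[tuple[int, str, str], np.ndarray] = {}
    runs = sorted(design["run"].unique())
    for run in runs:
        cells = _cells_of(design[design["run"] == run])
        for cond in conditions:
            for stim in STIMULI:
                if (cond, stim) not in cells:
                    raise ValueError(
                        f"design has no trials for run {run}, condition {cond!r}, stimulus {stim!r}"
                    )
                m = len(cells[(cond, stim)])
                mean = mean_response_volume(grid, spec, stim, cond)
                noise = rng.normal(0.0, spec.noise_sd / np.sqrt(m), size=grid.shape)
                vol = mean + noise
                vol[~grid.mask] = 0.0
                data[(int(run), cond, stim)] = vol
    subject = str(design["subject_id"].iloc[0]) if "subject_id" in design else "sub-01"
    return BetaSet(grid=grid, data=data, subject_id=subject)


def simulate_timeseries(
    design: pd.DataFrame,
    grid: VolumeGrid,
    spec: PopulationSpec,
    tr_s: float = 3.36,
    seed: int = 0,
    drift_slope: float = 0.0,
    hrf_tail_s: float = 32.0,
    n_scans: int | None = None,
) -> TimeSeriesDataset:
    """Generate BOLD-like runs: evoked amplitudes × HRF + drift + noise.

    Each trial contributes its cell's evoked amplitude (mean response
    minus baseline) times a canonical double-gamma HRF locked to the
    observed-stimulus onset, evaluated in continuous time at scan times;
    the constant baseline and an optional linear drift ride on top.
    Noise is white Normal with SD ``spec.noise_sd`` per scan.
    """
    from .glm import hrf  # late import to avoid a cycle

    rng = np.random.default_rng(seed)
    runs: dict[int, np.ndarray] = {}
    for run in sorted(design["run"].unique()):
        dr = design[design["run"] == run]
        onsets = dr["onset_s"].to_numpy(float)
        needed = int(np.ceil((onsets.max() + hrf_tail_s) / tr_s)) + 1
        ns = needed if n_scans is None else int(n_scans)
        if ns * tr_s <= onsets.max():
            raise ValueError(
                f"run {run}: duration {ns * tr_s:.1f}s shorter than last onset {onsets.max():.1f}s"
            )
        t = np.arange(ns) * tr_s
        data = np.zeros(grid.shape + (ns,), dtype=float)
        # per-cell regressor shared by all voxels; amplitudes vary by voxel
        for (cond, stim), grp in dr.groupby(["condition", "observed"], sort=True):
            reg = np.zeros(ns)
            for onset in grp["onset_s"]:
                reg += hrf(t - onset)
            amp = mean_response_volume(grid, spec, stim, cond) - spec.baseline * grid.mask
            data += amp[..., None] * reg[None, None, None, :]
        data += (spec.baseline * grid.mask)[..., None]
        data += drift_slope * t[None, None, None, :] * grid.mask[..., None]
        data += rng.normal(0.0, spec.noise_sd, size=data.shape) * grid.mask[..., None]
        runs[int(run)] = data
    subject = str(design["subject_id"].iloc[0]) if "subject_id" in design else "sub-01"
    return TimeSeriesDataset(grid=grid, runs=runs, tr_s=tr_s, subject_id=subject)


def pattern_separation(spec: PopulationSpec, condition: str) -> float:
    """Euclidean distance between the two stimulus mean patterns.

    Computed analytically over informative voxels from :func:`mean_response`;
    this is the quantity the competing hypotheses order oppositely:
    sharpening widens it on congruent trials, cancellation narrows it.
    """
    sq = 0.0
    for vox in spec.informative_region:
        pref = spec.preference_assignment[vox]
        d = mean_response(pref, "index", condition, spec) - mean_response(pref, "little", condition, spec)
        sq += d * d
    return float(np.sqrt(sq))
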