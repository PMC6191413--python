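"""Group cluster inference: smoothing, one-sample t maps, ROI definition.

Per-subject no-move accuracy maps are Gaussian-smoothed, combined into a
group one-sample t map (is decoding above chance?), thresholded at an
uncorrected height threshold (default p < 0.001 one-sided), and the
surviving connected components are kept only if their size exceeds an
extent threshold controlling family-wise error (default p < 0.05). The
extent threshold is calibrated by a sign-flip permutation of the
max-cluster-size statistic — exact under a symmetric null — rather than
random-field theory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .decoding import AccuracyMap
from .simulate import VolumeGrid


@dataclass
class Cluster:
    label: str
    voxels: list[tuple[int, int, int]]
    size: int
    peak_t: float
    peak_voxel: tuple[int, int, int] = (0, 0, 0)


@dataclass
class ClusterSet:
    """Disjoint suprathreshold clusters surviving the extent threshold."""

    clusters: list[Cluster] = field(default_factory=list)
    extent_cutoff: float = 0.0
    t_threshold: float = float("nan")

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    def labelled_volume(self, shape: tuple[int, int, int]) -> np.ndarray:
        """Integer-labelled volume: cluster i+1 at its voxels, 0 elsewhere."""
        vol = np.zeros(shape, dtype=int)
        for i, cl in enumerate(self.clusters, start=1):
            for vox in cl.voxels:
                vol[vox] = i
        return vol

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"label": c.label, "size": c.size, "peak_t": c.peak_t} for c in self.clusters]
        )


def smooth_map(amap: AccuracyMap, fwhm_mm: float) -> AccuracyMap:
    """Gaussian-smooth an accuracy map (σ = FWHM / 2√(2 ln 2), voxel units).

    Boundary mode is zero padding (``mode="constant"``): interior values
    of a constant map are unchanged and the mass of an interior impulse
    is preserved, while map edges are attenuated. Voxels outside the mask
    contribute zero and stay NaN in the output.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return AccuracyMap(
            grid=amap.grid,
            volume=amap.volume.copy(),
            condition=amap.condition,
            subject_id=amap.subject_id,
            chance=amap.chance,
        )
    sigma_vox = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / amap.grid.voxel_size_mm
    filled = np.where(amap.grid.mask, np.nan_to_num(amap.volume), 0.0)
    sm = ndimage.gaussian_filter(filled, sigma=sigma_vox, mode="constant", cval=0.0)
    out = np.where(amap.grid.mask, sm, np.nan)
    return AccuracyMap(
        grid=amap.grid, volume=out, condition=amap.condition, subject_id=amap.subject_id, chance=amap.chance
    )


def group_t_map(maps: list[AccuracyMap]) -> np.ndarray:
    """One-sample t of accuracy-minus-chance against zero, per voxel.

    df = n_subjects − 1; intended one-sided (above chance). Voxels with
    zero across-subject variance get t = 0 (the flagging convention for
    the degenerate case); voxels outside the common mask are NaN.
    """
    if len(maps) < 2:
        raise ValueError("group t map needs at least 2 subjects")
    grid = maps[0].grid
    for m in maps[1:]:
        if m.grid.shape != grid.shape:
            raise ValueError("subject maps are not on a common grid")
    data = np.stack([m.volume for m in maps])  # subjects × x × y × z
    n = data.shape[0]
    t = _one_sample_t(data, n)
    t[~grid.mask] = np.nan
    return t


def _one_sample_t(data: np.ndarray, n: int) -> np.ndarray:
    """Voxel-wise one-sample t with zero-variance voxels flagged as t = 0.

    "Zero" variance is judged relative to the mean's magnitude so that
    numerically identical subject values (e.g. a constant map) do not
    explode through rounding residue.
    """
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    degenerate = sd <= 1e-12 * np.maximum(1.0, np.abs(mean))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    return np.where(degenerate, 0.0, t)


def _connectivity(connectivity: int) -> np.ndarray:
    order = {6: 1, 18: 2, 26: 3}
    if connectivity not in order:
        raise ValueError("connectivity must be 6, 18 or 26")
    return ndimage.generate_binary_structure(3, order[connectivity])


def _cluster_sizes(t: np.ndarray, threshold: float, structure: np.ndarray) -> tuple[np.ndarray, int, np.ndarray]:
    supra = np.nan_to_num(t, nan=-np.inf) > threshold
    labelled, n = ndimage.label(supra, structure=structure)
    if n == 0:
        return labelled, 0, np.zeros(0, dtype=int)
    sizes = np.bincount(labelled.ravel())[1:]
    return labelled, n, sizes


def define_rois(
    maps: list[AccuracyMap],
    height_p: float = 0.001,
    extent_fwe_p: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    connectivity: int = 26,
    restrict_mask: np.ndarray | None = None,
) -> ClusterSet:
    """Height + permutation-calibrated extent thresholding of the group map.

    Steps: group t map → one-sided height threshold at the t quantile for
    ``height_p`` → connected components (default 26-connectivity) → null
    distribution of the maximum cluster size from ``n_perm`` random
    sign-flips of the subject maps → keep clusters whose permutation
    p-value ``(1 + #{null ≥ size}) / (n_perm + 1)`` is ≤ ``extent_fwe_p``.
    An empty result is a legitimate outcome, not an error.
    ``restrict_mask`` optionally limits the analysis to a subregion
    (the stand-in for an anatomical search volume).
    """
    if not 0 < height_p < 0.5:
        raise ValueError("height_p must lie in (0, 0.5) to act as a one-sided height threshold")
    if not 0 < extent_fwe_p < 1:
        raise ValueError("extent_fwe_p must lie in (0, 1)")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a usable extent null")
    n = len(maps)
    df = n - 1
    t_thresh = float(stats.t.ppf(1.0 - height_p, df))
    structure = _connectivity(connectivity)

    data = np.stack([m.volume for m in maps])
    if restrict_mask is not None:
        data = np.where(np.asarray(restrict_mask, bool)[None], data, np.nan)

    def tmap(d: np.ndarray) -> np.ndarray:
        return _one_sample_t(d, n)

    t_obs = tmap(data)
    labelled, n_clust, sizes = _cluster_sizes(t_obs, t_thresh, structure)

    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    for p in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=n)
        _, _, psizes = _cluster_sizes(tmap(data * signs[:, None, None, None]), t_thresh, structure)
        null_max[p] = psizes.max() if psizes.size else 0

    clusters = []
    order = np.argsort(sizes)[::-1]
    for rank, ci in enumerate(order, start=1):
        size = int(sizes[ci])
        p_clust = (1 + np.sum(null_max >= size)) / (n_perm + 1)
        if p_clust <= extent_fwe_p:
            voxmask = labelled == ci + 1
            voxels = [tuple(v) for v in np.argwhere(voxmask)]
            masked_t = np.where(voxmask, t_obs, -np.inf)
            peak_voxel = tuple(int(x) for x in np.unravel_index(np.nanargmax(masked_t), masked_t.shape))
            clusters.append(
                Cluster(
                    label=f"c{rank}",
                    voxels=voxels,
                    size=size,
                    peak_t=float(masked_t[peak_voxel]),
                    peak_voxel=peak_voxel,
                )
            )
    cutoff = float(np.quantile(null_max, 1 - extent_fwe_p)) if n_perm else 0.0
    return ClusterSet(clusters=clusters, extent_cutoff=cutoff, t_threshold=t_thresh)
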