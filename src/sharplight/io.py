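"""Volume and manifest I/O: NIfTI for images, JSON manifests, TSV tables."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .cluster import ClusterSet
from .decoding import AccuracyMap
from .simulate import BetaSet, VolumeGrid


def _affine(voxel_size_mm: float) -> np.ndarray:
    return np.diag([voxel_size_mm, voxel_size_mm, voxel_size_mm, 1.0])


def save_volume(volume: np.ndarray, grid: VolumeGrid, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float64), _affine(grid.voxel_size_mm))
    nib.save(img, str(path))


def load_volume(path: str | Path) -> tuple[np.ndarray, float]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), float(abs(img.affine[0, 0]))


def load_timeseries(
    run_paths: dict[int, str | Path],
    tr_s: float,
    subject_id: str = "sub-01",
    mask_path: str | Path | None = None,
) -> "TimeSeriesDataset":
    """Real-data mode: one 4D NIfTI per run (x, y, z, scan) on a shared grid."""
    from .simulate import TimeSeriesDataset

    runs = {}
    voxel_size = None
    for run, path in sorted(run_paths.items()):
        vol, vs = load_volume(path)
        if vol.ndim != 4:
            raise ValueError(f"run {run}: expected a 4D volume, got shape {vol.shape}")
        runs[int(run)] = vol
        voxel_size = vs if voxel_size is None else voxel_size
    shape = next(iter(runs.values())).shape[:3]
    if mask_path is not None:
        mask, _ = load_volume(mask_path)
        mask = mask.astype(bool)
    else:
        mask = np.ones(shape, dtype=bool)
    grid = VolumeGrid(shape=shape, voxel_size_mm=voxel_size or 3.0, mask=mask)
    return TimeSeriesDataset(grid=grid, runs=runs, tr_s=tr_s, subject_id=subject_id)


def save_betaset(betas: BetaSet, out_dir: str | Path) -> Path:
    """One NIfTI per (run, condition, stimulus) plus a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    for (run, cond, stim), vol in sorted(betas.data.items()):
        name = f"beta_run-{run:02d}_{cond}_{stim}.nii"
        save_volume(vol, betas.grid, out / name)
        files[f"{run}|{cond}|{stim}"] = name
    mask_name = "mask.nii"
    save_volume(betas.grid.mask.astype(np.uint8), betas.grid, out / mask_name)
    manifest = {
        "subject_id": betas.subject_id,
        "voxel_size_mm": betas.grid.voxel_size_mm,
        "shape": list(betas.grid.shape),
        "mask": mask_name,
        "betas": files,
    }
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    return mpath


def load_betaset(manifest_path: str | Path) -> BetaSet:
    mpath = Path(manifest_path)
    if mpath.is_dir():
        mpath = mpath / "manifest.json"
    manifest = json.loads(mpath.read_text())
    base = mpath.parent
    mask, _ = load_volume(base / manifest["mask"])
    grid = VolumeGrid(
        shape=tuple(manifest["shape"]),
        voxel_size_mm=manifest["voxel_size_mm"],
        mask=mask.astype(bool),
    )
    data = {}
    for key, name in manifest["betas"].items():
        run, cond, stim = key.split("|")
        vol, _ = load_volume(base / name)
        data[(int(run), cond, stim)] = vol
    return BetaSet(grid=grid, data=data, subject_id=manifest["subject_id"])


def save_accuracy_map(amap: AccuracyMap, path: str | Path) -> None:
    save_volume(amap.volume, amap.grid, path)


def load_accuracy_map(path: str | Path, grid: VolumeGrid, condition: str, subject_id: str = "sub-01") -> AccuracyMap:
    vol, _ = load_volume(path)
    return AccuracyMap(grid=grid, volume=vol, condition=condition, subject_id=subject_id)


def save_clusters(rois: ClusterSet, grid: VolumeGrid, out_dir: str | Path) -> None:
    """Integer-labelled cluster volume plus a TSV cluster table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_volume(rois.labelled_volume(grid.shape).astype(np.int16), grid, out / "clusters.nii")
    table = rois.table()
    table["peak_voxel"] = ["{} {} {}".format(*cl.peak_voxel) for cl in rois]
    table.to_csv(out / "clusters.tsv", sep="\t", index=False)
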