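"""Readers and writers: NIfTI / TSV BOLD data, truth tables, fit tables.

TSV (tab-separated, UTF-8, '.' decimal) is the canonical tabular dialect.
Synthetic datasets round-trip through a directory of
``bold.nii.gz`` (voxel strip reshaped into a small 3D grid x time),
``truth.tsv`` and ``designs.json``.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .fitting import ModelComparison, VoxelFitResult
from .prf_model import PRFParameters
from .space import design_from_json
from .synthetic import GroundTruthVoxel, SyntheticDataset

__all__ = [
    "read_bold",
    "write_bold_nifti",
    "write_bold_tsv",
    "save_dataset",
    "load_dataset",
    "fits_to_frame",
    "write_fits_tsv",
    "read_fits_tsv",
]

logger = logging.getLogger(__name__)

TRUTH_COLUMNS = ["voxel_id", "roi", "x_mm", "y_mm", "z_mm", "model",
                 "x0", "y0", "sigma_x", "sigma_y", "sigma_d",
                 "beta_e", "beta_i", "baseline", "noise_sd", "drift_amplitude"]


def _grid_shape(n_voxels: int) -> tuple[int, int, int]:
    nx = min(n_voxels, 16)
    ny = int(np.ceil(n_voxels / nx))
    return nx, ny, 1


def write_bold_nifti(bold: np.ndarray, path: str | Path, tr: float) -> None:
    """Write a voxel x time matrix as 4D NIfTI-1 (strip folded into 3D)."""
    n_vox, n_time = bold.shape
    nx, ny, nz = _grid_shape(n_vox)
    vol = np.full((nx * ny * nz, n_time), np.nan, dtype=np.float64)
    vol[:n_vox] = bold
    data = vol.reshape(ny, nx, nz, n_time).transpose(1, 0, 2, 3)
    img = nib.Nifti1Image(data, affine=np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, tr))
    nib.save(img, str(path))


def write_bold_tsv(bold: np.ndarray, path: str | Path) -> None:
    """Write a voxel x time matrix as TSV with t<i> column headers."""
    df = pd.DataFrame(bold, columns=[f"t{j}" for j in range(bold.shape[1])])
    df.insert(0, "voxel_id", np.arange(bold.shape[0]))
    df.to_csv(path, sep="\t", index=False)


def read_bold(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a voxel x time BOLD matrix from 4D NIfTI-1 or TSV.

    NIfTI voxels are flattened in the same order ``write_bold_nifti`` uses;
    all-NaN voxels (padding or masked) are dropped with a logged count.
    Returns the matrix and metadata (tr when available, voxel count).
    """
    path = Path(path)
    if path.suffix in (".nii", ".gz") or path.name.endswith(".nii.gz"):
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if data.ndim != 4:
            raise ValueError(f"expected 4D time-series NIfTI, got {data.ndim}D")
        nx, ny, nz, n_time = data.shape
        mat = data.transpose(1, 0, 2, 3).reshape(nx * ny * nz, n_time)
        keep = ~np.all(np.isnan(mat), axis=1)
        dropped = int((~keep).sum())
        if dropped:
            logger.info("dropped %d masked/NaN voxels", dropped)
        tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else None
        return mat[keep], {"tr": tr, "n_voxels": int(keep.sum())}
    df = pd.read_csv(path, sep="\t")
    cols = [c for c in df.columns if c != "voxel_id"]
    mat = df[cols].to_numpy(dtype=float)
    return mat, {"tr": None, "n_voxels": mat.shape[0]}


def _truth_frame(truth: Sequence[GroundTruthVoxel]) -> pd.DataFrame:
    rows = []
    for t in truth:
        p = t.true_params
        rows.append({
            "voxel_id": t.voxel_id, "roi": t.roi_label,
            "x_mm": t.anat_xyz[0], "y_mm": t.anat_xyz[1], "z_mm": t.anat_xyz[2],
            "model": p.model, "x0": p.x0, "y0": p.y0,
            "sigma_x": p.sigma_x, "sigma_y": p.sigma_y, "sigma_d": p.sigma_d,
            "beta_e": p.beta_e, "beta_i": p.beta_i, "baseline": p.baseline,
            "noise_sd": t.noise_sd, "drift_amplitude": t.drift_amplitude,
        })
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def save_dataset(ds: SyntheticDataset, outdir: str | Path) -> Path:
    """Write a synthetic dataset (NIfTI + truth TSV + design JSON) to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_bold_nifti(ds.bold, outdir / "bold.nii.gz", ds.tr)
    _truth_frame(ds.truth).to_csv(outdir / "truth.tsv", sep="\t", index=False,
                                  float_format="%.17g")
    specs = [d.to_dict() for d in ds.designs]
    (outdir / "designs.json").write_text(json.dumps(
        {"designs": specs, "seed": ds.seed, "tr": ds.tr}, indent=2))
    return outdir


def load_dataset(indir: str | Path) -> SyntheticDataset:
    """Round-trip reader for :func:`save_dataset`."""
    indir = Path(indir)
    meta = json.loads((indir / "designs.json").read_text())
    designs = [design_from_json(json.dumps(spec)) for spec in meta["designs"]]
    bold, _ = read_bold(indir / "bold.nii.gz")
    df = pd.read_csv(indir / "truth.tsv", sep="\t", float_precision="round_trip")
    truth = []
    for _, row in df.iterrows():
        params = PRFParameters(
            model=row["model"], x0=row["x0"], y0=row["y0"],
            sigma_x=row["sigma_x"], sigma_y=row["sigma_y"],
            sigma_d=row["sigma_d"], beta_e=row["beta_e"],
            beta_i=row["beta_i"], baseline=row["baseline"],
        )
        truth.append(GroundTruthVoxel(
            voxel_id=int(row["voxel_id"]),
            anat_xyz=(row["x_mm"], row["y_mm"], row["z_mm"]),
            roi_label=row["roi"], true_params=params,
            noise_sd=row["noise_sd"], drift_amplitude=row["drift_amplitude"],
        ))
    return SyntheticDataset(bold=bold, designs=designs, truth=truth,
                            seed=int(meta["seed"]), tr=float(meta["tr"]))


FIT_COLUMNS = ["voxel_id", "model", "x0", "y0", "sigma_x", "sigma_y", "sigma_d",
               "beta_e", "beta_i", "baseline", "free_energy",
               "posterior_model_prob", "r_fit", "converged"]


def fits_to_frame(fits: Sequence[VoxelFitResult],
                  comparisons: Sequence[ModelComparison] | None = None) -> pd.DataFrame:
    rows = []
    verdicts = {c.voxel_id: c.verdict for c in comparisons} if comparisons else {}
    for f in fits:
        p = f.params
        rows.append({
            "voxel_id": f.voxel_id, "model": f.model,
            "x0": p.x0, "y0": p.y0, "sigma_x": p.sigma_x, "sigma_y": p.sigma_y,
            "sigma_d": p.sigma_d, "beta_e": p.beta_e, "beta_i": p.beta_i,
            "baseline": p.baseline, "free_energy": f.free_energy,
            "posterior_model_prob": f.posterior_model_prob,
            "r_fit": f.r_fit, "converged": f.converged,
            "verdict": verdicts.get(f.voxel_id, ""),
        })
    return pd.DataFrame(rows, columns=FIT_COLUMNS + ["verdict"])


def write_fits_tsv(fits: Sequence[VoxelFitResult], path: str | Path,
                   comparisons: Sequence[ModelComparison] | None = None) -> None:
    fits_to_frame(fits, comparisons).to_csv(path, sep="\t", index=False,
                                            float_format="%.17g")


def read_fits_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")
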