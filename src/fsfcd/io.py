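"""NIfTI / TSV / JSON input-output and run manifests.

Volumes are NIfTI-1 with a diagonal affine built from the voxel size; masked
values are placed at their grid coordinates with NaN background.  Voxel
ordering everywhere is ascending linear index, x fastest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import MaskedBoldSeries, mask_coordinates
from .fcd import FcdMap

log = logging.getLogger("fsfcd")


def _affine(voxel_size_mm) -> np.ndarray:
    return np.diag(list(voxel_size_mm) + [1.0])


def save_series_nifti(series: MaskedBoldSeries, path) -> None:
    """Write a subject's 4-D volume (zeros outside the mask)."""
    vol = series.to_volume(fill=0.0)
    img = nib.Nifti1Image(vol.astype(np.float64), _affine(series.voxel_size_mm))
    img.header.set_zooms(tuple(series.voxel_size_mm) + (series.tr_s,))
    nib.save(img, str(path))


def save_mask_nifti(mask: np.ndarray, voxel_size_mm, path) -> None:
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), _affine(voxel_size_mm))
    nib.save(img, str(path))


def save_fcd_map_nifti(fcd_map: FcdMap, path) -> None:
    img = nib.Nifti1Image(
        fcd_map.to_volume(fill=np.nan), _affine(fcd_map.voxel_size_mm)
    )
    nib.save(img, str(path))


def load_bold(
    nifti_path, mask_path, tr_s: float | None = None, subject_id: str | None = None
) -> MaskedBoldSeries:
    """Extract a masked voxel-by-time matrix from a 4-D NIfTI + binary mask.

    The image and mask must share grid and affine (within tolerance); the
    mask must be binary.  Zero-variance voxels are dropped with a logged
    count.  TR is read from the time-axis zoom unless overridden.
    """
    img = nib.load(str(nifti_path))
    msk = nib.load(str(mask_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected a 4-D image, got shape {data.shape}")
    mvol = np.asarray(msk.dataobj, dtype=float)
    if mvol.ndim != 3:
        raise ValueError(f"expected a 3-D mask, got shape {mvol.shape}")
    if data.shape[:3] != mvol.shape:
        raise ValueError(
            f"grid mismatch: image {data.shape[:3]} vs mask {mvol.shape}"
        )
    if not np.allclose(img.affine, msk.affine, atol=1e-4):
        raise ValueError("image and mask affines differ")
    uniq = np.unique(mvol)
    if not np.all(np.isin(uniq, (0.0, 1.0))):
        raise ValueError(f"mask is not binary (values {uniq[:5]})")
    mask = mvol > 0
    if not mask.any():
        raise ValueError("mask selects no voxels")
    coords = mask_coordinates(mask)
    rows = data[tuple(coords.T)]
    sd = rows.std(axis=1)
    keep = sd > 0
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("dropping %d zero-variance voxels", n_drop)
    if tr_s is None:
        zooms = img.header.get_zooms()
        tr_s = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    if subject_id is None:
        subject_id = Path(nifti_path).stem.replace(".nii", "")
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return MaskedBoldSeries(
        data=rows[keep],
        voxel_index=coords[keep],
        tr_s=tr_s,
        subject_id=subject_id,
        grid_shape=tuple(int(s) for s in data.shape[:3]),
        voxel_size_mm=voxel_size,
        provenance=[f"load_bold(dropped={n_drop})"],
    )


def fcd_long_table(maps: list) -> pd.DataFrame:
    """Long-format export of FCD maps: subject, band, kind, stage, voxel, value."""
    rows = []
    for m in maps:
        for vi, val in enumerate(m.values):
            rows.append(
                {
                    "subject_id": m.subject_id,
                    "band": m.band,
                    "kind": m.kind,
                    "stage": m.stage,
                    "voxel": vi,
                    "value": val,
                }
            )
    return pd.DataFrame(rows)


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_manifest(out_dir, config: dict, seed: int, entries: dict) -> Path:
    """Record the run's config hash, seed and per-stage artifacts/QC."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "config_hash": config_hash(config),
        "seed": seed,
        "config": config,
        "stages": entries,
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
    return path
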