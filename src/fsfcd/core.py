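"""Core containers shared across the pipeline.

A subject's data lives as a masked matrix of voxel time series: one row per
gray-matter voxel, one column per retained volume.  The 3-D grid geometry
(shape, voxel size) travels with the matrix so that maps derived from it can
be re-embedded into volumes for smoothing, cluster labeling, and NIfTI export.

Voxel ordering is fixed project-wide: ascending linear index with x fastest,
``lin = x + nx * (y + ny * z)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


def linear_index(coords: np.ndarray, grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Linear voxel index (x fastest) for an (V, 3) array of grid coordinates."""
    coords = np.asarray(coords, dtype=np.intp)
    nx, ny, _ = grid_shape
    return coords[:, 0] + nx * (coords[:, 1] + ny * coords[:, 2])


def mask_coordinates(mask: np.ndarray) -> np.ndarray:
    """(V, 3) coordinates of True voxels in project voxel order."""
    coords = np.argwhere(mask)
    shape = mask.shape
    order = np.argsort(linear_index(coords, shape), kind="stable")
    return coords[order]


@dataclass
class MaskedBoldSeries:
    """Per-subject voxel time series restricted to a mask.

    Parameters
    ----------
    data : (n_voxels, n_timepoints) float array
        Signal amplitude in arbitrary units.
    voxel_index : (n_voxels, 3) int array
        Grid coordinate of each row, in fixed ascending-linear-index order.
    tr_s : float
        Repetition time in seconds.
    subject_id : str
    grid_shape : 3-tuple of int
    voxel_size_mm : 3-tuple of float
    provenance : list of str
        Names of processing steps already applied, in order.
    """

    data: np.ndarray
    voxel_index: np.ndarray
    tr_s: float
    subject_id: str
    grid_shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.voxel_index = np.asarray(self.voxel_index, dtype=np.intp)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (voxels x timepoints)")
        if self.voxel_index.shape != (self.data.shape[0], 3):
            raise ValueError("voxel_index must be (n_voxels, 3) and match data rows")
        if np.any(self.voxel_index < 0) or np.any(
            self.voxel_index >= np.asarray(self.grid_shape)
        ):
            raise ValueError("voxel_index out of grid bounds")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    @property
    def nyquist_hz(self) -> float:
        return 0.5 / self.tr_s

    def with_data(self, data: np.ndarray, step: str | None = None) -> "MaskedBoldSeries":
        """Copy carrying new data and an optional provenance entry."""
        prov = list(self.provenance) + ([step] if step else [])
        return replace(self, data=np.asarray(data, dtype=float), provenance=prov)

    def to_volume(self, fill: float = np.nan) -> np.ndarray:
        """Embed as a 4-D (x, y, z, t) array with `fill` outside the mask."""
        vol = np.full(self.grid_shape + (self.n_timepoints,), fill, dtype=float)
        vol[tuple(self.voxel_index.T)] = self.data
        return vol

    def mask_volume(self) -> np.ndarray:
        vol = np.zeros(self.grid_shape, dtype=bool)
        vol[tuple(self.voxel_index.T)] = True
        return vol
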