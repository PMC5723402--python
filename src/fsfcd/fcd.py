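"""Voxelwise functional connectivity density (FCD) mapping.

Two voxels are functionally connected when their Pearson correlation exceeds
the threshold (strictly; default 0.6).  Global FCD counts a voxel's
connections to every other mask voxel.  Short-range FCD counts connections
from the seed to its local cluster, grown by a region-growing search: start
from the seed and repeatedly absorb any voxel that is a spatial neighbor
(6/18/26-connectivity, default 26) of a cluster member AND correlated with
the seed above threshold.  Long-range FCD is global minus short-range, so
short + long = global is an exact integer identity at the raw-count stage.

Maps are z-scored within the mask per subject (population-SD convention by
default) and smoothed with a Gaussian kernel parameterized by FWHM, computed
on the full grid with zeros outside the mask and renormalized by the smoothed
mask so a constant map stays constant inside the mask.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import MaskedBoldSeries

FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))


@dataclass
class FcdConfig:
    threshold: float = 0.6  # strict: r > threshold
    connectivity: int = 26  # 6, 18 or 26 spatial neighbors
    smooth_fwhm_mm: float = 6.0
    zscore_ddof: int = 0  # population SD; 1 for sample SD

    def __post_init__(self):
        if not (0 < self.threshold < 1):
            raise ValueError("threshold must be in (0, 1)")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")


@dataclass
class FcdMap:
    """Per-mask-voxel scalar map tagged with its provenance."""

    values: np.ndarray
    voxel_index: np.ndarray
    grid_shape: tuple
    voxel_size_mm: tuple
    kind: str  # "global" | "short" | "long"
    stage: str  # "raw_count" | "zscored" | "smoothed"
    band: str = ""
    subject_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.voxel_index = np.asarray(self.voxel_index, dtype=np.intp)
        if self.values.shape[0] != self.voxel_index.shape[0]:
            raise ValueError("values and voxel_index length mismatch")

    def to_volume(self, fill: float = np.nan) -> np.ndarray:
        vol = np.full(self.grid_shape, fill, dtype=float)
        vol[tuple(self.voxel_index.T)] = self.values
        return vol


def neighbor_offsets(connectivity: int) -> np.ndarray:
    """Offsets of the 6-, 18- or 26-neighborhood."""
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                order = abs(dx) + abs(dy) + abs(dz)
                if order == 0:
                    continue
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offs.append((dx, dy, dz))
    return np.asarray(offs, dtype=int)


def correlation_matrix(series: MaskedBoldSeries) -> np.ndarray:
    """All-pairs Pearson correlation of voxel rows; rejects flat voxels."""
    data = series.data
    if data.shape[0] < 2:
        raise ValueError("need at least 2 voxels")
    sd = data.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise ValueError(
            f"zero-variance voxels present (rows {flat[:10].tolist()}); "
            "mask them out before FCD"
        )
    z = (data - data.mean(axis=1, keepdims=True)) / sd[:, None]
    return (z @ z.T) / data.shape[1]


def neighbor_lists(voxel_index: np.ndarray, connectivity: int) -> list:
    """Row indices of the in-mask spatial neighbors of every voxel."""
    lut = {tuple(c): i for i, c in enumerate(voxel_index)}
    offs = neighbor_offsets(connectivity)
    out = []
    for c in voxel_index:
        nbs = []
        for o in offs:
            j = lut.get((c[0] + o[0], c[1] + o[1], c[2] + o[2]))
            if j is not None:
                nbs.append(j)
        out.append(np.asarray(nbs, dtype=np.intp))
    return out


def _map_from(series: MaskedBoldSeries, values, kind, band) -> FcdMap:
    return FcdMap(
        values=values,
        voxel_index=series.voxel_index,
        grid_shape=series.grid_shape,
        voxel_size_mm=series.voxel_size_mm,
        kind=kind,
        stage="raw_count",
        band=band,
        subject_id=series.subject_id,
    )


def global_fcd(
    band_series: MaskedBoldSeries,
    cfg: FcdConfig | None = None,
    band: str = "",
    corr: np.ndarray | None = None,
) -> FcdMap:
    """Connections of each voxel with all other mask voxels (r > threshold)."""
    cfg = cfg or FcdConfig()
    if corr is None:
        corr = correlation_matrix(band_series)
    adj = corr > cfg.threshold
    np.fill_diagonal(adj, False)
    return _map_from(band_series, adj.sum(axis=1).astype(float), "global", band)


def short_fcd(
    band_series: MaskedBoldSeries,
    cfg: FcdConfig | None = None,
    band: str = "",
    corr: np.ndarray | None = None,
) -> FcdMap:
    """Seed-to-local-cluster connection counts via region growing.

    The cluster of seed x0 starts as {x0} and absorbs any voxel that is a
    spatial neighbor of a member and has r(x0, .) > threshold; the value is
    |cluster| - 1 (seed-to-member connections only).
    """
    cfg = cfg or FcdConfig()
    if corr is None:
        corr = correlation_matrix(band_series)
    nbrs = neighbor_lists(band_series.voxel_index, cfg.connectivity)
    n = band_series.n_voxels
    counts = np.zeros(n)
    for seed in range(n):
        linked = corr[seed] > cfg.threshold
        in_cluster = np.zeros(n, dtype=bool)
        in_cluster[seed] = True
        stack = [seed]
        while stack:
            v = stack.pop()
            for j in nbrs[v]:
                if not in_cluster[j] and linked[j]:
                    in_cluster[j] = True
                    stack.append(j)
        counts[seed] = in_cluster.sum() - 1
    return _map_from(band_series, counts, "short", band)


def long_fcd(global_map: FcdMap, short_map: FcdMap) -> FcdMap:
    """Long-range FCD: global minus short-range, voxelwise."""
    if global_map.kind != "global" or short_map.kind != "short":
        raise ValueError("long_fcd needs a global and a short map")
    same = (
        global_map.subject_id == short_map.subject_id
        and global_map.band == short_map.band
        and global_map.grid_shape == short_map.grid_shape
        and np.array_equal(global_map.voxel_index, short_map.voxel_index)
    )
    if not same:
        raise ValueError("global and short maps do not describe the same data")
    values = global_map.values - short_map.values
    if np.any(values < 0):
        raise ValueError("long-range FCD came out negative; inconsistent maps")
    return replace(global_map, values=values, kind="long")


def compute_fcd(
    band_series: MaskedBoldSeries, cfg: FcdConfig | None = None, band: str = ""
) -> dict:
    """Global, short and long raw-count maps from one correlation pass."""
    cfg = cfg or FcdConfig()
    corr = correlation_matrix(band_series)
    g = global_fcd(band_series, cfg, band, corr=corr)
    s = short_fcd(band_series, cfg, band, corr=corr)
    return {"global": g, "short": s, "long": long_fcd(g, s)}


def zscore_map(fcd_map: FcdMap, ddof: int = 0) -> FcdMap:
    """Standardize within the mask (population SD by default)."""
    sd = fcd_map.values.std(ddof=ddof)
    if sd == 0:
        raise ValueError("constant map cannot be z-scored")
    z = (fcd_map.values - fcd_map.values.mean()) / sd
    return replace(fcd_map, values=z, stage="zscored")


def smooth_map(
    fcd_map: FcdMap,
    cfg: FcdConfig | None = None,
    fwhm_mm: float | None = None,
) -> FcdMap:
    """Gaussian smoothing on the grid with mask renormalization.

    sigma per axis = FWHM / sqrt(8 ln 2) / voxel size.  The map is embedded
    with zeros outside the mask and divided by the identically smoothed mask,
    so constant maps are unchanged inside the mask.
    """
    cfg = cfg or FcdConfig()
    fwhm = cfg.smooth_fwhm_mm if fwhm_mm is None else fwhm_mm
    if fwhm < 0:
        raise ValueError("FWHM must be >= 0")
    if fwhm == 0:
        return replace(fcd_map, values=fcd_map.values.copy(), stage="smoothed")
    sigma = [
        fwhm * FWHM_TO_SIGMA / vs for vs in fcd_map.voxel_size_mm
    ]
    vol = np.zeros(fcd_map.grid_shape)
    msk = np.zeros(fcd_map.grid_shape)
    idx = tuple(fcd_map.voxel_index.T)
    vol[idx] = fcd_map.values
    msk[idx] = 1.0
    sm_vol = gaussian_filter(vol, sigma, mode="constant", cval=0.0)
    sm_msk = gaussian_filter(msk, sigma, mode="constant", cval=0.0)
    values = sm_vol[idx] / sm_msk[idx]
    return replace(fcd_map, values=values, stage="smoothed")
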