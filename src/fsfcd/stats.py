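"""Group inference: voxelwise t-tests, Monte-Carlo cluster-extent correction,
partial correlation with FDR, and demographic-table tests.

Cluster correction follows the AlphaSim recipe: simulate null volumes of
white Gaussian noise on the mask grid, smooth to the map's (estimated or
supplied) FWHM, standardize within the mask (so the voxel-level p maps to a
z cutoff exactly), threshold two-tailed, label positive and negative
clusters separately, and record each simulation's maximum cluster extent.
The reported minimum extent is the smallest k whose exceedance fraction is
<= alpha, i.e. the smallest cluster size controlling family-wise error.

The t-map sign convention is fixed: group A minus group B (patients minus
controls in the pipeline).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats as sstats
from statsmodels.stats.multitest import multipletests

from .fcd import FcdMap, FWHM_TO_SIGMA

_STRUCTURES = {6: 1, 18: 2, 26: 3}


@dataclass
class CorrectionConfig:
    voxel_p: float = 0.001  # uncorrected two-tailed voxel threshold
    alpha: float = 0.05  # corrected family-wise level
    n_sims: int = 1000
    fwhm_mm: tuple | None = None  # map smoothness; None -> estimate from residuals
    connectivity: int = 26
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.voxel_p < 1):
            raise ValueError("voxel_p must be in (0, 1)")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        if self.n_sims < 100:
            raise ValueError("n_sims must be >= 100")
        if self.connectivity not in _STRUCTURES:
            raise ValueError("connectivity must be 6, 18 or 26")


@dataclass
class StatMap:
    t_values: np.ndarray  # per mask voxel; NaN where pooled variance is zero
    df: int
    voxel_index: np.ndarray
    grid_shape: tuple
    voxel_size_mm: tuple
    contrast: str = "groupA - groupB"

    def to_volume(self, fill: float = np.nan) -> np.ndarray:
        vol = np.full(self.grid_shape, fill)
        vol[tuple(self.voxel_index.T)] = self.t_values
        return vol


@dataclass
class ClusterRecord:
    cluster_id: int
    size: int
    peak_voxel: tuple
    peak_mm: tuple
    peak_t: float
    sign: str  # "increase" | "decrease"
    voxel_rows: np.ndarray = field(repr=False, default=None)


def _stack(maps) -> np.ndarray:
    """(n_subjects, n_voxels) array from FcdMaps or array-likes."""
    rows = [m.values if isinstance(m, FcdMap) else np.asarray(m, float) for m in maps]
    return np.vstack(rows)


def voxelwise_ttest(maps_a, maps_b, geometry=None) -> StatMap:
    """Pooled-variance two-sample t per voxel; sign is A minus B.

    `geometry` (voxel_index, grid_shape, voxel_size_mm) is taken from the
    first map when FcdMaps are passed.
    """
    a, b = _stack(maps_a), _stack(maps_b)
    n1, n2 = a.shape[0], b.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 subjects per group")
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups have different voxel counts")
    df = n1 + n2 - 2
    diff = a.mean(axis=0) - b.mean(axis=0)
    pooled = ((n1 - 1) * a.var(axis=0, ddof=1) + (n2 - 1) * b.var(axis=0, ddof=1)) / df
    se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / se, np.nan)
    if geometry is None:
        first = maps_a[0]
        if not isinstance(first, FcdMap):
            raise ValueError("pass geometry=(voxel_index, grid_shape, voxel_size_mm)")
        geometry = (first.voxel_index, first.grid_shape, first.voxel_size_mm)
    vi, gs, vs = geometry
    return StatMap(
        t_values=t, df=df, voxel_index=np.asarray(vi), grid_shape=tuple(gs),
        voxel_size_mm=tuple(vs), contrast="groupA - groupB",
    )


def estimate_smoothness(residual_maps) -> tuple:
    """Per-axis Gaussian-equivalent FWHM (mm) of residual maps.

    Classical variance-of-derivative estimator: along each axis, the lag-one
    autocorrelation of the standardized residuals is rho = 1 - var(diff)/2.
    White noise smoothed with a Gaussian of width sigma has ACF
    exp(-d^2 / (4 sigma^2)), so sigma^2 = -1/(4 ln rho) in voxel units and
    FWHM = sqrt(8 ln 2) * sigma * voxel size.  Averaged across maps.
    """
    if len(residual_maps) < 2:
        raise ValueError("need at least 2 residual maps")
    first = residual_maps[0]
    vol_mask = np.zeros(first.grid_shape, dtype=bool)
    vol_mask[tuple(first.voxel_index.T)] = True
    fwhm_acc = np.zeros(3)
    for m in residual_maps:
        vals = m.values
        sd = vals.std()
        if sd == 0:
            raise ValueError("constant residual map")
        vol = np.full(first.grid_shape, np.nan)
        vol[tuple(m.voxel_index.T)] = (vals - vals.mean()) / sd
        for ax in range(3):
            if first.grid_shape[ax] < 2:
                raise ValueError(f"axis {ax} is single-voxel thick")
            d = np.diff(vol, axis=ax)
            d = d[np.isfinite(d)]
            if d.size == 0:
                raise ValueError(f"axis {ax} has no in-mask voxel pairs")
            rho = 1.0 - d.var() / 2.0
            if rho <= 0:
                fwhm_vox = 0.0
            else:
                sigma = np.sqrt(-1.0 / (4.0 * np.log(rho)))
                fwhm_vox = sigma / FWHM_TO_SIGMA
            fwhm_acc[ax] += fwhm_vox * first.voxel_size_mm[ax]
    return tuple(fwhm_acc / len(residual_maps))


def _max_cluster_extent(vol: np.ndarray, mask: np.ndarray, z_crit: float,
                        structure: np.ndarray) -> int:
    best = 0
    for sup in (vol >= z_crit, vol <= -z_crit):
        labeled, n = ndimage.label(sup & mask, structure=structure)
        if n:
            best = max(best, int(np.bincount(labeled.ravel())[1:].max()))
    return best


def monte_carlo_cluster_threshold(
    mask: np.ndarray,
    cfg: CorrectionConfig,
    voxel_size_mm: tuple = (3.0, 3.0, 3.0),
) -> int:
    """AlphaSim-style minimum cluster extent (in voxels) at cfg.alpha.

    Null volumes of white noise are smoothed to cfg.fwhm_mm, standardized
    within the mask, thresholded two-tailed at cfg.voxel_p, and cluster-
    labeled; the returned extent k is the smallest with
    P(max cluster >= k) <= alpha under the null.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    if cfg.fwhm_mm is None:
        raise ValueError("cfg.fwhm_mm must be set (estimate or supply smoothness)")
    if cfg.alpha * cfg.n_sims < 1:
        raise ValueError(
            f"alpha={cfg.alpha} is unresolvable with n_sims={cfg.n_sims}; "
            "increase n_sims"
        )
    sigma = [f * FWHM_TO_SIGMA / vs for f, vs in zip(cfg.fwhm_mm, voxel_size_mm)]
    z_crit = sstats.norm.isf(cfg.voxel_p / 2.0)
    structure = ndimage.generate_binary_structure(3, _STRUCTURES[cfg.connectivity])
    rng = np.random.default_rng(cfg.seed)
    max_extents = np.empty(cfg.n_sims, dtype=int)
    for s in range(cfg.n_sims):
        noise = rng.standard_normal(mask.shape)
        if any(sg > 0 for sg in sigma):
            noise = ndimage.gaussian_filter(noise, sigma, mode="constant", cval=0.0)
        vals = noise[mask]
        noise = (noise - vals.mean()) / vals.std()
        max_extents[s] = _max_cluster_extent(noise, mask, z_crit, structure)
    srt = np.sort(max_extents)
    for k in range(1, int(srt[-1]) + 2):
        frac = (cfg.n_sims - np.searchsorted(srt, k, side="left")) / cfg.n_sims
        if frac <= cfg.alpha:
            return k
    return int(srt[-1]) + 1


def extract_clusters(
    stat: StatMap, cfg: CorrectionConfig, min_extent: int
) -> list:
    """Suprathreshold clusters of at least `min_extent` voxels, by sign.

    Voxels with |t| >= the two-tailed cutoff at cfg.voxel_p (df from the
    map) are labeled into connected components separately for positive and
    negative signs; surviving records are sorted by size, largest first.
    """
    if min_extent < 1:
        raise ValueError("min_extent must be >= 1")
    t_cut = sstats.t.isf(cfg.voxel_p / 2.0, stat.df)
    structure = ndimage.generate_binary_structure(3, _STRUCTURES[cfg.connectivity])
    vol = stat.to_volume()
    finite = np.isfinite(vol)
    lin_lut = {tuple(c): i for i, c in enumerate(stat.voxel_index)}
    records = []
    for sign, sup in (
        ("increase", finite & (vol >= t_cut)),
        ("decrease", finite & (vol <= -t_cut)),
    ):
        labeled, n = ndimage.label(sup, structure=structure)
        for lab in range(1, n + 1):
            coords = np.argwhere(labeled == lab)
            if coords.shape[0] < min_extent:
                continue
            ts = vol[tuple(coords.T)]
            peak = coords[np.argmax(np.abs(ts))]
            rows = np.asarray([lin_lut[tuple(c)] for c in coords], dtype=np.intp)
            records.append(
                ClusterRecord(
                    cluster_id=0,
                    size=int(coords.shape[0]),
                    peak_voxel=tuple(int(v) for v in peak),
                    peak_mm=tuple(
                        float(v * s) for v, s in zip(peak, stat.voxel_size_mm)
                    ),
                    peak_t=float(vol[tuple(peak)]),
                    sign=sign,
                    voxel_rows=rows,
                )
            )
    records.sort(key=lambda r: -r.size)
    for i, r in enumerate(records, start=1):
        r.cluster_id = i
    return records


# ---------------------------------------------------------------------------
# scalar statistics


def partial_correlation(x, y, covariates=None) -> tuple[float, float]:
    """Pearson correlation of x and y after regressing out covariates.

    Two-tailed p from the t transform with df = n - 2 - n_covariates.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    if covariates is None:
        Z = np.ones((n, 1))
        k = 0
    else:
        C = np.atleast_2d(np.asarray(covariates, float))
        if C.shape[0] != n:
            C = C.T
        Z = np.column_stack([np.ones(n), C])
        k = Z.shape[1] - 1
        if np.linalg.matrix_rank(Z) < Z.shape[1]:
            raise ValueError("collinear covariates")
    if n <= k + 2:
        raise ValueError("too few observations for the covariate count")
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    denom = np.sqrt(np.sum(rx**2) * np.sum(ry**2))
    if denom == 0:
        raise ValueError("degenerate residuals")
    r = float(np.sum(rx * ry) / denom)
    df = n - 2 - k
    r_ = np.clip(r, -0.9999999999, 0.9999999999)
    t = r_ * np.sqrt(df / (1.0 - r_**2))
    p = 2.0 * sstats.t.sf(abs(t), df)
    return r, float(p)


def fdr_bh(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at level q."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def contingency_chisq(table) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on a 2x2 count table."""
    t = np.asarray(table, float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero margin in the table")
    chi2, p, _, _ = sstats.chi2_contingency(t, correction=False)
    return float(chi2), float(p)


def two_sample_ttest_scalar(a, b) -> tuple[float, float]:
    """Pooled-variance two-sided two-sample t-test on scalar samples."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("zero pooled variance")
    t, p = sstats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def demographics_table(subject_table, continuous=("age", "sai", "tai", "bdi", "pswq")):
    """Table-1-style group tests: t for continuous columns, chi-square for sex."""
    pat = subject_table[subject_table["group"] == "patient"]
    con = subject_table[subject_table["group"] == "control"]
    out = {}
    for col in continuous:
        if col in subject_table.columns:
            t, p = two_sample_ttest_scalar(pat[col], con[col])
            out[col] = {"t": t, "p": p}
    if "sex" in subject_table.columns:
        tab = [
            [(pat["sex"] == "M").sum(), (pat["sex"] == "F").sum()],
            [(con["sex"] == "M").sum(), (con["sex"] == "F").sum()],
        ]
        chi2, p = contingency_chisq(tab)
        out["sex"] = {"chi2": chi2, "p": p}
    return out
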