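"""Empirical mode decomposition, its complete-ensemble adaptive-noise variant,
and Hilbert weighted frequency.

EMD sifts a series into intrinsic mode functions (IMFs): oscillations whose
extrema and zero-crossing counts differ by at most one and whose upper/lower
envelope mean is near zero.  Envelopes are cubic splines through the local
extrema with mirror-symmetric boundary extension (two mirrored extrema per
end); sifting stops on a Cauchy-type criterion (sum of squared sift updates
over signal energy below `sd_threshold`) or after `max_siftings` passes.

CEEMDAN extracts modes stage by stage: the k-th mode is the ensemble mean of
the first EMD mode of (current residue + scaled k-th EMD mode of a white-noise
realization).  Because every stage subtracts the extracted mode from the
running residue, the decomposition is complete: input = sum of IMFs + residue
to floating-point accuracy, by construction.  One noise bank (the realizations
and their EMD modes) can be shared across the many voxels of a subject, which
dominates runtime.

The Hilbert weighted frequency (HWF) of an IMF is the amplitude-weighted mean
instantaneous frequency of its analytic signal; for an energy weighting the
weights are the squared instantaneous amplitude.  Edge samples are excluded
because the Hilbert transform of a finite series is unreliable there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.signal import hilbert

MIN_SAMPLES = 16


@dataclass
class CeemdanConfig:
    noise_amplitude: float = 0.2  # fraction of the current residue's SD
    ensemble_size: int = 100
    max_imfs: int = 4
    sd_threshold: float = 0.2
    max_siftings: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.noise_amplitude <= 0:
            raise ValueError("noise_amplitude must be > 0")
        if self.ensemble_size < 2:
            raise ValueError("ensemble_size must be >= 2")
        if self.max_imfs < 1:
            raise ValueError("max_imfs must be >= 1")


@dataclass
class ImfSet:
    """Ordered IMFs plus the residue of one voxel's decomposition."""

    imfs: list
    residue: np.ndarray
    source_length: int

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        out = self.residue.copy()
        for imf in self.imfs:
            out = out + imf
        return out


@dataclass
class HwfValue:
    frequency: float
    imf_order: int | None = None
    voxel_index: int | None = None
    subject_id: str | None = None


# ---------------------------------------------------------------------------
# extrema and envelopes


def local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of interior local maxima and minima (plateau-safe)."""
    dx = np.diff(x)
    s = np.sign(dx)
    nz = np.flatnonzero(s)
    if nz.size == 0:
        return np.empty(0, dtype=np.intp), np.empty(0, dtype=np.intp)
    # carry the previous non-zero slope sign across plateaus
    pos = np.maximum.accumulate(np.where(s != 0, np.arange(s.size), -1))
    filled = np.where(pos >= 0, s[np.clip(pos, 0, None)], s[nz[0]])
    d2 = np.diff(filled)
    maxima = np.flatnonzero(d2 < 0) + 1
    minima = np.flatnonzero(d2 > 0) + 1
    return maxima.astype(np.intp), minima.astype(np.intp)


def zero_crossings(x: np.ndarray) -> int:
    s = np.sign(x)
    s = s[s != 0]
    if s.size < 2:
        return 0
    return int(np.sum(s[1:] != s[:-1]))


def _mirrored_spline(idx: np.ndarray, val: np.ndarray, n: int) -> np.ndarray:
    """Cubic-spline envelope through extrema, mirror-extended past both ends."""
    k = min(2, idx.size)
    pre_t = -idx[:k][::-1]
    pre_v = val[:k][::-1]
    post_t = 2 * (n - 1) - idx[-k:][::-1]
    post_v = val[-k:][::-1]
    t = np.concatenate([pre_t, idx, post_t]).astype(float)
    v = np.concatenate([pre_v, val, post_v])
    keep = np.concatenate([[True], np.diff(t) > 0])
    t, v = t[keep], v[keep]
    bc = "not-a-knot" if t.size >= 4 else "natural"
    return CubicSpline(t, v, bc_type=bc)(np.arange(n))


def _is_imf(x: np.ndarray) -> bool:
    maxima, minima = local_extrema(x)
    return abs((maxima.size + minima.size) - zero_crossings(x)) <= 1


def _sift_once(x: np.ndarray):
    maxima, minima = local_extrema(x)
    if maxima.size < 1 or minima.size < 1:
        return None
    n = x.size
    upper = _mirrored_spline(maxima, x[maxima], n)
    lower = _mirrored_spline(minima, x[minima], n)
    mean_env = 0.5 * (upper + lower)
    return x - mean_env, mean_env


def extract_imf(
    x: np.ndarray, sd_threshold: float = 0.2, max_siftings: int = 50
) -> np.ndarray | None:
    """Sift out a single IMF, or None if the signal cannot be enveloped."""
    h = x
    for it in range(max_siftings):
        step = _sift_once(h)
        if step is None:
            return None if it == 0 else h
        h_new, mean_env = step
        energy = float(np.sum(h * h))
        if energy == 0:
            return None
        sd = float(np.sum(mean_env * mean_env)) / energy
        h = h_new
        if sd < sd_threshold and _is_imf(h):
            break
    return h


def emd(
    signal: np.ndarray,
    sd_threshold: float = 0.2,
    max_siftings: int = 50,
    max_imfs: int | None = None,
) -> ImfSet:
    """Plain EMD: sift IMFs until the residue is (near-)monotonic.

    A constant or monotone input yields zero IMFs with residue = input.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    if x.size < MIN_SAMPLES:
        raise ValueError(f"signal too short ({x.size} < {MIN_SAMPLES} samples)")
    imfs: list = []
    residue = x.copy()
    # dyadic-filterbank bound: EMD of an n-sample series yields ~log2(n) modes
    hard_cap = int(np.log2(x.size)) + 4
    cap = hard_cap if max_imfs is None else min(max_imfs, hard_cap)
    while len(imfs) < cap:
        maxima, minima = local_extrema(residue)
        n_ext = maxima.size + minima.size
        if n_ext < 2:
            break  # residue is a monotone trend or single hump
        imf = extract_imf(residue, sd_threshold, max_siftings)
        if imf is None:
            break
        new_residue = residue - imf
        nm, nn = local_extrema(new_residue)
        if nm.size + nn.size >= n_ext and n_ext <= 4:
            break  # extraction stalled near termination; keep current residue
        imfs.append(imf)
        residue = new_residue
    return ImfSet(imfs=imfs, residue=residue, source_length=x.size)


# ---------------------------------------------------------------------------
# CEEMDAN


def make_noise_bank(
    n: int, cfg: CeemdanConfig, rng: np.random.Generator | None = None
) -> list:
    """Ensemble of unit-variance noise realizations with their EMD modes.

    Each entry is (noise, [mode_1, mode_2, ...]).  One bank can be shared by
    every voxel of a subject.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    bank = []
    for _ in range(cfg.ensemble_size):
        w = rng.standard_normal(n)
        w /= w.std()
        modes = emd(
            w, cfg.sd_threshold, cfg.max_siftings, max_imfs=cfg.max_imfs
        ).imfs
        bank.append((w, modes))
    return bank


def ceemdan(
    signal: np.ndarray, cfg: CeemdanConfig | None = None, noise_bank: list | None = None
) -> ImfSet:
    """Complete-ensemble EMD with adaptive noise.

    Mode 1 is the ensemble mean of the first EMD mode of (x + b0*w_i); mode
    k+1 averages the first EMD mode of (residue_k + b_k * mode_k(w_i)), with
    b_k = noise_amplitude * SD(residue_k).  The final residue is computed as
    input minus the sum of modes, so reconstruction is exact.
    """
    if cfg is None:
        cfg = CeemdanConfig()
    x = np.asarray(signal, dtype=float)
    if x.size < MIN_SAMPLES:
        raise ValueError(f"signal too short ({x.size} < {MIN_SAMPLES} samples)")
    if noise_bank is None:
        noise_bank = make_noise_bank(x.size, cfg)

    imfs: list = []
    residue = x.copy()
    for k in range(cfg.max_imfs):
        maxima, minima = local_extrema(residue)
        if maxima.size < 1 or minima.size < 1:
            break
        beta = cfg.noise_amplitude * residue.std()
        acc = np.zeros_like(x)
        count = 0
        for noise, modes in noise_bank:
            if k == 0:
                perturbed = residue + beta * noise
            elif k - 1 < len(modes):
                perturbed = residue + beta * modes[k - 1]
            else:
                perturbed = residue
            mode = extract_imf(perturbed, cfg.sd_threshold, cfg.max_siftings)
            if mode is not None:
                acc += mode
                count += 1
        if count == 0:
            break
        imfs.append(acc / count)
        residue = residue - imfs[-1]
    final_residue = x - np.sum(imfs, axis=0) if imfs else x.copy()
    return ImfSet(imfs=imfs, residue=final_residue, source_length=x.size)


# ---------------------------------------------------------------------------
# Hilbert weighted frequency


def hwf_frequency(
    imf: np.ndarray,
    tr_s: float,
    weighting: str = "energy",
    edge_exclude: int = 2,
) -> float:
    """Amplitude-weighted mean instantaneous frequency of one IMF, in Hz.

    weighting "energy" uses squared instantaneous amplitude; "amplitude" uses
    plain amplitude.  The first/last `edge_exclude` samples are excluded.
    """
    x = np.asarray(imf, dtype=float)
    if x.size < 2 * edge_exclude + 4:
        raise ValueError("IMF too short for HWF")
    if not np.any(x):
        raise ValueError("zero-energy IMF has no defined frequency")
    analytic = hilbert(x)
    amp = np.abs(analytic)
    phase = np.unwrap(np.angle(analytic))
    inst_freq = np.gradient(phase) / (2 * np.pi * tr_s)
    sl = slice(edge_exclude, x.size - edge_exclude if edge_exclude else None)
    if weighting == "energy":
        w = amp[sl] ** 2
    elif weighting == "amplitude":
        w = amp[sl]
    else:
        raise ValueError("weighting must be 'energy' or 'amplitude'")
    total = w.sum()
    if total == 0:
        raise ValueError("zero-energy IMF has no defined frequency")
    return float(np.sum(w * inst_freq[sl]) / total)


def hwf(imf: np.ndarray, tr_s: float, **kwargs) -> HwfValue:
    return HwfValue(frequency=hwf_frequency(imf, tr_s, **kwargs))


# ---------------------------------------------------------------------------
# cohort-level decomposition


def decompose_cohort(
    subjects: list,
    cfg: CeemdanConfig | None = None,
    n_orders: int = 4,
) -> tuple[dict, pd.DataFrame, dict]:
    """CEEMDAN + HWF for every voxel of every subject.

    Returns (decompositions, hwf_table, qc).  `decompositions` maps
    subject_id -> list of ImfSet in voxel order.  The tidy table has one row
    per (subject, voxel, imf_order 1..n_orders) with hwf_hz NaN where the
    voxel yielded fewer modes; `qc` counts those voxels.  Each subject gets
    its own noise bank derived deterministically from cfg.seed, so results do
    not depend on execution order.
    """
    if cfg is None:
        cfg = CeemdanConfig()
    if not subjects:
        raise ValueError("no subjects")
    geom = (subjects[0].grid_shape, subjects[0].n_voxels, subjects[0].tr_s)
    for s in subjects[1:]:
        if (s.grid_shape, s.n_voxels, s.tr_s) != geom:
            raise ValueError(f"subject {s.subject_id} geometry mismatch")

    decomps: dict = {}
    rows = []
    qc = {"n_voxels_missing_imfs": 0, "n_voxels": 0}
    for si, subj in enumerate(subjects):
        rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), si]))
        bank = make_noise_bank(subj.n_timepoints, cfg, rng)
        per_voxel = []
        for vi in range(subj.n_voxels):
            dec = ceemdan(subj.data[vi], cfg, noise_bank=bank)
            per_voxel.append(dec)
            qc["n_voxels"] += 1
            if dec.n_imfs < n_orders:
                qc["n_voxels_missing_imfs"] += 1
            for order in range(1, n_orders + 1):
                if order <= dec.n_imfs and np.any(dec.imfs[order - 1]):
                    f = hwf_frequency(dec.imfs[order - 1], subj.tr_s)
                else:
                    f = np.nan
                rows.append(
                    {
                        "subject_id": subj.subject_id,
                        "voxel": vi,
                        "imf_order": order,
                        "hwf_hz": f,
                    }
                )
        decomps[subj.subject_id] = per_voxel
    table = pd.DataFrame(rows)
    return decomps, table, qc
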