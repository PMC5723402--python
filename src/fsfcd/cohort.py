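"""Synthetic two-group resting-state BOLD cohorts with known connectivity truth.

Every voxel series is a sum of sinusoidal oscillators (subject-specific random
phase, shared across the oscillator's spatial support), optional band-limited
latent components planted in spatially contiguous effect regions of one group
(which raise pairwise correlation in that band only), and white noise.  The
construction keeps the Hilbert-weighted-frequency ground truth analytic and
makes planted connectivity differences band-specific by design.

Defaults mirror a TR = 3 s acquisition with 190 retained volumes and group
sizes of 31 patients / 28 controls on a ~700-voxel ellipsoidal mask embedded
in a 12x12x12 grid of 3-mm voxels.  Synthetic covariates (age, sex, anxiety /
worry / depression scores) are drawn from configurable group distributions so
demographic-table code can run end to end; they are stand-ins, not data.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .core import MaskedBoldSeries, mask_coordinates
from .prep import butter_filtfilt

GROUPS = ("patient", "control")

#: Group covariate distributions: mean/sd for continuous scores, male
#: probability for sex.  Values follow the demographic table of a typical
#: adolescent anxiety cohort; they only exercise the demographic tests.
DEFAULT_COVARIATES = {
    "patient": {
        "age": (16.90, 0.12),
        "p_male": 14 / 31,
        "sai": (43.48, 8.51),
        "tai": (52.34, 7.63),
        "bdi": (8.36, 4.60),
        "pswq": (55.16, 9.76),
    },
    "control": {
        "age": (16.46, 0.18),
        "p_male": 16 / 28,
        "sai": (39.86, 7.87),
        "tai": (44.25, 9.18),
        "bdi": (6.12, 5.21),
        "pswq": (38.79, 11.26),
    },
}


@dataclass(frozen=True)
class Oscillator:
    """A sinusoid at `freq_hz` shared (same phase) by all voxels of `support`.

    support is None (whole mask) or a tuple of (x, y, z) grid coordinates.
    """

    freq_hz: float
    amplitude: float = 1.0
    support: tuple | None = None


@dataclass(frozen=True)
class EffectRegion:
    """A contiguous voxel set receiving a shared band-limited latent component.

    The latent is unit-variance noise band-passed to `band_hz` and added with
    mixing weight `gain` to every region voxel of subjects in `group`; the
    gain therefore acts as a correlation gain in that band only.
    """

    voxels: tuple
    band_hz: tuple
    gain: float
    group: str = "patient"


@dataclass
class CohortSpec:
    n_per_group: tuple = (31, 28)  # (patients, controls)
    grid_shape: tuple = (12, 12, 12)
    voxel_size_mm: tuple = (3.0, 3.0, 3.0)
    tr_s: float = 3.0
    n_timepoints: int = 190
    mask: dict = field(
        default_factory=lambda: {"kind": "ellipsoid", "semi_axes": (5.5, 5.5, 5.5)}
    )
    oscillators: tuple = (
        Oscillator(freq_hz=0.05, amplitude=0.5),
        Oscillator(freq_hz=0.015, amplitude=0.5),
    )
    effect_regions: tuple = ()
    noise_sd: float = 1.0
    seed: int = 0
    covariates: dict = field(default_factory=lambda: copy.deepcopy(DEFAULT_COVARIATES))


def ellipsoid_mask(
    grid_shape: tuple, semi_axes: tuple, center: tuple | None = None
) -> np.ndarray:
    """Boolean ellipsoidal mask centered in the grid by default."""
    if center is None:
        center = tuple((n - 1) / 2.0 for n in grid_shape)
    grids = np.indices(grid_shape, dtype=float)
    r2 = sum(
        ((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes)
    )
    return r2 <= 1.0


def box_mask(grid_shape: tuple, lo: tuple, hi: tuple) -> np.ndarray:
    """Boolean box mask over half-open coordinate ranges [lo, hi)."""
    m = np.zeros(grid_shape, dtype=bool)
    m[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
    return m


def mask_array(spec: CohortSpec) -> np.ndarray:
    """Materialize the spec's mask descriptor as a boolean volume."""
    desc = spec.mask
    kind = desc.get("kind")
    if kind == "ellipsoid":
        return ellipsoid_mask(
            spec.grid_shape, desc["semi_axes"], desc.get("center")
        )
    if kind == "box":
        return box_mask(spec.grid_shape, desc["lo"], desc["hi"])
    if kind == "explicit":
        m = np.zeros(spec.grid_shape, dtype=bool)
        coords = np.asarray(desc["voxels"], dtype=int)
        m[tuple(coords.T)] = True
        return m
    raise ValueError(f"unknown mask kind: {kind!r}")


def ball_region(center: tuple, radius: float, grid_shape: tuple) -> tuple:
    """Coordinates of a discrete ball, for defining contiguous effect regions."""
    grids = np.indices(grid_shape, dtype=float)
    r2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    coords = np.argwhere(r2 <= radius**2)
    return tuple(tuple(int(v) for v in c) for c in coords)


def validate_spec(spec: CohortSpec) -> np.ndarray:
    """Check the spec's invariants; returns the materialized mask."""
    nyq = 0.5 / spec.tr_s
    for osc in spec.oscillators:
        if not (0 < osc.freq_hz < nyq):
            raise ValueError(
                f"oscillator frequency {osc.freq_hz} Hz outside (0, Nyquist={nyq})"
            )
    for reg in spec.effect_regions:
        f_lo, f_hi = reg.band_hz
        if not (0 <= f_lo < f_hi <= nyq):
            raise ValueError(f"effect band {reg.band_hz} invalid for Nyquist {nyq}")
        if reg.group not in GROUPS:
            raise ValueError(f"effect group must be one of {GROUPS}")
    if spec.n_timepoints < 64:
        raise ValueError("need at least 64 timepoints")
    if spec.noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    mask = mask_array(spec)
    if not mask.any():
        raise ValueError("empty mask")
    for reg in spec.effect_regions:
        coords = np.asarray(reg.voxels, dtype=int)
        if not mask[tuple(coords.T)].all():
            raise ValueError("effect region extends outside the mask")
    return mask


def _rows_for(
    coords_or_none, voxel_index: np.ndarray, strict: bool = False
) -> np.ndarray:
    """Row indices in mask order for a coordinate set (all rows if None).

    Non-strict lookups intersect the set with the mask (an oscillator's
    support may overhang the mask edge); strict lookups reject out-of-mask
    voxels (effect regions must lie inside the mask).
    """
    if coords_or_none is None:
        return np.arange(voxel_index.shape[0])
    lut = {tuple(c): i for i, c in enumerate(voxel_index)}
    rows = []
    for c in coords_or_none:
        i = lut.get(tuple(c))
        if i is not None:
            rows.append(i)
        elif strict:
            raise ValueError(f"voxel {tuple(c)} not inside the mask")
    return np.asarray(rows, dtype=np.intp)


def band_limited_noise(
    rng: np.random.Generator, n: int, tr_s: float, band_hz: tuple
) -> np.ndarray:
    """Unit-variance white noise band-passed to `band_hz` (zero-phase)."""
    raw = rng.standard_normal(n)
    out = butter_filtfilt(raw, band_hz[0], band_hz[1], fs=1.0 / tr_s)
    sd = out.std()
    if sd == 0:
        raise ValueError("degenerate band-limited component")
    return out / sd


def generate_subject(
    spec: CohortSpec, group: str, subject_seed: int, subject_id: str | None = None
) -> MaskedBoldSeries:
    """Generate one subject's masked voxel-by-time matrix.

    The same random draws are made regardless of group (latents are drawn and
    discarded when the effect does not apply), so patient and control subjects
    with the same seed differ only by the planted effects.
    """
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}")
    mask = validate_spec(spec)
    coords = mask_coordinates(mask)
    n_vox, n_t = coords.shape[0], spec.n_timepoints
    rng = np.random.default_rng(subject_seed)
    t = np.arange(n_t) * spec.tr_s
    data = np.zeros((n_vox, n_t))

    for osc in spec.oscillators:
        phase = rng.uniform(0, 2 * np.pi)
        rows = _rows_for(osc.support, coords)
        data[rows] += osc.amplitude * np.sin(2 * np.pi * osc.freq_hz * t + phase)

    for reg in spec.effect_regions:
        latent = band_limited_noise(rng, n_t, spec.tr_s, reg.band_hz)
        if reg.group == group:
            rows = _rows_for(reg.voxels, coords, strict=True)
            data[rows] += reg.gain * latent

    data += spec.noise_sd * rng.standard_normal((n_vox, n_t))

    flat = np.where(data.std(axis=1) == 0)[0]
    if flat.size:
        raise ValueError(
            f"{flat.size} voxels have zero variance (e.g. rows {flat[:5].tolist()}); "
            "give every voxel an oscillator or positive noise_sd"
        )
    if subject_id is None:
        subject_id = f"{group}-{subject_seed}"
    return MaskedBoldSeries(
        data=data,
        voxel_index=coords,
        tr_s=spec.tr_s,
        subject_id=subject_id,
        grid_shape=tuple(spec.grid_shape),
        voxel_size_mm=tuple(spec.voxel_size_mm),
        provenance=["synthetic"],
    )


def _draw_covariates(rng: np.random.Generator, params: dict) -> dict:
    out = {}
    for key in ("age", "sai", "tai", "bdi", "pswq"):
        mu, sd = params[key]
        out[key] = round(float(rng.normal(mu, sd)), 2)
    out["sex"] = "M" if rng.uniform() < params["p_male"] else "F"
    return out


def generate_cohort(spec: CohortSpec) -> tuple[list, pd.DataFrame]:
    """Generate all subjects plus a subject table.

    Per-subject seeds are derived deterministically from spec.seed, so the
    same spec reproduces the cohort element for element.
    """
    validate_spec(spec)
    master = np.random.default_rng(spec.seed)
    subjects, rows = [], []
    for group, n in zip(GROUPS, spec.n_per_group):
        for k in range(n):
            sseed = int(master.integers(0, 2**31 - 1))
            sid = f"{group}{k:03d}"
            subjects.append(generate_subject(spec, group, sseed, subject_id=sid))
            cov = _draw_covariates(master, spec.covariates[group])
            rows.append({"subject_id": sid, "group": group, **cov, "seed": sseed})
    table = pd.DataFrame(rows)
    return subjects, table


def planted_effect_spec(
    n_per_group: tuple = (15, 15),
    gain: float = 1.5,
    band_hz: tuple = (0.02, 0.04),
    region_radius: float = 2.5,
    seed: int = 0,
) -> tuple[CohortSpec, tuple]:
    """Benchmark cohort: background networks plus one patient-only effect.

    Three contiguous "network" oscillators give every subject spatially
    structured short-range connectivity (so FCD maps are non-degenerate in
    both groups), and a central ~60-voxel region receives a shared
    band-limited latent in patients only.  Returns (spec, effect voxels).
    """
    grid = (12, 12, 12)
    region = ball_region((5.5, 5.5, 5.5), region_radius, grid)
    networks = (
        Oscillator(0.03, 1.2, ball_region((3.0, 3.0, 3.0), 2.2, grid)),
        Oscillator(0.05, 1.2, ball_region((8.0, 8.0, 3.0), 2.2, grid)),
        Oscillator(0.015, 1.2, ball_region((3.0, 8.0, 8.0), 2.2, grid)),
    )
    spec = CohortSpec(
        n_per_group=n_per_group,
        grid_shape=grid,
        oscillators=(
            Oscillator(0.05, 0.5),
            Oscillator(0.015, 0.5),
        )
        + networks,
        effect_regions=(
            EffectRegion(voxels=region, band_hz=band_hz, gain=gain),
        ),
        seed=seed,
    )
    return spec, region


# ---------------------------------------------------------------------------
# Spec (de)serialization: YAML/JSON round trip


def spec_to_dict(spec: CohortSpec) -> dict:
    d = asdict(spec)
    d["oscillators"] = [asdict(o) for o in spec.oscillators]
    d["effect_regions"] = [asdict(r) for r in spec.effect_regions]
    # canonical JSON-compatible form (tuples -> lists) so that a
    # YAML/JSON round trip compares equal
    return json.loads(json.dumps(d))


def spec_from_dict(d: dict) -> CohortSpec:
    d = copy.deepcopy(d)
    d["oscillators"] = tuple(
        Oscillator(
            freq_hz=o["freq_hz"],
            amplitude=o.get("amplitude", 1.0),
            support=(
                tuple(map(tuple, o["support"])) if o.get("support") is not None else None
            ),
        )
        for o in d.get("oscillators", ())
    )
    d["effect_regions"] = tuple(
        EffectRegion(
            voxels=tuple(map(tuple, r["voxels"])),
            band_hz=tuple(r["band_hz"]),
            gain=r["gain"],
            group=r.get("group", "patient"),
        )
        for r in d.get("effect_regions", ())
    )
    for key in ("n_per_group", "grid_shape", "voxel_size_mm"):
        if key in d:
            d[key] = tuple(d[key])
    return CohortSpec(**d)


def save_spec(spec: CohortSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spec_to_dict(spec), fh, sort_keys=True)


def load_spec(path) -> CohortSpec:
    with open(path) as fh:
        return spec_from_dict(yaml.safe_load(fh))
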