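"""Frequency-of-interest (FOI) bands from group HWF distributions.

For each IMF order, the pooled within-group HWF values (all voxels, all
subjects of a group) define an empirical 95% interval (2.5th-97.5th
percentiles).  The group-consistent FOI for that order is the intersection:
maximum of the two lower limits to minimum of the two upper limits.  Bands
are labeled FOI-1..FOI-4 by descending frequency (IMF order 1 oscillates
fastest); the conventional 0.01-0.08 Hz band is FOI-N.

The per-voxel band signal for a derived FOI-k is IMF order k directly; an
HWF-gated alternative (keep IMF-k only where its HWF falls inside the band)
is available behind a flag.  FOI-N uses the band-passed prepared series.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .core import MaskedBoldSeries
from .prep import butter_filtfilt
from .emd import ImfSet, hwf_frequency

CONVENTIONAL_BAND = (0.01, 0.08)


@dataclass
class FoiBand:
    label: str
    f_low: float
    f_high: float
    source: str = "derived"  # "derived" | "conventional"
    imf_order: int | None = None

    def __post_init__(self):
        if not (0 < self.f_low < self.f_high):
            raise ValueError(
                f"band limits must satisfy 0 < f_low < f_high, got "
                f"({self.f_low}, {self.f_high})"
            )
        if self.source not in ("derived", "conventional"):
            raise ValueError("source must be 'derived' or 'conventional'")

    def contains(self, f: float) -> bool:
        return self.f_low <= f <= self.f_high


def conventional_band() -> FoiBand:
    return FoiBand("FOI-N", *CONVENTIONAL_BAND, source="conventional")


def hwf_percentiles(
    hwf_table: pd.DataFrame,
    imf_order: int,
    group: str,
    min_values: int = 100,
) -> tuple[float, float]:
    """Empirical (2.5th, 97.5th) percentiles of pooled within-group HWF values.

    Pooled over all voxels and subjects of the group for one IMF order, with
    linear interpolation between order statistics.
    """
    if "group" not in hwf_table.columns:
        raise ValueError("hwf_table needs a 'group' column (merge the subject table)")
    cell = hwf_table.loc[
        (hwf_table["imf_order"] == imf_order) & (hwf_table["group"] == group),
        "hwf_hz",
    ].dropna()
    if cell.empty:
        raise ValueError(f"no HWF values for imf_order={imf_order}, group={group}")
    if len(cell) < min_values:
        raise ValueError(
            f"only {len(cell)} HWF values for imf_order={imf_order}, group={group}; "
            f"need >= {min_values}"
        )
    lo, hi = np.percentile(cell.to_numpy(), [2.5, 97.5])
    return float(lo), float(hi)


def select_fois(
    group_a_intervals: dict,
    group_b_intervals: dict,
) -> list:
    """Group-consistent FOI bands: per order, [max of lows, min of highs].

    Inputs map IMF order -> (low, high) in Hz, one entry per order.  Orders
    whose intersection is empty are dropped with a warning.  The output is
    labeled FOI-1.. by descending frequency, and adjacent overlapping bands
    (possible on synthetic edge cases) are trimmed at the midpoint of the
    overlap so bands come out disjoint.
    """
    bands = []
    for order in sorted(set(group_a_intervals) & set(group_b_intervals)):
        a_lo, a_hi = group_a_intervals[order]
        b_lo, b_hi = group_b_intervals[order]
        if a_lo > a_hi or b_lo > b_hi:
            raise ValueError(f"inverted interval for order {order}")
        lo, hi = max(a_lo, b_lo), min(a_hi, b_hi)
        if lo >= hi:
            warnings.warn(
                f"IMF order {order}: group intervals do not intersect; dropped",
                stacklevel=2,
            )
            continue
        bands.append((order, lo, hi))
    bands.sort(key=lambda b: -b[2])  # descending frequency
    # Trim overlaps between consecutive bands at the midpoint of the overlap.
    # On heavily overlapping inputs (tiny cohorts) a band can be swallowed by
    # its neighbors; such bands are dropped and the pass repeated.
    entries = [[order, lo, hi] for order, lo, hi in bands]
    while True:
        for i in range(len(entries) - 1):
            hi_band, lo_band = entries[i], entries[i + 1]
            if lo_band[2] > hi_band[1]:
                mid = 0.5 * (hi_band[1] + lo_band[2])
                hi_band[1] = mid
                lo_band[2] = mid
        kept = [e for e in entries if e[1] < e[2]]
        for e in entries:
            if e[1] >= e[2]:
                warnings.warn(
                    f"IMF order {e[0]}: band swallowed by neighbors after "
                    "overlap trimming; dropped",
                    stacklevel=2,
                )
        if len(kept) == len(entries):
            break
        entries = kept
    return [
        FoiBand(
            label=f"FOI-{i + 1}",
            f_low=lo,
            f_high=hi,
            source="derived",
            imf_order=order,
        )
        for i, (order, lo, hi) in enumerate(entries)
    ]


def derive_bands(
    hwf_table: pd.DataFrame,
    groups: tuple = ("patient", "control"),
    orders: tuple = (1, 2, 3, 4),
    min_values: int = 100,
) -> list:
    """Convenience: percentile intervals per group/order, then select_fois."""
    ia = {o: hwf_percentiles(hwf_table, o, groups[0], min_values) for o in orders}
    ib = {o: hwf_percentiles(hwf_table, o, groups[1], min_values) for o in orders}
    return select_fois(ia, ib)


def band_signal(
    imfset: ImfSet,
    band: FoiBand,
    prepared: np.ndarray | None = None,
    tr_s: float | None = None,
    hwf_gate: bool = False,
) -> np.ndarray | None:
    """Per-voxel series for one band; None flags a missing decomposition order.

    Derived FOI-k returns IMF order k's series (optionally gated on its HWF
    lying inside the band); FOI-N band-passes the prepared series.
    """
    if band.source == "conventional":
        if prepared is None or tr_s is None:
            raise ValueError("FOI-N needs the prepared series and tr_s")
        return butter_filtfilt(prepared, band.f_low, band.f_high, fs=1.0 / tr_s)
    order = band.imf_order
    if order is None:
        raise ValueError("derived band lacks an IMF order")
    if order > imfset.n_imfs:
        return None
    imf = imfset.imfs[order - 1]
    if not np.any(imf):
        return None
    if hwf_gate and not band.contains(hwf_frequency(imf, tr_s or 1.0)):
        return None
    return imf


def cohort_band_series(
    series: MaskedBoldSeries,
    decomposition: list,
    band: FoiBand,
    hwf_gate: bool = False,
) -> tuple[MaskedBoldSeries, np.ndarray]:
    """Band-specific matrix for a whole subject.

    Returns (MaskedBoldSeries restricted to voxels with a usable band signal,
    boolean keep-mask over the original voxel rows).
    """
    keep = np.ones(series.n_voxels, dtype=bool)
    rows = []
    for vi in range(series.n_voxels):
        sig = band_signal(
            decomposition[vi] if decomposition is not None else None,
            band,
            prepared=series.data[vi],
            tr_s=series.tr_s,
            hwf_gate=hwf_gate,
        )
        if sig is None or sig.std() == 0:
            keep[vi] = False
        else:
            rows.append(sig)
    from dataclasses import replace

    out = replace(
        series,
        data=np.asarray(rows),
        voxel_index=series.voxel_index[keep],
        provenance=list(series.provenance) + [f"band_signal({band.label})"],
    )
    return out, keep


def bands_to_json(bands: list, path=None) -> str:
    payload = json.dumps([asdict(b) for b in bands], indent=2)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(payload)
    return payload


def bands_from_json(text_or_path) -> list:
    try:
        data = json.loads(text_or_path)
    except (json.JSONDecodeError, TypeError):
        with open(text_or_path) as fh:
            data = json.load(fh)
    return [FoiBand(**d) for d in data]
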