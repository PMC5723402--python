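import numpy as np
import pytest

from fsfcd.cohort import CohortSpec, EffectRegion, Oscillator, ball_region
from fsfcd.core import MaskedBoldSeries, mask_coordinates

TR = 3.0
N_T = 190


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def time_axis():
    return np.arange(N_T) * TR


def make_series(data, grid_shape=None, tr_s=TR, subject_id="test"):
    """Wrap a (V, T) matrix as a MaskedBoldSeries on a line of voxels."""
    data = np.atleast_2d(np.asarray(data, float))
    v = data.shape[0]
    if grid_shape is None:
        grid_shape = (v, 1, 1)
    coords = mask_coordinates(np.ones(grid_shape, bool))[:v]
    return MaskedBoldSeries(
        data=data,
        voxel_index=coords,
        tr_s=tr_s,
        subject_id=subject_id,
        grid_shape=grid_shape,
    )


def grid_series(vol4d, tr_s=TR, subject_id="test"):
    """MaskedBoldSeries over every voxel of a small 4-D (x,y,z,t) array."""
    vol4d = np.asarray(vol4d, float)
    gs = vol4d.shape[:3]
    coords = mask_coordinates(np.ones(gs, bool))
    return MaskedBoldSeries(
        data=vol4d[tuple(coords.T)],
        voxel_index=coords,
        tr_s=tr_s,
        subject_id=subject_id,
        grid_shape=gs,
    )


@pytest.fixture
def small_spec():
    """Desk-scale cohort spec: tiny grid, short series, fast to generate."""
    return CohortSpec(
        n_per_group=(3, 3),
        grid_shape=(8, 8, 8),
        n_timepoints=96,
        mask={"kind": "ellipsoid", "semi_axes": (3.2, 3.2, 3.2)},
        seed=11,
    )


@pytest.fixture
def planted_spec():
    """Cohort with a band-specific connectivity effect planted in patients."""
    grid = (12, 12, 12)
    region = ball_region((5.5, 5.5, 5.5), 2.2, grid)
    return CohortSpec(
        n_per_group=(10, 10),
        grid_shape=grid,
        n_timepoints=N_T,
        effect_regions=(
            EffectRegion(voxels=region, band_hz=(0.02, 0.04), gain=1.5),
        ),
        seed=7,
    )
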