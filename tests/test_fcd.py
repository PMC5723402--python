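"""FCD mapping: global counts, region-growing short-range search, the
short+long=global identity, z-scoring and mask-renormalized smoothing."""

import numpy as np
import pytest

from fsfcd.fcd import (
    FcdConfig,
    FcdMap,
    compute_fcd,
    correlation_matrix,
    global_fcd,
    long_fcd,
    neighbor_offsets,
    short_fcd,
    smooth_map,
    zscore_map,
)

from conftest import grid_series, make_series

N_T = 190


def brute_force_global(data, threshold):
    """All-pairs oracle, independent of the implementation path."""
    corr = np.corrcoef(data)
    counts = []
    for i in range(data.shape[0]):
        counts.append(sum(1 for j in range(data.shape[0])
                          if j != i and corr[i, j] > threshold))
    return np.asarray(counts, float)


def brute_force_short(data, coords, threshold, connectivity=26):
    """Independently coded BFS cluster oracle (set arithmetic on coordinates)."""
    corr = np.corrcoef(data)
    offs = [tuple(o) for o in neighbor_offsets(connectivity)]
    coord_set = {tuple(c): i for i, c in enumerate(coords)}
    counts = []
    clusters = []
    for seed in range(data.shape[0]):
        cluster = {seed}
        frontier = [seed]
        while frontier:
            nxt = []
            for v in frontier:
                cv = coords[v]
                for o in offs:
                    j = coord_set.get((cv[0] + o[0], cv[1] + o[1], cv[2] + o[2]))
                    if j is not None and j not in cluster and corr[seed, j] > threshold:
                        cluster.add(j)
                        nxt.append(j)
            frontier = nxt
        counts.append(len(cluster) - 1)
        clusters.append(frozenset(cluster))
    return np.asarray(counts, float), clusters


def random_lattice_series(rng, n_side, n_t=60):
    vol = rng.standard_normal((n_side, n_side, n_side, n_t))
    # add pockets of shared signal so some correlations clear the threshold
    shared = rng.standard_normal(n_t)
    vol[: n_side // 2, : n_side // 2] += 1.2 * shared
    return grid_series(vol)


class TestGlobalFcd:
    def test_identical_series_all_connected(self):
        s = make_series(np.tile(np.sin(np.arange(N_T)), (4, 1)))
        m = global_fcd(s, FcdConfig())
        assert np.all(m.values == 3)

    def test_matches_brute_force_oracle(self, rng):
        s = random_lattice_series(rng, 6)
        m = global_fcd(s, FcdConfig())
        assert np.array_equal(m.values, brute_force_global(s.data, 0.6))

    def test_extreme_threshold_on_independent_noise_gives_zeros(self, rng):
        s = make_series(rng.standard_normal((100, N_T)))
        m = global_fcd(s, FcdConfig(threshold=0.999))
        assert np.all(m.values == 0)

    def test_zero_variance_voxel_rejected_with_indices(self, rng):
        data = rng.standard_normal((5, N_T))
        data[2] = 4.0
        with pytest.raises(ValueError, match=r"\[2\]"):
            global_fcd(make_series(data), FcdConfig())


class TestShortFcd:
    def test_fully_correlated_block_seed_at_center(self):
        tone = np.sin(np.arange(N_T))
        vol = np.tile(tone, (3, 3, 3, 1))
        m = short_fcd(grid_series(vol), FcdConfig())
        center = np.all(m.voxel_index == 1, axis=1)
        assert m.values[center][0] == 26

    def test_spatially_disconnected_partners_do_not_join(self, rng):
        # seed at origin; its only correlated partner is far away
        vol = rng.standard_normal((5, 1, 1, N_T))
        vol[0, 0, 0] = vol[4, 0, 0]  # corr 1 but not adjacent
        m = short_fcd(grid_series(vol), FcdConfig())
        assert m.values[0] == 0

    def test_matches_independent_bfs_oracle_on_random_lattices(self, rng):
        for _ in range(5):
            s = random_lattice_series(rng, 5)
            m = short_fcd(s, FcdConfig())
            oracle, _ = brute_force_short(s.data, s.voxel_index, 0.6)
            assert np.array_equal(m.values, oracle)


class TestLongFcd:
    def test_fully_correlated_volume_has_no_long_range(self):
        tone = np.sin(np.arange(N_T))
        vol = np.tile(tone, (3, 3, 3, 1))
        maps = compute_fcd(grid_series(vol), FcdConfig())
        assert np.all(maps["long"].values == 0)

    def test_disconnected_twin_blocks_count_each_other(self, rng):
        # two 2x2x2 blocks sharing a signal, separated by a noise gap
        vol = 0.01 * rng.standard_normal((7, 2, 2, N_T))
        shared = np.sin(np.arange(N_T))
        vol[:2] += shared
        vol[5:] += shared
        maps = compute_fcd(grid_series(vol), FcdConfig())
        block_a = maps["long"].voxel_index[:, 0] < 2
        assert np.all(maps["long"].values[block_a] == 8)

    def test_short_plus_long_equals_global(self, rng):
        s = random_lattice_series(rng, 6)
        maps = compute_fcd(s, FcdConfig())
        assert np.array_equal(
            maps["global"].values, maps["short"].values + maps["long"].values
        )

    def test_mismatched_maps_rejected(self, rng):
        a = random_lattice_series(rng, 4)
        g = global_fcd(a, FcdConfig())
        s = short_fcd(a, FcdConfig())
        s.subject_id = "other"
        with pytest.raises(ValueError, match="same data"):
            long_fcd(g, s)


class TestThresholdMonotonicity:
    def test_raising_threshold_never_increases_counts(self, rng):
        s = random_lattice_series(rng, 5)
        lo = compute_fcd(s, FcdConfig(threshold=0.4))
        hi = compute_fcd(s, FcdConfig(threshold=0.7))
        assert np.all(hi["global"].values <= lo["global"].values)
        assert np.all(hi["short"].values <= lo["short"].values)


class TestSymmetry:
    def test_mirror_symmetric_input_yields_mirror_symmetric_maps(self, rng):
        half = rng.standard_normal((3, 4, 4, N_T))
        half[:2, :2] += 1.5 * rng.standard_normal(N_T)
        vol = np.concatenate([half, half[::-1]], axis=0)
        maps = compute_fcd(grid_series(vol), FcdConfig())
        for m in maps.values():
            v = m.to_volume()
            assert np.array_equal(v, v[::-1])


class TestZscore:
    def test_population_convention_hand_computation(self):
        m = FcdMap(values=[1.0, 2.0, 3.0], voxel_index=[[0, 0, 0], [1, 0, 0], [2, 0, 0]],
                   grid_shape=(3, 1, 1), voxel_size_mm=(3, 3, 3), kind="global",
                   stage="raw_count")
        z = zscore_map(m)
        assert np.allclose(z.values, [-1.224744871, 0, 1.224744871])

    def test_idempotent_and_standardized(self, rng):
        m = FcdMap(values=rng.standard_normal(50) * 7 + 3,
                   voxel_index=np.column_stack([np.arange(50), np.zeros(50), np.zeros(50)]),
                   grid_shape=(50, 1, 1), voxel_size_mm=(3, 3, 3), kind="global",
                   stage="raw_count")
        z = zscore_map(m)
        assert abs(z.values.mean()) < 1e-12
        assert abs(z.values.std() - 1) < 1e-12
        assert np.allclose(zscore_map(z).values, z.values)

    def test_constant_map_rejected(self):
        m = FcdMap(values=np.ones(4), voxel_index=[[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]],
                   grid_shape=(4, 1, 1), voxel_size_mm=(3, 3, 3), kind="global",
                   stage="raw_count")
        with pytest.raises(ValueError, match="constant"):
            zscore_map(m)


class TestSmoothing:
    def _full_grid_map(self, values, gs=(9, 9, 9)):
        coords = np.argwhere(np.ones(gs, bool))
        order = np.argsort(coords[:, 0] + gs[0] * (coords[:, 1] + gs[1] * coords[:, 2]))
        return FcdMap(values=values, voxel_index=coords[order], grid_shape=gs,
                      voxel_size_mm=(3.0, 3.0, 3.0), kind="global", stage="zscored")

    def test_constant_map_unchanged_inside_mask(self):
        m = self._full_grid_map(np.full(9**3, 2.5))
        out = smooth_map(m, FcdConfig(smooth_fwhm_mm=6.0))
        assert np.allclose(out.values, 2.5, atol=1e-10)

    def test_interior_delta_matches_sampled_gaussian_kernel(self):
        gs = (9, 9, 9)
        vals = np.zeros(9**3)
        m = self._full_grid_map(vals)
        center = np.all(m.voxel_index == 4, axis=1)
        vals[np.flatnonzero(center)[0]] = 1.0
        out = smooth_map(self._full_grid_map(vals), FcdConfig(smooth_fwhm_mm=4.0))
        sigma_vox = 4.0 / np.sqrt(8 * np.log(2)) / 3.0
        vol = out.to_volume()
        # closed-form separable kernel comparison at a few offsets
        x = np.arange(-4, 5)
        kern = np.exp(-(x**2) / (2 * sigma_vox**2))
        kern /= kern.sum()
        expected = kern[:, None, None] * kern[None, :, None] * kern[None, None, :]
        assert np.allclose(vol, expected[::-1], atol=1e-6) or np.allclose(
            vol, expected, atol=1e-6
        )
        assert abs(vol.sum() - 1.0) < 1e-6

    def test_zero_fwhm_limit_is_identity(self, rng):
        m = self._full_grid_map(rng.standard_normal(9**3))
        out = smooth_map(m, fwhm_mm=0.0)
        assert np.array_equal(out.values, m.values)

    def test_negative_fwhm_rejected(self, rng):
        m = self._full_grid_map(rng.standard_normal(9**3))
        with pytest.raises(ValueError, match="FWHM"):
            smooth_map(m, fwhm_mm=-1.0)
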