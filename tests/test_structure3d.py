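"""COMSTAT-style stack metrics and the cluster-growth diagnostic."""

import numpy as np
import pytest

from phycofilm import (BiofilmStack, batch_metrics, biovolume, cluster_slope,
                       compute_metrics, gen_stack, max_thickness,
                       mean_thickness, roughness, thickness_map,
                       ScenarioConfig)


def slab(n_slices, nz=10, ny=6, nx=6, voxel_z=1.0, voxel_xy=1.0):
    grid = np.zeros((nz, ny, nx), bool)
    grid[:n_slices] = True
    return BiofilmStack(grid, voxel_xy, voxel_z)


class TestBiovolume:
    def test_full_slab(self):
        assert biovolume(slab(10)) == pytest.approx(10.0)

    def test_empty_stack(self):
        assert biovolume(slab(0)) == 0.0

    def test_matches_voxel_count_oracle(self, rng):
        grid = rng.random((10, 30, 30)) > 0.5
        stack = BiofilmStack(grid, 1.25, 3.94)
        expected = grid.sum() * 1.25**2 * 3.94 / (30 * 30 * 1.25**2)
        assert biovolume(stack) == pytest.approx(expected, rel=1e-12)


class TestThickness:
    def test_column_height_from_top_voxel(self):
        grid = np.zeros((8, 1, 1), bool)
        grid[4, 0, 0] = True   # highest occupied slice index 4
        stack = BiofilmStack(grid, 1.25, 3.94)
        assert thickness_map(stack)[0, 0] == pytest.approx(5 * 3.94)

    def test_voids_are_bridged(self):
        grid = np.zeros((8, 1, 1), bool)
        grid[0, 0, 0] = grid[5, 0, 0] = True  # internal void
        stack = BiofilmStack(grid, 1.0, 1.0)
        assert thickness_map(stack)[0, 0] == 6.0
        assert biovolume(stack) == 2.0        # voids not counted as volume

    def test_empty_column_is_zero(self):
        grid = np.zeros((5, 2, 1), bool)
        grid[0, 0, 0] = True
        tm = thickness_map(BiofilmStack(grid, 1.0, 1.0))
        assert tm[1, 0] == 0.0

    def test_reductions_match_map(self, rng):
        grid = rng.random((10, 20, 20)) > 0.7
        stack = BiofilmStack(grid, 1.0, 2.0)
        tm = thickness_map(stack)
        assert max_thickness(stack) == tm.max()
        assert mean_thickness(stack) == pytest.approx(tm.mean())


class TestRoughness:
    def test_flat_slab_is_smooth(self):
        assert roughness(slab(5)) == 0.0

    def test_two_column_heterogeneity(self):
        grid = np.zeros((4, 1, 2), bool)
        grid[:2, 0, 1] = True  # thicknesses (0, 2t): mean deviation t / mean t
        stack = BiofilmStack(grid, 1.0, 1.0)
        assert roughness(stack) == pytest.approx(1.0)

    def test_matches_direct_sum_oracle(self, rng):
        heights = rng.integers(0, 9, size=(15, 15))
        grid = np.arange(10)[:, None, None] < heights[None]
        stack = BiofilmStack(grid, 1.0, 1.0)
        L = heights.astype(float).ravel()
        expected = np.abs(L - L.mean()).mean() / L.mean()
        assert roughness(stack) == pytest.approx(expected, rel=1e-12)

    def test_scale_invariance_and_bound(self, rng):
        heights = rng.integers(0, 5, size=(8, 8))
        g1 = np.arange(10)[:, None, None] < heights[None]
        g2 = np.arange(10)[:, None, None] < (2 * heights)[None]
        r1 = roughness(BiofilmStack(g1, 1.0, 1.0))
        r2 = roughness(BiofilmStack(g2, 1.0, 1.0))
        assert r1 == pytest.approx(r2, rel=1e-12)
        n = 64
        assert r1 < 2 * (n - 1) / n

    def test_empty_stack_undefined(self):
        with pytest.raises(ValueError, match="empty"):
            roughness(slab(0))

    def test_occupied_only_variant(self):
        grid = np.zeros((4, 1, 2), bool)
        grid[:2, 0, 1] = True
        stack = BiofilmStack(grid, 1.0, 1.0)
        assert roughness(stack, occupied_only=True) == 0.0


class TestGeometricInvariance:
    def test_rotation_and_translation(self, rng):
        grid = rng.random((8, 12, 12)) > 0.6
        s0 = BiofilmStack(grid, 1.0, 1.0)
        s_rot = BiofilmStack(np.rot90(grid, axes=(1, 2)), 1.0, 1.0)
        s_shift = BiofilmStack(np.roll(grid, 3, axis=2), 1.0, 1.0)
        for s in (s_rot, s_shift):
            assert biovolume(s) == pytest.approx(biovolume(s0))
            assert roughness(s) == pytest.approx(roughness(s0))
            assert max_thickness(s) == max_thickness(s0)

    def test_solid_morphology_biovolume_equals_mean_thickness(self, rng):
        heights = rng.integers(0, 9, size=(10, 10))
        grid = np.arange(10)[:, None, None] < heights[None]
        stack = BiofilmStack(grid, 1.0, 1.0)
        assert biovolume(stack) == pytest.approx(mean_thickness(stack))


class TestClusterSlope:
    def test_layered_slab_slope_is_unity(self):
        stacks = [slab(n, nz=12) for n in (2, 4, 6, 8, 10)]
        bv = [biovolume(s) for s in stacks]
        mt = [max_thickness(s) for s in stacks]
        slope, r2 = cluster_slope(bv, mt)
        assert slope == pytest.approx(1.0)
        assert r2 > 0.99

    def test_clustered_exceeds_layered(self, scenario):
        """Colony growth shows a steeper max-thickness-vs-biovolume slope
        than conformal growth over a matched biovolume range."""
        targets = 2.0 * np.exp(0.35 * np.arange(5))
        slopes = {}
        for mode in ("layered", "clustered"):
            bv, mt = [], []
            for i, t in enumerate(targets):
                s = gen_stack(scenario, mode, t, label=f"d{i}")
                m = compute_metrics(s)
                bv.append(m.biovolume)
                mt.append(m.max_thickness)
            slopes[mode], _ = cluster_slope(bv, mt)
        assert slopes["clustered"] > slopes["layered"]

    def test_preconditions(self):
        with pytest.raises(ValueError, match="3 time points"):
            cluster_slope([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="constant"):
            cluster_slope([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestBatchMetrics:
    def test_identical_stacks_average_to_single(self):
        stacks = [(0, p, slab(4)) for p in range(5)]
        table = batch_metrics(stacks)
        assert len(table) == 6  # 5 stacks + 1 group row
        mean_row = table[table["position"] == "mean"].iloc[0]
        assert mean_row["biovolume"] == pytest.approx(4.0)
        assert mean_row["biovolume_sd"] == pytest.approx(0.0)

    def test_row_count_stacks_plus_groups(self):
        recs = [(d, p, slab(d + 1)) for d in range(3) for p in range(2)]
        assert len(batch_metrics(recs)) == 6 + 3

    def test_mixed_voxel_dims_rejected(self):
        recs = [(0, 0, slab(3, voxel_z=1.0)), (0, 1, slab(3, voxel_z=2.0))]
        with pytest.raises(ValueError, match="mixed voxel"):
            batch_metrics(recs)
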