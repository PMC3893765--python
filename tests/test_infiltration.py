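"""Clonogen density maps for the three infiltration scenarios."""

import math

import numpy as np
import pytest

from srstcp import (
    GridGeometry,
    InfiltrationConfig,
    StructureMask,
    VoxelGrid3D,
    build_density,
    density_continuous,
    density_heterogeneous,
    density_none,
    distance_to_target,
    make_ellipsoid_mask,
    masked_volume,
)


@pytest.fixture(scope="module")
def small_mask():
    geom = GridGeometry((25, 25, 25), (1, 1, 1), (-12, -12, -12))
    return make_ellipsoid_mask((0, 0, 0), (4, 4, 4), geom)


@pytest.fixture(scope="module")
def small_dmap(small_mask):
    return distance_to_target(small_mask)


class TestDensityNone:
    def test_total_cells_equals_clonogen_number(self, small_mask):
        dens = density_none(small_mask, InfiltrationConfig(clonogen_number_in_target=1e6))
        assert dens.total_cells == pytest.approx(1e6, rel=1e-6)
        assert np.all(dens.values[~small_mask.array] == 0.0)

    def test_single_voxel_target_density(self):
        arr = np.zeros((3, 3, 3))
        arr[1, 1, 1] = 1
        mask = StructureMask(VoxelGrid3D(arr, (1, 1, 1)))
        dens = density_none(mask, InfiltrationConfig())
        assert dens.values[1, 1, 1] == pytest.approx(1e6)

    def test_linearity_in_clonogen_number(self, small_mask):
        d1 = density_none(small_mask, InfiltrationConfig(clonogen_number_in_target=1e6))
        d2 = density_none(small_mask, InfiltrationConfig(clonogen_number_in_target=2e6))
        np.testing.assert_allclose(d2.values, 2 * d1.values)


class TestDensityContinuous:
    def test_exponential_decay_value_at_cutoff(self, small_mask, small_dmap):
        cfg = InfiltrationConfig(scenario="continuous")
        dens = density_continuous(small_mask, small_dmap, cfg)
        d = small_dmap.values
        probe = (d > 9.9) & (d <= 10.0)
        assert probe.any()
        rel = dens.values[probe] / dens.rho0
        np.testing.assert_allclose(rel, np.exp(-d[probe]), rtol=1e-12)
        assert rel.min() > 4.0e-5 and rel.max() < 5.1e-5  # ~exp(-10)

    def test_zero_beyond_cutoff(self, small_mask, small_dmap):
        dens = density_continuous(small_mask, small_dmap, InfiltrationConfig(scenario="continuous"))
        assert np.all(dens.values[small_dmap.values > 10.0] == 0.0)

    def test_continuous_at_border_and_monotone_in_distance(self, small_mask, small_dmap):
        dens = density_continuous(small_mask, small_dmap, InfiltrationConfig(scenario="continuous"))
        d = small_dmap.values
        inside_cut = d <= 10.0
        order = np.argsort(d[inside_cut])
        vals = dens.values[inside_cut][order]
        assert np.all(np.diff(vals) <= 1e-9)  # non-increasing with distance
        near = (d > 0) & (d <= 1.0)
        assert dens.values[near].max() <= dens.rho0
        assert dens.values[near].max() >= dens.rho0 * math.exp(-1.0)

    def test_target_density_matches_none_scenario(self, small_mask, small_dmap):
        inside = small_mask.array
        none = density_none(small_mask, InfiltrationConfig())
        cont = density_continuous(small_mask, small_dmap, InfiltrationConfig(scenario="continuous"))
        np.testing.assert_array_equal(cont.values[inside], none.values[inside])

    def test_grid_mismatch_rejected(self, small_mask):
        other = GridGeometry((10, 10, 10), (1, 1, 1), (0, 0, 0))
        bad_mask = make_ellipsoid_mask((4.5, 4.5, 4.5), (3, 3, 3), other)
        dmap = distance_to_target(bad_mask)
        with pytest.raises(ValueError, match="different grids"):
            density_continuous(small_mask, dmap, InfiltrationConfig(scenario="continuous"))


class TestDensityHeterogeneous:
    cfg = InfiltrationConfig(scenario="heterogeneous", seed=7)

    def test_deterministic_given_seed(self, small_mask, small_dmap):
        a = density_heterogeneous(small_mask, small_dmap, self.cfg)
        b = density_heterogeneous(small_mask, small_dmap, self.cfg)
        np.testing.assert_array_equal(a.values, b.values)

    def test_seed_changes_realization(self, small_mask, small_dmap):
        other = InfiltrationConfig(scenario="heterogeneous", seed=8)
        a = density_heterogeneous(small_mask, small_dmap, self.cfg)
        b = density_heterogeneous(small_mask, small_dmap, other)
        assert not np.array_equal(a.values, b.values)

    def test_occupancy_is_all_or_nothing(self, small_mask, small_dmap):
        dens = density_heterogeneous(small_mask, small_dmap, self.cfg)
        outside = ~small_mask.array
        vals = dens.values[outside]
        assert set(np.unique(vals)).issubset({0.0, dens.rho0})

    def test_zero_beyond_cutoff_every_realization(self, small_mask, small_dmap):
        for seed in range(10):
            cfg = InfiltrationConfig(scenario="heterogeneous", seed=seed)
            dens = density_heterogeneous(small_mask, small_dmap, cfg)
            assert np.all(dens.values[small_dmap.values > 10.0] == 0.0)

    def test_mean_over_seeds_matches_continuous(self, small_mask, small_dmap):
        """Bernoulli occupancy expectation equals the continuous decay (50 seeds)."""
        cont = density_continuous(
            small_mask, small_dmap, InfiltrationConfig(scenario="continuous")
        )
        n_seeds = 50
        acc = np.zeros(small_dmap.values.shape)
        for seed in range(n_seeds):
            cfg = InfiltrationConfig(scenario="heterogeneous", seed=seed)
            acc += density_heterogeneous(small_mask, small_dmap, cfg).values
        mean = acc / n_seeds
        d = small_dmap.values
        probe = (d > 0.5) & (d < 2.0)
        p = np.exp(-d[probe])
        se = np.sqrt(p * (1 - p) / n_seeds) * cont.rho0
        err = np.abs(mean[probe] - cont.values[probe])
        # allow 4 sigma per voxel over ~hundreds of probes
        assert np.all(err <= 4 * se + 1e-9)

    def test_requires_seed(self, small_mask, small_dmap):
        with pytest.raises(ValueError, match="seed"):
            density_heterogeneous(
                small_mask, small_dmap, InfiltrationConfig(scenario="heterogeneous")
            )


class TestConfigAndDispatch:
    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            InfiltrationConfig(scenario="diffusion")

    @pytest.mark.parametrize("bad", [dict(d_max_mm=0), dict(decay_length_mm=-1),
                                     dict(clonogen_number_in_target=0)])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            InfiltrationConfig(**bad)

    def test_build_density_dispatch(self, small_mask, small_dmap):
        for scenario in ("none", "continuous", "heterogeneous"):
            cfg = InfiltrationConfig(scenario=scenario, seed=1)
            dens = build_density(small_mask, cfg, small_dmap)
            assert dens.rho0 == pytest.approx(1e6 / masked_volume(small_mask))
            np.testing.assert_array_equal(
                dens.values[small_mask.array], np.full(small_mask.n_target_voxels, dens.rho0)
            )
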