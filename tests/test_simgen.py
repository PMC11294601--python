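"""Simulator invariants: hard-core spacing, Voronoi region counts, noise model."""

import numpy as np
import pytest
from scipy import ndimage as ndi
from scipy.spatial.distance import pdist

from cyclecell import simgen


class TestTissueMask:
    def test_zero_islands_is_empty(self):
        m = simgen.generate_tissue_mask((256, 256), 0, rng_seed=0)
        assert not m.mask.any()

    @pytest.mark.parametrize("n_islands", [1, 2, 3])
    def test_component_count_matches_request(self, n_islands):
        m = simgen.generate_tissue_mask((256, 256), n_islands, rng_seed=1)
        _, n = ndi.label(m.mask)
        assert n == n_islands

    def test_deterministic_for_fixed_seed(self):
        a = simgen.generate_tissue_mask((256, 256), 2, rng_seed=7)
        b = simgen.generate_tissue_mask((256, 256), 2, rng_seed=7)
        np.testing.assert_array_equal(a.mask, b.mask)

    def test_background_reaches_border(self):
        m = simgen.generate_tissue_mask((256, 256), 2, rng_seed=3)
        assert not m.mask[0].any() and not m.mask[-1].any()

    def test_impossible_geometry_raises(self):
        with pytest.raises(RuntimeError):
            simgen.generate_tissue_mask((64, 64), 40, rng_seed=0,
                                        max_retries=50)

    def test_too_small_shape_rejected(self):
        with pytest.raises(ValueError):
            simgen.generate_tissue_mask((32, 32), 1, rng_seed=0)


class TestHardcoreSeeds:
    def test_zero_density_empty(self):
        m = simgen.TissueMask(np.ones((100, 100), dtype=bool))
        s = simgen.sample_hardcore_seeds(m, 0.0, 8.0, rng_seed=0)
        assert len(s) == 0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_min_pairwise_distance_holds_exactly(self, seed):
        """Brute-force all-pairs check of the hard-core constraint."""
        m = simgen.TissueMask(np.ones((120, 120), dtype=bool))
        s = simgen.sample_hardcore_seeds(m, 0.003, 9.0, rng_seed=seed)
        assert len(s) >= 2
        assert pdist(s.points).min() >= 9.0

    def test_target_count_from_density(self):
        m = simgen.TissueMask(np.ones((100, 100), dtype=bool))
        s = simgen.sample_hardcoreseeds = simgen.sample_hardcore_seeds(
            m, 0.002, 8.0, rng_seed=3, edge_margin=0.0)
        assert round(0.002 * 10000) == 20
        assert len(s) <= 20

    def test_saturation_flagged_not_raised(self):
        m = simgen.TissueMask(np.ones((64, 64), dtype=bool))
        s = simgen.sample_hardcore_seeds(m, 0.5, 20.0, rng_seed=0,
                                         max_proposals=500)
        assert s.saturated
        assert len(s) < round(0.5 * 64 * 64)

    def test_points_inside_mask(self):
        m = simgen.generate_tissue_mask((128, 128), 1, rng_seed=2)
        s = simgen.sample_hardcore_seeds(m, 0.004, 8.0, rng_seed=0)
        idx = np.round(s.points).astype(int)
        assert m.mask[idx[:, 0], idx[:, 1]].all()


class TestRenderMembranes:
    def test_two_seeds_bisector(self):
        """Two seeds in a full mask: one boundary, two regions split by the
        perpendicular bisector."""
        m = simgen.TissueMask(np.ones((64, 64), dtype=bool))
        seeds = simgen.SeedSet(points=np.array([[32.0, 16.0], [32.0, 48.0]]),
                               min_distance=10, density=0)
        sample = simgen.render_membranes(seeds, m, membrane_width=1)
        interior = m.mask & ~sample.binary
        lab, n = ndi.label(interior)
        assert n == 2
        # regions sit left/right of the vertical bisector col=32
        assert lab[32, 5] != lab[32, 60]

    @pytest.mark.parametrize("index", [0, 1, 2])
    def test_region_count_equals_seed_count(self, index):
        s = simgen.generate_training_sample(rng_seed=11, index=index)
        interior = s.mask.mask & ~s.binary
        _, n = ndi.label(interior)
        assert n == len(s.centers)

    def test_each_seed_in_its_own_region(self, honeycomb_sample):
        s = honeycomb_sample
        interior = s.mask.mask & ~s.binary
        lab, n = ndi.label(interior)
        idx = np.round(s.centers.points).astype(int)
        region_of_seed = lab[idx[:, 0], idx[:, 1]]
        assert (region_of_seed > 0).all()          # seeds off-membrane
        assert len(set(region_of_seed)) == len(s.centers)  # one region each

    def test_seed_set_passed_through(self):
        m = simgen.TissueMask(np.ones((64, 64), dtype=bool))
        seeds = simgen.SeedSet(points=np.array([[20.0, 20.0], [40.0, 40.0]]),
                               min_distance=10, density=0)
        sample = simgen.render_membranes(seeds, m)
        assert sample.centers is seeds

    def test_single_seed_gives_contour_only(self):
        m = simgen.generate_tissue_mask((128, 128), 1, rng_seed=4)
        seeds = simgen.SeedSet(
            points=np.argwhere(ndi.binary_erosion(m.mask, iterations=5))
            [:1].astype(float), min_distance=10, density=0)
        sample = simgen.render_membranes(seeds, m, membrane_width=1)
        # no Voronoi boundary: nothing deep inside the island is membrane
        assert not (sample.binary & ndi.binary_erosion(
            m.mask, iterations=3)).any()
        # and the membrane forms a closed ring: the island interior is one
        # region fully enclosed by it
        interior = m.mask & ~sample.binary
        lab, n = ndi.label(interior)
        assert n == 1
        border = set(np.unique(np.concatenate(
            [lab[0], lab[-1], lab[:, 0], lab[:, -1]])))
        assert lab.max() not in border


class TestRenderRcm:
    def test_noiseless_limit_reproduces_binary(self, honeycomb_sample,
                                               noiseless_params):
        img = simgen.render_synthetic_rcm(honeycomb_sample, noiseless_params,
                                          rng_seed=0)
        np.testing.assert_array_equal(img,
                                      honeycomb_sample.binary.astype(float))

    def test_membranes_brighter_than_background(self, honeycomb_sample):
        img = simgen.render_synthetic_rcm(honeycomb_sample,
                                          simgen.NoiseParams(), rng_seed=1)
        on = img[honeycomb_sample.binary].mean()
        off = img[~honeycomb_sample.binary].mean()
        assert on > off

    def test_bit_identical_for_same_seed(self, honeycomb_sample):
        p = simgen.NoiseParams()
        a = simgen.render_synthetic_rcm(honeycomb_sample, p, rng_seed=9)
        b = simgen.render_synthetic_rcm(honeycomb_sample, p, rng_seed=9)
        np.testing.assert_array_equal(a, b)

    def test_output_in_unit_range(self, honeycomb_sample):
        img = simgen.render_synthetic_rcm(honeycomb_sample,
                                          simgen.NoiseParams(), rng_seed=2)
        assert img.min() >= 0.0 and img.max() <= 1.0

    def test_negative_noise_param_rejected(self):
        with pytest.raises(ValueError):
            simgen.NoiseParams(speckle_sigma=-0.1)


class TestNonconfluent:
    def test_zero_overlap_two_disks_disjoint(self):
        s = simgen.generate_nonconfluent_sample((128, 128), 2,
                                                radius_range=(8, 12),
                                                max_overlap_fraction=0.0,
                                                rng_seed=0)
        assert len(s.centers) == 2
        d = np.linalg.norm(s.centers.points[0] - s.centers.points[1])
        assert d >= sum(s.params["radii"]) - 1e-9

    @pytest.mark.parametrize("frac", [0.0, 0.15, 0.3])
    def test_pairwise_overlap_bound_brute_force(self, frac):
        s = simgen.generate_nonconfluent_sample((160, 160), 15,
                                                radius_range=(6, 12),
                                                max_overlap_fraction=frac,
                                                rng_seed=2)
        pts, radii = s.centers.points, s.params["radii"]
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                d = np.linalg.norm(pts[i] - pts[j])
                lens = simgen._lens_area(d, radii[i], radii[j])
                small = min(radii[i], radii[j])
                assert lens <= frac * np.pi * small ** 2 + 1e-6

    def test_zero_cells_empty(self):
        s = simgen.generate_nonconfluent_sample((64, 64), 0, rng_seed=0)
        assert len(s.centers) == 0
        assert not s.binary.any()

    def test_saturation_flag_on_impossible_packing(self):
        s = simgen.generate_nonconfluent_sample(
            (64, 64), 500, radius_range=(10, 12), max_overlap_fraction=0.0,
            rng_seed=0, max_proposals=2000)
        assert s.centers.saturated
        assert len(s.centers) < 500


def test_sample_rng_counter_scheme_isolated():
    """Sample i is reproducible without generating samples 0..i-1."""
    a = simgen.sample_rng(123, 5).random(4)
    b = simgen.sample_rng(123, 5).random(4)
    c = simgen.sample_rng(123, 6).random(4)
    np.testing.assert_array_equal(a, b)
    assert not np.array_equal(a, c)
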