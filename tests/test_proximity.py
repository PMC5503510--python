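import numpy as np
import pytest
from scipy import ndimage as ndi

from chanprox.locmap import RasterMap
from chanprox.segmentation import build_catalog
from chanprox import proximity
from chanprox.proximity import (annulus_occupancy, edge_distance_map,
                                fit_distance_bell, fraction_refs_isolated,
                                fraction_targets_near, mean_targets_within,
                                nearest_edge_distances, overlap_percent)
from _oracles import brute_edge_distance_map, brute_nearest_cluster_distances
from conftest import random_blob_mask


def catalog_of(mask, pixel_size_nm=20.0):
    lab, _ = ndi.label(mask, structure=np.ones((3, 3)))
    return build_catalog(lab, pixel_size_nm=pixel_size_nm)


class TestEdgeDistanceMap:
    def test_three_four_five_triangle(self):
        g = np.zeros((10, 10), dtype=bool)
        g[0, 0] = True
        d = edge_distance_map(RasterMap(g, pixel_size_nm=20))
        assert d[3, 4] == pytest.approx(100.0)
        assert d[4, 3] == pytest.approx(100.0)

    def test_zero_on_reference(self, rng):
        g = random_blob_mask(rng, (32, 32))
        d = edge_distance_map(RasterMap(g, pixel_size_nm=20))
        assert np.all(d[g] == 0)

    def test_matches_bruteforce(self, rng):
        for _ in range(10):
            g = rng.random((24, 24)) < 0.05
            if not g.any():
                g[5, 5] = True
            d = edge_distance_map(RasterMap(g, pixel_size_nm=20))
            np.testing.assert_allclose(d, brute_edge_distance_map(g, 20.0),
                                       atol=1e-9)

    def test_empty_reference_errors(self):
        with pytest.raises(ValueError):
            edge_distance_map(np.zeros((5, 5), dtype=bool))


class TestNearestEdgeDistances:
    def test_adjacent_cluster_one_pixel_away(self):
        ref = np.zeros((10, 10), dtype=bool)
        ref[4, 4] = True
        tgt = np.zeros_like(ref)
        tgt[4, 5] = True
        d = nearest_edge_distances(catalog_of(tgt), RasterMap(ref, pixel_size_nm=20))
        assert d.distances_nm[0] == pytest.approx(20.0)

    def test_overlap_is_zero(self):
        ref = np.zeros((10, 10), dtype=bool)
        ref[2:5, 2:5] = True
        tgt = np.zeros_like(ref)
        tgt[4:7, 4:7] = True
        d = nearest_edge_distances(catalog_of(tgt), ref)
        assert d.distances_nm[0] == 0.0

    def test_matches_bruteforce(self, rng):
        for _ in range(8):
            ref = rng.random((32, 32)) < 0.04
            if not ref.any():
                ref[0, 0] = True
            tgt = random_blob_mask(rng, (32, 32), density=0.03)
            if not tgt.any():
                tgt[20, 20] = True
            cat = catalog_of(tgt)
            d = nearest_edge_distances(cat, RasterMap(ref, pixel_size_nm=20))
            expected = brute_nearest_cluster_distances(
                [c.pixels for c in cat.clusters], ref, 20.0)
            np.testing.assert_allclose(d.distances_nm, expected, atol=1e-9)

    def test_grid_mismatch_errors(self):
        ref = np.zeros((10, 10), dtype=bool)
        ref[0, 0] = True
        tgt = np.zeros((12, 12), dtype=bool)
        tgt[5, 5] = True
        with pytest.raises(ValueError, match="mismatch"):
            nearest_edge_distances(catalog_of(tgt), ref)


class TestAnnulusOccupancy:
    def test_rings_partition_footprint(self, rng):
        ref = np.zeros((40, 40), dtype=bool)
        ref[18:22, 18:22] = True
        tgt = random_blob_mask(rng, (40, 40))
        prof = annulus_occupancy(RasterMap(ref, pixel_size_nm=20), tgt,
                                 max_radius_nm=20 * 60)   # covers whole grid
        assert prof.ring_pixels.sum() == 40 * 40

    def test_uniform_target_all_rings_near_density(self, rng):
        ref = np.zeros((200, 200), dtype=bool)
        ref[95:105, 95:105] = True
        tgt = (rng.random((200, 200)) < 0.10) & ~ref
        prof = annulus_occupancy(RasterMap(ref, pixel_size_nm=20), tgt)
        # rings away from the mask hold ~10% occupancy (binomial spread)
        for pct, n in zip(prof.occupied_percent[1:], prof.ring_pixels[1:]):
            se = 100 * np.sqrt(0.1 * 0.9 / n)
            assert abs(pct - 10.0) < 4 * se

    def test_target_equals_ref_gives_full_ring0(self):
        ref = np.zeros((30, 30), dtype=bool)
        ref[10:15, 10:15] = True
        prof = annulus_occupancy(ref, ref)
        assert prof.occupied_percent[0] == 100.0

    def test_disjoint_target_ring0_zero(self):
        ref = np.zeros((30, 30), dtype=bool)
        ref[5:8, 5:8] = True
        tgt = np.zeros_like(ref)
        tgt[20:22, 20:22] = True
        assert annulus_occupancy(ref, tgt).occupied_percent[0] == 0.0

    def test_empty_ring_reported_missing(self):
        # tiny grid: outer rings have no pixels -> NaN, not 0
        ref = np.ones((3, 3), dtype=bool)
        prof = annulus_occupancy(ref, np.zeros_like(ref))
        assert np.isnan(prof.occupied_percent[-1])

    def test_translation_invariance(self):
        ref = np.zeros((60, 60), dtype=bool)
        ref[10:14, 10:14] = True
        tgt = np.zeros_like(ref)
        tgt[16:18, 10:12] = True
        p1 = annulus_occupancy(ref, tgt)
        p2 = annulus_occupancy(np.roll(ref, (20, 25), (0, 1)),
                               np.roll(tgt, (20, 25), (0, 1)))
        np.testing.assert_allclose(p1.occupied_percent, p2.occupied_percent,
                                   equal_nan=True)


class TestScalarStatistics:
    def test_isolated_and_near_trivial_cases(self):
        ref = np.zeros((50, 50), dtype=bool)
        ref[10:13, 10:13] = True
        near_tgt = np.zeros_like(ref)
        near_tgt[14, 14] = True
        assert fraction_refs_isolated(catalog_of(ref), near_tgt) == 0.0
        assert fraction_targets_near(catalog_of(near_tgt), ref) == 1.0
        far_tgt = np.zeros_like(ref)
        far_tgt[45, 45] = True     # ~900 nm away
        assert fraction_refs_isolated(catalog_of(ref), far_tgt) == 1.0
        assert fraction_targets_near(catalog_of(far_tgt), ref) == 0.0
        assert fraction_refs_isolated(catalog_of(ref), np.zeros_like(ref)) == 1.0

    def test_mean_targets_within_counts_by_edge_distance(self):
        ref = np.zeros((40, 40), dtype=bool)
        ref[20, 20] = True
        tgt = np.zeros_like(ref)
        tgt[20, 22] = True    # 40 nm
        tgt[22, 20] = True    # 40 nm
        tgt[20, 26] = True    # 120 nm
        res = mean_targets_within(catalog_of(ref), catalog_of(tgt), radius_nm=50)
        assert res["mean"] == 2.0
        assert list(res["counts"]) == [2]

    def test_mean_targets_within_no_targets(self):
        ref = np.zeros((10, 10), dtype=bool)
        ref[3, 3] = True
        empty = catalog_of(np.zeros_like(ref))
        assert mean_targets_within(catalog_of(ref), empty)["mean"] == 0.0

    def test_overlap_percent_arithmetic(self):
        ref = np.zeros((10, 10), dtype=bool)
        ref[0:5, 0:10] = True      # 50 px
        tgt = np.zeros_like(ref)
        tgt[0, 0:5] = True         # 5 of them overlap
        assert overlap_percent(ref, tgt) == pytest.approx(10.0)
        assert overlap_percent(ref, np.zeros_like(ref)) == 0.0
        assert overlap_percent(ref, np.ones_like(ref)) == 100.0

    def test_pairwise_cutoff_consistent_with_exact(self, rng):
        ref = random_blob_mask(rng, (48, 48), density=0.02)
        tgt = random_blob_mask(rng, (48, 48), density=0.02)
        if not (ref.any() and tgt.any()):
            pytest.skip("degenerate draw")
        rc, tc = catalog_of(ref), catalog_of(tgt)
        full = proximity.cluster_pair_distances(rc, tc)
        cut = proximity.cluster_pair_distances(rc, tc, cutoff_nm=100.0)
        inside = full <= 100.0
        np.testing.assert_allclose(cut[inside], full[inside])


class TestDistanceBell:
    def test_recovers_known_gaussian(self, rng):
        d = rng.normal(120.0, 30.0, 10_000)
        d = d[d > 0]
        fit = fit_distance_bell(d, bin_width_nm=10.0)
        assert fit["peak_nm"] == pytest.approx(120.0, abs=2.0)
        assert fit["fwhm_nm"] == pytest.approx(2.3548 * 30.0, rel=0.05)
        assert fit["hwhm_nm"] == pytest.approx(fit["fwhm_nm"] / 2)

    def test_translation_equivariance(self, rng):
        d = np.abs(rng.normal(80.0, 15.0, 5000))
        f1 = fit_distance_bell(d, 10.0)
        f2 = fit_distance_bell(d + 40.0, 10.0)
        assert f2["peak_nm"] - f1["peak_nm"] == pytest.approx(40.0, abs=2.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_distance_bell(np.full(100, 60.0))
        with pytest.raises(ValueError):
            fit_distance_bell(np.array([1.0, 2.0]))
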