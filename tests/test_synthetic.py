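import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chanprox.locmap import bleedthrough_fraction
from chanprox import proximity
from chanprox.synthetic import (SceneSpec, convolved_line_fwhm,
                                generate_cluster_scene, generate_gv_dataset,
                                generate_line_structures,
                                generate_single_channel_trace,
                                sample_distribution)


class TestDeterminism:
    def test_scene_bit_identical_given_seed(self):
        spec = SceneSpec(seed=21, n_red_clusters=6, n_green_clusters=15)
        r1, g1, t1 = generate_cluster_scene(spec)
        r2, g2, t2 = generate_cluster_scene(SceneSpec(seed=21, n_red_clusters=6,
                                                      n_green_clusters=15))
        pd.testing.assert_frame_equal(r1.df, r2.df)
        pd.testing.assert_frame_equal(g1.df, g2.df)
        np.testing.assert_array_equal(t1.association_labels, t2.association_labels)
        np.testing.assert_array_equal(t1.true_gap_nm, t2.true_gap_nm)

    def test_other_generators_deterministic(self):
        a = generate_gv_dataset(-37, 4, 1.0, 126, np.arange(-80, 40, 5),
                                noise_sd=2.0, seed=9)
        b = generate_gv_dataset(-37, 4, 1.0, 126, np.arange(-80, 40, 5),
                                noise_sd=2.0, seed=9)
        np.testing.assert_array_equal(a.currents_pA, b.currents_pA)
        ta = generate_single_channel_trace(3, 0.5, 8.0, 0.5, 200.0, seed=4)
        tb = generate_single_channel_trace(3, 0.5, 8.0, 0.5, 200.0, seed=4)
        np.testing.assert_array_equal(ta.samples_pA, tb.samples_pA)


class TestClusterScene:
    def test_degenerate_gap_all_twenty_nm(self):
        """association 1, gap = 20 nm exactly: every true edge gap is 20 nm."""
        spec = SceneSpec(
            seed=5, n_red_clusters=8, n_green_clusters=16,
            association_fraction=1.0,
            association_gap_nm_dist={"kind": "constant", "value": 20.0},
            localization_sigma_nm=0.0,
            field_width_nm=12_000.0, field_height_nm=12_000.0,
        )
        _, _, truth = generate_cluster_scene(spec)
        assert np.all(truth.association_labels >= 0)
        np.testing.assert_allclose(truth.true_gap_nm, 20.0, atol=0.2)

    def test_ground_truth_scalars_recomputable_from_catalogs(self, default_scene):
        truth = default_scene[3]
        red_mask = truth.true_red_catalog.mask()
        iso = 1.0 - proximity.fraction_targets_near(
            truth.true_green_catalog, red_mask, radius_nm=200.0)
        assert iso == pytest.approx(truth.true_isolated_fraction)
        mw = proximity.mean_targets_within(
            truth.true_red_catalog, truth.true_green_catalog, radius_nm=50.0)
        assert mw["mean"] == pytest.approx(truth.true_mean_green_within_50nm)

    def test_photon_distribution_matches_spec(self):
        """Pooled photon draws pass a KS test against the spec log-normal."""
        spec = SceneSpec(seed=8, n_red_clusters=0, n_green_clusters=120,
                         association_fraction=0.0,
                         events_per_cluster_dist={"kind": "constant", "value": 90},
                         bleedthrough_green_into_red=0.0,
                         bleedthrough_red_into_green=0.0,
                         field_width_nm=20_000.0, field_height_nm=20_000.0)
        _, green, _ = generate_cluster_scene(spec)
        photons = green.photons
        assert len(photons) >= 10_000
        dist = stats.lognorm(s=1.0, scale=1900.0)
        res = stats.kstest(photons, dist.cdf)
        assert res.pvalue > 0.01

    def test_events_per_cluster_matches_spec(self):
        spec = SceneSpec(seed=3, n_red_clusters=0, n_green_clusters=200,
                         association_fraction=0.0,
                         bleedthrough_green_into_red=0.0,
                         bleedthrough_red_into_green=0.0,
                         localization_sigma_nm=0.0,
                         field_width_nm=30_000.0, field_height_nm=30_000.0)
        _, green, truth = generate_cluster_scene(spec)
        # count events per true cluster by nearest-centroid assignment
        counts = np.zeros(len(truth.true_green_catalog))
        cents = np.array([c.centroid_nm for c in truth.true_green_catalog.clusters])
        for x, y in zip(green.x_nm, green.y_nm):
            counts[np.argmin((cents[:, 0] - x) ** 2 + (cents[:, 1] - y) ** 2)] += 1
        ref = np.maximum(np.random.default_rng(99).poisson(30.0, 20_000), 3)
        res = stats.ks_2samp(counts, ref)
        assert res.pvalue > 0.01

    def test_subthreshold_events_flagged_not_dropped(self):
        spec = SceneSpec(seed=2, n_red_clusters=4, n_green_clusters=4,
                         association_fraction=0.0,
                         photons_dist={"kind": "uniform", "low": 10, "high": 90})
        red, green, _ = generate_cluster_scene(spec)
        for t in (red, green):
            below = t.df["photons"] < 50
            assert below.any()                      # kept in the table ...
            assert (~t.df.loc[below, "above_threshold"]).all()   # ... but flagged

    def test_bleedthrough_fraction_recovered(self):
        spec = SceneSpec(seed=6, n_red_clusters=0, n_green_clusters=150,
                         association_fraction=0.0,
                         events_per_cluster_dist={"kind": "constant", "value": 60},
                         bleedthrough_green_into_red=0.008,
                         bleedthrough_red_into_green=0.0,
                         field_width_nm=20_000.0, field_height_nm=20_000.0)
        red, green, _ = generate_cluster_scene(spec)
        n = len(green)
        est = bleedthrough_fraction(red, green)
        se = np.sqrt(0.008 * 0.992 / n)
        assert abs(est - 0.008) < 3.5 * se

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            SceneSpec(association_fraction=1.5).validate()
        with pytest.raises(ValueError):
            SceneSpec(field_width_nm=-1).validate()


class TestLineStructures:
    def test_zero_blur_events_exactly_on_line(self):
        table, truth = generate_line_structures(0.0, 0.0, 500, seed=1)
        y_line = truth["segments"][0][0][1]
        np.testing.assert_allclose(table.y_nm, y_line)
        assert truth["fwhm_nm"] == 0.0

    def test_closed_form_fwhm_zero_width(self):
        assert convolved_line_fwhm(0.0, 14.0) == pytest.approx(2.3548 * 14.0,
                                                               rel=1e-4)
        assert convolved_line_fwhm(30.0, 0.0) == 30.0

    def test_convolved_fwhm_between_limits(self):
        fw = convolved_line_fwhm(25.0, 14.0)
        assert fw > 2.3548 * 14.0
        assert fw > 25.0
        assert fw < 25.0 + 2.3548 * 14.0


class TestEphysGenerators:
    def test_midpoint_current_identity(self):
        series = generate_gv_dataset(-37.0, 4.0, 2.0, 126.0, [-37.0])
        assert series.currents_pA[0] == pytest.approx(0.5 * 2.0 * (-37.0 - 126.0))

    def test_trace_limits(self):
        tr0 = generate_single_channel_trace(3, 0.0, 8.0, 0.0, 100.0, seed=1)
        assert tr0.metadata["true_npo"] == 0.0
        assert not tr0.samples_pA.any()
        tr1 = generate_single_channel_trace(2, 1.0, 8.0, 0.0, 100.0, seed=1)
        np.testing.assert_allclose(tr1.samples_pA, 16.0)

    def test_single_channel_occupancy_converges(self):
        tr = generate_single_channel_trace(1, 0.5, 8.0, 0.0, 20_000.0,
                                           dwell_ms=5.0, seed=12)
        assert tr.idealization.mean() == pytest.approx(0.5, abs=0.03)


def test_sample_distribution_kinds(rng):
    assert np.all(sample_distribution({"kind": "constant", "value": 3}, 5, rng) == 3)
    u = sample_distribution({"kind": "uniform", "low": 1, "high": 2}, 100, rng)
    assert u.min() >= 1 and u.max() <= 2
    p = sample_distribution({"kind": "poisson", "mean": 5, "min": 2}, 100, rng)
    assert p.min() >= 2
    with pytest.raises(ValueError):
        sample_distribution({"kind": "zipf"}, 3, rng)
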