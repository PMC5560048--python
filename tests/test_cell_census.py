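"""Nucleus detection, window counts, red areas and population tracking."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from jointquant import (
    CountWindow,
    SceneParams,
    count_in_window,
    detect_nuclei,
    generate_tracking_pair,
    percent_increase,
    red_area,
    track_population,
)
from jointquant.errors import DegenerateHistogramError, DomainError, UndefinedBaselineError


class TestDetectNuclei:
    def test_constant_stack_gives_empty_detection(self, stack_factory):
        stack = stack_factory(np.full((4, 1, 8, 8), 50.0), channels=("GFP",))
        det = detect_nuclei(stack, "GFP")
        assert det.count == 0

    def test_recovers_well_separated_planted_blobs(self):
        from jointquant.synthetic_data import generate_joint_stack

        params = SceneParams(
            seed=3,
            shape_vox=(20, 112, 160),
            n_gfp_nuclei=8,
            min_nucleus_separation_um=22.0,
            cluster_sd_um=30.0,
            nucleus_radius_um=4.0,
        )
        stack, truth = generate_joint_stack(params)
        det = detect_nuclei(stack, "GFP", min_size_vox=30)
        assert det.count == 8
        # each centroid within one voxel (max axis pitch 1 um) of a planted center
        dists = np.linalg.norm(
            det.centroids_um[:, None, :] - truth.nuclei_centers_um[None, :, :], axis=2
        ).min(axis=1)
        assert dists.max() < 1.0

    def test_touching_blobs_merge_into_one_component(self, stack_factory):
        vox = np.full((7, 1, 9, 15), 10.0)
        vox[2:5, 0, 3:6, 3:6] = 200.0
        vox[2:5, 0, 3:6, 6:9] = 200.0  # adjacent block: 26-connected with the first
        det = detect_nuclei(stack_factory(vox, channels=("GFP",)), "GFP", min_size_vox=5)
        assert det.count == 1  # documented under-count for abutting nuclei

    def test_min_size_filter_discards_specks(self, stack_factory):
        vox = np.full((7, 1, 12, 12), 10.0)
        vox[2:5, 0, 2:5, 2:5] = 200.0  # 27-voxel nucleus
        vox[6, 0, 10, 10] = 200.0  # single-voxel speck
        det = detect_nuclei(stack_factory(vox, channels=("GFP",)), "GFP", min_size_vox=5)
        assert det.count == 1


class TestCountWindow:
    def test_empty_input_counts_zero(self):
        assert count_in_window(np.empty((0, 3)), CountWindow((0.0, 0.0))) == 0

    def test_centroid_at_anchor_counts(self):
        assert count_in_window(np.array([[5.0, 5.0, 1.0]]), CountWindow((5.0, 5.0))) == 1

    def test_low_edge_inclusive_high_edge_exclusive(self):
        w = CountWindow((0.0, 0.0), width=10.0, height=10.0)
        assert count_in_window(np.array([[-5.0, 0.0]]), w) == 1
        assert count_in_window(np.array([[5.0, 0.0]]), w) == 0

    def test_matches_exhaustive_membership(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(-60, 60, size=(100, 2))
        w = CountWindow((3.0, -7.0), width=50.0, height=80.0)
        expected = sum(
            1
            for x, y in pts
            if 3.0 - 25.0 <= x < 3.0 + 25.0 and -7.0 - 40.0 <= y < -7.0 + 40.0
        )
        assert count_in_window(pts, w) == expected

    def test_translation_equivariance(self):
        rng = np.random.default_rng(9)
        pts = rng.uniform(0, 100, size=(50, 2))
        w0 = CountWindow((50.0, 50.0))
        shift = np.array([13.7, -4.2])
        w1 = CountWindow((50.0 + shift[0], 50.0 + shift[1]))
        assert count_in_window(pts, w0) == count_in_window(pts + shift, w1)

    def test_nonpositive_window_rejected(self):
        with pytest.raises(DomainError):
            CountWindow((0.0, 0.0), width=0.0)


class TestRedArea:
    def test_fixed_threshold_square(self, stack_factory):
        vox = np.full((3, 1, 20, 20), 10.0)
        vox[1, 0, 5:15, 5:15] = 200.0  # 10x10 px on the MIP
        stack = stack_factory(vox, voxel_size=(1.0, 0.5, 0.5), channels=("redKaede",))
        assert red_area(stack, "redKaede", threshold=100.0) == pytest.approx(25.0)

    def test_background_with_fixed_threshold_is_zero(self, stack_factory):
        stack = stack_factory(np.full((3, 1, 8, 8), 10.0), channels=("redKaede",))
        assert red_area(stack, "redKaede", threshold=100.0) == 0.0

    def test_constant_projection_with_otsu_raises(self, stack_factory):
        stack = stack_factory(np.full((3, 1, 8, 8), 10.0), channels=("redKaede",))
        with pytest.raises(DegenerateHistogramError):
            red_area(stack, "redKaede", threshold="otsu")

    def test_planted_disc_area_recovered(self):
        """Rendered red cells: combined MIP area within 10% of the analytic
        supra-threshold disc area at the measured threshold."""
        params = SceneParams(seed=21, division_prob=0.0, migration_scale_um=0.0)
        t0, _, truth = generate_tracking_pair(params, "control")
        from jointquant.gfp_volume import otsu_threshold
        from jointquant.image_io import max_intensity_projection

        t = otsu_threshold(max_intensity_projection(t0, "redKaede"))
        measured = red_area(t0, "redKaede", threshold=t)
        # analytic: each Gaussian cell's MIP crosses t at r = sigma*sqrt(2 ln(A/(t-bg)))
        sigma = truth.nucleus_sigma_um
        r2 = 2 * sigma**2 * np.log(params.red_amplitude / (t - params.background))
        expected = truth.true_count_t0 * np.pi * r2
        assert measured == pytest.approx(expected, rel=0.10)


class TestPercentIncrease:
    @pytest.mark.parametrize("v0, v1, expected", [(10, 10, 0.0), (50, 100, 100.0), (40, 30, -25.0)])
    def test_known_values(self, v0, v1, expected):
        assert percent_increase(v0, v1) == pytest.approx(expected)

    @pytest.mark.parametrize("v0", [0.0, -3.0])
    def test_nonpositive_baseline_raises(self, v0):
        with pytest.raises(UndefinedBaselineError):
            percent_increase(v0, 5.0)

    @given(
        v=st.floats(min_value=1e-3, max_value=1e6),
        p=st.floats(min_value=-99.0, max_value=500.0),
    )
    @settings(derandomize=True, max_examples=100)
    def test_round_trip_identity(self, v, p):
        assert percent_increase(v, v * (1 + p / 100.0)) == pytest.approx(p, abs=1e-6)


class TestTrackPopulation:
    def test_identical_stacks_give_zero_increase(self):
        params = SceneParams(seed=13, division_prob=0.0, migration_scale_um=0.0)
        t0, _, _ = generate_tracking_pair(params, "control")
        pop = track_population(t0, t0)
        assert pop.pct_count_increase == 0.0
        assert pop.pct_area_increase == 0.0

    def test_every_cell_dividing_doubles_the_count(self):
        params = SceneParams(seed=2, division_prob=1.0, migration_scale_um=0.0)
        t0, t1, truth = generate_tracking_pair(params, "control")
        pop = track_population(t0, t1)
        assert truth.true_pct_count_increase == 100.0
        assert pop.pct_count_increase == pytest.approx(100.0)

    def test_no_planted_events_give_zero_truth_increase(self):
        params = SceneParams(seed=4, division_prob=0.0, migration_scale_um=0.0)
        _, _, truth = generate_tracking_pair(params, "control", render=False)
        assert truth.true_pct_count_increase == 0.0
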