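"""Determinism, planted-truth consistency and condition presets of the generator."""

import numpy as np
import pytest

from jointquant import (
    CONDITION_PRESETS,
    SceneParams,
    compare_groups,
    generate_cohort,
    generate_joint_stack,
    generate_tracking_pair,
)
from jointquant.errors import DomainError
from jointquant.synthetic_data import joint_roi


class TestSceneParams:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(DomainError):
            SceneParams(seed=1, rod_radius_um=0.0)
        with pytest.raises(DomainError):
            SceneParams(seed=1, division_prob=1.5)
        with pytest.raises(DomainError):
            SceneParams(seed=1, rod_radius_um=60.0)  # rod larger than the field

    def test_seed_is_mandatory(self):
        with pytest.raises(TypeError):
            SceneParams()


class TestGenerateJointStack:
    def test_same_seed_is_bit_identical(self):
        p = SceneParams(seed=42)
        s1, _ = generate_joint_stack(p)
        s2, _ = generate_joint_stack(p)
        np.testing.assert_array_equal(s1.voxels, s2.voxels)
        assert s1.voxels.dtype == np.uint16

    def test_different_seeds_differ(self):
        s1, _ = generate_joint_stack(SceneParams(seed=1))
        s2, _ = generate_joint_stack(SceneParams(seed=2))
        assert (s1.voxels != s2.voxels).any()

    def test_no_nuclei_leaves_pure_noise_background(self):
        p = SceneParams(seed=6, n_gfp_nuclei=0)
        stack, truth = generate_joint_stack(p)
        gfp = stack.channel("GFP").astype(float)
        # mean within 3 standard errors of the noise model's background
        se = np.sqrt(p.gaussian_noise_sd**2 + p.background) / np.sqrt(gfp.size)
        assert abs(gfp.mean() - p.background) < 3 * se

    def test_truth_lists_planted_nuclei_and_gap(self):
        p = SceneParams(seed=9, n_gfp_nuclei=7, interzone_gap_um=-3.0)
        _, truth = generate_joint_stack(p)
        assert len(truth.nuclei_centers_um) == 7
        assert truth.interzone_gap_um == -3.0

    def test_single_blob_supra_threshold_volume_recovered(self):
        """The scene's isocontour truth: pipeline volume within 15% of the
        noiseless supra-threshold hull at the measured threshold."""
        from jointquant import quantify_region

        p = SceneParams(seed=12, n_gfp_nuclei=1, cluster_sd_um=2.0, nucleus_radius_um=5.0)
        stack, truth = generate_joint_stack(p)
        rep = quantify_region(stack, "GFP", joint_roi(p, 18.0), "joint")
        expected = truth.suprathreshold_hull_volume(rep.threshold)
        assert rep.volume_um3 == pytest.approx(expected, rel=0.15)

    def test_truth_serialises(self, tmp_path):
        _, truth = generate_joint_stack(SceneParams(seed=3))
        truth.to_json(tmp_path / "truth.json")
        assert (tmp_path / "truth.json").stat().st_size > 0


class TestGenerateTrackingPair:
    def test_no_events_means_no_true_increase(self):
        p = SceneParams(seed=5, division_prob=0.0, migration_scale_um=0.0)
        _, _, truth = generate_tracking_pair(p, "control", render=False)
        assert truth.true_pct_count_increase == 0.0
        assert len(truth.events) == 0
        np.testing.assert_allclose(truth.red_t0_um, truth.red_t1_um)

    def test_forced_division_doubles_truth_count(self):
        p = SceneParams(seed=5, division_prob=1.0)
        _, _, truth = generate_tracking_pair(p, "control", render=False)
        assert truth.true_count_t1 == 2 * truth.true_count_t0

    def test_batch_size_drawn_from_10_to_12(self):
        sizes = {
            generate_tracking_pair(SceneParams(seed=s), "control", render=False)[2].true_count_t0
            for s in range(30)
        }
        assert sizes <= {10, 11, 12} and len(sizes) > 1

    def test_division_rate_matches_binomial_expectation(self):
        """Mean true count increase over replicate pairs ~ 100 * division prob."""
        p_div = 0.5
        incs = []
        for seed in range(300):
            p = SceneParams(seed=seed, division_prob=p_div)
            _, _, truth = generate_tracking_pair(p, "control", render=False)
            incs.append(truth.true_pct_count_increase)
        incs = np.asarray(incs)
        se = incs.std(ddof=1) / np.sqrt(len(incs))
        assert abs(incs.mean() - 100.0 * p_div) < 3 * se

    def test_render_false_matches_rendered_truth(self):
        p = SceneParams(seed=8)
        _, _, t_fast = generate_tracking_pair(p, "control", render=False)
        _, _, t_full = generate_tracking_pair(p, "control", render=True)
        np.testing.assert_allclose(t_fast.red_t1_um, t_full.red_t1_um)

    def test_unknown_condition_rejected(self):
        with pytest.raises(DomainError):
            generate_tracking_pair(SceneParams(seed=1), "mystery")

    def test_condition_ordering_in_truth(self):
        ctrl, imm = [], []
        for seed in range(60):
            p = SceneParams(seed=seed)
            ctrl.append(generate_tracking_pair(p, "control", render=False)[2].true_pct_count_increase)
            imm.append(generate_tracking_pair(p, "immobilised", render=False)[2].true_pct_count_increase)
        assert np.mean(ctrl) > np.mean(imm)


class TestGenerateCohort:
    def test_single_fish_group_rejected(self):
        with pytest.raises(DomainError):
            generate_cohort(1, {"a": "control", "b": "control"}, seed=1)

    def test_long_format_columns_and_size(self):
        table, _ = generate_cohort(5, {"ctl": "control", "imm": "immobilised"}, seed=2)
        assert set(table.columns) == {"sample_id", "group", "measure", "value"}
        assert len(table) == 2 * 5 * 5  # 2 groups x 5 fish x 5 measures

    def test_identical_groups_null_rejection_rate(self):
        """Two control groups: compare_groups should reject ~5% of the time."""
        rejections = 0
        n_rep = 300
        for seed in range(n_rep):
            table, _ = generate_cohort(10, {"a": "control", "b": "control"}, seed=seed)
            sub = table[table.measure == "volume_um3"]
            groups = [g["value"].to_numpy() for _, g in sub.groupby("group")]
            rejections += compare_groups(groups).p_value < 0.05
        assert 0.02 <= rejections / n_rep <= 0.09

    def test_volume_effect_detected_with_power(self):
        """Control vs immobilised (40% volume reduction) at n=15: detected
        in at least 80% of replicate cohorts."""
        hits = 0
        n_rep = 150
        for seed in range(n_rep):
            table, _ = generate_cohort(15, {"ctl": "control", "imm": "immobilised"}, seed=seed)
            sub = table[table.measure == "volume_um3"]
            groups = [g["value"].to_numpy() for _, g in sub.groupby("group")]
            rep = compare_groups(groups)
            ctl = sub[sub.group == "ctl"]["value"].mean()
            imm = sub[sub.group == "imm"]["value"].mean()
            hits += (rep.p_value < 0.05) and (imm < ctl)
        assert hits / n_rep >= 0.80

    def test_render_mode_produces_truths(self):
        table, truths = generate_cohort(2, {"ctl": "control"}, seed=3, mode="render")
        assert len(truths) == 2
        assert (table.measure == "pct_count_increase").sum() == 2


def test_condition_presets_scale_down_for_perturbations():
    ctl = CONDITION_PRESETS["control"]
    for name in ("immobilised", "wnt16_loss"):
        preset = CONDITION_PRESETS[name]
        assert preset.division_factor < ctl.division_factor
        assert preset.migration_factor < ctl.migration_factor
        assert preset.gfp_volume_factor < ctl.gfp_volume_factor
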