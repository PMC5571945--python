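import numpy as np
import pytest

from musclempi.phantom import (
    CohortDistribution,
    PhantomParams,
    build_labels,
    generate_cohort,
    generate_timepoint,
)
from musclempi.stats import spearman
from musclempi.volio import CANONICAL_LABELS, MUSCLE_ROIS

from conftest import noiseless_params, small_params


class TestParamsValidation:
    def test_radius_ordering_is_enforced(self):
        with pytest.raises(ValueError, match="marrow_radius_mm < femur_radius_mm"):
            PhantomParams(marrow_radius_mm=30.0, femur_radius_mm=20.0)

    def test_marrow_must_be_fatty(self):
        with pytest.raises(ValueError, match="within 5%"):
            PhantomParams(mu_marrow=300.0)

    def test_infiltration_fraction_bounds(self):
        with pytest.raises(ValueError, match="f0_by_roi"):
            PhantomParams(f0_by_roi=1.2)

    def test_grid_too_small_for_geometry(self):
        with pytest.raises(ValueError, match="grid too small"):
            generate_timepoint(small_params(thigh_radius_mm=120.0), 0.0)


class TestLabelPartition:
    def test_every_reserved_class_present_and_partition_covers_grid(self):
        mask = build_labels(small_params())
        present = set(np.unique(mask.labels))
        assert present == set(CANONICAL_LABELS.values())
        # a single integer grid is by construction one label per voxel;
        # check the mask's dictionary matches the canonical convention
        assert mask.label_names == CANONICAL_LABELS

    def test_left_right_symmetry_of_voxel_counts(self):
        mask = build_labels(small_params())
        for pair in (("muscle_ant_R", "muscle_ant_L"), ("marrow_R", "marrow_L")):
            a, b = (int((mask.labels == CANONICAL_LABELS[n]).sum()) for n in pair)
            assert a == b


class TestGenerateTimepoint:
    def test_noiseless_zero_infiltration_muscle_equals_mu_muscle_exactly(self):
        p = noiseless_params(f0_by_roi=0.0, rate_by_roi=0.0)
        vol, mask, _ = generate_timepoint(p, 0.0)
        vox = vol.data[mask.region(["muscle_ant_R", "muscle_ant_L"])]
        assert np.all(vox == p.mu_muscle)

    def test_full_infiltration_muscle_equals_mu_fat_exactly(self):
        p = noiseless_params(f0_by_roi=1.0, rate_by_roi=0.0)
        vol, mask, _ = generate_timepoint(p, 0.0)
        vox = vol.data[mask.region(MUSCLE_ROIS)]
        assert np.all(vox == p.mu_fat)

    def test_roi_mean_weight_tracks_trajectory(self):
        # f(t) = 0.2 + 0.1 * 2 = 0.4; empirical mean of w within Monte-Carlo
        # error (the correlated texture leaves ~250 independent patches per
        # compartment, so single-ROI means scatter with SD ~0.05)
        means = []
        for seed in range(5):
            p = small_params(
                grid_shape=(10, 64, 64), f0_by_roi=0.2, rate_by_roi=0.1, seed=seed
            )
            _, _, truth = generate_timepoint(p, 2.0)
            for roi, f in truth.f_applied_by_roi.items():
                assert truth.f_target_by_roi[roi] == pytest.approx(0.4)
                assert f == pytest.approx(0.4, abs=0.16)
                means.append(f)
        assert np.mean(means) == pytest.approx(0.4, abs=0.03)

    def test_trajectory_clips_to_unit_interval(self):
        p = small_params(f0_by_roi=0.9, rate_by_roi=0.2)
        assert generate_timepoint(p, 3.0)[2].f_target_by_roi["right_ant"] == 1.0

    def test_same_seed_is_bit_identical(self):
        a = generate_timepoint(small_params(seed=9), 1.0)
        b = generate_timepoint(small_params(seed=9), 1.0)
        np.testing.assert_array_equal(a[0].data, b[0].data)
        np.testing.assert_array_equal(a[1].labels, b[1].labels)

    def test_baseline_is_in_template_space_and_later_visits_move(self):
        p = small_params(seed=3)
        _, _, t0 = generate_timepoint(p, 0.0)
        _, _, t1 = generate_timepoint(p, 1.0)
        assert t0.applied_transform.is_identity()
        assert not t1.applied_transform.is_identity()
        assert t1.applied_transform.convention == "visit_to_template"

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            generate_timepoint(small_params(), -0.5)

    def test_noiseless_volume_is_piecewise_determined_by_labels_and_w(self):
        p = noiseless_params(f0_by_roi=0.4, rate_by_roi=0.0, beta_concentration=0.5)
        vol, _, truth = generate_timepoint(p, 0.0)
        lab = truth.template_labels
        muscle = lab.region(list(MUSCLE_ROIS) + ["muscle_margin"])
        expect = (1 - truth.w_field[muscle]) * p.mu_muscle + truth.w_field[
            muscle
        ] * p.mu_fat
        np.testing.assert_allclose(vol.data[muscle], expect, rtol=1e-12)
        assert np.all(vol.data[lab.region(["subcut_fat", "fat_margin"])] == p.mu_fat)
        assert np.all(vol.data[lab.region(["marrow_R", "marrow_L"])] == p.mu_marrow)


class TestCohort:
    def test_cohort_bookkeeping_one_row_per_subject_visit(self):
        cohort = generate_cohort(
            4, [0.0, 1.04], seed=1, base_params=small_params()
        )
        table = cohort.clinical_table()
        assert len(table) == 8
        assert set(table["subject_id"].unique()) == {
            s.subject_id for s in cohort.subjects
        }

    def test_mrcs_is_sum_of_thigh_scores(self):
        cohort = generate_cohort(3, [0.0, 1.0], seed=2, base_params=small_params())
        t = cohort.clinical_table()
        np.testing.assert_allclose(
            t["mrcs"], t["mrc_right_thigh"] + t["mrc_left_thigh"]
        )

    def test_score_ranges(self):
        t = generate_cohort(
            6, [0.0, 1.0], seed=4, base_params=small_params()
        ).clinical_table()
        assert t["css"].between(0, 5).all()
        assert (t["css"] * 2 == (t["css"] * 2).round()).all()  # half points
        for c in ("mfm_d1_pct", "mfm_d2_pct", "mfm_d3_pct", "mfm_total_pct"):
            assert t[c].between(0, 100).all()
        assert t["mrcs"].between(0, 20).all()

    def test_noiseless_link_gives_perfect_rank_correlation(self):
        dist = CohortDistribution(clinical_noise_scale=0.0)
        cohort = generate_cohort(
            10, [0.0], dist, seed=6, base_params=small_params()
        )
        fmean = [
            np.mean(list(s.params.f0_by_roi.values())) for s in cohort.subjects
        ]
        mrcs = [s.clinical[0].mrcs for s in cohort.subjects]
        assert spearman(fmean, mrcs).statistic == pytest.approx(-1.0)

    def test_empty_visit_list_rejected(self):
        with pytest.raises(ValueError, match="empty|increasing"):
            generate_cohort(3, [], seed=0)

    def test_visit_times_must_increase_from_zero(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            generate_cohort(3, [0.0, 1.0, 0.5], seed=0)
        with pytest.raises(ValueError, match="start at 0"):
            generate_cohort(3, [0.5, 1.0], seed=0)
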