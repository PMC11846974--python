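"""Tests of the synthetic study generator against its generating model."""

import numpy as np
import pandas as pd
import pytest

from dbmcov import CohortSpec, GroundTruth, generate_behavior, generate_cohort, generate_components, generate_jacobians
from dbmcov.synthetic import EXPERIMENT_END_DPI, POLE_CAP_S, WIREHANG_CAP_S, brain_mask, default_truth


def test_spec_validation():
    with pytest.raises(ValueError):
        CohortSpec(n_per_cell=1)
    with pytest.raises(ValueError):
        CohortSpec(timepoints_dpi=(30, 30))
    with pytest.raises(ValueError):
        CohortSpec(grid_shape=(4, 16, 16))


class TestComponents:
    def test_single_blob_support_fraction(self):
        spec = CohortSpec(n_per_cell=2, grid_shape=(16, 16, 16), seed=0)
        comps = generate_components(spec, 1)
        frac = (comps[0] > 0).mean()
        assert 0 < frac < 0.5
        assert comps.min() >= 0

    def test_determinism(self):
        spec = CohortSpec(n_per_cell=2, grid_shape=(16, 16, 16), seed=5)
        a = generate_components(spec, 4, seed=5)
        b = generate_components(spec, 4, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_pairwise_disjoint_supports(self):
        spec = CohortSpec(n_per_cell=2, grid_shape=(16, 16, 16), seed=3)
        comps = generate_components(spec, 4)
        supports = [set(map(tuple, np.argwhere(c > 0))) for c in comps]
        for i in range(4):
            for j in range(i + 1, 4):
                assert not supports[i] & supports[j]

    def test_supports_inside_mask(self):
        spec = CohortSpec(n_per_cell=2, grid_shape=(16, 16, 16), seed=3)
        comps = generate_components(spec, 4)
        mask = brain_mask(spec)
        assert np.all(mask[(comps > 0).any(axis=0)])

    def test_impossible_placement_raises(self):
        spec = CohortSpec(n_per_cell=2, grid_shape=(8, 8, 8), seed=0)
        with pytest.raises(RuntimeError, match="too small"):
            generate_components(spec, 20)


class TestCohort:
    def test_counting(self):
        spec = CohortSpec(n_per_cell=2, grid_shape=(16, 16, 16), seed=0)
        cohort = generate_cohort(spec, default_truth(spec, k0=1))
        assert len(cohort) == 8
        assert (cohort.groupby(["sex", "group"]).size() == 2).all()

    def test_zero_hazard_matches_exponential_survivor(self):
        # all log-HRs zero: event rate is the closed-form 1 - exp(-rate*end)
        spec = CohortSpec(n_per_cell=100, grid_shape=(16, 16, 16), seed=1)
        truth = default_truth(spec, k0=1)
        truth.hazard_model.update(group=0.0, sex=0.0, group_sex=0.0, baseline=5e-3)
        cohort = generate_cohort(spec, truth)
        expected = 1.0 - np.exp(-5e-3 * EXPERIMENT_END_DPI)
        observed = cohort["event_flag"].mean()
        se = np.sqrt(expected * (1 - expected) / len(cohort))
        assert abs(observed - expected) < 4 * se
        assert (cohort.loc[cohort.event_flag == 0, "survival_dpi"] == EXPERIMENT_END_DPI).all()

    def test_male_pff_excess_hazard_shortens_survival(self):
        spec = CohortSpec(n_per_cell=100, grid_shape=(16, 16, 16), seed=2)
        truth = default_truth(spec, k0=1)
        truth.hazard_model.update(baseline=2e-3, group=1.0, sex=0.0, group_sex=2.0)
        cohort = generate_cohort(spec, truth)
        med = cohort[cohort.group == "PFF"].groupby("sex")["survival_dpi"].median()
        assert med["M"] < med["F"]

    def test_onset_precedes_endpoint(self, small_cohort):
        both = small_cohort.dropna(subset=["motor_onset_dpi"])
        assert (both["motor_onset_dpi"] <= both["survival_dpi"]).all()


class TestJacobians:
    def _null_truth(self, spec, k0=1):
        comps = generate_components(spec, k0)
        truth = GroundTruth(
            components=comps,
            loadings_model=np.zeros((k0, 6)),
            noise_sd=1e-12,
            loading_noise_sd=0.0,
        )
        truth.hazard_model.update(baseline=1e-9)
        return truth

    def test_null_case_all_zero(self):
        spec = CohortSpec(n_per_cell=2, grid_shape=(16, 16, 16), seed=4)
        truth = self._null_truth(spec)
        cohort = generate_cohort(spec, truth)
        imgs = generate_jacobians(cohort, truth, spec)
        assert max(np.abs(im.data).max() for im in imgs) < 1e-9

    def test_pure_component_construction(self):
        # loading exactly 1 for PFF at 120 dpi, zero noise: volume == -component
        spec = CohortSpec(n_per_cell=2, grid_shape=(16, 16, 16), seed=4, timepoints_dpi=(120,))
        truth = self._null_truth(spec)
        truth.loadings_model[0, 1] = 1.0  # pure group effect
        cohort = generate_cohort(spec, truth)
        imgs = generate_jacobians(cohort, truth, spec)
        for im in imgs:
            sub = cohort.set_index("subject_id").loc[im.subject_id]
            target = -truth.components[0] if sub.group == "PFF" else np.zeros(spec.grid_shape)
            np.testing.assert_allclose(im.data, target, atol=1e-8)

    def test_planted_slope_recovered_by_ols(self):
        # group x dpi slope of -0.02/day at the component peak, estimated by
        # per-subject OLS of the mean in-support voxel value on dpi
        spec = CohortSpec(n_per_cell=10, grid_shape=(16, 16, 16), seed=6)
        comps = generate_components(spec, 1)
        loadings = np.zeros((1, 6))
        loadings[0, 4] = 0.02  # group:dpi loading; volume slope is -0.02
        truth = GroundTruth(components=comps, loadings_model=loadings,
                            noise_sd=0.02, loading_noise_sd=0.0)
        truth.hazard_model.update(baseline=1e-9)
        cohort = generate_cohort(spec, truth)
        imgs = generate_jacobians(cohort, truth, spec)
        core = truth.components[0] > 0.9
        amp = truth.components[0][core]
        rows = []
        for im in imgs:
            # divide out the component amplitude so every core voxel carries
            # the loading slope itself
            rows.append({"subject_id": im.subject_id, "dpi": im.dpi,
                         "y": (im.data[core] / amp).mean()})
        df = pd.DataFrame(rows).merge(cohort[["subject_id", "group"]], on="subject_id")
        pff = df[df.group == "PFF"]
        slopes = pff.groupby("subject_id").apply(
            lambda d: np.polyfit(d.dpi, d.y, 1)[0], include_groups=False
        )
        se = slopes.std(ddof=1) / np.sqrt(len(slopes))
        assert abs(slopes.mean() - (-0.02)) < 3 * max(se, 1e-6)

    def test_attrition_consistency(self, small_spec, small_truth, small_cohort,
                                   small_images, small_behavior):
        surv = small_cohort.set_index("subject_id")["survival_dpi"]
        assert all(im.dpi <= surv[im.subject_id] for im in small_images)
        assert (small_behavior["dpi"] <= surv[small_behavior["subject_id"]].to_numpy()).all()

    def test_absolute_flavor_adds_per_subject_offset(self, small_spec, small_truth, small_cohort):
        rel = generate_jacobians(small_cohort, small_truth, small_spec, "relative")
        ab = generate_jacobians(small_cohort, small_truth, small_spec, "absolute")
        diffs = {}
        for r, a in zip(rel, ab):
            assert (r.subject_id, r.dpi) == (a.subject_id, a.dpi)
            delta = a.data - r.data
            assert np.ptp(delta) < 1e-9  # constant within a scan
            diffs.setdefault(r.subject_id, set()).add(round(float(delta.ravel()[0]), 12))
        assert all(len(v) == 1 for v in diffs.values())  # constant within subject


class TestBehavior:
    def test_wirehang_ceiling(self, small_spec, small_cohort):
        truth = default_truth(small_spec, k0=1)
        truth.behavior_model["wirehang"].update(base_log=np.log(1e5), decline_per_day=0.0)
        beh = generate_behavior(small_cohort, truth, small_spec, tasks=("wirehang",))
        assert (beh["latency_s"] == WIREHANG_CAP_S).all()
        assert (beh["outcome"] == "success").all()

    def test_pole_floor(self, small_spec, small_cohort):
        truth = default_truth(small_spec, k0=1)
        truth.behavior_model["pole"].update(fail_intercept=50.0)  # failure prob 1
        beh = generate_behavior(small_cohort, truth, small_spec, tasks=("pole",))
        assert (beh["latency_s"] == POLE_CAP_S).all()
        assert (beh["outcome"] == "failure").all()

    def test_unknown_task(self, small_spec, small_truth, small_cohort):
        with pytest.raises(ValueError, match="unknown task"):
            generate_behavior(small_cohort, small_truth, small_spec, tasks=("beam",))

    def test_three_trials_per_subject_timepoint(self, small_behavior):
        counts = small_behavior.groupby(["subject_id", "task", "dpi"]).size()
        assert (counts == 3).all()

    def test_caps_respected(self, small_behavior):
        pole = small_behavior[small_behavior.task == "pole"]
        wh = small_behavior[small_behavior.task == "wirehang"]
        assert (pole.latency_s <= POLE_CAP_S).all()
        assert (wh.latency_s <= WIREHANG_CAP_S).all()


def test_full_generator_determinism(small_spec, small_truth):
    c1 = generate_cohort(small_spec, small_truth)
    c2 = generate_cohort(small_spec, small_truth)
    pd.testing.assert_frame_equal(c1, c2)
    i1 = generate_jacobians(c1, small_truth, small_spec)
    i2 = generate_jacobians(c2, small_truth, small_spec)
    assert all(np.array_equal(a.data, b.data) for a, b in zip(i1, i2))
    b1 = generate_behavior(c1, small_truth, small_spec)
    b2 = generate_behavior(c2, small_truth, small_spec)
    pd.testing.assert_frame_equal(b1, b2)
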