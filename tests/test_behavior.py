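"""Censoring-aware survival and motor-behavior statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from dbmcov import CohortSpec, default_truth, generate_behavior, generate_cohort
from dbmcov.behavior import bonferroni, encode_task, fit_cox, fit_longitudinal_lme, fit_survival, motor_onset_glm


def _trials(rows):
    base = {"subject_id": "s0", "sex": "M", "group": "PBS", "dpi": 90.0,
            "trial": 1, "weight_g": 25.0}
    return pd.DataFrame([{**base, **r} for r in rows])


class TestEncodeTask:
    def test_hand_encoded_flags(self):
        # mixed six-trial table, flags worked out by hand from the task rules
        table = _trials(
            [
                {"task": "wirehang", "latency_s": 150.0, "outcome": "success"},
                {"task": "wirehang", "latency_s": 42.0, "outcome": "failure"},
                {"task": "wirehang", "latency_s": 8.0, "outcome": "failure"},
                {"task": "pole", "latency_s": 120.0, "outcome": "failure"},
                {"task": "pole", "latency_s": 11.0, "outcome": "success"},
                {"task": "pole", "latency_s": 95.0, "outcome": "success"},
            ]
        )
        wh = encode_task(table, "wirehang")
        np.testing.assert_array_equal(wh["event"], [0, 1, 1])  # fall = event
        pole = encode_task(table, "pole")
        np.testing.assert_array_equal(pole["event"], [0, 1, 1])  # descent = event
        assert (wh["event"].sum() + (1 - wh["event"]).sum()) == 3

    def test_all_censored_refuses_cox(self):
        table = _trials(
            [{"task": "wirehang", "latency_s": 150.0, "outcome": "success"}] * 4
        )
        rec = encode_task(table, "wirehang")
        with pytest.raises(ValueError, match="no events"):
            fit_cox(rec, covariates=["trial"])

    def test_pole_all_fast_successes_are_events(self):
        table = _trials(
            [{"task": "pole", "latency_s": v, "outcome": "success"} for v in (8.0, 9.5, 12.0)]
        )
        rec = encode_task(table, "pole")
        assert rec["event"].sum() == 3

    def test_cap_violation_is_generator_contract_error(self):
        table = _trials([{"task": "pole", "latency_s": 121.0, "outcome": "failure"}])
        with pytest.raises(ValueError, match="cap"):
            encode_task(table, "pole")

    def test_unknown_task(self):
        with pytest.raises(ValueError, match="pole|wirehang"):
            encode_task(_trials([{"task": "rotarod", "latency_s": 30.0, "outcome": "success"}]), "rotarod")


def _partial_loglik(beta, durations, events, x):
    """Breslow partial log-likelihood for one binary covariate, no ties."""
    ll = 0.0
    for i in np.flatnonzero(events):
        at_risk = durations >= durations[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[at_risk])))
    return ll


class TestFitCox:
    def test_matches_brute_force_partial_likelihood(self):
        # small untied table: compare against direct maximization of the
        # partial likelihood written out by hand
        records = pd.DataFrame(
            {
                "duration": [2.0, 3.0, 5.0, 7.0, 11.0, 13.0],
                "event": [1, 1, 0, 1, 1, 0],
                "group": ["PFF", "PBS", "PFF", "PFF", "PBS", "PBS"],
                "sex": ["M"] * 6,
                "trial": [1.0] * 6,
                "weight_g": [25.0] * 6,
            }
        )
        fit = fit_cox(records, covariates=["group"])
        x = (records.group == "PFF").to_numpy(float)
        res = optimize.minimize_scalar(
            lambda b: -_partial_loglik(b, records.duration.to_numpy(), records.event.to_numpy(), x),
            bounds=(-10, 10),
            method="bounded",
        )
        assert fit.coefs["group[PFF]"] == pytest.approx(res.x, abs=1e-4)
        assert fit.hazard_ratios["group[PFF]"] == pytest.approx(np.exp(res.x), rel=1e-3)

    def test_planted_hr_recovered_single_draw(self):
        rng = np.random.default_rng(0)
        n = 400
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1.0 / (0.01 * np.exp(np.log(2.0) * x)))
        cens = np.quantile(t, 0.7)
        records = pd.DataFrame(
            {
                "duration": np.minimum(t, cens),
                "event": (t <= cens).astype(int),
                "group": np.where(x > 0, "PFF", "PBS"),
                "sex": ["M"] * n,
                "trial": [1.0] * n,
                "weight_g": 25.0 + rng.normal(0, 1, n),
            }
        )
        fit = fit_cox(records, covariates=["group", "trial", "weight_g"])
        assert fit.coefs["group[PFF]"] == pytest.approx(np.log(2.0), abs=0.35)

    def test_null_covariate_p_uniform(self):
        # covariate independent of the hazard: Wald p uniform over replicates
        rng = np.random.default_rng(1)
        pvals = []
        for _ in range(100):
            n = 80
            x = rng.integers(0, 2, n).astype(float)
            t = rng.exponential(100.0, n)
            records = pd.DataFrame(
                {
                    "duration": np.minimum(t, 150.0),
                    "event": (t <= 150.0).astype(int),
                    "group": np.where(x > 0, "PFF", "PBS"),
                    "sex": ["M"] * n,
                    "trial": [1.0] * n,
                    "weight_g": [25.0] * n,
                }
            )
            pvals.append(fit_cox(records, covariates=["group"]).pvalues["group[PFF]"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestFitSurvival:
    def test_planted_male_pff_excess_hazard_detected(self):
        spec = CohortSpec(n_per_cell=100, grid_shape=(16, 16, 16), seed=12)
        truth = default_truth(spec, k0=1)
        truth.hazard_model.update(baseline=1e-3, group=0.5, sex=0.0, group_sex=1.5)
        cohort = generate_cohort(spec, truth)
        fit = fit_survival(cohort)
        assert fit.coefs["group[PFF]:sex[M]"] > 0
        assert fit.pvalues["group[PFF]:sex[M]"] < 0.05

    def test_no_events_rejected(self):
        cohort = pd.DataFrame(
            {
                "subject_id": ["a", "b", "c"],
                "sex": ["M", "F", "M"],
                "group": ["PFF", "PBS", "PBS"],
                "survival_dpi": [130.0] * 3,
                "event_flag": [0, 0, 0],
            }
        )
        with pytest.raises((ValueError, RuntimeError), match="no events"):
            fit_survival(cohort)

    def test_km_curves_start_at_one_and_decrease(self, small_cohort):
        fit = fit_survival(small_cohort)
        for _, cell in fit.km_curves.groupby(["group", "sex"]):
            s = cell.sort_values("time")["survival"].to_numpy()
            assert s[0] == 1.0
            assert np.all(np.diff(s) <= 1e-12)
            assert np.all((0.0 <= s) & (s <= 1.0))


class TestLongitudinal:
    def test_planted_inverted_u_weight_trajectory(self):
        spec = CohortSpec(n_per_cell=20, grid_shape=(16, 16, 16), seed=13)
        truth = default_truth(spec, k0=1)
        truth.weight_model["pff_quad"] = 4e-4  # pronounced inverted U
        cohort = generate_cohort(spec, truth)
        res = fit_longitudinal_lme("weight", cohort, quadratic_time=True)
        assert res.params["group[PFF]:dpi2"] < 0
        assert res.pvalues["group[PFF]:dpi2"] < 0.05

    def test_flat_null_rotarod(self, small_spec, small_cohort):
        truth = default_truth(small_spec, k0=1)
        truth.behavior_model["rotarod"]["decline_per_day"] = 0.0
        beh = generate_behavior(small_cohort, truth, small_spec, tasks=("rotarod",))
        res = fit_longitudinal_lme("rotarod", small_cohort, beh)
        assert res.pvalues["group[PFF]:sex[M]:dpi"] > 0.01

    def test_single_subject_rejected(self):
        cohort = pd.DataFrame(
            {
                "subject_id": ["a"],
                "sex": ["M"],
                "group": ["PFF"],
                "weight_-7": [25.0],
                "weight_30": [26.0],
            }
        )
        with pytest.raises(ValueError, match="2 subjects"):
            fit_longitudinal_lme("weight", cohort)

    def test_unknown_measure(self, small_cohort):
        with pytest.raises(ValueError, match="unknown"):
            fit_longitudinal_lme("grip", small_cohort)


class TestMotorOnset:
    def _cohort(self, onset):
        n = len(onset)
        return pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "sex": ["M", "F"] * (n // 2),
                "group": ["PFF"] * n,
                "survival_dpi": [130.0] * n,
                "event_flag": [0] * n,
                "motor_onset_dpi": onset,
            }
        )

    def test_identical_onset_gives_zero_effects(self):
        res = motor_onset_glm(self._cohort([95.0] * 12))
        assert res.params.drop("Intercept").abs().max() < 1e-10

    def test_planted_male_shift_recovered(self):
        rng = np.random.default_rng(14)
        onset = rng.normal(90, 3, 60)
        onset[::2] += 10.0  # males (even rows) 10 dpi later
        res = motor_onset_glm(self._cohort(list(onset)))
        assert res.params["sex[M]"] == pytest.approx(10.0, abs=2.5)

    def test_no_symptomatic_mice_rejected(self):
        cohort = self._cohort([np.nan] * 4)
        with pytest.raises(ValueError, match="no symptomatic"):
            motor_onset_glm(cohort)

    def test_single_mouse_cells_flagged(self):
        res = motor_onset_glm(self._cohort([90.0, 100.0]))
        assert any("unreliable" in n for n in res.notes)


class TestBonferroni:
    def test_hand_arithmetic(self):
        out = bonferroni([0.001], m=8)
        assert bool(out.significant[0]) and out.p_adjusted[0] == pytest.approx(0.008)

    def test_strict_boundary(self):
        out = bonferroni([0.05], m=1)
        assert not bool(out.significant[0])

    def test_p_one_stays_one(self):
        assert bonferroni([1.0], m=8).p_adjusted[0] == 1.0

    def test_invalid_m(self):
        with pytest.raises(ValueError):
            bonferroni([0.5], m=0)

    def test_equals_brute_force(self):
        rng = np.random.default_rng(15)
        p = rng.uniform(0, 1, 50)
        out = bonferroni(p, m=8)
        np.testing.assert_allclose(out.p_adjusted, np.minimum(1.0, 8 * p))
        np.testing.assert_array_equal(out.significant, p < 0.05 / 8)
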