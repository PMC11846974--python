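"""Voxelwise mixed models, BH correction, weight GLMs and effect sizes."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dbmcov.voxelstats import (
    build_design,
    cohens_d,
    fdr_correct,
    fit_voxelwise_lme,
    subject_weight_glm,
)


def _brute_force_bh(p, q):
    """Step-up enumeration: largest i with p_(i) <= i*q/m, reject all below."""
    m = len(p)
    order = np.argsort(p)
    sorted_p = np.asarray(p)[order]
    cutoff = 0
    for i in range(1, m + 1):
        if sorted_p[i - 1] <= i * q / m:
            cutoff = i
    sig = np.zeros(m, bool)
    sig[order[:cutoff]] = True
    return sig


class TestFdrCorrect:
    def test_single_test(self):
        q, sig = fdr_correct(np.array([0.001]), 0.05)
        assert q[0] == pytest.approx(0.001) and sig[0]

    def test_hand_bh_example(self):
        # thresholds at q=0.05 for m=3 are 0.0167, 0.0333, 0.05
        q, sig = fdr_correct(np.array([0.01, 0.02, 0.5]), 0.05)
        np.testing.assert_array_equal(sig, [True, True, False])
        np.testing.assert_allclose(q, [0.03, 0.03, 0.5])

    def test_all_ones_nothing_significant(self):
        q, sig = fdr_correct(np.ones(10), 0.05)
        assert not sig.any() and (q == 1.0).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fdr_correct(np.array([]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_correct(np.array([0.0, 0.5]))

    def test_nan_entries_excluded_not_dropped(self):
        q, sig = fdr_correct(np.array([0.001, np.nan, 0.9]), 0.05)
        assert np.isnan(q[1]) and not sig[1] and sig[0]

    @pytest.mark.parametrize("q_level", [0.01, 0.05])
    def test_matches_brute_force_enumeration(self, q_level):
        # all p-vectors of length <= 8 over a coarse grid of values
        grid = [0.001, 0.012, 0.04, 0.2, 0.8, 1.0]
        rng = np.random.default_rng(0)
        for m in range(1, 9):
            for _ in range(40):
                p = rng.choice(grid, size=m)
                _, sig = fdr_correct(p, q_level)
                np.testing.assert_array_equal(sig, _brute_force_bh(p, q_level))

    def test_q_values_monotone_in_p(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(1e-6, 1, 200)
        q, _ = fdr_correct(p, 0.05)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q >= p)


class TestCohensD:
    def test_identical_groups_zero(self):
        a = np.array([1.0, 2.0, 3.0])
        assert cohens_d(a, a.copy()) == 0.0

    def test_unit_case(self):
        rng = np.random.default_rng(2)
        base = rng.normal(0, 1, 2000)
        base = (base - base.mean()) / base.std(ddof=1)
        assert cohens_d(base + 1.0, base) == pytest.approx(1.0, abs=1e-9)

    def test_hand_pooled_sd(self):
        # a=(0,2), b=(1,3): mean diff -1, each sample variance 2 (ddof=1),
        # pooled SD sqrt(2), so d = -1/sqrt(2)
        assert cohens_d(np.array([0.0, 2.0]), np.array([1.0, 3.0])) == pytest.approx(-1.0 / np.sqrt(2.0))

    def test_sign_convention_first_minus_second(self):
        assert cohens_d(np.array([2.0, 3.0]), np.array([0.0, 1.0])) > 0

    def test_zero_pooled_sd(self):
        with pytest.raises(ValueError, match="pooled"):
            cohens_d(np.array([1.0, 1.0]), np.array([1.0, 1.0]))

    def test_min_group_size(self):
        with pytest.raises(ValueError, match="at least 2"):
            cohens_d(np.array([1.0]), np.array([1.0, 2.0]))


def _subject_meta(n_per_cell, rng=None):
    rows = []
    for sex in "MF":
        for group in ("PBS", "PFF"):
            rows += [{"sex": sex, "group": group}] * n_per_cell
    return pd.DataFrame(rows)


class TestSubjectWeightGlm:
    def test_constant_weights_null(self):
        meta = _subject_meta(5)
        H = np.full((2, len(meta)), 3.3)
        res = subject_weight_glm(H, 0, meta)
        for term in ("group[PFF]", "sex[M]", "group[PFF]:sex[M]"):
            assert res.params[term] == pytest.approx(0.0, abs=1e-10)
            assert res.pvalues[term] == pytest.approx(1.0)

    def test_planted_sex_effect_recovered(self):
        rng = np.random.default_rng(3)
        meta = _subject_meta(10)
        w = rng.normal(0, 1, len(meta))
        w[(meta.sex == "F").to_numpy()] += 2.0  # females 2 SD higher
        res = subject_weight_glm(w[None, :], 0, meta)
        assert res.pvalues["sex[M]"] < 0.01
        assert res.cohens_d["sex[M]"] == pytest.approx(-2.0, abs=0.75)
        assert res.d_variant == "pooled-sd"

    def test_interaction_p_uniform_under_group_only_effect(self):
        # planted group effect but no interaction: the interaction p-value
        # should be uniform across simulations (KS test at alpha=0.01)
        rng = np.random.default_rng(4)
        meta = _subject_meta(10)
        g = (meta.group == "PFF").to_numpy(float)
        pvals = []
        for _ in range(200):
            w = 2.0 * g + rng.normal(0, 1, len(meta))
            res = subject_weight_glm(w[None, :], 0, meta)
            pvals.append(res.pvalues["group[PFF]:sex[M]"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_empty_cell_drops_interaction(self):
        meta = _subject_meta(4)
        meta = meta[~((meta.sex == "M") & (meta.group == "PFF"))].reset_index(drop=True)
        H = np.random.default_rng(5).uniform(0, 1, (1, len(meta)))
        with pytest.warns(UserWarning, match="interaction"):
            res = subject_weight_glm(H, 0, meta)
        assert "group[PFF]:sex[M]" not in res.params.index

    def test_component_bounds(self):
        with pytest.raises(ValueError, match="out of range"):
            subject_weight_glm(np.ones((2, 4)), 5, _subject_meta(1))


class TestVoxelwiseLme:
    def _cohort_matrix(self, seed, G=20, m=50, effect=0.0):
        rng = np.random.default_rng(seed)
        meta = pd.DataFrame(
            {
                "subject_id": np.repeat([f"s{i}" for i in range(G)], 4),
                "group": np.repeat(["PFF", "PBS"] * (G // 2), 4),
                "sex": np.repeat(["M"] * (G // 2) + ["F"] * (G // 2), 4),
                "dpi": np.tile([-7.0, 30.0, 90.0, 120.0], G),
            }
        )
        g = (meta.group == "PFF").to_numpy(float)
        t = meta.dpi.to_numpy()
        Y = rng.normal(0, 1, (G, m))[np.repeat(np.arange(G), 4)] + rng.normal(0, 1, (len(meta), m))
        Y[:, :5] += (effect * g * t)[:, None]  # planted group:dpi in 5 voxels
        return Y.T, meta

    def test_planted_group_dpi_effect_found(self):
        matrix, meta = self._cohort_matrix(0, effect=0.05)
        maps = fit_voxelwise_lme(matrix, meta, q_level=0.01)
        sig = maps["group[PFF]:dpi"].significant
        assert sig[:5].all()
        assert sig[5:].mean() <= 0.05

    def test_single_timepoint_design_rejected(self):
        meta = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(12)],
                "group": ["PFF", "PBS"] * 6,
                "sex": ["M"] * 6 + ["F"] * 6,
                "dpi": [90.0] * 12,
            }
        )
        matrix = np.random.default_rng(1).normal(size=(10, 12))
        with pytest.raises(ValueError):
            fit_voxelwise_lme(matrix, meta)

    def test_missing_metadata_column(self):
        matrix, meta = self._cohort_matrix(2, m=4)
        with pytest.raises(ValueError, match="sex"):
            fit_voxelwise_lme(matrix, meta.drop(columns=["sex"]))

    def test_design_terms(self):
        _, meta = self._cohort_matrix(3, m=4)
        X, names = build_design(meta)
        assert X.shape[1] == len(names) == 8
        X2, names2 = build_design(meta, quadratic_time=True)
        assert "group[PFF]:dpi2" in names2 and X2.shape[1] == 10
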