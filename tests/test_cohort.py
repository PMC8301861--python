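"""Cohort statistics tests: percentage error, derived indices, t test, ROC."""

import warnings

import numpy as np
import pytest
from scipy import stats as sps

from plrkit import (
    PLRParameters,
    StimulusSpec,
    cv_across_conditions,
    derive_parameters,
    group_comparison,
    percentage_error,
    roc_curve,
    two_sample_t,
    two_sample_t_from_stats,
)
from plrkit.reference import cohort_summary_frame

STIM = StimulusSpec(t_s=5.0, t_d=0.01)

HEALTHY_MEANS = PLRParameters(
    tau_p1=0.205, tau_p2=0.779, tau_s1=0.423, tau_s2=1.391,
    f_p0=10.573, f_s0=7.745, f_s1=1.264, k_d1=1.251, k_d2=1.656, l0=3.051,
)


class TestPercentageError:
    def test_identical_values(self):
        assert percentage_error(3.0, 3.0) == 0.0

    def test_right_left_eye_examples(self):
        # consensual (left) eye vs stimulated (right) eye reference
        assert percentage_error(6.600, 7.100) == pytest.approx(7.576, abs=5e-4)
        assert percentage_error(0.19, 0.200) == pytest.approx(5.263, abs=5e-4)
        assert percentage_error(11.400, 11.300) == pytest.approx(-0.877, abs=5e-4)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            percentage_error(0.0, 1.0)


class TestDeriveParameters:
    def test_impulses_are_intensity_times_phase_duration(self):
        d = derive_parameters(HEALTHY_MEANS, STIM)
        p = HEALTHY_MEANS
        assert d.imp1 == pytest.approx(p.f_p0 * (p.tau_s1 - p.tau_p1))
        assert d.imp2 == pytest.approx(
            (p.f_p0 - p.f_s0) * (STIM.t_d + p.tau_p2 - p.tau_s1)
        )
        assert d.imp3 == pytest.approx(p.f_s1 * (p.tau_s2 - p.tau_p2))
        # consistent with the published group means (product-of-means vs
        # mean-of-products keeps these close but not equal)
        assert d.imp1 == pytest.approx(2.333, abs=0.05)

    def test_dan_is_exact_product(self):
        d = derive_parameters(HEALTHY_MEANS, STIM)
        assert d.dan == d.imp2 * d.l0_prime * HEALTHY_MEANS.k_d1
        # with the published derived group means the product is 3.680
        # (agreement to the precision those means are printed at)
        assert 0.964 * 3.051 * 1.251 == pytest.approx(3.680, abs=1e-3)

    def test_default_normalisation_keeps_l0_scale(self):
        d = derive_parameters(HEALTHY_MEANS, STIM)
        assert d.l0_prime == pytest.approx(HEALTHY_MEANS.l0)
        assert d.l0_prime_times_k_d1 == pytest.approx(3.051 * 1.251)

    def test_differences(self):
        d = derive_parameters(HEALTHY_MEANS, STIM)
        assert d.tau_p2_minus_tau_s1 == pytest.approx(0.779 - 0.423)
        assert d.f_p0_minus_f_s0 == pytest.approx(10.573 - 7.745)

    def test_non_positive_phase_zeroes_impulse(self):
        p = HEALTHY_MEANS.replace(tau_s1=1.0, tau_p2=0.3)  # antagonistic phase < 0
        with pytest.warns(UserWarning, match="non-positive"):
            d = derive_parameters(p, STIM)
        assert d.imp2 == 0.0


class TestTwoSampleT:
    def test_identical_groups(self):
        r = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t == 0.0
        assert r.p == pytest.approx(1.0)

    def test_matches_scipy_welch(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 30), rng.normal(0.5, 2, 45)
        r = two_sample_t(a, b)
        o = sps.ttest_ind(a, b, equal_var=False)
        assert r.t == pytest.approx(o.statistic, abs=1e-12)
        assert r.p == pytest.approx(o.pvalue, abs=1e-12)

    def test_antisymmetric_under_group_swap(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 20), rng.normal(1, 1, 25)
        assert two_sample_t(a, b).t == pytest.approx(-two_sample_t(b, a).t)

    def test_large_separation(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 1, 50)
        b = rng.normal(10, 1, 50)
        assert two_sample_t(a, b).p < 1e-10

    def test_summary_statistic_input(self):
        ref = cohort_summary_frame()
        m1, s1 = ref.loc["tau_s1", ["healthy_mean", "healthy_sd"]]
        m2, s2 = ref.loc["tau_s1", ["dm_mean", "dm_sd"]]
        r = two_sample_t_from_stats(m1, s1, 336, m2, s2, 336)
        assert r.t == pytest.approx(-4.36, abs=0.005)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0, 1.0], [1.0, 1.0])


class TestCvAcrossConditions:
    @staticmethod
    def _table(values_by_color):
        import pandas as pd

        rows = []
        for color, vals in values_by_color.items():
            rows += [{"color": color, "tau_s1": v} for v in vals]
        return pd.DataFrame(rows)

    def test_equal_condition_means_give_zero(self):
        t = self._table({"W": [0.4, 0.5], "R": [0.45], "G": [0.42, 0.48], "B": [0.45]})
        r = cv_across_conditions(t, "tau_s1")
        assert r["cv"] == pytest.approx(0.0, abs=1e-12)

    def test_reduces_to_cv_of_condition_means(self):
        t = self._table({"W": [0.416], "R": [0.418], "G": [0.428], "B": [0.423]})
        r = cv_across_conditions(t, "tau_s1")
        assert r["cv"] == pytest.approx(0.0128, abs=1e-4)
        assert r["mean"] == pytest.approx(0.421, abs=5e-4)

    def test_missing_level_rejected(self):
        t = self._table({"W": [0.4], "R": [0.42]})
        with pytest.raises(ValueError, match="missing"):
            cv_across_conditions(t, "tau_s1", levels=("W", "R", "G", "B"))


class TestRocCurve:
    def test_perfect_separation(self):
        scores = np.r_[np.zeros(20), np.ones(20)]
        labels = ["healthy"] * 20 + ["DM"] * 20
        r = roc_curve(scores, labels)
        assert r.auc == 1.0
        assert r.sensitivity == 1.0 and r.specificity == 1.0

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(size=2000)
        labels = np.where(rng.random(2000) < 0.5, "DM", "healthy")
        r = roc_curve(scores, labels)
        assert r.auc == pytest.approx(0.5, abs=0.06)

    def test_orientation_flip_reported(self):
        scores = np.r_[np.ones(10), np.zeros(10)]  # positives score LOWER
        labels = ["healthy"] * 10 + ["DM"] * 10
        r = roc_curve(scores, labels)
        assert r.flipped
        assert r.auc == 1.0 and r.auc_raw == 0.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([1.0, 2.0], ["DM", "DM"])

    def test_synthetic_cohort_dan_auc_in_published_band(self):
        """DAN on a summary-statistics cohort discriminates with AUC near 0.67.

        The published per-recording data are unavailable; sampling from
        the group summaries preserves the means/sds and the implied
        pairwise correlations, which puts the Monte-Carlo AUC in a band
        around the published 0.6713 rather than at it.
        """
        from plrkit import CohortSpec, generate_cohort

        aucs = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for seed in range(3):
                table = generate_cohort(CohortSpec(seed=seed))
                aucs.append(roc_curve(table["dan"], table["group"]).auc)
        assert 0.6 <= np.mean(aucs) <= 0.75, aucs


class TestGroupComparison:
    def test_summary_shape_and_separated_column(self):
        import pandas as pd

        rng = np.random.default_rng(9)
        n = 40
        table = pd.DataFrame(
            {
                "group": ["healthy"] * n + ["DM"] * n,
                "tau_s1": np.r_[rng.normal(0.42, 0.04, n), rng.normal(0.60, 0.04, n)],
                "k_d1": rng.normal(1.25, 0.25, 2 * n),
            }
        )
        out = group_comparison(table)
        assert set(out.index) == {"tau_s1", "k_d1"}
        assert out.loc["tau_s1", "p"] < 1e-6
        assert out.loc["k_d1", "p"] > 0.001
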