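"""Derivation/validation statistics: k1/k2 estimation, repeated-measures
Bland-Altman, ROC discrimination, PTP correlation and cross-validation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import poccscreen as pk
from poccscreen.validation import (bland_altman_repeated, cross_validate,
                                   derive_conversion_factors, discrimination,
                                   ptp_correlation)


def _summaries_df(ratios1, ratios2, patients, pocc=-20.0, n_occ=5):
    rows = []
    for i, (r1, r2, p) in enumerate(zip(ratios1, ratios2, patients)):
        rows.append(dict(
            patient=p, day=i, mean_pmus=r1 * pocc, mean_delta_pes=r2 * pocc,
            mean_delta_paw=5.0, mean_delta_pl_dyn=5.0 - r2 * pocc,
            mean_delta_pocc=pocc, mean_ptp_mus=8.0, n_breaths=40,
            n_occlusions=n_occ, pocc_pes_ratio=1.0, valid=True,
            pocc_values=[pocc] * n_occ))
    return pd.DataFrame(rows)


class TestDeriveFactors:
    def test_degenerate_cohort_recovers_exact_ratio_with_zero_ci(self):
        df = _summaries_df([-0.75] * 6, [0.6] * 6,
                           ["A", "A", "B", "B", "C", "C"])
        est = derive_conversion_factors(df)
        assert est.factors.k1 == pytest.approx(-0.75, abs=1e-12)
        assert est.k1.ci_high - est.k1.ci_low == pytest.approx(0.0, abs=1e-10)
        assert est.factors.k2 == pytest.approx(0.6, abs=1e-12)

    def test_requires_two_patients(self):
        df = _summaries_df([-0.7, -0.8], [0.6, 0.7], ["A", "A"])
        with pytest.raises(ValueError, match="2 patients"):
            derive_conversion_factors(df)

    def test_single_recording_per_patient_falls_back(self):
        rng = np.random.default_rng(0)
        r1 = -0.75 + 0.03 * rng.standard_normal(8)
        r2 = 0.65 + 0.03 * rng.standard_normal(8)
        df = _summaries_df(r1, r2, [f"P{i}" for i in range(8)])
        est = derive_conversion_factors(df)
        assert est.k1.method == "patient-means"
        assert est.factors.k1 == pytest.approx(r1.mean(), abs=1e-9)

    def test_recovers_cohort_ground_truth(self, small_cohort,
                                          small_cohort_summaries):
        """Derived k1/k2 fall near the ratios computed from simulator
        truth over the same recordings."""
        sdf = pk.summaries_frame(small_cohort_summaries)
        ts = pk.cohort_truth_summaries(small_cohort.truth)
        est = derive_conversion_factors(sdf)
        v = sdf.merge(ts, on=["patient", "day"])
        v = v[v.valid]
        k1_true = (v.true_mean_pmus_meas / v.true_mean_pocc).mean()
        k2_true = (v.true_mean_delta_pes / v.true_mean_pocc).mean()
        assert est.factors.k1 == pytest.approx(k1_true, abs=0.06)
        assert est.factors.k2 == pytest.approx(k2_true, abs=0.06)
        assert abs(est.factors.k1) > est.factors.k2  # Pcw adds to Pmus


class TestBlandAltman:
    def test_identity_gives_zero_bias_and_zero_limits(self):
        m = np.array([8.0, 12.0, 15.0, 20.0, 6.0, 9.0])
        rep = bland_altman_repeated(m, m, ["A", "A", "B", "B", "C", "C"])
        assert rep.bias_mean == 0.0
        assert rep.la_pct_within == 0.0
        assert rep.sd_bias_between == 0.0
        for x in (5.0, 15.0, 40.0):
            assert rep.total_loa(x) == 0.0

    def test_lognormal_noise_recovers_analytic_within_limit(self):
        """predicted = measured * LogNormal(0, 0.1) with no patient
        structure -> LA%,within ~ (exp(1.96*0.1)-1)*100."""
        rng = np.random.default_rng(1)
        m = rng.uniform(8, 25, 400)
        p = m * np.exp(0.1 * rng.standard_normal(400))
        rep = bland_altman_repeated(p, m, [f"P{i}" for i in range(400)])
        expected = (np.exp(1.96 * 0.1) - 1) * 100
        assert rep.la_pct_within == pytest.approx(expected, abs=2.0)

    def test_two_patient_offsets_give_between_sd_of_log_offsets(self):
        m = np.array([10.0, 12.0, 14.0, 10.0, 12.0, 14.0])
        mult = np.array([1.2] * 3 + [1 / 1.2] * 3)
        rep = bland_altman_repeated(m * mult, m, ["A"] * 3 + ["B"] * 3)
        closed_form = float(np.std([np.log(1.2), -np.log(1.2)], ddof=1))
        assert rep.sd_log_between == pytest.approx(closed_form, abs=1e-9)
        assert rep.la_pct_within == pytest.approx(0.0, abs=1e-9)

    def test_total_loa_widens_with_estimate(self):
        rng = np.random.default_rng(2)
        m = rng.uniform(8, 25, 40)
        p = m * np.exp(0.15 * rng.standard_normal(40)) + 0.5
        rep = bland_altman_repeated(p, m, np.repeat([f"P{i}" for i in range(10)], 4))
        assert rep.total_loa(20.0) > rep.total_loa(10.0) >= 0.0

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError, match="log"):
            bland_altman_repeated([1.0, -2.0], [1.0, 2.0], ["A", "B"])


class TestDiscrimination:
    def test_perfect_separation(self):
        meas = np.r_[np.full(10, 5.0), np.full(10, 15.0)]
        rep = discrimination(meas, meas, threshold=10.0, n_boot=0)
        assert rep.auroc == 1.0
        assert rep.sensitivity == 100.0 and rep.specificity == 100.0

    def test_uninformative_predictions_near_half(self):
        rng = np.random.default_rng(3)
        pred = rng.standard_normal(2000)
        meas = rng.uniform(0, 20, 2000)
        rep = discrimination(pred, meas, threshold=10.0, n_boot=0)
        assert rep.auroc == pytest.approx(0.5, abs=0.04)

    def test_auroc_equals_concordant_pair_count(self):
        """Empirical AUROC equals the exhaustive proportion of concordant
        pairs plus half-ties, on 30 points with ties present."""
        rng = np.random.default_rng(4)
        pred = np.round(rng.uniform(0, 5, 30), 0)  # coarse -> ties
        labels = rng.uniform(0, 1, 30) > 0.5
        pos, neg = pred[labels], pred[~labels]
        conc = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        oracle = conc / (len(pos) * len(neg))
        rep = discrimination(pred, labels=labels, threshold=2.0, n_boot=0)
        assert rep.auroc == pytest.approx(oracle, abs=1e-12)

    def test_bootstrap_ci_brackets_estimate(self):
        rng = np.random.default_rng(5)
        meas = rng.uniform(0, 20, 60)
        pred = meas + rng.normal(0, 3, 60)
        rep = discrimination(pred, meas, threshold=10.0, n_boot=200, seed=0)
        lo, hi = rep.ci
        assert lo <= rep.auroc <= hi

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            discrimination([1.0, 2.0], [1.0, 2.0], threshold=10.0)

    def test_auroc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(6)
        meas = rng.uniform(0, 20, 50)
        pred = meas + rng.normal(0, 4, 50)
        a = discrimination(pred, meas, 10.0, n_boot=0).auroc
        b = discrimination(np.exp(pred / 5.0), meas, 10.0, n_boot=0).auroc
        assert a == pytest.approx(b, abs=1e-12)


class TestPtpCorrelation:
    def test_proportionality_gives_unit_r2(self):
        df = pd.DataFrame({
            "patient": np.repeat(["A", "B", "C"], 3),
            "mean_delta_pocc": -np.arange(1.0, 10.0),
            "mean_ptp_mus": 2.0 * np.arange(1.0, 10.0)})
        rep = ptp_correlation(df)
        assert rep.between_r2 == pytest.approx(1.0, abs=1e-12)
        assert rep.within_r2 == pytest.approx(1.0, abs=1e-12)

    def test_centered_shuffle_destroys_within_correlation(self):
        rng = np.random.default_rng(7)
        n = 400
        df = pd.DataFrame({
            "patient": np.repeat([f"P{i}" for i in range(20)], 20),
            "mean_delta_pocc": rng.uniform(-30, -5, n),
            "mean_ptp_mus": rng.uniform(2, 15, n)})
        rep = ptp_correlation(df)
        assert rep.within_r2 == pytest.approx(0.0, abs=0.03)

    def test_matches_least_squares_oracle(self):
        rng = np.random.default_rng(8)
        pats = np.repeat([f"P{i}" for i in range(8)], 4)
        x = rng.uniform(-30, -5, 32)
        y = -0.4 * x + rng.normal(0, 1, 32)
        df = pd.DataFrame({"patient": pats, "mean_delta_pocc": x,
                           "mean_ptp_mus": y})
        rep = ptp_correlation(df)
        gm = df.groupby("patient").mean(numeric_only=True)
        lr_b = stats.linregress(gm.mean_delta_pocc, gm.mean_ptp_mus)
        cx = x - gm.mean_delta_pocc[pats].to_numpy()
        cy = y - gm.mean_ptp_mus[pats].to_numpy()
        lr_w = stats.linregress(cx, cy)
        assert rep.between_r2 == pytest.approx(lr_b.rvalue ** 2, abs=1e-9)
        assert rep.within_r2 == pytest.approx(lr_w.rvalue ** 2, abs=1e-9)


class TestCrossValidation:
    def test_fixed_seed_reproduces_report(self, small_cohort_summaries):
        sdf = pk.summaries_frame(small_cohort_summaries)
        a = cross_validate(sdf, reps=2, seed=3)
        b = cross_validate(sdf, reps=2, seed=3)
        pd.testing.assert_frame_equal(a.per_rep, b.per_rep)

    def test_homogeneous_cohort_gives_constant_factors(self):
        df = _summaries_df([-0.75] * 8, [0.66] * 8,
                           ["A", "A", "B", "B", "C", "C", "D", "D"])
        rep = cross_validate(df, reps=5, seed=0)
        assert np.allclose(rep.per_rep.k1, -0.75, atol=1e-10)
        assert np.allclose(rep.per_rep.k2, 0.66, atol=1e-10)

    def test_requires_four_patients(self):
        df = _summaries_df([-0.75] * 3, [0.66] * 3, ["A", "B", "C"])
        with pytest.raises(ValueError, match="4 patients"):
            cross_validate(df, reps=2, seed=0)

    def test_screening_discriminates_on_cohort(self, small_cohort,
                                               small_cohort_summaries):
        """Cross-validated predictions separate truly high from truly low
        effort recordings."""
        sdf = pk.summaries_frame(small_cohort_summaries)
        truth = pk.cohort_truth_summaries(small_cohort.truth)
        rep = cross_validate(sdf, truth=truth, reps=20, seed=1)
        med = rep.per_rep["auroc_pmus_gt10"].median()
        assert np.isnan(med) or med > 0.7
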