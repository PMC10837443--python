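"""Time-dependent ROC, optimal cut-point, KM/log-rank, calibration,
Bonferroni."""

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test as ll_logrank

import stacksurv as ss

from conftest import exponential_cox_outcome


def mann_whitney_auc(marker, label):
    """Tie-aware Mann-Whitney AUC of marker for binary label (oracle)."""
    pos = marker[label]
    neg = marker[~label]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestTdRoc:
    def test_km_estimator_reduces_to_mann_whitney_uncensored(self):
        rng = np.random.default_rng(1)
        n = 150
        marker = rng.standard_normal(n)
        outc = exponential_cox_outcome(1.2 * marker, rng, censor_frac=0.0)
        t = float(np.median(outc.time))
        roc = ss.td_roc(marker, outc, t, method="km")
        label = outc.time <= t
        assert roc.auc == pytest.approx(mann_whitney_auc(marker, label),
                                        abs=1e-9)

    def test_perfect_marker_auc_one(self):
        n = 50
        time = np.arange(1.0, n + 1)
        marker = -time  # higher marker = earlier death
        outc = ss.SurvivalOutcome([f"s{i}" for i in range(n)], time,
                                  np.ones(n, dtype=int))
        roc = ss.td_roc(marker, outc, 25.5, method="km")
        assert roc.auc == pytest.approx(1.0)

    def test_null_marker_auc_near_half(self):
        rng = np.random.default_rng(2)
        n = 2000
        marker = rng.standard_normal(n)
        outc = exponential_cox_outcome(np.zeros(n), rng)
        t = float(np.median(outc.time))
        roc = ss.td_roc(marker, outc, t)  # NNE default
        assert 0.47 <= roc.auc <= 0.53

    def test_nne_invariant_to_monotone_marker_transform(self):
        rng = np.random.default_rng(3)
        n = 300
        marker = rng.standard_normal(n)
        outc = exponential_cox_outcome(marker, rng)
        t = float(np.median(outc.time))
        a = ss.td_roc(marker, outc, t)
        b = ss.td_roc(np.exp(2.0 * marker), outc, t)
        assert a.auc == pytest.approx(b.auc, abs=1e-12)

    def test_curve_contract(self):
        rng = np.random.default_rng(4)
        marker = rng.standard_normal(400)
        outc = exponential_cox_outcome(0.8 * marker, rng)
        roc = ss.td_roc(marker, outc, float(np.median(outc.time)))
        assert roc.fpr[0] == 0 and roc.tpr[-1] == 1
        assert np.all(np.diff(roc.fpr) >= 0) and np.all(np.diff(roc.tpr) >= 0)

    def test_no_cases_rejected(self):
        outc = ss.SurvivalOutcome(["a", "b", "c"], [10.0, 12.0, 14.0],
                                  [0, 1, 1])
        with pytest.raises(ValueError, match="case"):
            ss.td_roc(np.array([1.0, 2.0, 3.0]), outc, 5.0)


def brute_force_cutpoint(marker, outcome, minprop=0.1):
    """Independent scan: lifelines log-rank at every admissible midpoint."""
    n = len(marker)
    svals = np.sort(np.unique(marker))
    best = (None, -np.inf)
    for c in (svals[:-1] + svals[1:]) / 2:
        hi = marker > c
        if hi.sum() < minprop * n or (~hi).sum() < minprop * n:
            continue
        res = ll_logrank(outcome.time[hi], outcome.time[~hi],
                         outcome.event[hi], outcome.event[~hi])
        z = np.sqrt(res.test_statistic)
        if z > best[1]:
            best = (c, z)
    return best


class TestOptimalCutpoint:
    def test_equals_brute_force_scan(self):
        """Property check on 12 random instances (the acceptance suite runs
        the full 50)."""
        for rep in range(12):
            rng = np.random.default_rng(100 + rep)
            n = 80
            marker = rng.standard_normal(n)
            outc = exponential_cox_outcome(rng.uniform(0, 1.5) * marker, rng)
            with pytest.warns(UserWarning, match="cut-point"):
                res = ss.optimal_cutpoint(marker, outc)
            c_ref, z_ref = brute_force_cutpoint(marker, outc)
            assert res.cutpoint == pytest.approx(c_ref, abs=1e-12)
            assert res.max_standardized_statistic == pytest.approx(z_ref,
                                                                   abs=1e-8)

    def test_separated_groups_recovered_by_cut(self):
        """Two groups at hazard ratio 5 with disjoint marker supports: the
        selected cut reproduces the true grouping to within 2% of samples in
        >= 90% of 20 replicates. (The argmax itself can wander a few order
        statistics into a support because the maximally selected statistic
        is nearly flat at the boundary, so exact gap membership is not a
        stable property of the statistic.)"""
        hits = 0
        for rep in range(20):
            rng = np.random.default_rng(200 + rep)
            n = 400
            hi = rng.uniform(size=n) < 0.5
            marker = np.where(hi, rng.uniform(2, 3, n), rng.uniform(0, 1, n))
            lp = np.where(hi, np.log(5.0), 0.0)
            outc = exponential_cox_outcome(lp, rng)
            with pytest.warns(UserWarning):
                res = ss.optimal_cutpoint(marker, outc)
            misassigned = np.mean((marker > res.cutpoint) != hi)
            hits += misassigned <= 0.02
        assert hits >= 18

    def test_minprop_half_only_median_split(self):
        marker = np.arange(20, dtype=float)
        outc = ss.SurvivalOutcome([f"s{i}" for i in range(20)],
                                  np.arange(1.0, 21.0),
                                  np.ones(20, dtype=int))
        with pytest.warns(UserWarning):
            res = ss.optimal_cutpoint(marker, outc, minprop=0.5)
        assert len(res.scan) == 1
        assert res.group_sizes == (10, 10)

    def test_degenerate_marker_rejected(self):
        outc = ss.SurvivalOutcome(["a", "b"], [1.0, 2.0], [1, 1])
        with pytest.raises(ValueError, match="distinct"):
            ss.optimal_cutpoint(np.array([1.0, 1.0]), outc)


class TestKaplanMeierAndLogrank:
    def test_six_subject_hand_computed_products(self):
        outc = ss.SurvivalOutcome(list("abcdef"),
                                  [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                                  [1, 1, 0, 1, 0, 1])
        km = ss.km_curve(outc)
        np.testing.assert_array_equal(km.times, [1.0, 2.0, 4.0, 6.0])
        expected = [5 / 6, 5 / 6 * 4 / 5, 5 / 6 * 4 / 5 * 2 / 3, 0.0]
        np.testing.assert_allclose(km.survival, expected, atol=1e-12)
        np.testing.assert_array_equal(km.at_risk, [6, 5, 3, 1])

    def test_no_events_survival_one(self):
        outc = ss.SurvivalOutcome(["a", "b"], [3.0, 5.0], [0, 0])
        km = ss.km_curve(outc)
        assert km.at(4.0) == 1.0 and km.times.size == 0

    def test_final_step_equals_product_of_factors(self):
        rng = np.random.default_rng(6)
        outc = exponential_cox_outcome(np.zeros(100), rng)
        km = ss.km_curve(outc)
        prod = np.prod(1.0 - km.events / km.at_risk)
        assert km.survival[-1] == pytest.approx(prod, abs=1e-12)

    def test_group_compared_with_its_duplicate_chi2_zero(self):
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.array([1, 0, 1, 1])
        outc = ss.SurvivalOutcome(list("abcdwxyz"), np.r_[time, time],
                                  np.r_[event, event])
        chi2, df, p = ss.logrank_test(np.r_[np.zeros(4), np.ones(4)], outc)
        assert chi2 == pytest.approx(0.0, abs=1e-12) and df == 1

    def test_single_group_rejected(self):
        outc = ss.SurvivalOutcome(["a", "b"], [1.0, 2.0], [1, 1])
        with pytest.raises(ValueError, match="2 non-empty"):
            ss.logrank_test(np.zeros(2), outc)


class TestCalibration:
    def test_population_self_consistency(self):
        rng = np.random.default_rng(7)
        outc = exponential_cox_outcome(np.zeros(200), rng)
        t = float(np.median(outc.time))
        km_val = ss.km_curve(outc).at(t)
        tab = ss.calibration(np.full(200, km_val), outc, t,
                             population_mode=True)
        row = tab.table.iloc[0]
        assert row["predicted"] == pytest.approx(row["observed"], abs=1e-12)

    def test_gross_miscalibration_detected(self):
        rng = np.random.default_rng(8)
        outc = exponential_cox_outcome(np.zeros(100), rng)
        t = float(np.median(outc.time))
        tab = ss.calibration(np.ones(100), outc, t, population_mode=True)
        row = tab.table.iloc[0]
        assert row["predicted"] == 1.0 > row["observed"]

    def test_well_specified_cox_calibrated_in_bins(self):
        """n=1000, 5 quantile bins: max |predicted - observed| <= 0.1 in
        >= 90% of 20 replicates under a correctly specified model."""
        from stacksurv.cox import breslow_cumhazard, cumhazard_at

        ok = 0
        for rep in range(20):
            rng = np.random.default_rng(900 + rep)
            n = 1000
            lp = rng.standard_normal(n)
            outc = exponential_cox_outcome(lp, rng)
            t = float(np.median(outc.time))
            fit = ss.fit_cox(lp[:, None], outc)
            eta = fit.beta[0] * lp
            times, H0 = breslow_cumhazard(eta, outc)
            pred = np.exp(-cumhazard_at(times, H0, np.full(n, t)) * np.exp(eta))
            tab = ss.calibration(pred, outc, t, n_groups=5)
            gap = (tab.table["predicted"] - tab.table["observed"]).abs().max()
            ok += gap <= 0.1
        assert ok >= 18

    def test_out_of_range_predictions_rejected(self):
        outc = ss.SurvivalOutcome(["a", "b"], [1.0, 2.0], [1, 1])
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            ss.calibration(np.array([0.5, 1.2]), outc, 1.5)


class TestBonferroni:
    def test_three_comparison_threshold_is_0017(self):
        res = ss.bonferroni_adjust([0.02], m=3)
        assert round(res.threshold, 3) == 0.017
        assert res.threshold == pytest.approx(0.05 / 3)

    def test_m_one_threshold_alpha(self):
        assert ss.bonferroni_adjust([0.04], m=1).threshold == 0.05

    def test_published_pairwise_p_significant(self):
        # p = 0.011 between medium- and high-risk groups, m = 3 comparisons
        res = ss.bonferroni_adjust([0.011], m=3)
        assert res.significant[0]

    def test_invalid_m_rejected(self):
        with pytest.raises(ValueError):
            ss.bonferroni_adjust([0.01], m=0)


def test_plot_helpers_render(tmp_path):
    """Plot helpers draw without error and write a vector file."""
    import matplotlib.pyplot as plt

    from stacksurv import plotting

    rng = np.random.default_rng(11)
    marker = rng.standard_normal(120)
    outc = exponential_cox_outcome(marker, rng)
    t = float(np.median(outc.time))
    roc = ss.td_roc(marker, outc, t)
    ax = plotting.plot_td_roc([roc])
    plotting.plot_km(ss.km_curve(outc))
    cal = ss.calibration(np.clip(rng.uniform(size=120), 0, 1), outc, t,
                         population_mode=True)
    plotting.plot_calibration(cal)
    ax.figure.savefig(tmp_path / "roc.svg")
    plt.close("all")
    assert (tmp_path / "roc.svg").stat().st_size > 0
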