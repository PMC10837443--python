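"""Folds, out-of-fold discipline and the non-negative Cox meta-fit."""

import numpy as np
import pandas as pd
import pytest

import stacksurv as ss
from stacksurv.cox import CoxData, cox_loglik

from conftest import exponential_cox_outcome


def _outcome(n, seed=0, censor=0.25):
    rng = np.random.default_rng(seed)
    return exponential_cox_outcome(np.zeros(n), rng, censor_frac=censor)


class TestMakeFolds:
    def test_550_samples_give_ten_folds_of_55(self):
        outc = _outcome(550, seed=1)
        folds = ss.make_folds(outc, K=10, rng_seed=2)
        assert (folds.sizes() == 55).all()

    def test_singleton_folds_when_k_equals_n(self):
        outc = ss.SurvivalOutcome([f"s{i}" for i in range(10)],
                                  np.arange(1.0, 11.0), np.ones(10, dtype=int))
        folds = ss.make_folds(outc, K=10, rng_seed=0)
        assert (folds.sizes() == 1).all()

    def test_balanced_partition_23_into_10(self):
        outc = ss.SurvivalOutcome([f"s{i}" for i in range(23)],
                                  np.arange(1.0, 24.0), np.ones(23, dtype=int))
        folds = ss.make_folds(outc, K=10, rng_seed=0)
        sizes = folds.sizes()
        assert set(sizes) <= {2, 3} and sizes.sum() == 23

    def test_deterministic_and_event_stratified(self):
        outc = _outcome(200, seed=3)
        a = ss.make_folds(outc, K=10, rng_seed=5)
        b = ss.make_folds(outc, K=10, rng_seed=5)
        assert np.array_equal(a.fold, b.fold)
        for k in range(1, 11):
            assert outc.event[a.fold == k].sum() >= 1

    def test_impossible_event_constraint_rejected(self):
        outc = ss.SurvivalOutcome(
            [f"s{i}" for i in range(20)], np.arange(1.0, 21.0),
            np.r_[np.ones(3, dtype=int), np.zeros(17, dtype=int)])
        with pytest.raises(ValueError, match="event"):
            ss.make_folds(outc, K=10, rng_seed=0)


def _cohort_with_submodels(seed=11, n=200, informativeness=(1.0, 0.0)):
    cfg = ss.SimulationConfig(n_samples=n, n_genes=80, n_correlated=25,
                              n_causal=3, true_beta_range=(0.7, 0.9),
                              rng_seed=seed)
    expr, outc, clin, truth = ss.simulate_cohort(cfg)
    sigs = ss.simulate_submodel_signatures(truth, len(informativeness),
                                           list(informativeness),
                                           expr.gene_ids, rng_seed=seed)
    specs = [ss.SubModelSpec(f"m{i}", "fixed_signature", s)
             for i, s in enumerate(sigs)]
    return expr, outc, truth, specs


class TestOofLinearPredictors:
    def test_fixed_signature_equals_direct_risk_score(self):
        expr, outc, _, specs = _cohort_with_submodels()
        folds = ss.make_folds(outc, K=5, rng_seed=1)
        oof = ss.oof_linear_predictors(specs, expr, outc, folds)
        direct = ss.risk_score(specs[0].definition,
                               expr.subset_samples(outc.sample_ids)).score
        np.testing.assert_array_equal(oof.lp["m0"].to_numpy(), direct)

    def test_leave_one_out_matches_manual_loop(self):
        """K = n with a 1-gene refittable signature: every OOF entry equals
        a manual fit-on-(n-1)/predict-1 loop."""
        rng = np.random.default_rng(4)
        n = 6
        x = rng.standard_normal(n)
        outc = ss.SurvivalOutcome([f"s{i}" for i in range(n)],
                                  np.array([3., 1., 4., 2., 6., 5.]),
                                  np.ones(n, dtype=int))
        expr = ss.ExpressionMatrix(pd.DataFrame(x[None, :], index=["g"],
                                                columns=outc.sample_ids))

        def recipe(e, o):
            fit = ss.fit_cox(e.values.T, o)
            return ss.GeneSignature(["g"], fit.beta)

        folds = ss.make_folds(outc, K=n, rng_seed=0)
        oof = ss.oof_linear_predictors(
            [ss.SubModelSpec("loo", "refittable_signature", recipe)],
            expr, outc, folds)
        for i, sid in enumerate(outc.sample_ids):
            keep = np.arange(n) != i
            fit = ss.fit_cox(x[keep][:, None], outc.subset(keep))
            assert oof.lp.loc[sid, "loo"] == pytest.approx(fit.beta[0] * x[i],
                                                           abs=1e-9)

    def test_out_of_fold_discipline_structural(self):
        """No sample's OOF value may come from a model trained on it: a spy
        recipe records its training samples per fold."""
        expr, outc, _, _ = _cohort_with_submodels(seed=12, n=60)
        seen = {}

        def spy_recipe(e, o):
            sig = ss.GeneSignature([e.gene_ids[0]], [1.0])
            seen[len(seen)] = set(o.sample_ids)
            return sig

        folds = ss.make_folds(outc, K=5, rng_seed=2)
        oof = ss.oof_linear_predictors(
            [ss.SubModelSpec("spy", "refittable_signature", spy_recipe)],
            expr, outc, folds)
        for k in range(1, 6):
            held_ids = {outc.sample_ids[i]
                        for i in np.flatnonzero(folds.fold == k)}
            assert not held_ids & seen[k - 1]
        assert oof.lp["spy"].notna().all()

    def test_sample_order_invariance(self):
        expr, outc, _, specs = _cohort_with_submodels(seed=13, n=80)
        folds = ss.make_folds(outc, K=4, rng_seed=3)
        oof = ss.oof_linear_predictors(specs, expr, outc, folds)
        perm = np.random.default_rng(5).permutation(outc.n)
        outc_p = outc.subset(perm)
        expr_p = expr.subset_samples(outc_p.sample_ids)
        folds_p = ss.FoldAssignment(outc_p.sample_ids, folds.fold[perm],
                                    folds.K, folds.rng_seed)
        oof_p = ss.oof_linear_predictors(specs, expr_p, outc_p, folds_p)
        pd.testing.assert_frame_equal(oof_p.lp.sort_index(),
                                      oof.lp.sort_index())

    def test_failing_fold_flagged_missing(self):
        expr, outc, _, _ = _cohort_with_submodels(seed=14, n=50)

        calls = {"k": 0}

        def flaky(e, o):
            calls["k"] += 1
            if calls["k"] == 2:
                raise ValueError("synthetic fit failure")
            return ss.GeneSignature([e.gene_ids[0]], [1.0])

        folds = ss.make_folds(outc, K=5, rng_seed=1)
        with pytest.warns(UserWarning, match="failed in fold"):
            oof = ss.oof_linear_predictors(
                [ss.SubModelSpec("flaky", "refittable_signature", flaky)],
                expr, outc, folds)
        n_missing = oof.lp["flaky"].isna().sum()
        assert n_missing == (folds.fold == 2).sum()


def _profiled_pll(X, outcome, direction):
    """Partial log-likelihood of a weight direction with the overall scale
    profiled out by golden-section search (independent oracle helper)."""
    from scipy.optimize import minimize_scalar

    data = CoxData(outcome.time, outcome.event)
    Xs = data.sort(X)
    f = lambda c: -cox_loglik(data, Xs, c * np.asarray(direction), order=0)
    res = minimize_scalar(f, bounds=(0.0, 50.0), method="bounded",
                          options={"xatol": 1e-8})
    return -res.fun


class TestStackingWeights:
    def test_single_submodel_weight_one(self):
        expr, outc, _, specs = _cohort_with_submodels(seed=15, n=100,
                                                      informativeness=(1.0,))
        folds = ss.make_folds(outc, K=5, rng_seed=1)
        oof = ss.oof_linear_predictors(specs[:1], expr, outc, folds)
        w = ss.fit_stacking_weights(oof, outc)
        assert w.as_series().to_numpy() == pytest.approx([1.0])

    def test_noise_submodel_downweighted(self):
        """True lp vs independent noise at n=500: normalized noise weight
        <= 0.1 (median of 20 replicates)."""
        noise_w = []
        for rep in range(20):
            rng = np.random.default_rng(6000 + rep)
            n = 500
            lp_true = rng.standard_normal(n)
            outc = exponential_cox_outcome(lp_true, rng)
            lp = pd.DataFrame({"true": lp_true,
                               "noise": rng.standard_normal(n)},
                              index=outc.sample_ids)
            oof = ss.OofMatrix(outc.sample_ids, lp)
            w = ss.fit_stacking_weights(oof, outc)
            noise_w.append(w.as_series()["noise"])
        assert np.median(noise_w) <= 0.1

    def test_matches_simplex_grid_search(self):
        """3 sub-models, n=300: normalized weights within 0.02 of a dense
        grid over the 2-simplex (step 0.01, scale profiled per direction)."""
        rng = np.random.default_rng(77)
        n = 300
        Z = rng.standard_normal((n, 3))
        lp_true = Z @ [0.9, 0.5, 0.1]
        outc = exponential_cox_outcome(lp_true, rng)
        X = Z + 0.3 * rng.standard_normal((n, 3))
        oof = ss.OofMatrix(outc.sample_ids,
                           pd.DataFrame(X, index=outc.sample_ids,
                                        columns=["a", "b", "c"]))
        w = ss.fit_stacking_weights(oof, outc)
        best, best_val = None, -np.inf
        for i in range(101):
            for j in range(101 - i):
                direction = np.array([i, j, 100 - i - j]) / 100.0
                val = _profiled_pll(X, outc, direction)
                if val > best_val:
                    best, best_val = direction, val
        np.testing.assert_allclose(w.as_series().to_numpy(), best, atol=0.02)

    def test_objective_at_least_best_single_submodel(self):
        rng = np.random.default_rng(17)
        n = 250
        X = rng.standard_normal((n, 3))
        outc = exponential_cox_outcome(X @ [0.7, 0.4, 0.0], rng)
        oof = ss.OofMatrix(outc.sample_ids,
                           pd.DataFrame(X, index=outc.sample_ids,
                                        columns=list("abc")))
        w = ss.fit_stacking_weights(oof, outc, normalize=False)
        singles = [_profiled_pll(X, outc, np.eye(3)[m]) for m in range(3)]
        assert w.loglik >= max(singles) - 1e-4

    def test_column_scaling_leaves_lp_invariant(self):
        rng = np.random.default_rng(18)
        n = 300
        X = rng.standard_normal((n, 2))
        outc = exponential_cox_outcome(X @ [0.8, 0.5], rng)
        oof1 = ss.OofMatrix(outc.sample_ids,
                            pd.DataFrame(X, index=outc.sample_ids,
                                         columns=["a", "b"]))
        X2 = X.copy()
        X2[:, 0] *= 4.0
        oof2 = ss.OofMatrix(outc.sample_ids,
                            pd.DataFrame(X2, index=outc.sample_ids,
                                         columns=["a", "b"]))
        w1 = ss.fit_stacking_weights(oof1, outc, normalize=False)
        w2 = ss.fit_stacking_weights(oof2, outc, normalize=False)
        assert w2.w[0] == pytest.approx(w1.w[0] / 4.0, abs=1e-3)
        lp1 = ss.stacking_lp(w1, X)
        lp2 = ss.stacking_lp(w2, X2)
        np.testing.assert_allclose(lp1, lp2, atol=1e-3)


class TestStackingLp:
    def test_published_weight_basis_vectors(self):
        w = ss.StackingWeights(["crg", "mrna4", "gene24"],
                               [0.68, 0.25, 0.07], normalized=True)
        assert ss.stacking_lp(w, [1.0, 0.0, 0.0]) == pytest.approx(0.68)
        assert ss.stacking_lp(w, [0.0, 1.0, 0.0]) == pytest.approx(0.25)
        assert ss.stacking_lp(w, [0.0, 0.0, 1.0]) == pytest.approx(0.07)

    def test_zero_lps_give_zero(self):
        w = ss.StackingWeights(["a", "b"], [0.4, 0.6], normalized=True)
        assert ss.stacking_lp(w, [0.0, 0.0]) == 0.0

    def test_dimension_mismatch_rejected(self):
        w = ss.StackingWeights(["a", "b"], [0.5, 0.5], normalized=True)
        with pytest.raises(ValueError, match="mismatch"):
            ss.stacking_lp(w, [1.0, 2.0, 3.0])

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            ss.StackingWeights(["a"], [-0.1], normalized=False)
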