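"""Shared fixtures: small simulated cohorts with known ground truth."""

import numpy as np
import pytest

import stacksurv as ss


@pytest.fixture(scope="session")
def small_cohort():
    """250 samples, 3 causal genes among 40 seed-correlated, ~27% censoring."""
    cfg = ss.SimulationConfig(
        n_samples=250, n_genes=120, n_correlated=40, n_causal=3,
        true_beta_range=(0.7, 0.9), rng_seed=11,
    )
    return cfg, *ss.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def informative_features(small_cohort):
    """Feature frame whose stacking_lp column is the true risk."""
    _, expr, outc, clin, truth = small_cohort
    clin_full = ss.impute_clinical(clin, rng_seed=0) if clin.n_missing else clin
    return ss.build_features(truth.true_lp.to_numpy(), clin_full,
                             outc.sample_ids), outc


def exponential_cox_outcome(lp, rng, censor_frac=0.25, base=0.002):
    """Tiny helper used across tests: exponential-baseline Cox sampler."""
    n = lp.size
    t_event = rng.exponential(size=n) / (base * np.exp(lp - lp.mean()))
    if censor_frac <= 0:
        time, event = t_event, np.ones(n, dtype=int)
    else:
        scale = np.quantile(t_event, 1 - censor_frac) / 1.2
        c = rng.exponential(scale=scale * 3.0, size=n)
        time = np.minimum(t_event, c)
        event = (t_event <= c).astype(int)
    return ss.SurvivalOutcome([f"P{i}" for i in range(n)], np.maximum(time, 1e-6),
                              event)
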