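import numpy as np
import pytest

from phscox.simulate import SimConfig, gen_causal_effects, gen_genotypes, gen_survival


def random_cox_instance(seed, n=200, p=5, ties=False, censor=0.3):
    """Small random survival dataset for solver/metric checks."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    beta = rng.normal(scale=0.3, size=p)
    T = rng.exponential(1.0 / np.exp(X @ beta))
    if censor > 0:
        C = rng.exponential(np.quantile(T, 1 - censor) / 0.7, size=n)
        y = np.minimum(T, C)
        status = (T <= C).astype(float)
    else:
        y, status = T, np.ones(n)
    if ties:
        y = np.ceil(y / np.quantile(y, 0.2)) * np.quantile(y, 0.2)
    return y, status, X


@pytest.fixture(scope="session")
def sim_small():
    """One simulated cohort shared across read-only tests (n=500, p=200)."""
    cfg = SimConfig(
        n_individuals=500, n_variants=200, n_causal=5, seed=3, missing_genotype_rate=0.0
    )
    store = gen_genotypes(cfg)
    truth = gen_causal_effects(cfg)
    ds = gen_survival(store, truth, cfg)
    X = store.dosages()
    mu, sd = X.mean(0), X.std(0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    return cfg, store, truth, ds, Xs
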