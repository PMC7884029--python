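"""Shared fixtures: small simulated studies built at test time."""

import numpy as np
import pandas as pd
import pytest

from centproteo import SimulationConfig, Study, simulate_cohort


def make_study(**overrides):
    """Simulate a cohort and wrap it as a canonically ordered Study."""
    defaults = dict(n_aptamers=300, n_modules=2, module_size_range=(20, 40),
                    seed=0)
    defaults.update(overrides)
    expr, samples, aptamers, truth = simulate_cohort(SimulationConfig(**defaults))
    study = Study(expr.sort_index().sort_index(axis=1),
                  samples.sort_index(), aptamers.sort_index())
    return study, truth


@pytest.fixture(scope="session")
def small_study():
    """Default-shape cohort (224 samples) with 300 aptamers, 2 modules."""
    return make_study()


@pytest.fixture(scope="session")
def null_study():
    """No planted effects of any kind: group labels carry no signal."""
    return make_study(n_aptamers=400, frac_up=0.0, frac_down=0.0,
                      n_modules=0, n_survival_proteins=0, seed=42)


def block_expression(seed, n=100, m=200, block_size=30, n_blocks=2,
                     latent_share=0.6, sd=0.25):
    """Expression with planted correlated blocks at the start of the columns."""
    rng = np.random.default_rng(seed)
    logx = rng.normal(7.0, sd, (n, m))
    loading = sd * np.sqrt(latent_share / (1 - latent_share))
    for b in range(n_blocks):
        latent = rng.normal(0.0, 1.0, n)
        cols = slice(b * block_size, (b + 1) * block_size)
        logx[:, cols] += np.outer(latent, np.full(block_size, loading))
    return pd.DataFrame(np.exp(logx),
                        index=[f"S{i:03d}" for i in range(n)],
                        columns=[f"A{j:03d}" for j in range(m)])
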