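"""Shared fixtures: small simulated assays and fitted posteriors.

Expensive fits are session-scoped so several tests can share them.
"""

import numpy as np
import pytest

from barfit import (
    ADVIOptions,
    ModelConfig,
    SimulationConfig,
    build_single_model,
    fit_advi,
    simulate_logistic_assay,
    split_counts,
)


@pytest.fixture(scope="session")
def small_sim():
    """Single-environment assay, 20 neutral + 50 mutant lineages."""
    cfg = SimulationConfig(n_neutral=20, n_mutant=50, n_timepoints=5, seed=3)
    return simulate_logistic_assay(cfg)


@pytest.fixture(scope="session")
def small_counts(small_sim):
    return split_counts(small_sim.table)


@pytest.fixture(scope="session")
def small_model(small_counts):
    return build_single_model(small_counts, ModelConfig())


@pytest.fixture(scope="session")
def small_fit(small_model):
    opts = ADVIOptions(n_steps=12_000, seed=0, n_posterior_draws=1_500)
    return fit_advi(small_model, opts)


@pytest.fixture(scope="session")
def tiny_sim():
    """Tiny assay for gradient checks and oracles (3 neutral + 2 mutant)."""
    cfg = SimulationConfig(n_neutral=3, n_mutant=2, n_timepoints=4, seed=31,
                           reads_per_timepoint=100_000)
    return simulate_logistic_assay(cfg)


@pytest.fixture(scope="session")
def tiny_model(tiny_sim):
    return build_single_model(split_counts(tiny_sim.table), ModelConfig())


def finite_difference_check(model, rtol=2e-5, jitter=0.05, n_probe=None, seed=0):
    """Compare the analytic gradient against central differences."""
    rng = np.random.default_rng(seed)
    z = model.init_loc() + jitter * rng.standard_normal(model.n_params)
    _, g = model.logp_and_grad(z)
    idx = np.arange(model.n_params)
    if n_probe is not None and n_probe < idx.size:
        idx = rng.choice(idx, n_probe, replace=False)
    h = 1e-5
    for i in idx:
        zp = z.copy()
        zp[i] += h
        zm = z.copy()
        zm[i] -= h
        num = (model.logp(zp) - model.logp(zm)) / (2 * h)
        assert abs(num - g[i]) <= rtol * max(1.0, abs(num)), (
            f"gradient mismatch at parameter {i}: fd={num}, analytic={g[i]}"
        )
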