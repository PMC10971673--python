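"""Core model: frequency transforms, log joint, gradients, structure."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import logsumexp
from scipy.stats import lognorm, norm, poisson

from barfit import (
    ModelConfig,
    SimulationConfig,
    build_single_model,
    log_freq_ratios,
    log_joint,
    naive_frequencies,
    naive_mean_fitness,
    simulate_logistic_assay,
    split_counts,
)
from barfit.io import SplitCounts

from conftest import finite_difference_check


# -- elementary transforms ----------------------------------------------------

def _split(counts):
    counts = np.asarray(counts)
    return SplitCounts(r_neutral=counts[:, :1], r_mutant=counts[:, 1:],
                       neutral_ids=["n0"],
                       mutant_ids=[f"m{i}" for i in range(counts.shape[1] - 1)])


def test_naive_frequencies_matches_read_fractions():
    sc = _split([[10, 10, 20, 60], [5, 5, 10, 30]])
    f = naive_frequencies(sc, pseudocount=0.0)
    np.testing.assert_allclose(f[0], [0.1, 0.1, 0.2, 0.6])
    np.testing.assert_allclose(f[1], [0.1, 0.1, 0.2, 0.6])


def test_naive_frequencies_pseudocount():
    sc = _split([[0, 10], [1, 9]])
    f = naive_frequencies(sc, pseudocount=1.0)
    np.testing.assert_allclose(f[0], [1 / 12, 11 / 12])


@given(st.lists(st.lists(st.integers(0, 1000), min_size=3, max_size=6),
                min_size=2, max_size=5).filter(
                    lambda rows: len({len(r) for r in rows}) == 1
                    and all(sum(r) > 0 for r in rows)))
@settings(max_examples=50, deadline=None)
def test_naive_frequency_rows_sum_to_one(rows):
    f = naive_frequencies(_split(rows), pseudocount=0.5)
    np.testing.assert_allclose(f.sum(axis=1), 1.0, atol=1e-12)
    assert np.all(f > 0)


def test_log_freq_ratios_identities():
    f = np.array([[0.05, 0.95], [0.05 * np.e**0.3, 1 - 0.05 * np.e**0.3]])
    g = log_freq_ratios(f, tau=1.0)
    assert g[0, 0] == pytest.approx(0.3)
    assert log_freq_ratios(f, tau=2.0)[0, 0] == pytest.approx(0.15)
    same = np.array([[0.05, 0.95], [0.05, 0.95]])
    assert log_freq_ratios(same)[0, 0] == 0.0


def test_log_freq_ratios_rejects_zero_frequency():
    with pytest.raises(ValueError, match="pseudocount|latent"):
        log_freq_ratios(np.array([[0.0, 1.0], [0.5, 0.5]]))


def test_naive_mean_fitness_examples():
    # all neutrals decline by e^{-0.2} per cycle -> mean fitness 0.2
    f = np.array([[0.1, 0.1], [0.1 * np.e**-0.2, 0.1 * np.e**-0.2]])
    np.testing.assert_allclose(naive_mean_fitness(f), [0.2])
    # constant frequencies -> 0
    np.testing.assert_allclose(naive_mean_fitness(np.full((3, 2), 0.25)), [0, 0])
    # two neutrals with ratios e^{-0.1}, e^{-0.3} -> mean 0.2
    f = np.array([[0.1, 0.1], [0.1 * np.e**-0.1, 0.1 * np.e**-0.3]])
    np.testing.assert_allclose(naive_mean_fitness(f), [0.2])


# -- model structure ----------------------------------------------------------

def test_parameter_count_closed_form():
    cfg = SimulationConfig(n_neutral=2, n_mutant=3, n_timepoints=4, seed=0,
                           reads_per_timepoint=10_000)
    sc = split_counts(simulate_logistic_assay(cfg).table)
    model = build_single_model(sc)
    T, B, M = 4, 5, 3
    assert model.n_params == T * B + (T - 1) + (T - 1) + M + M == 32
    # neutral barcodes contribute no fitness parameter
    assert model._shapes["fitness"] == (M,)


def test_model_json_description(tiny_model):
    import json

    desc = json.loads(tiny_model.to_json())
    assert desc["variant"] == "single"
    assert desc["n_params"] == tiny_model.n_params
    assert {b["name"] for b in desc["blocks"]} >= {"log_rate", "fitness", "mean_fitness"}


def test_gradient_matches_finite_differences(tiny_model):
    finite_difference_check(tiny_model)


def test_frequencies_from_rates_sum_to_one(tiny_model):
    rng = np.random.default_rng(0)
    Z = tiny_model.init_loc()[None, :] + 0.3 * rng.standard_normal(
        (20, tiny_model.n_params))
    draws = tiny_model.constrain_draws(Z)
    freq = draws["frequency"]
    np.testing.assert_allclose(freq.sum(axis=2), 1.0, atol=1e-10)
    assert np.all(freq > 0)
    assert np.all(draws["sigma_fitness"] > 0)
    assert np.all(draws["sigma_mean"] > 0)


# -- log joint ----------------------------------------------------------------

def _toy_model():
    """1 neutral + 1 mutant, T=2, hand-checkable."""
    sc = SplitCounts(r_neutral=[[8], [6]], r_mutant=[[4], [9]],
                     neutral_ids=["n0"], mutant_ids=["m0"])
    return build_single_model(sc, ModelConfig())


def _toy_state():
    return {
        "log_rate": np.log([[8.0, 4.0], [6.0, 9.0]]),
        "mean_fitness": np.array([0.15]),
        "sigma_mean": np.array([0.3]),
        "fitness": np.array([0.4]),
        "sigma_fitness": np.array([0.25]),
    }


def test_log_joint_matches_direct_density_summation():
    """Oracle: sum every prior and likelihood term with scipy densities."""
    model = _toy_model()
    state = _toy_state()
    R = np.array([[8, 4], [6, 9]], dtype=float)
    ell = state["log_rate"]
    lam = np.exp(ell)
    f = np.exp(ell - logsumexp(ell, axis=1)[:, None])
    gamma = np.log(f[1] / f[0])

    expected = poisson.logpmf(R, lam).sum()
    expected += norm.logpdf(ell, np.log(np.maximum(R, 1.0)), 2.0).sum()
    expected += norm.logpdf(gamma[0], -state["mean_fitness"][0], state["sigma_mean"][0])
    expected += norm.logpdf(gamma[1], state["fitness"][0] - state["mean_fitness"][0],
                            state["sigma_fitness"][0])
    # priors: mean fitness centered on the naive estimate (pseudocount 1)
    f1 = naive_frequencies(model.counts, pseudocount=1.0)
    sbar0 = naive_mean_fitness(f1[:, :1])
    expected += norm.logpdf(state["mean_fitness"][0], sbar0[0], 2.0)
    expected += norm.logpdf(state["fitness"][0], 0.0, 2.0)
    expected += lognorm.logpdf(state["sigma_mean"][0], s=1.0, scale=np.exp(-1.0))
    expected += lognorm.logpdf(state["sigma_fitness"][0], s=1.0, scale=np.exp(-1.0))

    assert log_joint(model, state) == pytest.approx(expected, rel=1e-10)


def test_log_joint_out_of_support_noise():
    model = _toy_model()
    state = _toy_state()
    state["sigma_fitness"] = np.array([-0.1])
    assert log_joint(model, state) == -np.inf


def test_log_joint_shape_mismatch_raises():
    model = _toy_model()
    state = _toy_state()
    state["fitness"] = np.array([0.4, 0.1])
    with pytest.raises(ValueError):
        log_joint(model, state)


def test_rate_shift_moves_only_poisson_and_rate_prior_terms():
    """Adding a constant to all log rates at one time point leaves the
    frequency-dependent (log-ratio) terms unchanged."""
    model = _toy_model()
    state = _toy_state()
    c = 0.37
    shifted = {k: np.array(v, copy=True) for k, v in state.items()}
    shifted["log_rate"][1] += c

    R = np.array([[8, 4], [6, 9]], dtype=float)
    delta_pois = (poisson.logpmf(R[1], np.exp(shifted["log_rate"][1])).sum()
                  - poisson.logpmf(R[1], np.exp(state["log_rate"][1])).sum())
    ell0 = np.log(np.maximum(R[1], 1.0))
    delta_prior = (norm.logpdf(shifted["log_rate"][1], ell0, 2.0).sum()
                   - norm.logpdf(state["log_rate"][1], ell0, 2.0).sum())
    delta = log_joint(model, shifted) - log_joint(model, state)
    assert delta == pytest.approx(delta_pois + delta_prior, rel=1e-9)


def test_doubling_mutant_noise_at_zero_residual():
    """With mutant residuals exactly zero, doubling sigma_m lowers each mutant
    likelihood term by ln 2; the remaining change is the sigma prior shift."""
    model = _toy_model()
    state = _toy_state()
    # choose mean fitness so the single mutant residual vanishes
    ell = state["log_rate"]
    f = np.exp(ell - logsumexp(ell, axis=1)[:, None])
    gamma_m = np.log(f[1, 1] / f[0, 1])
    state["mean_fitness"] = np.array([state["fitness"][0] - gamma_m])

    doubled = {k: np.array(v, copy=True) for k, v in state.items()}
    doubled["sigma_fitness"] = state["sigma_fitness"] * 2.0
    delta = log_joint(model, doubled) - log_joint(model, state)
    prior_delta = (lognorm.logpdf(doubled["sigma_fitness"][0], s=1.0, scale=np.exp(-1))
                   - lognorm.logpdf(state["sigma_fitness"][0], s=1.0, scale=np.exp(-1)))
    n_mutant_terms = 1  # (T-1) * M = 1
    assert delta == pytest.approx(-n_mutant_terms * np.log(2) + prior_delta, rel=1e-9)


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        ModelConfig(tau=-1.0)
    with pytest.raises(ValueError):
        ModelConfig(fitness_prior_sd=0.0)
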