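"""Synthetic assay generator: conservation laws, closed forms, noise scaling."""

import numpy as np
import pandas as pd
import pytest

from barfit import (
    SimulationConfig,
    ground_truth_fitness,
    naive_frequencies,
    simulate_logistic_assay,
    simulate_variant,
    split_counts,
)


def test_fixed_seed_reproduces_count_table():
    cfg = SimulationConfig(n_neutral=5, n_mutant=10, seed=11,
                           reads_per_timepoint=50_000)
    a = simulate_logistic_assay(cfg)
    b = simulate_logistic_assay(cfg)
    pd.testing.assert_frame_equal(a.table.data, b.table.data)
    pd.testing.assert_frame_equal(a.truth, b.truth)


def test_total_reads_conserved_each_timepoint():
    cfg = SimulationConfig(n_neutral=10, n_mutant=40, seed=2,
                           reads_per_timepoint=123_457)
    out = simulate_logistic_assay(cfg)
    totals = out.table.data.groupby("time")["count"].sum()
    assert (totals == 123_457).all()


def test_reference_strain_keeps_majority_at_defaults():
    out = simulate_logistic_assay(SimulationConfig(seed=4))
    cells = out.cell_trajectories
    ref_fraction = cells[:, 0] / cells.sum(axis=1)
    assert np.all(ref_fraction > 0.5)


def test_neutral_dynamics_without_fitness_differences():
    """All growth rates equal and no jitter: observed neutral log-ratios stay
    within 3 binomial sds of zero."""
    cfg = SimulationConfig(n_neutral=30, n_mutant=10, seed=6,
                           fitness_effect_mean=0.0, fitness_effect_sd=0.0,
                           growth_jitter=False, dilution_noise=False)
    out = simulate_logistic_assay(cfg)
    sc = split_counts(out.table)
    f = naive_frequencies(sc, pseudocount=0.5)
    gamma = np.diff(np.log(f), axis=0)
    reads = sc.counts[:-1]
    three_sd = 3.0 * np.sqrt(2.0 / np.maximum(reads, 1))
    assert (np.abs(gamma) < three_sd + 0.02).mean() > 0.99
    # and the ground truth is exactly zero for every lineage
    np.testing.assert_allclose(out.truth["value"], 0.0, atol=1e-12)


def test_exponential_mode_truth_closed_form():
    """kappa -> inf with fixed growth time: truth = (lambda_b - lambda_0) dt / tau."""
    # modest growth per cycle: disable the 1000x dilution bottleneck, which
    # would (correctly) extinguish lineages under exponential growth
    cfg = SimulationConfig(n_neutral=5, n_mutant=20, seed=8,
                           growth_mode="exponential", exponential_dt=2.0, tau=1.0,
                           dilution_noise=False)
    out = simulate_logistic_assay(cfg)
    rates = out.growth_rates
    expected = (rates[1:] - rates[0]) * cfg.exponential_dt / cfg.tau
    observed = out.truth.set_index("barcode")["value"]
    names = [f"neutral_{i:04d}" for i in range(5)] + \
        [f"mutant_{i:04d}" for i in range(20)]
    np.testing.assert_allclose(observed[names], expected, atol=1e-10)


def test_logistic_truth_consistent_with_noise_free_trajectories():
    cfg = SimulationConfig(n_neutral=5, n_mutant=10, seed=12,
                           growth_jitter=False, dilution_noise=False,
                           sequencing_noise=False)
    out = simulate_logistic_assay(cfg)
    cells = out.cell_trajectories[:, 1:]  # barcoded lineages only
    f = cells / cells.sum(axis=1, keepdims=True)
    gamma = np.diff(np.log(f), axis=0)
    s = (gamma - gamma[:, :5].mean(axis=1, keepdims=True)).mean(axis=0)
    np.testing.assert_allclose(out.truth["value"].to_numpy(), s, atol=1e-8)


def test_deeper_sequencing_shrinks_shot_noise():
    """10x read depth cuts the sampling variance of neutral log-ratios ~10x."""
    def neutral_logratio_var(depth, seed):
        cfg = SimulationConfig(n_neutral=50, n_mutant=10, seed=seed,
                               reads_per_timepoint=depth,
                               growth_jitter=False, dilution_noise=False)
        out = simulate_logistic_assay(cfg)
        sc = split_counts(out.table)
        f = naive_frequencies(sc, pseudocount=0.5)
        gamma = np.diff(np.log(f[:, :50]), axis=0)
        return np.var(gamma - gamma.mean(axis=1, keepdims=True))

    v_low = np.mean([neutral_logratio_var(100_000, s) for s in (1, 2, 3)])
    v_high = np.mean([neutral_logratio_var(1_000_000, s) for s in (1, 2, 3)])
    assert 6.0 < v_low / v_high < 15.0


def test_ground_truth_standalone_matches_simulation_sidecar():
    cfg = SimulationConfig(n_neutral=5, n_mutant=10, seed=14)
    out = simulate_logistic_assay(cfg)
    standalone = ground_truth_fitness(cfg)
    np.testing.assert_allclose(standalone["value"], out.truth["value"], atol=1e-12)


# -- variants -----------------------------------------------------------------

def test_multienv_multipliers_halve_and_double_growth():
    cfg = SimulationConfig(n_neutral=4, n_mutant=6, n_timepoints=7, seed=15,
                           reads_per_timepoint=20_000)
    out = simulate_variant(cfg, "multienv")
    sched = out.table.environment_schedule()
    assert sched == [1, 1, 2, 2, 3, 3]
    # environment column covers every time point; truth has one entry per
    # (barcode, environment)
    truth = out.truth
    assert set(truth["environment"]) == {1, 2, 3}
    assert len(truth) == 3 * 10
    # the average realized per-cycle fitness is comparable across environments
    # (effects are specified on the per-cycle scale regardless of multiplier)
    for env in (1, 2, 3):
        vals = out.truth_vector(environment=env).filter(like="mutant")
        assert 0.0 < vals.mean() < 0.6


def test_replicates_zero_batch_scale_degenerates():
    cfg = SimulationConfig(n_neutral=4, n_mutant=8, seed=16, batch_scale=0.0,
                           reads_per_timepoint=20_000)
    out = simulate_variant(cfg, "replicates")
    l1 = out.truth_vector("fitness", replicate=1)
    l2 = out.truth_vector("fitness", replicate=2)
    np.testing.assert_allclose(l1.to_numpy(), l2.reindex(l1.index).to_numpy(),
                               atol=1e-12)
    hyper = out.truth_vector("hyper_fitness")
    local = l1.filter(like="mutant")
    np.testing.assert_allclose(local.to_numpy(),
                               hyper.reindex(local.index).to_numpy(), atol=0.03)


def test_genotype_allocation_mean_barcodes_per_genotype():
    cfg = SimulationConfig(seed=17)  # 900 barcodes over 90 genotypes
    out = simulate_variant(cfg, "genotypes")
    gmap = out.table.genotype_map()
    counts = pd.Series(gmap).value_counts()
    assert len(counts) == 90
    assert counts.min() >= 1
    assert counts.sum() == 900
    assert counts.mean() == pytest.approx(10.0)


def test_unknown_variant_rejected():
    with pytest.raises(ValueError, match="variant"):
        simulate_variant(SimulationConfig(n_neutral=2, n_mutant=2), "weird")


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(dilution=2.0)
    with pytest.raises(ValueError):
        SimulationConfig(n_timepoints=1)
    with pytest.raises(ValueError):
        SimulationConfig(reference_fraction=0.99, neutral_fraction=0.04)
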