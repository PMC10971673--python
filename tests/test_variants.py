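"""Structure and behavior of the multi-environment and hierarchical models."""

import numpy as np
import pytest

from barfit import (
    ADVIOptions,
    EnvironmentSchedule,
    GenotypeMap,
    HierarchyConfig,
    ModelConfig,
    SimulationConfig,
    build_genotype_model,
    build_multienv_model,
    build_replicate_model,
    build_single_model,
    fit_advi,
    pool_genotype_counts,
    simulate_variant,
    split_counts,
    summarize,
    zscore_ecdf,
)
from barfit.io import ValidationError

from conftest import finite_difference_check


@pytest.fixture(scope="module")
def tiny_multienv():
    cfg = SimulationConfig(n_neutral=4, n_mutant=6, n_timepoints=7, seed=5,
                           reads_per_timepoint=20_000)
    return simulate_variant(cfg, "multienv")


@pytest.fixture(scope="module")
def tiny_replicates():
    cfg = SimulationConfig(n_neutral=3, n_mutant=5, n_timepoints=4, seed=9,
                           reads_per_timepoint=20_000, n_replicates=2)
    return simulate_variant(cfg, "replicates")


@pytest.fixture(scope="module")
def tiny_genotypes():
    cfg = SimulationConfig(n_neutral=3, n_mutant=6, n_timepoints=4, seed=9,
                           reads_per_timepoint=20_000, n_genotypes=2)
    return simulate_variant(cfg, "genotypes")


# -- multi-environment --------------------------------------------------------

def test_multienv_parameter_layout(tiny_multienv):
    sc = split_counts(tiny_multienv.table)
    sched = EnvironmentSchedule(tiny_multienv.table.environment_schedule())
    model = build_multienv_model(sc, sched)
    M, E = sc.n_mutant, sched.n_environments
    assert E == 3
    assert model._shapes["fitness"] == (E, M)  # 3M fitness parameters
    # schedule bookkeeping: transitions 1-2 -> env 1, 3-4 -> env 2, 5-6 -> env 3
    assert sched.env_index.tolist() == [0, 0, 1, 1, 2, 2]


def test_multienv_single_environment_reduces_to_core_model(small_counts):
    T = small_counts.n_timepoints
    sched = EnvironmentSchedule(["env_A"] * (T - 1))
    me = build_multienv_model(small_counts, sched)
    single = build_single_model(small_counts)
    assert me.n_params == single.n_params
    assert [(b.name, b.shape[-1]) for b in me.blocks] == \
        [(b.name, b.shape[-1]) for b in single.blocks]


def test_multienv_gradient(tiny_multienv):
    sc = split_counts(tiny_multienv.table)
    sched = EnvironmentSchedule(tiny_multienv.table.environment_schedule())
    finite_difference_check(build_multienv_model(sc, sched))


def test_multienv_unlabeled_transition_rejected(small_counts):
    with pytest.raises(ValueError):
        build_multienv_model(small_counts,
                             EnvironmentSchedule([1, 2]))  # too few labels


def test_multienv_uncertainty_propagates_across_environments():
    """Corrupting neutral counts in environment-1 cycles widens the posterior
    for environment-2 fitness: all parameters share one joint posterior."""
    cfg = SimulationConfig(n_neutral=20, n_mutant=30, n_timepoints=7, seed=55)
    out = simulate_variant(cfg, "multienv")
    table = out.table
    sched = EnvironmentSchedule(table.environment_schedule())

    def env2_sd(tab):
        sc = split_counts(tab)
        model = build_multienv_model(sc, sched)
        samples = fit_advi(model, ADVIOptions(n_steps=8_000, seed=0,
                                              n_posterior_draws=800,
                                              store_frequencies=False))
        res = summarize(samples, tab)
        f = res.fitness()
        return f[f["environment"] == 2]["sd"].mean()

    clean_sd = env2_sd(table)
    # multiply neutral counts at the env-1 time points by noisy factors
    noisy = table.data.copy()
    rng = np.random.default_rng(1)
    mask = noisy["neutral"] & noisy["time"].isin([1, 2, 3])
    noisy.loc[mask, "count"] = np.maximum(
        1, (noisy.loc[mask, "count"] * rng.lognormal(0.0, 0.6, mask.sum()))
    ).astype(int)
    from barfit import BarcodeCountTable

    corrupted_sd = env2_sd(BarcodeCountTable(noisy))
    assert corrupted_sd > clean_sd


# -- replicates ---------------------------------------------------------------

def test_replicate_parameter_layout(tiny_replicates):
    tabs = [split_counts(tiny_replicates.table.subset_replicate(r))
            for r in tiny_replicates.table.replicate_ids]
    model = build_replicate_model(tabs)
    M, K = tabs[0].n_mutant, 2
    assert model._shapes["hyper_fitness"] == (M,)
    assert model._shapes["fitness"] == (K, M)  # M hyper + K*M local


@pytest.mark.parametrize("non_centered", [False, True])
def test_replicate_gradient(tiny_replicates, non_centered):
    tabs = [split_counts(tiny_replicates.table.subset_replicate(r))
            for r in tiny_replicates.table.replicate_ids]
    model = build_replicate_model(tabs, ModelConfig(),
                                  HierarchyConfig(non_centered=non_centered))
    finite_difference_check(model)


def test_replicate_inconsistent_barcodes_rejected(tiny_replicates):
    tabs = [split_counts(tiny_replicates.table.subset_replicate(r))
            for r in tiny_replicates.table.replicate_ids]
    tabs[1].mutant_ids[-1] = "rogue_barcode"
    with pytest.raises(ValidationError, match="rogue_barcode"):
        build_replicate_model(tabs)


def test_replicate_hierarchy_tracks_batch_spread():
    """Posterior sd of the hyper-fitness grows with the simulated batch-effect
    spread, and the inferred deviation scale tracks the simulated one."""
    sds, devs = [], []
    for batch in (0.01, 0.1, 0.3):
        cfg = SimulationConfig(n_neutral=20, n_mutant=30, seed=77,
                               batch_scale=batch)
        out = simulate_variant(cfg, "replicates")
        tabs = [split_counts(out.table.subset_replicate(r))
                for r in out.table.replicate_ids]
        model = build_replicate_model(tabs)
        samples = fit_advi(model, ADVIOptions(n_steps=8_000, seed=0,
                                              n_posterior_draws=800,
                                              store_frequencies=False))
        sds.append(samples.draws["hyper_fitness"].std(axis=0).mean())
        devs.append(samples.draws["dev_scale"].mean())
    assert sds[0] < sds[1] < sds[2]
    assert devs[0] < devs[1] < devs[2]


# -- genotypes ----------------------------------------------------------------

@pytest.mark.parametrize("non_centered", [False, True])
def test_genotype_gradient(tiny_genotypes, non_centered):
    sc = split_counts(tiny_genotypes.table)
    gmap = GenotypeMap(tiny_genotypes.table.genotype_map())
    model = build_genotype_model(sc, gmap, ModelConfig(),
                                 HierarchyConfig(non_centered=non_centered))
    finite_difference_check(model)


def test_genotype_parameter_layout(tiny_genotypes):
    sc = split_counts(tiny_genotypes.table)
    gmap = GenotypeMap(tiny_genotypes.table.genotype_map())
    model = build_genotype_model(sc, gmap)
    assert model._shapes["hyper_fitness"] == (gmap.n_genotypes,)
    assert model._shapes["fitness"] == (sc.n_mutant,)


def test_genotype_unmapped_barcode_rejected(tiny_genotypes):
    sc = split_counts(tiny_genotypes.table)
    gmap = GenotypeMap({b: "g0" for b in sc.mutant_ids[:-1]})
    with pytest.raises(ValidationError):
        build_genotype_model(sc, gmap)


def test_pooled_counts_comparator(tiny_genotypes):
    sc = split_counts(tiny_genotypes.table)
    gmap = GenotypeMap(tiny_genotypes.table.genotype_map())
    pooled = pool_genotype_counts(sc, gmap)
    assert pooled.n_mutant == gmap.n_genotypes
    # reads are conserved within genotypes
    assert pooled.r_mutant.sum() == sc.r_mutant.sum()
    np.testing.assert_array_equal(pooled.total_reads, sc.total_reads)
    model = build_single_model(pooled)
    assert model._shapes["fitness"] == (gmap.n_genotypes,)
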