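"""Synthetic competition-assay generator with known ground truth.

The generator emulates pooled growth-dilution competition assays: an
unlabeled reference strain dominating the culture (>= 90%), a set of neutral
barcoded lineages genetically equivalent to the reference, and a larger set
of barcoded mutants.  Each cycle consists of

1. batch growth of all lineages under a shared-carrying-capacity logistic
   model ``dN_b/dt = lambda_b j_b N_b (1 - sum_b' N_b' / kappa)`` integrated
   to saturation (99% of kappa), with optional per-cycle, per-lineage
   log-normal jitter ``j_b`` on growth rates;
2. multinomial dilution of a ``D`` fraction of the saturated culture into
   fresh medium;
3. multinomial sequencing of the barcoded lineages only (the reference strain
   carries no barcode and is never sequenced), at fixed read depth.

Because every lineage shares the same crowding factor, the logistic system is
solved exactly: in the time-warped coordinate ``dtau* = (1 - S/kappa) dt``
every lineage grows exponentially, ``N_b(tau*) = N_b(0) exp(lambda_b tau*)``,
and the saturation point is found by scalar root finding.  An explicit
exponential-growth mode (``kappa -> inf``, fixed growth time) exists for
closed-form checks.

Effect sizes are specified on the per-cycle relative-fitness scale the models
infer.  A growth-rate offset ``delta`` maps to per-cycle fitness approximately
``delta * ln(1/D) / lambda_0`` (the saturation time of a ``1/D`` dilution), so
the generator converts fitness effects ``s`` to rate offsets via
``delta = s * lambda_0 / ln(1/D)``.  Ground truth is always computed
numerically from a noise-free, infinite-depth companion run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import BarcodeCountTable

__all__ = [
    "SimulationConfig",
    "SimulationOutput",
    "simulate_logistic_assay",
    "ground_truth_fitness",
    "simulate_variant",
    "simulate_from_fitness_model",
]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic assay.

    Fitness-scale fields (``fitness_effect_*``, ``jitter_scale``,
    ``batch_scale``, ``genotype_dev_scale``) are per-cycle relative fitness
    values; the generator converts them to growth-rate offsets internally.
    """

    n_neutral: int = 100
    n_mutant: int = 900
    n_timepoints: int = 5
    baseline_growth_rate: float = 1.0  # lambda_0, per unit time
    fitness_effect_mean: float = 0.3  # mean mutant per-cycle fitness
    fitness_effect_sd: float = 0.15
    carrying_capacity: float = 1e9  # kappa, cells
    dilution: float = 1e-3  # D
    reference_fraction: float = 0.90
    neutral_fraction: float = 0.04  # total across all neutral lineages
    reads_per_timepoint: int = 1_000_000
    jitter_scale: float = 0.05  # per-cycle fitness sd of growth-rate jitter
    seed: int = 0
    # noise switches (each independently ablatable)
    growth_jitter: bool = True
    dilution_noise: bool = True
    sequencing_noise: bool = True
    # growth mode
    growth_mode: str = "logistic"  # or "exponential"
    exponential_dt: float = 1.0  # growth time per cycle in exponential mode
    tau: float = 1.0  # elapsed time per cycle, as reported to the models
    # multi-environment variant
    env_schedule: tuple = (1, 1, 2, 2, 3, 3)  # per-transition labels
    env_multipliers: dict = field(default_factory=lambda: {1: 1.0, 2: 0.5, 3: 2.0})
    # replicate variant
    n_replicates: int = 2
    batch_scale: float = 0.1  # per-cycle fitness sd of replicate batch effects
    # genotype variant
    n_genotypes: int = 90
    genotype_dev_scale: float = 0.05

    def __post_init__(self) -> None:
        if self.n_neutral < 1 or self.n_mutant < 1:
            raise ValueError("need at least one neutral and one mutant lineage")
        if self.n_timepoints < 2:
            raise ValueError("need at least two time points")
        if not (0 < self.dilution < 1):
            raise ValueError("dilution must be in (0, 1)")
        if self.reference_fraction + self.neutral_fraction >= 1.0:
            raise ValueError("initial fractions must leave room for mutants")
        if self.growth_mode not in ("logistic", "exponential"):
            raise ValueError(f"unknown growth mode {self.growth_mode!r}")
        if self.carrying_capacity * self.dilution < 10 * self.n_lineages:
            raise ValueError("kappa * D too small: lineages would go extinct")

    @property
    def n_lineages(self) -> int:
        return self.n_neutral + self.n_mutant + 1  # + unlabeled reference

    @property
    def cycle_log_fold(self) -> float:
        """Nominal log fold-growth per cycle, ln(1/D)."""
        return float(np.log(1.0 / self.dilution))

    def fitness_to_rate_offset(self, s) -> np.ndarray:
        """Per-cycle fitness effect -> growth-rate offset."""
        return np.asarray(s, dtype=float) * self.baseline_growth_rate / self.cycle_log_fold


@dataclass
class SimulationOutput:
    """Synthetic count table plus ground-truth sidecar."""

    table: BarcodeCountTable
    truth: pd.DataFrame  # columns: parameter, barcode, [environment|replicate|genotype], value
    config: SimulationConfig
    cell_trajectories: np.ndarray | None = None  # (T, B+1) incl. reference in col 0
    growth_rates: np.ndarray | None = None  # (B+1,) reference first, where applicable

    def truth_vector(self, parameter: str = "fitness", **selectors) -> pd.Series:
        """Ground-truth values indexed by barcode (or genotype), after filtering."""
        df = self.truth[self.truth["parameter"] == parameter]
        for key, val in selectors.items():
            df = df[df[key] == val]
        key = "barcode"
        if parameter == "hyper_fitness" and "genotype" in df.columns \
                and df["barcode"].isna().all():
            key = "genotype"
        return df.set_index(key)["value"]

    def write(self, prefix) -> None:
        """Write the count table, truth sidecar and a JSON config echo."""
        import dataclasses
        import json

        self.table.data.to_csv(f"{prefix}_counts.csv", index=False)
        self.truth.to_csv(f"{prefix}_truth.csv", index=False)
        cfg = dataclasses.asdict(self.config)
        cfg["env_schedule"] = list(cfg["env_schedule"])
        with open(f"{prefix}_config.json", "w") as fh:
            json.dump(cfg, fh, indent=1, default=str)


def _saturation_warp(n0: np.ndarray, rates: np.ndarray, kappa: float) -> float:
    """Warped time tau* at which the total population reaches 0.99 kappa."""
    target = 0.99 * kappa
    total0 = n0.sum()
    if total0 >= target:
        return 0.0

    def excess(t):
        return np.sum(n0 * np.exp(rates * t)) - target

    hi = 1.0
    while excess(hi) < 0:
        hi *= 2.0
        if hi > 1e4:  # pragma: no cover - unreachable for valid configs
            raise RuntimeError("culture never saturates")
    return brentq(excess, 0.0, hi, xtol=1e-12, rtol=1e-14)


def _grow_one_cycle(n0, rates, cfg: SimulationConfig):
    if cfg.growth_mode == "exponential":
        return n0 * np.exp(rates * cfg.exponential_dt)
    tau_star = _saturation_warp(n0, rates, cfg.carrying_capacity)
    return n0 * np.exp(rates * tau_star)


def _run_assay(rates: np.ndarray, cfg: SimulationConfig, rng: np.random.Generator,
               noisy: bool, per_cycle_rates=None):
    """One assay pass.  Lineage 0 is the unlabeled reference.

    Returns (reads (T, B), cells (T, B+1)).  ``per_cycle_rates`` optionally
    overrides the rates for each cycle (used for environment schedules).
    """
    n_lin = rates.shape[0]
    T = cfg.n_timepoints
    inoc = cfg.carrying_capacity * cfg.dilution * 0.99
    frac0 = np.empty(n_lin)
    frac0[0] = cfg.reference_fraction
    frac0[1:cfg.n_neutral + 1] = cfg.neutral_fraction / cfg.n_neutral
    frac0[cfg.n_neutral + 1:] = (1.0 - cfg.reference_fraction - cfg.neutral_fraction) \
        / cfg.n_mutant

    use_dilution_noise = noisy and cfg.dilution_noise
    use_seq_noise = noisy and cfg.sequencing_noise
    use_jitter = noisy and cfg.growth_jitter
    jitter_rate_sd = cfg.jitter_scale * cfg.baseline_growth_rate / cfg.cycle_log_fold

    if use_dilution_noise:
        n_cells = rng.multinomial(int(round(inoc)), frac0).astype(float)
    else:
        n_cells = inoc * frac0

    reads = np.empty((T, n_lin - 1))
    cells = np.empty((T, n_lin))
    for t in range(T):
        cycle_rates = rates if per_cycle_rates is None else per_cycle_rates[t]
        if use_jitter:
            cycle_rates = cycle_rates * np.exp(
                rng.normal(0.0, jitter_rate_sd / cfg.baseline_growth_rate, n_lin))
        n_cells = _grow_one_cycle(n_cells, cycle_rates, cfg)
        cells[t] = n_cells
        barcoded = n_cells[1:]
        if barcoded.sum() <= 0:
            raise RuntimeError("all barcoded lineages went extinct; increase kappa*D")
        f_bc = barcoded / barcoded.sum()
        if use_seq_noise:
            reads[t] = rng.multinomial(cfg.reads_per_timepoint, f_bc)
        else:
            reads[t] = cfg.reads_per_timepoint * f_bc
        if t < T - 1:
            if use_dilution_noise:
                frac = n_cells / n_cells.sum()
                n_cells = rng.multinomial(
                    int(round(n_cells.sum() * cfg.dilution)), frac).astype(float)
                if n_cells[1:cfg.n_neutral + 1].sum() == 0:
                    raise RuntimeError(
                        "all neutral lineages lost at dilution; increase kappa*D")
            else:
                n_cells = n_cells * cfg.dilution
    return reads, cells


def _truth_from_noise_free(reads: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    """Per-transition fitness of every barcoded lineage vs the neutral reference.

    ``reads`` must come from a noise-free run.  Returns (T-1, B).
    """
    f = reads / reads.sum(axis=1, keepdims=True)
    gamma = np.diff(np.log(f), axis=0) / cfg.tau
    gamma_neutral = gamma[:, :cfg.n_neutral].mean(axis=1)
    return gamma - gamma_neutral[:, None]


def _barcode_names(cfg: SimulationConfig):
    neutral = [f"neutral_{i:04d}" for i in range(cfg.n_neutral)]
    mutant = [f"mutant_{i:04d}" for i in range(cfg.n_mutant)]
    return neutral, mutant


def _counts_frame(reads, cfg, extra_cols=None):
    neutral, mutant = _barcode_names(cfg)
    names = neutral + mutant
    T = cfg.n_timepoints
    rows = {
        "barcode": np.repeat([names], T, axis=0).ravel(),
        "time": np.repeat(np.arange(1, T + 1), len(names)),
        "count": np.round(reads).astype(np.int64).ravel(),
        "neutral": np.tile([True] * cfg.n_neutral + [False] * cfg.n_mutant, T),
    }
    df = pd.DataFrame(rows)
    if extra_cols:
        for key, fn in extra_cols.items():
            df[key] = fn(df)
    return df


def _draw_mutant_effects(cfg: SimulationConfig, rng: np.random.Generator,
                         mean=None, sd=None) -> np.ndarray:
    mean = cfg.fitness_effect_mean if mean is None else mean
    sd = cfg.fitness_effect_sd if sd is None else sd
    eff = rng.normal(mean, sd, cfg.n_mutant)
    # truncate so every growth rate stays positive
    floor = -0.9 * cfg.cycle_log_fold
    return np.maximum(eff, floor)


def _rates_from_effects(cfg: SimulationConfig, effects: np.ndarray,
                        multiplier: float = 1.0) -> np.ndarray:
    """Absolute growth rates: [reference, neutrals..., mutants...]."""
    lam0 = cfg.baseline_growth_rate * multiplier
    rates = np.full(cfg.n_lineages, lam0)
    rates[cfg.n_neutral + 1:] += cfg.fitness_to_rate_offset(effects) * multiplier
    return rates


def simulate_logistic_assay(config: SimulationConfig | None = None,
                            rng: np.random.Generator | None = None) -> SimulationOutput:
    """Single-environment assay: noisy counts plus noise-free ground truth."""
    cfg = config or SimulationConfig()
    root = np.random.SeedSequence(cfg.seed)
    s_draw, s_noise = root.spawn(2)
    rng_draw = np.random.default_rng(s_draw)
    rng_noise = rng or np.random.default_rng(s_noise)

    effects = _draw_mutant_effects(cfg, rng_draw)
    rates = _rates_from_effects(cfg, effects)

    reads, cells = _run_assay(rates, cfg, rng_noise, noisy=True)
    clean_reads, _ = _run_assay(rates, cfg, rng_noise, noisy=False)
    truth_all = _truth_from_noise_free(clean_reads, cfg).mean(axis=0)

    neutral, mutant = _barcode_names(cfg)
    truth = pd.DataFrame({
        "parameter": "fitness",
        "barcode": neutral + mutant,
        "value": truth_all,
    })
    table = BarcodeCountTable(_counts_frame(reads, cfg))
    return SimulationOutput(table=table, truth=truth, config=cfg,
                            cell_trajectories=cells, growth_rates=rates)


def ground_truth_fitness(config: SimulationConfig) -> pd.DataFrame:
    """Noise-free, infinite-depth companion run; per-barcode fitness truth.

    In exponential mode with fixed growth time ``dt`` this equals
    ``(lambda_b - lambda_0) * dt / tau`` exactly.
    """
    cfg = config
    root = np.random.SeedSequence(cfg.seed)
    s_draw, _ = root.spawn(2)
    effects = _draw_mutant_effects(cfg, np.random.default_rng(s_draw))
    rates = _rates_from_effects(cfg, effects)
    reads, _ = _run_assay(rates, cfg, np.random.default_rng(0), noisy=False)
    truth = _truth_from_noise_free(reads, cfg).mean(axis=0)
    neutral, mutant = _barcode_names(cfg)
    return pd.DataFrame({"parameter": "fitness", "barcode": neutral + mutant,
                         "value": truth})


def _simulate_multienv(cfg: SimulationConfig, rng_draw, rng_noise) -> SimulationOutput:
    schedule = list(cfg.env_schedule)
    T = cfg.n_timepoints
    if len(schedule) != T - 1:
        cfg = replace(cfg, n_timepoints=len(schedule) + 1)
        T = cfg.n_timepoints
    envs = sorted(set(schedule))
    # independent per-environment mutant effects (per-cycle fitness scale)
    effects = {e: _draw_mutant_effects(cfg, rng_draw) for e in envs}
    mult = cfg.env_multipliers
    rates_by_env = {
        e: _rates_from_effects(cfg, effects[e], multiplier=float(mult[e]))
        for e in envs
    }
    # cycle c (0-based) grows in the environment of transition c, with the
    # first growth cycle sharing transition 1's environment
    cycle_envs = [schedule[0]] + schedule
    per_cycle = [rates_by_env[cycle_envs[t]] for t in range(T)]
    base = per_cycle[0]

    reads, cells = _run_assay(base, cfg, rng_noise, noisy=True, per_cycle_rates=per_cycle)
    clean, _ = _run_assay(base, cfg, np.random.default_rng(0), noisy=False,
                          per_cycle_rates=per_cycle)
    per_transition = _truth_from_noise_free(clean, cfg)  # (T-1, B)

    neutral, mutant = _barcode_names(cfg)
    names = neutral + mutant
    frames = []
    for e in envs:
        rows = [t for t, lab in enumerate(schedule) if lab == e]
        frames.append(pd.DataFrame({
            "parameter": "fitness",
            "barcode": names,
            "environment": e,
            "value": per_transition[rows].mean(axis=0),
        }))
    truth = pd.concat(frames, ignore_index=True)

    env_of_time = {1: cycle_envs[0]}
    for t in range(2, T + 1):
        env_of_time[t] = schedule[t - 2]
    table = BarcodeCountTable(_counts_frame(
        reads, cfg, extra_cols={"environment": lambda d: d["time"].map(env_of_time)}))
    return SimulationOutput(table=table, truth=truth, config=cfg,
                            cell_trajectories=cells)


def _simulate_replicates(cfg: SimulationConfig, rng_draw, rng_noise) -> SimulationOutput:
    hyper = _draw_mutant_effects(cfg, rng_draw)
    tables = []
    truths = [pd.DataFrame({
        "parameter": "hyper_fitness",
        "barcode": _barcode_names(cfg)[1],
        "value": hyper[: cfg.n_mutant],
    })]
    for k in range(cfg.n_replicates):
        local = hyper + rng_draw.normal(0.0, cfg.batch_scale, cfg.n_mutant)
        rates = _rates_from_effects(cfg, local)
        reads, _ = _run_assay(rates, cfg, rng_noise, noisy=True)
        clean, _ = _run_assay(rates, cfg, np.random.default_rng(0), noisy=False)
        truth_local = _truth_from_noise_free(clean, cfg).mean(axis=0)
        neutral, mutant = _barcode_names(cfg)
        truths.append(pd.DataFrame({
            "parameter": "fitness",
            "barcode": neutral + mutant,
            "replicate": k + 1,
            "value": truth_local,
        }))
        df = _counts_frame(reads, cfg)
        df["rep"] = k + 1
        df = df.rename(columns={"rep": "replicate"})
        tables.append(df)
    table = BarcodeCountTable(pd.concat(tables, ignore_index=True))
    return SimulationOutput(table=table, truth=pd.concat(truths, ignore_index=True),
                            config=cfg)


def _simulate_genotypes(cfg: SimulationConfig, rng_draw, rng_noise) -> SimulationOutput:
    G, M = cfg.n_genotypes, cfg.n_mutant
    if M < G:
        raise ValueError("need at least one barcode per genotype")
    # one barcode guaranteed per genotype, remainder multinomial (mean M/G)
    alloc = np.ones(G, dtype=int) + rng_draw.multinomial(M - G, np.full(G, 1.0 / G))
    gidx = np.repeat(np.arange(G), alloc)
    theta = np.maximum(rng_draw.normal(cfg.fitness_effect_mean, cfg.fitness_effect_sd, G),
                       -0.9 * cfg.cycle_log_fold)
    local = theta[gidx] + rng_draw.normal(0.0, cfg.genotype_dev_scale, M)
    rates = _rates_from_effects(cfg, local)
    reads, _ = _run_assay(rates, cfg, rng_noise, noisy=True)
    clean, _ = _run_assay(rates, cfg, np.random.default_rng(0), noisy=False)
    truth_local = _truth_from_noise_free(clean, cfg).mean(axis=0)

    neutral, mutant = _barcode_names(cfg)
    gnames = [f"genotype_{g:03d}" for g in range(G)]
    truth = pd.concat([
        pd.DataFrame({"parameter": "hyper_fitness", "barcode": pd.NA,
                      "genotype": gnames, "value": theta}),
        pd.DataFrame({"parameter": "fitness", "barcode": neutral + mutant,
                      "genotype": ["" for _ in neutral] + [gnames[g] for g in gidx],
                      "value": truth_local}),
    ], ignore_index=True)
    bc_to_geno = dict(zip(mutant, [gnames[g] for g in gidx]))
    table = BarcodeCountTable(_counts_frame(
        reads, cfg,
        extra_cols={"genotype": lambda d: d["barcode"].map(
            lambda b: bc_to_geno.get(b, ""))}))
    return SimulationOutput(table=table, truth=truth, config=cfg)


def simulate_variant(config: SimulationConfig | None = None,
                     variant: str = "multienv") -> SimulationOutput:
    """Variant datasets: ``multienv``, ``replicates`` or ``genotypes``."""
    cfg = config or SimulationConfig()
    root = np.random.SeedSequence(cfg.seed)
    s_draw, s_noise = root.spawn(2)
    rng_draw = np.random.default_rng(s_draw)
    rng_noise = np.random.default_rng(s_noise)
    if variant == "multienv":
        return _simulate_multienv(cfg, rng_draw, rng_noise)
    if variant == "replicates":
        return _simulate_replicates(cfg, rng_draw, rng_noise)
    if variant == "genotypes":
        return _simulate_genotypes(cfg, rng_draw, rng_noise)
    raise ValueError(f"unknown variant {variant!r}")


def simulate_from_fitness_model(n_neutral: int, n_mutant: int, n_timepoints: int,
                                fitness: np.ndarray, mean_fitness: np.ndarray,
                                sigma_neutral: float, sigma_mutant: float,
                                depth: int, seed: int = 0,
                                initial_freq: np.ndarray | None = None,
                                poisson_counts: bool = True) -> tuple:
    """Generate counts from the inference model's own generative process.

    Frequency trajectories follow the per-cycle log-ratio likelihood exactly
    (Gaussian noise around ``s - sbar_t`` on log ratios, renormalized each
    cycle), and reads are Poisson with rate ``depth * f``.  Used for
    calibration-closure and posterior-predictive self-consistency checks,
    where data must come from the fitted model family itself.

    Returns ``(BarcodeCountTable, truth Series indexed by barcode)``.
    """
    rng = np.random.default_rng(seed)
    B = n_neutral + n_mutant
    T = n_timepoints
    if initial_freq is None:
        f = np.full(B, 1.0 / B)
    else:
        f = np.asarray(initial_freq, dtype=float)
        f = f / f.sum()
    s = np.concatenate([np.zeros(n_neutral), np.asarray(fitness, dtype=float)])
    sig = np.concatenate([np.full(n_neutral, sigma_neutral),
                          np.full(n_mutant, sigma_mutant)])
    freqs = [f]
    for t in range(T - 1):
        gamma = rng.normal(s - mean_fitness[t], sig)
        f = f * np.exp(gamma)
        f = f / f.sum()
        freqs.append(f)
    F = np.array(freqs)
    if poisson_counts:
        reads = rng.poisson(depth * F)
    else:  # deterministic infinite-depth limit, rounded to integer reads
        reads = np.round(depth * F).astype(np.int64)
    # Poisson draws can zero out a whole row only at absurdly low depth
    neutral_names = [f"neutral_{i:04d}" for i in range(n_neutral)]
    mutant_names = [f"mutant_{i:04d}" for i in range(n_mutant)]
    names = neutral_names + mutant_names
    df = pd.DataFrame({
        "barcode": np.repeat([names], T, axis=0).ravel(),
        "time": np.repeat(np.arange(1, T + 1), B),
        "count": reads.ravel(),
        "neutral": np.tile([True] * n_neutral + [False] * n_mutant, T),
    })
    truth = pd.Series(np.asarray(fitness, dtype=float), index=mutant_names)
    return BarcodeCountTable(df), truth
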