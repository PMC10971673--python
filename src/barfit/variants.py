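"""Extended model variants.

Three extensions of the single-dataset model:

* **multi-environment** — growth-dilution cycles alternate between
  environments; each non-neutral barcode gets one fitness parameter per
  environment, all sharing a joint posterior so that uncertainty in one
  environment's mean fitness propagates to the others;
* **experimental replicates** — a two-level hierarchy with a hyper-fitness
  ``theta_m`` per barcode and replicate-local fitness values
  ``s_im = theta_m + tau_theta * z_im`` (non-centered by default); latent
  frequencies, mean fitness and noise scales stay replicate-local so batch
  effects in the environment are not shared;
* **genotypes** — many barcodes map to one genotype; a per-genotype
  hyper-fitness ``theta_g`` with barcode-level deviations of scale
  ``tau_g``.  The likelihood stays at the barcode level.

Hierarchical deviation scales carry half-normal priors and are
log-parameterized internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .io import SplitCounts, ValidationError
from .model import (
    BaseModel,
    ModelConfig,
    SingleModel,
    _gamma_grad_to_ell,
    _gamma_stats,
    _gaussian_residual_terms,
    _poisson_terms,
    log_freq_ratios,
    naive_frequencies,
    naive_mean_fitness,
)

__all__ = [
    "EnvironmentSchedule",
    "HierarchyConfig",
    "GenotypeMap",
    "MultiEnvModel",
    "ReplicateModel",
    "GenotypeModel",
    "build_multienv_model",
    "build_replicate_model",
    "build_genotype_model",
    "pool_genotype_counts",
]


@dataclass
class EnvironmentSchedule:
    """Environment label for each transition ``t -> t+1`` (length ``T-1``)."""

    labels: list

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        if len(self.labels) < 1:
            raise ValueError("schedule must cover at least one transition")
        if any(lab is None for lab in self.labels):
            raise ValueError("every transition needs an environment label")
        # unique environments in order of first appearance (deterministic)
        seen: dict = {}
        for lab in self.labels:
            seen.setdefault(lab, len(seen))
        self.environments = list(seen)
        self.env_index = np.array([seen[lab] for lab in self.labels], dtype=int)

    @property
    def n_environments(self) -> int:
        return len(self.environments)


@dataclass
class HierarchyConfig:
    """Hyper-prior and deviation-scale prior for hierarchical variants."""

    hyper_prior_mean: float = 0.0
    hyper_prior_sd: float = 2.0
    dev_scale_prior: float = 1.0  # half-normal scale for the spread around theta
    # centered local fitness by default: with informative per-barcode data the
    # centered form recovers the deviation scale reliably, whereas the
    # factorized variational posterior collapses it in non-centered form
    non_centered: bool = False

    def __post_init__(self) -> None:
        if self.hyper_prior_sd <= 0 or self.dev_scale_prior <= 0:
            raise ValueError("hierarchy prior scales must be positive")


@dataclass
class GenotypeMap:
    """Known mapping from non-neutral barcode ids to genotype ids."""

    mapping: dict

    def __post_init__(self) -> None:
        self.mapping = dict(self.mapping)
        seen: dict = {}
        for bc in sorted(self.mapping):
            seen.setdefault(self.mapping[bc], len(seen))
        self.genotypes = list(seen)
        self._gindex = {g: i for i, g in enumerate(self.genotypes)}

    @property
    def n_genotypes(self) -> int:
        return len(self.genotypes)

    def index_for(self, barcode_ids) -> np.ndarray:
        missing = [b for b in barcode_ids if b not in self.mapping]
        if missing:
            raise ValidationError(f"barcodes without a genotype mapping: {missing[:5]}")
        return np.array([self._gindex[self.mapping[b]] for b in barcode_ids], dtype=int)


class MultiEnvModel(SingleModel):
    """One fitness parameter per (mutant, environment).

    The per-mutant noise scale is shared across environments by default:
    with a handful of transitions per environment a per-(mutant, environment)
    scale is essentially unidentified and its prior would dominate the
    intervals.  Set ``per_env_noise=True`` to get independent scales.
    """

    variant = "multienv"

    def __init__(self, counts: SplitCounts, schedule: EnvironmentSchedule,
                 config: ModelConfig, per_env_noise: bool = False):
        if len(schedule.labels) != counts.n_timepoints - 1:
            raise ValueError(
                f"schedule covers {len(schedule.labels)} transitions but the data "
                f"has {counts.n_timepoints - 1}"
            )
        self.schedule = schedule
        self.per_env_noise = per_env_noise
        SingleModel.__init__(self, counts, config)

    # override the fitness blocks declared by SingleModel.__init__: rebuild
    def _add_block(self, name, shape, prior_desc, prior_loc, prior_scale, **kw):
        E = self.schedule.n_environments
        if name == "fitness":
            # per-environment initialization from transitions in that environment
            f_naive = naive_frequencies(self.counts, pseudocount=1.0)
            sbar0 = naive_mean_fitness(f_naive[:, : self.N], self.tau)
            gamma = log_freq_ratios(f_naive, self.tau)[:, self.N:]
            resid = gamma + sbar0[:, None]
            init = np.zeros((E, self.M))
            for e in range(E):
                rows = self.schedule.env_index == e
                init[e] = resid[rows].mean(axis=0)
            super()._add_block(name, (E, self.M), prior_desc + " per environment",
                               self.config.fitness_prior_mean,
                               self.config.fitness_prior_sd, init=init.ravel())
        elif name == "log_sigma_fitness" and self.per_env_noise:
            super()._add_block(name, (E, self.M), prior_desc + " per environment",
                               prior_loc, prior_scale)
        else:
            super()._add_block(name, shape, prior_desc, prior_loc, prior_scale, **kw)

    def dims(self):
        d = super().dims()
        d["E"] = self.schedule.n_environments
        return d

    def _mutant_moments(self, p):
        idx = self.schedule.env_index
        mu = p["fitness"][idx] - p["mean_fitness"][:, None]
        sig_m = np.exp(p["log_sigma_fitness"])
        if self.per_env_noise:
            sig = sig_m[idx]
        else:
            sig = np.broadcast_to(sig_m[None, :], mu.shape)
        return mu, sig

    def _loglik_and_grad(self, z):
        # SingleModel's path works except the fitness gradients must be
        # scattered per environment; redo just those entries.
        p = self.unpack(z)
        N, E = self.N, self.schedule.n_environments
        lp, g_ell = _poisson_terms(p["log_rate"], self.R, self._lgamma_R)
        f, gamma = _gamma_stats(p["log_rate"], self.tau)

        sig_t = np.exp(p["log_sigma_mean"])
        mu = np.empty((self.T - 1, self.B))
        sig = np.empty_like(mu)
        mu[:, :N] = -p["mean_fitness"][:, None]
        sig[:, :N] = sig_t[:, None]
        mu[:, N:], sig[:, N:] = self._mutant_moments(p)

        lg, w2, dls = _gaussian_residual_terms(gamma, mu, sig)
        lp += lg
        g_ell += _gamma_grad_to_ell(-w2, f, self.tau)

        g = np.zeros(self.n_params)
        g[self._slices["log_rate"]] = g_ell.ravel()
        g[self._slices["mean_fitness"]] = -w2.sum(axis=1)
        g[self._slices["log_sigma_mean"]] = dls[:, :N].sum(axis=1)
        g_s = np.zeros((E, self.M))
        np.add.at(g_s, self.schedule.env_index, w2[:, N:])
        g[self._slices["fitness"]] = g_s.ravel()
        if self.per_env_noise:
            g_v = np.zeros((E, self.M))
            np.add.at(g_v, self.schedule.env_index, dls[:, N:])
            g[self._slices["log_sigma_fitness"]] = g_v.ravel()
        else:
            g[self._slices["log_sigma_fitness"]] = dls[:, N:].sum(axis=0)
        return lp, g

    def constrain_draws(self, Z, store_frequencies=True):
        out = super().constrain_draws(Z, store_frequencies=store_frequencies)
        E = self.schedule.n_environments
        out["fitness"] = out["fitness"].reshape(-1, E, self.M)
        if self.per_env_noise:
            out["sigma_fitness"] = out["sigma_fitness"].reshape(-1, E, self.M)
        return out

    def scale_couplings(self):
        loc = self._block_indices("fitness")
        scale = self._block_indices("log_sigma_fitness")
        if not self.per_env_noise:
            scale = np.tile(scale, self.schedule.n_environments)
        return loc, scale

    def meta(self):
        m = super().meta()
        m["environments"] = list(self.schedule.environments)
        return m


class GenotypeModel(BaseModel):
    """Barcode-level likelihood with per-genotype hyper-fitness."""

    variant = "genotypes"

    def __init__(self, counts: SplitCounts, gmap: GenotypeMap, config: ModelConfig,
                 hier: HierarchyConfig):
        super().__init__()
        T, N, M = counts.n_timepoints, counts.n_neutral, counts.n_mutant
        if T < 2:
            raise ValueError("at least two time points are required")
        self.counts, self.config, self.hier, self.gmap = counts, config, hier, gmap
        self.T, self.N, self.M, self.B = T, N, M, N + M
        self.G = gmap.n_genotypes
        self.gidx = gmap.index_for(counts.mutant_ids)
        self.R = counts.counts.astype(float)
        self.tau = config.tau_vector(T - 1)
        from scipy.special import gammaln
        self._lgamma_R = float(np.sum(gammaln(self.R + 1.0)))

        ell0 = np.log(np.maximum(self.R, 1.0))
        f_naive = naive_frequencies(counts, pseudocount=1.0)
        sbar0 = naive_mean_fitness(f_naive[:, :N], self.tau)
        s0 = (log_freq_ratios(f_naive, self.tau)[:, N:] + sbar0[:, None]).mean(axis=0)
        theta0 = np.bincount(self.gidx, weights=s0, minlength=self.G) / \
            np.bincount(self.gidx, minlength=self.G)

        c, h = config, hier
        self._add_block("log_rate", (T, self.B),
                        f"Normal(log max(r,1), {c.rate_prior_sd})", ell0, c.rate_prior_sd)
        self._add_block("mean_fitness", (T - 1,),
                        f"Normal(naive estimate, {c.mean_fitness_prior_sd})",
                        sbar0, c.mean_fitness_prior_sd)
        self._add_block("log_sigma_mean", (T - 1,),
                        f"Normal({c.noise_prior_loc}, {c.noise_prior_scale}) [log scale]",
                        c.noise_prior_loc, c.noise_prior_scale)
        self._add_block("hyper_fitness", (self.G,),
                        f"Normal({h.hyper_prior_mean}, {h.hyper_prior_sd})",
                        h.hyper_prior_mean, h.hyper_prior_sd, init=theta0)
        self._add_block("log_dev_scale", (1,),
                        f"HalfNormal({h.dev_scale_prior}) [log scale]",
                        0.0, 1.0, init=np.log(0.1),
                        halfnormal_log_scale=h.dev_scale_prior)
        if h.non_centered:
            self._add_block("fitness_z", (M,), "Normal(0, 1) [non-centered local]",
                            0.0, 1.0, init=0.0)
        else:
            # centered local fitness; its conditional prior N(theta_g, tau_g)
            # is added in the likelihood pass (infinite scale masks the
            # generic normal prior)
            self._add_block("fitness", (M,), "Normal(theta_g, tau_g) [centered local]",
                            0.0, np.inf, init=s0)
        self._add_block("log_sigma_fitness", (M,),
                        f"Normal({c.noise_prior_loc}, {c.noise_prior_scale}) [log scale]",
                        c.noise_prior_loc, c.noise_prior_scale)
        self._finalize()

    def dims(self):
        return {"T": self.T, "N": self.N, "M": self.M, "B": self.B, "G": self.G}

    def _local_fitness(self, p):
        theta = p["hyper_fitness"]
        if self.hier.non_centered:
            tau_g = np.exp(p["log_dev_scale"][0])
            return theta[self.gidx] + tau_g * p["fitness_z"]
        return p["fitness"]

    def _loglik_and_grad(self, z):
        p = self.unpack(z)
        N = self.N
        lp, g_ell = _poisson_terms(p["log_rate"], self.R, self._lgamma_R)
        f, gamma = _gamma_stats(p["log_rate"], self.tau)

        s_local = self._local_fitness(p)
        sig_t = np.exp(p["log_sigma_mean"])
        sig_m = np.exp(p["log_sigma_fitness"])
        mu = np.empty((self.T - 1, self.B))
        sig = np.empty_like(mu)
        mu[:, :N] = -p["mean_fitness"][:, None]
        sig[:, :N] = sig_t[:, None]
        mu[:, N:] = s_local[None, :] - p["mean_fitness"][:, None]
        sig[:, N:] = sig_m[None, :]

        lg, w2, dls = _gaussian_residual_terms(gamma, mu, sig)
        lp += lg
        g_ell += _gamma_grad_to_ell(-w2, f, self.tau)

        g = np.zeros(self.n_params)
        g[self._slices["log_rate"]] = g_ell.ravel()
        g[self._slices["mean_fitness"]] = -w2.sum(axis=1)
        g[self._slices["log_sigma_mean"]] = dls[:, :N].sum(axis=1)
        g[self._slices["log_sigma_fitness"]] = dls[:, N:].sum(axis=0)

        g_s = w2[:, N:].sum(axis=0)  # d loglik / d local fitness
        if self.hier.non_centered:
            tau_g = np.exp(p["log_dev_scale"][0])
            g[self._slices["hyper_fitness"]] = np.bincount(
                self.gidx, weights=g_s, minlength=self.G)
            g[self._slices["fitness_z"]] = tau_g * g_s
            g[self._slices["log_dev_scale"]] = tau_g * float(np.dot(p["fitness_z"], g_s))
        else:
            # centered: local prior N(theta_g, tau_g) belongs to the joint here
            tau_g = np.exp(p["log_dev_scale"][0])
            dev = p["fitness"] - p["hyper_fitness"][self.gidx]
            lp += -0.5 * np.sum((dev / tau_g) ** 2) - self.M * np.log(tau_g) \
                - 0.5 * self.M * np.log(2 * np.pi)
            g[self._slices["fitness"]] = g_s - dev / tau_g**2
            g[self._slices["hyper_fitness"]] = np.bincount(
                self.gidx, weights=dev / tau_g**2, minlength=self.G)
            g[self._slices["log_dev_scale"]] += np.sum((dev / tau_g) ** 2) - self.M
        return lp, g

    def constrain_draws(self, Z, store_frequencies=True):
        out = {}
        sl = self._slices
        out["mean_fitness"] = Z[:, sl["mean_fitness"]]
        out["sigma_mean"] = np.exp(Z[:, sl["log_sigma_mean"]])
        out["hyper_fitness"] = Z[:, sl["hyper_fitness"]]
        out["dev_scale"] = np.exp(Z[:, sl["log_dev_scale"]])
        if self.hier.non_centered:
            out["fitness"] = out["hyper_fitness"][:, self.gidx] + \
                out["dev_scale"] * Z[:, sl["fitness_z"]]
        else:
            out["fitness"] = Z[:, sl["fitness"]]
        out["sigma_fitness"] = np.exp(Z[:, sl["log_sigma_fitness"]])
        if store_frequencies:
            n = Z.shape[0]
            ell = Z[:, sl["log_rate"]].reshape(n, self.T, self.B)
            out["frequency"] = np.exp(ell - logsumexp(ell, axis=2)[:, :, None])
        return out

    def meta(self):
        return {
            "variant": self.variant,
            "mutant_ids": list(self.counts.mutant_ids),
            "neutral_ids": list(self.counts.neutral_ids),
            "genotypes": list(self.gmap.genotypes),
            "genotype_index": self.gidx.tolist(),
            "n_transitions": self.T - 1,
        }

    def scale_couplings(self):
        local = "fitness_z" if self.hier.non_centered else "fitness"
        loc = np.concatenate([self._block_indices(local),
                              self._block_indices("hyper_fitness")])
        dev = self._block_indices("log_dev_scale")
        scale = np.concatenate([self._block_indices("log_sigma_fitness"),
                                np.repeat(dev, self.G)])
        return loc, scale


class ReplicateModel(BaseModel):
    """Hierarchical model over experimental replicates.

    Latent rates, mean fitness and noise scales are replicate-local; only the
    per-barcode fitness is tied across replicates through the hyper-fitness.
    """

    variant = "replicates"

    def __init__(self, tables: list[SplitCounts], config: ModelConfig,
                 hier: HierarchyConfig):
        super().__init__()
        if len(tables) < 2:
            raise ValueError("at least two replicates are required")
        ids0 = tables[0].barcode_ids
        for k, t in enumerate(tables[1:], start=2):
            if t.barcode_ids != ids0:
                extra = sorted(set(t.barcode_ids) ^ set(ids0))
                raise ValidationError(
                    f"replicate {k} barcode set differs from replicate 1: {extra[:5]}"
                )
        self.tables = tables
        self.config, self.hier = config, hier
        self.K = len(tables)
        self.T = [t.n_timepoints for t in tables]
        self.N, self.M = tables[0].n_neutral, tables[0].n_mutant
        self.B = self.N + self.M
        self.R = [t.counts.astype(float) for t in tables]
        self.tau = [config.tau_vector(T - 1) for T in self.T]
        from scipy.special import gammaln
        self._lgamma_R = [float(np.sum(gammaln(R + 1.0))) for R in self.R]

        c, h = config, hier
        s0_all = []
        for k, t in enumerate(tables):
            f_naive = naive_frequencies(t, pseudocount=1.0)
            sbar0 = naive_mean_fitness(f_naive[:, : self.N], self.tau[k])
            s0 = (log_freq_ratios(f_naive, self.tau[k])[:, self.N:]
                  + sbar0[:, None]).mean(axis=0)
            s0_all.append(s0)
            self._add_block(f"log_rate_{k}", (self.T[k], self.B),
                            f"Normal(log max(r,1), {c.rate_prior_sd})",
                            np.log(np.maximum(self.R[k], 1.0)), c.rate_prior_sd)
            self._add_block(f"mean_fitness_{k}", (self.T[k] - 1,),
                            f"Normal(naive estimate, {c.mean_fitness_prior_sd})",
                            sbar0, c.mean_fitness_prior_sd)
            self._add_block(f"log_sigma_mean_{k}", (self.T[k] - 1,),
                            f"Normal({c.noise_prior_loc}, {c.noise_prior_scale}) [log]",
                            c.noise_prior_loc, c.noise_prior_scale)
        theta0 = np.mean(s0_all, axis=0)
        self._add_block("hyper_fitness", (self.M,),
                        f"Normal({h.hyper_prior_mean}, {h.hyper_prior_sd})",
                        h.hyper_prior_mean, h.hyper_prior_sd, init=theta0)
        self._add_block("log_dev_scale", (1,),
                        f"HalfNormal({h.dev_scale_prior}) [log scale]",
                        0.0, 1.0, init=np.log(0.1),
                        halfnormal_log_scale=h.dev_scale_prior)
        if h.non_centered:
            self._add_block("fitness_z", (self.K, self.M),
                            "Normal(0, 1) [non-centered local]", 0.0, 1.0, init=0.0)
        else:
            self._add_block("fitness", (self.K, self.M),
                            "Normal(theta, tau_theta) [centered local]",
                            0.0, np.inf, init=np.tile(theta0, self.K))
            self._prior_scale_parts["fitness"] = np.full(self.K * self.M, np.inf)
        self._add_block("log_sigma_fitness", (self.K, self.M),
                        f"Normal({c.noise_prior_loc}, {c.noise_prior_scale}) [log]",
                        c.noise_prior_loc, c.noise_prior_scale)
        self._finalize()

    def dims(self):
        return {"K": self.K, "T": self.T, "N": self.N, "M": self.M, "B": self.B}

    def _local_fitness(self, p):
        if self.hier.non_centered:
            tau_t = np.exp(p["log_dev_scale"][0])
            return p["hyper_fitness"][None, :] + tau_t * p["fitness_z"]
        return p["fitness"]

    def _loglik_and_grad(self, z):
        p = self.unpack(z)
        N = self.N
        g = np.zeros(self.n_params)
        lp = 0.0
        s_local = self._local_fitness(p)  # (K, M)
        sig_m = np.exp(p["log_sigma_fitness"])  # (K, M)
        g_s_local = np.zeros((self.K, self.M))
        for k in range(self.K):
            ell = p[f"log_rate_{k}"]
            lpk, g_ell = _poisson_terms(ell, self.R[k], self._lgamma_R[k])
            lp += lpk
            f, gamma = _gamma_stats(ell, self.tau[k])
            sig_t = np.exp(p[f"log_sigma_mean_{k}"])
            Tm1 = self.T[k] - 1
            mu = np.empty((Tm1, self.B))
            sig = np.empty_like(mu)
            mu[:, :N] = -p[f"mean_fitness_{k}"][:, None]
            sig[:, :N] = sig_t[:, None]
            mu[:, N:] = s_local[k][None, :] - p[f"mean_fitness_{k}"][:, None]
            sig[:, N:] = sig_m[k][None, :]
            lg, w2, dls = _gaussian_residual_terms(gamma, mu, sig)
            lp += lg
            g_ell += _gamma_grad_to_ell(-w2, f, self.tau[k])
            g[self._slices[f"log_rate_{k}"]] = g_ell.ravel()
            g[self._slices[f"mean_fitness_{k}"]] = -w2.sum(axis=1)
            g[self._slices[f"log_sigma_mean_{k}"]] = dls[:, :N].sum(axis=1)
            g_s_local[k] = w2[:, N:].sum(axis=0)
            g[self._slices["log_sigma_fitness"]][k * self.M:(k + 1) * self.M] = \
                dls[:, N:].sum(axis=0)

        if self.hier.non_centered:
            tau_t = np.exp(p["log_dev_scale"][0])
            g[self._slices["hyper_fitness"]] = g_s_local.sum(axis=0)
            g[self._slices["fitness_z"]] = (tau_t * g_s_local).ravel()
            g[self._slices["log_dev_scale"]] = tau_t * float(
                np.sum(p["fitness_z"] * g_s_local))
        else:
            tau_t = np.exp(p["log_dev_scale"][0])
            dev = p["fitness"] - p["hyper_fitness"][None, :]
            lp += -0.5 * np.sum((dev / tau_t) ** 2) - dev.size * np.log(tau_t) \
                - 0.5 * dev.size * np.log(2 * np.pi)
            g[self._slices["fitness"]] = (g_s_local - dev / tau_t**2).ravel()
            g[self._slices["hyper_fitness"]] = (dev / tau_t**2).sum(axis=0)
            g[self._slices["log_dev_scale"]] += np.sum((dev / tau_t) ** 2) - dev.size
        return lp, g

    def constrain_draws(self, Z, store_frequencies=True):
        out = {}
        sl = self._slices
        out["hyper_fitness"] = Z[:, sl["hyper_fitness"]]
        out["dev_scale"] = np.exp(Z[:, sl["log_dev_scale"]])
        if self.hier.non_centered:
            zloc = Z[:, sl["fitness_z"]].reshape(-1, self.K, self.M)
            out["fitness"] = out["hyper_fitness"][:, None, :] + \
                out["dev_scale"][:, :, None] * zloc
        else:
            out["fitness"] = Z[:, sl["fitness"]].reshape(-1, self.K, self.M)
        out["sigma_fitness"] = np.exp(
            Z[:, sl["log_sigma_fitness"]]).reshape(-1, self.K, self.M)
        for k in range(self.K):
            out[f"mean_fitness_{k}"] = Z[:, sl[f"mean_fitness_{k}"]]
            out[f"sigma_mean_{k}"] = np.exp(Z[:, sl[f"log_sigma_mean_{k}"]])
            if store_frequencies:
                n = Z.shape[0]
                ell = Z[:, sl[f"log_rate_{k}"]].reshape(n, self.T[k], self.B)
                out[f"frequency_{k}"] = np.exp(
                    ell - logsumexp(ell, axis=2)[:, :, None])
        return out

    def meta(self):
        return {
            "variant": self.variant,
            "mutant_ids": list(self.tables[0].mutant_ids),
            "neutral_ids": list(self.tables[0].neutral_ids),
            "n_replicates": self.K,
            "n_transitions": [T - 1 for T in self.T],
        }

    def scale_couplings(self):
        local = "fitness_z" if self.hier.non_centered else "fitness"
        loc = np.concatenate([self._block_indices(local),
                              self._block_indices("hyper_fitness")])
        dev = self._block_indices("log_dev_scale")
        scale = np.concatenate([self._block_indices("log_sigma_fitness"),
                                np.repeat(dev, self.M)])
        return loc, scale


def build_multienv_model(counts: SplitCounts, schedule: EnvironmentSchedule,
                         config: ModelConfig | None = None) -> MultiEnvModel:
    """Multi-environment model: one fitness parameter per (mutant, environment)."""
    return MultiEnvModel(counts, schedule, config or ModelConfig())


def build_replicate_model(tables: list[SplitCounts], config: ModelConfig | None = None,
                          hier: HierarchyConfig | None = None) -> ReplicateModel:
    """Hierarchical replicate model tying local fitness through hyper-fitness."""
    return ReplicateModel(tables, config or ModelConfig(), hier or HierarchyConfig())


def build_genotype_model(counts: SplitCounts, gmap: GenotypeMap,
                         config: ModelConfig | None = None,
                         hier: HierarchyConfig | None = None) -> GenotypeModel:
    """Genotype hierarchy: per-genotype hyper-fitness over barcode-level data."""
    return GenotypeModel(counts, gmap, config or ModelConfig(), hier or HierarchyConfig())


def pool_genotype_counts(counts: SplitCounts, gmap: GenotypeMap) -> SplitCounts:
    """Comparator: sum reads within each genotype, one pooled lineage per genotype.

    The pooled table can be fed to :func:`~barfit.model.build_single_model`
    to obtain one fitness estimate per genotype.
    """
    gidx = gmap.index_for(counts.mutant_ids)
    G = gmap.n_genotypes
    pooled = np.zeros((counts.n_timepoints, G), dtype=np.int64)
    for j, g in enumerate(gidx):
        pooled[:, g] += counts.r_mutant[:, j]
    return SplitCounts(
        r_neutral=counts.r_neutral,
        r_mutant=pooled,
        neutral_ids=list(counts.neutral_ids),
        mutant_ids=list(gmap.genotypes),
    )
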