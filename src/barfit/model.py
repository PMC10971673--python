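"""Core probabilistic model for relative-fitness inference.

The joint posterior factorizes into three conditional pieces: latent barcode
frequencies given read counts, population mean fitness given the neutral
(reference) lineages, and per-barcode relative fitness given both.  The data
enter through a ``T x B`` count matrix; the model is

* observation: ``r_tb ~ Poisson(lambda_tb)`` with independent normal priors on
  ``log lambda_tb`` centered on the observed counts (floor 1).  Frequencies are
  the normalized rates ``f_tb = lambda_tb / sum_b' lambda_tb'``, which keeps
  every frequency strictly positive even for zero counts;
* neutral lineages: the per-cycle log frequency ratio
  ``(1/tau) ln(f_{t+1}/f_t)`` of each neutral barcode is normal with mean
  ``-sbar_t`` (minus the population mean fitness) and per-transition scale
  ``sigma_t`` shared across neutrals;
* non-neutral lineages: the same log ratio is normal with mean
  ``s_m - sbar_t`` and per-barcode scale ``sigma_m``.

Each population mean fitness ``sbar_t`` is a free parameter (no functional
form linking adjacent transitions).  Neutral lineages have relative fitness
identically zero by construction, which anchors the fitness scale.

All parameters live in an unconstrained vector ``z`` (positive scales are
log-parameterized), and every model exposes the exact gradient of the log
joint, which is what the variational engine consumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

from .io import SplitCounts

__all__ = [
    "ModelConfig",
    "ParamBlock",
    "BaseModel",
    "SingleModel",
    "naive_frequencies",
    "log_freq_ratios",
    "naive_mean_fitness",
    "build_single_model",
    "log_joint",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class ModelConfig:
    """Priors and time scale for all model variants.

    ``tau`` is the elapsed time per growth-dilution cycle (scalar or one value
    per transition); with the default ``tau = 1`` fitness is "per cycle".
    Scale priors are log-normal: ``log sigma ~ Normal(noise_prior_loc,
    noise_prior_scale)``.
    """

    tau: float | np.ndarray = 1.0
    fitness_prior_mean: float = 0.0
    fitness_prior_sd: float = 2.0
    mean_fitness_prior_sd: float = 2.0
    noise_prior_loc: float = -1.0
    noise_prior_scale: float = 1.0
    rate_prior_sd: float = 2.0

    def __post_init__(self) -> None:
        for name in ("fitness_prior_sd", "mean_fitness_prior_sd",
                     "noise_prior_scale", "rate_prior_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        tau = np.atleast_1d(np.asarray(self.tau, dtype=float))
        if np.any(tau <= 0):
            raise ValueError("tau must be positive")

    def tau_vector(self, n_transitions: int) -> np.ndarray:
        tau = np.atleast_1d(np.asarray(self.tau, dtype=float))
        if tau.size == 1:
            return np.full(n_transitions, tau[0])
        if tau.size != n_transitions:
            raise ValueError(
                f"tau has {tau.size} entries but the data has {n_transitions} transitions"
            )
        return tau.astype(float)


# ---------------------------------------------------------------------------
# elementary operations on count/frequency matrices
# ---------------------------------------------------------------------------

def naive_frequencies(counts: SplitCounts, pseudocount: float = 0.0) -> np.ndarray:
    """Plug-in frequency estimate ``f_tb = (r_tb + a) / sum_b (r_tb + a)``.

    With ``pseudocount == 0`` this is the raw read fraction; each row sums
    to 1.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    r = counts.counts.astype(float) + pseudocount
    row = r.sum(axis=1)
    if np.any(row <= 0):
        raise ValueError("a time point has zero total (pseudo)counts")
    return r / row[:, None]


def log_freq_ratios(freqs: np.ndarray, tau: float | np.ndarray = 1.0) -> np.ndarray:
    """Per-cycle log frequency ratios ``(1/tau) ln(f_{t+1,b} / f_{t,b})``."""
    f = np.asarray(freqs, dtype=float)
    if np.any(f <= 0):
        raise ValueError(
            "zero frequency encountered; use the latent-rate model or a pseudocount"
        )
    tau_vec = np.atleast_1d(np.asarray(tau, dtype=float))
    if tau_vec.size == 1:
        tau_vec = np.full(f.shape[0] - 1, tau_vec[0])
    return np.diff(np.log(f), axis=0) / tau_vec[:, None]


def naive_mean_fitness(neutral_freqs: np.ndarray, tau: float | np.ndarray = 1.0) -> np.ndarray:
    """Point estimate of the population mean fitness from neutral lineages.

    ``sbar_t = -(1/tau) mean_n ln(f_{t+1,n} / f_{t,n})``; used for prior
    centering and initialization only.
    """
    f = np.asarray(neutral_freqs, dtype=float)
    if f.shape[1] == 0:
        raise ValueError("no neutral lineages")
    return -log_freq_ratios(f, tau).mean(axis=1)


# ---------------------------------------------------------------------------
# shared likelihood machinery
# ---------------------------------------------------------------------------

def _gamma_stats(ell: np.ndarray, tau: np.ndarray):
    """Frequencies and per-cycle log-ratios implied by latent log rates."""
    lse = logsumexp(ell, axis=1)
    f = np.exp(ell - lse[:, None])
    gamma = (np.diff(ell, axis=0) - np.diff(lse)[:, None]) / tau[:, None]
    return f, gamma


def _gamma_grad_to_ell(g_gamma: np.ndarray, f: np.ndarray, tau: np.ndarray) -> np.ndarray:
    """Chain gradients w.r.t. log-ratios back to the log rates.

    Uses d gamma_tb / d ell_{t+1,b'} = (delta_bb' - f_{t+1,b'}) / tau_t and
    the mirror-image term at t.
    """
    tot = g_gamma.sum(axis=1)
    g_ell = np.zeros_like(f)
    adj_hi = (g_gamma - f[1:] * tot[:, None]) / tau[:, None]
    adj_lo = (g_gamma - f[:-1] * tot[:, None]) / tau[:, None]
    g_ell[1:] += adj_hi
    g_ell[:-1] -= adj_lo
    return g_ell


@dataclass
class ParamBlock:
    """One named parameter block of the unconstrained vector."""

    name: str
    shape: tuple
    prior: str  # human-readable description, for provenance only

    @property
    def size(self) -> int:
        return int(np.prod(self.shape)) if self.shape else 1


class BaseModel:
    """Shared packing / prior machinery for all model variants.

    Subclasses declare parameter blocks via :meth:`_add_block` and implement
    ``_loglik_and_grad``.  Normal priors are stored as per-element location and
    scale vectors; the deviation-scale block of hierarchical variants carries a
    half-normal prior handled separately.
    """

    variant = "base"

    def __init__(self) -> None:
        self.blocks: list[ParamBlock] = []
        self._slices: dict[str, slice] = {}
        self._shapes: dict[str, tuple] = {}
        self._prior_loc_parts: dict[str, np.ndarray] = {}
        self._prior_scale_parts: dict[str, np.ndarray] = {}
        self._halfnormal_log_blocks: dict[str, float] = {}
        self._init_parts: dict[str, np.ndarray] = {}
        self.prior_only = False

    # -- construction ----------------------------------------------------------
    def _add_block(self, name, shape, prior_desc, prior_loc, prior_scale,
                   init=None, halfnormal_log_scale=None):
        shape = tuple(int(s) for s in np.atleast_1d(shape))
        start = self.n_params
        blk = ParamBlock(name, shape, prior_desc)
        self.blocks.append(blk)
        self._slices[name] = slice(start, start + blk.size)
        self._shapes[name] = shape
        def _expand(value):
            arr = np.asarray(value, dtype=float).ravel()
            if arr.size == 1:
                return np.full(blk.size, arr[0])
            if arr.size != blk.size:
                raise ValueError(
                    f"block {name!r}: got {arr.size} values for size {blk.size}")
            return arr.copy()

        if halfnormal_log_scale is not None:
            self._halfnormal_log_blocks[name] = float(halfnormal_log_scale)
            self._prior_loc_parts[name] = np.zeros(blk.size)
            self._prior_scale_parts[name] = np.full(blk.size, np.inf)  # masked
        else:
            self._prior_loc_parts[name] = _expand(prior_loc)
            self._prior_scale_parts[name] = _expand(prior_scale)
        self._init_parts[name] = _expand(
            self._prior_loc_parts[name] if init is None else init)

    def _finalize(self) -> None:
        self._prior_loc = np.concatenate(
            [self._prior_loc_parts[b.name] for b in self.blocks]
        )
        self._prior_scale = np.concatenate(
            [self._prior_scale_parts[b.name] for b in self.blocks]
        )
        self._normal_mask = np.isfinite(self._prior_scale)
        self._init = np.concatenate([self._init_parts[b.name] for b in self.blocks])

    # -- packing ---------------------------------------------------------------
    @property
    def n_params(self) -> int:
        return sum(b.size for b in self.blocks)

    def unpack(self, z: np.ndarray) -> dict:
        return {
            name: z[sl].reshape(self._shapes[name])
            for name, sl in self._slices.items()
        }

    def pack(self, params: dict) -> np.ndarray:
        z = np.empty(self.n_params)
        for name, sl in self._slices.items():
            arr = np.asarray(params[name], dtype=float)
            if arr.shape != self._shapes[name] and arr.size != np.prod(self._shapes[name]):
                raise ValueError(
                    f"block {name!r}: expected shape {self._shapes[name]}, got {arr.shape}"
                )
            z[sl] = arr.ravel()
        return z

    def init_loc(self) -> np.ndarray:
        return self._init.copy()

    # -- densities -------------------------------------------------------------
    def _prior_logp_and_grad(self, z: np.ndarray):
        m = self._normal_mask
        resid = (z[m] - self._prior_loc[m]) / self._prior_scale[m]
        lp = -0.5 * np.sum(resid**2) - np.sum(np.log(self._prior_scale[m])) \
            - 0.5 * _LOG2PI * resid.size
        g = np.zeros_like(z)
        g[m] = -resid / self._prior_scale[m]
        for name, s in self._halfnormal_log_blocks.items():
            sl = self._slices[name]
            w = z[sl]
            # tau = e^w ~ HalfNormal(s), density over w includes the Jacobian e^w
            lp += np.sum(
                0.5 * np.log(2.0 / np.pi) - np.log(s) - np.exp(2 * w) / (2 * s**2) + w
            )
            g[sl] = -np.exp(2 * w) / s**2 + 1.0
        return lp, g

    def logp_and_grad(self, z: np.ndarray):
        """Unconstrained log joint density and its exact gradient."""
        z = np.asarray(z, dtype=float)
        if z.shape != (self.n_params,):
            raise ValueError(f"expected parameter vector of length {self.n_params}")
        lp, g = self._prior_logp_and_grad(z)
        if not self.prior_only:
            ll, gl = self._loglik_and_grad(z)
            lp += ll
            g += gl
        return lp, g

    def logp(self, z: np.ndarray) -> float:
        return self.logp_and_grad(z)[0]

    def _loglik_and_grad(self, z: np.ndarray):  # pragma: no cover - abstract
        raise NotImplementedError

    def scale_couplings(self):
        """Pairs of (location index, scale index) for the variational family.

        The fitness of a barcode and its log noise scale form a
        normal/log-normal scale mixture with only ``T - 1`` observations, so a
        fully factorized Gaussian approximation badly underestimates the
        fitness marginal sd.  Coupling the conditional sd of each location
        parameter to its scale parameter (``sd(s | u) ∝ exp(kappa (u - E u))``)
        restores the mixture shape at no entropy cost.  Returns two equal
        length integer arrays of global parameter indices; scale indices may
        repeat (shared scales).
        """
        return np.array([], dtype=int), np.array([], dtype=int)

    def _block_indices(self, name: str) -> np.ndarray:
        sl = self._slices[name]
        return np.arange(sl.start, sl.stop)

    # -- provenance ------------------------------------------------------------
    def dims(self) -> dict:
        raise NotImplementedError

    def to_json(self) -> str:
        """JSON description of parameter blocks, shapes and priors."""
        return json.dumps(
            {
                "variant": self.variant,
                "dims": self.dims(),
                "n_params": self.n_params,
                "blocks": [
                    {"name": b.name, "shape": list(b.shape), "prior": b.prior}
                    for b in self.blocks
                ],
            },
            indent=1,
        )

    # -- constrained-space views ------------------------------------------------
    def constrain_draws(self, Z: np.ndarray, store_frequencies: bool = True) -> dict:
        """Map unconstrained draws ``(n, n_params)`` to named constrained draws."""
        raise NotImplementedError


def _poisson_terms(ell, R, lgamma_const):
    lam = np.exp(ell)
    lp = float(np.sum(R * ell - lam)) - lgamma_const
    return lp, R - lam


def _gaussian_residual_terms(gamma, mu, sig):
    """Log density of gamma ~ N(mu, sig) plus the derivative building blocks."""
    eps = gamma - mu
    w2 = eps / sig**2
    lp = -0.5 * _LOG2PI * eps.size - float(np.sum(np.log(sig))) - 0.5 * float(np.sum(eps * w2))
    dl_dlogsig = (eps / sig) ** 2 - 1.0
    return lp, w2, dl_dlogsig


class SingleModel(BaseModel):
    """Single-environment, single-replicate fitness model."""

    variant = "single"

    def __init__(self, counts: SplitCounts, config: ModelConfig):
        super().__init__()
        T, N, M = counts.n_timepoints, counts.n_neutral, counts.n_mutant
        if T < 2:
            raise ValueError("at least two time points are required")
        self.counts = counts
        self.config = config
        self.T, self.N, self.M, self.B = T, N, M, N + M
        self.R = counts.counts.astype(float)
        self.tau = config.tau_vector(T - 1)
        self._lgamma_R = float(np.sum(gammaln(self.R + 1.0)))

        ell0 = np.log(np.maximum(self.R, 1.0))
        f_naive = naive_frequencies(counts, pseudocount=1.0)
        sbar0 = naive_mean_fitness(f_naive[:, :N], self.tau)
        gamma_naive = log_freq_ratios(f_naive, self.tau)
        s0 = (gamma_naive[:, N:] + sbar0[:, None]).mean(axis=0)

        c = config
        self._add_block("log_rate", (T, self.B),
                        f"Normal(log max(r,1), {c.rate_prior_sd})",
                        ell0, c.rate_prior_sd)
        self._add_block("mean_fitness", (T - 1,),
                        f"Normal(naive estimate, {c.mean_fitness_prior_sd})",
                        sbar0, c.mean_fitness_prior_sd)
        self._add_block("log_sigma_mean", (T - 1,),
                        f"Normal({c.noise_prior_loc}, {c.noise_prior_scale}) [log scale]",
                        c.noise_prior_loc, c.noise_prior_scale)
        self._add_block("fitness", (M,),
                        f"Normal({c.fitness_prior_mean}, {c.fitness_prior_sd})",
                        c.fitness_prior_mean, c.fitness_prior_sd, init=s0)
        self._add_block("log_sigma_fitness", (M,),
                        f"Normal({c.noise_prior_loc}, {c.noise_prior_scale}) [log scale]",
                        c.noise_prior_loc, c.noise_prior_scale)
        self._finalize()

    def dims(self) -> dict:
        return {"T": self.T, "N": self.N, "M": self.M, "B": self.B}

    # mean and scale of the mutant log-ratio likelihood, given unpacked params
    def _mutant_moments(self, p):
        mu = p["fitness"][None, :] - p["mean_fitness"][:, None]
        sig = np.broadcast_to(np.exp(p["log_sigma_fitness"])[None, :],
                              (self.T - 1, self.M))
        return mu, sig

    def _loglik_and_grad(self, z):
        p = self.unpack(z)
        ell = p["log_rate"]
        N = self.N
        lp, g_ell = _poisson_terms(ell, self.R, self._lgamma_R)
        f, gamma = _gamma_stats(ell, self.tau)

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
        g[self._slices["fitness"]] = w2[:, N:].sum(axis=0)
        g[self._slices["log_sigma_fitness"]] = dls[:, N:].sum(axis=0)
        return lp, g

    def constrain_draws(self, Z, store_frequencies=True):
        n = Z.shape[0]
        out = {}
        sl = self._slices
        out["mean_fitness"] = Z[:, sl["mean_fitness"]]
        out["sigma_mean"] = np.exp(Z[:, sl["log_sigma_mean"]])
        out["fitness"] = Z[:, sl["fitness"]]
        out["sigma_fitness"] = np.exp(Z[:, sl["log_sigma_fitness"]])
        if store_frequencies:
            ell = Z[:, sl["log_rate"]].reshape(n, self.T, self.B)
            lse = logsumexp(ell, axis=2)
            out["frequency"] = np.exp(ell - lse[:, :, None])
        return out

    def meta(self) -> dict:
        return {
            "variant": self.variant,
            "mutant_ids": list(self.counts.mutant_ids),
            "neutral_ids": list(self.counts.neutral_ids),
            "n_transitions": self.T - 1,
        }

    def scale_couplings(self):
        return (self._block_indices("fitness"),
                self._block_indices("log_sigma_fitness"))

    # -- constrained-space log joint --------------------------------------------
    _LOG_SCALE_BLOCKS = ("log_sigma_mean", "log_sigma_fitness")

    def state_to_z(self, state: dict) -> np.ndarray:
        params = dict(state)
        for name in self._LOG_SCALE_BLOCKS:
            key = name.replace("log_", "")
            if key in params and name not in params:
                sd = np.asarray(params.pop(key), dtype=float)
                if np.any(sd <= 0):
                    raise FloatingPointError("non-positive noise sd is out of support")
                params[name] = np.log(sd)
        return self.pack(params)

    def log_jacobian(self, z: np.ndarray) -> float:
        """log |dz/d(constrained)| summed over log-scale blocks."""
        return float(sum(np.sum(z[self._slices[n]]) for n in self._LOG_SCALE_BLOCKS
                         if n in self._slices))


def build_single_model(counts: SplitCounts, config: ModelConfig | None = None,
                       prior_only: bool = False) -> SingleModel:
    """Build the single-dataset model (three-factor posterior) from counts."""
    model = SingleModel(counts, config or ModelConfig())
    model.prior_only = prior_only
    return model


def log_joint(model: BaseModel, state: dict) -> float:
    """Unnormalized log posterior density at a constrained parameter point.

    ``state`` maps block names to arrays; positive scales may be given either
    as ``sigma_*`` (constrained) or ``log_sigma_*``.  Returns ``-inf`` for
    non-positive noise scales.  The density is with respect to the constrained
    parameterization (scales measured in sigma, not log sigma).
    """
    try:
        z = model.state_to_z(state)
    except FloatingPointError:
        return -np.inf
    lp, _ = model.logp_and_grad(z)
    return lp - model.log_jacobian(z)
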