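"""Posterior fitting: mean-field variational inference and ensemble MCMC.

The primary engine is ADVI-style stochastic variational inference: a diagonal
(mean-field) Gaussian in the unconstrained parameter space, optimized by
stochastic gradient ascent on the evidence lower bound (ELBO) with
reparameterization gradients and an Adam optimizer with exponential
learning-rate decay.  Because every model exposes an exact analytic gradient
of its log joint, a single Monte-Carlo sample per step suffices for stable
optimization at the default settings.

For validation on small instances, :func:`fit_mcmc` samples the same log joint
with the affine-invariant ensemble sampler (emcee) and attaches split-R-hat
and effective-sample-size diagnostics.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import BarcodeCountTable, FitnessResult
from .model import BaseModel

__all__ = [
    "ADVIOptions",
    "PosteriorSamples",
    "DivergenceError",
    "fit_advi",
    "fit_mcmc",
    "summarize",
]


class DivergenceError(RuntimeError):
    """The ELBO became persistently non-finite during optimization."""


@dataclass
class ADVIOptions:
    """Knobs for the stochastic variational optimizer."""

    n_steps: int = 30_000
    n_mc_samples: int = 1
    learning_rate: float = 0.01
    lr_decay: float = 0.1  # final learning rate = learning_rate * lr_decay
    n_posterior_draws: int = 3_000
    seed: int = 0
    full_rank: bool = False  # diagonal by default; full-rank not implemented
    scale_coupled: bool = True  # couple location sds to their scale parameters
    init_log_sd: float = np.log(0.1)
    clip_grad_norm: float = 1e6
    store_frequencies: bool = True

    def __post_init__(self) -> None:
        if self.n_steps < 1 or self.n_mc_samples < 1 or self.n_posterior_draws < 1:
            raise ValueError("step/sample counts must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.full_rank:
            raise NotImplementedError(
                "full-rank variational family is not implemented; use mean-field"
            )


@dataclass
class PosteriorSamples:
    """Named posterior draws plus fit provenance.

    ``draws`` maps parameter names to arrays whose first axis indexes draws.
    ``elbo_trace`` is per-step (ADVI only).  ``provenance`` records the model
    description hash, options, seed, and sampler diagnostics.
    """

    draws: dict
    provenance: dict
    elbo_trace: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ns = {v.shape[0] for v in self.draws.values()}
        if len(ns) > 1:
            raise ValueError("all parameters must have the same number of draws")

    @property
    def n_draws(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    def drop_nuisance(self) -> "PosteriorSamples":
        """Discard latent-frequency draws; fitness marginals are untouched.

        Marginalizing nuisance parameters out of a sampled joint posterior is
        just dropping their columns.
        """
        keep = {k: v for k, v in self.draws.items()
                if not k.startswith("frequency")}
        return PosteriorSamples(draws=keep, provenance=dict(self.provenance),
                                elbo_trace=self.elbo_trace, meta=dict(self.meta))

    def to_csv(self, path, exclude_prefixes=("frequency",)) -> None:
        """Columnar CSV of scalar parameter draws (frequencies excluded)."""
        cols = {}
        for name, arr in self.draws.items():
            if any(name.startswith(p) for p in exclude_prefixes):
                continue
            flat = arr.reshape(arr.shape[0], -1)
            for j in range(flat.shape[1]):
                cols[f"{name}[{j}]"] = flat[:, j]
        pd.DataFrame(cols).to_csv(path, index=False)


def _model_hash(model: BaseModel) -> str:
    return hashlib.sha256(model.to_json().encode()).hexdigest()[:16]


def fit_advi(model: BaseModel, opts: ADVIOptions | None = None) -> PosteriorSamples:
    """Fit a model by stochastic variational inference.

    The variational family is a diagonal Gaussian in the unconstrained space,
    optionally augmented (default) with scale couplings declared by the model:
    for coupled pairs ``(s, u)`` the conditional sd of ``s`` is
    ``exp(omega_s + kappa (u - mu_u))``, so the marginal of ``s`` is a
    log-normal scale mixture of normals — the correct shape for a fitness
    parameter whose noise scale is itself uncertain.  The entropy of this
    family equals the mean-field entropy, so the ELBO expression is unchanged.

    Deterministic for a fixed ``(model, options, seed)`` triple.  Raises
    :class:`DivergenceError` after more than 100 consecutive non-finite ELBO
    evaluations (typically cured by a smaller learning rate).
    """
    opts = opts or ADVIOptions()
    rng = np.random.default_rng(opts.seed)
    n = model.n_params
    mu = model.init_loc()
    omega = np.full(n, opts.init_log_sd)
    if opts.scale_coupled:
        loc_idx, scale_idx = model.scale_couplings()
    else:
        loc_idx = scale_idx = np.array([], dtype=int)
    nc = loc_idx.size
    kappa = np.ones(nc)

    # Adam state for the concatenated (mu, omega, kappa) vector
    m = np.zeros(2 * n + nc)
    v = np.zeros(2 * n + nc)
    b1, b2, adam_eps = 0.9, 0.999, 1e-8
    elbo_trace = np.empty(opts.n_steps)
    n_bad = 0
    decay = opts.lr_decay ** (1.0 / max(opts.n_steps - 1, 1))
    lr = opts.learning_rate

    def _sample(eps):
        """Draw z and the coupled conditional log-sds for one eps vector."""
        du = np.exp(omega) * eps  # z - mu for uncoupled entries
        z = mu + du
        if nc:
            clog = omega[loc_idx] + kappa * du[scale_idx]
            z[loc_idx] = mu[loc_idx] + np.exp(clog) * eps[loc_idx]
        return z

    for step in range(opts.n_steps):
        g_mu = np.zeros(n)
        g_om = np.zeros(n)
        g_ka = np.zeros(nc)
        elbo = 0.0
        ok = True
        for _ in range(opts.n_mc_samples):
            eps = rng.standard_normal(n)
            zt = _sample(eps)
            lp, g = model.logp_and_grad(zt)
            if not (np.isfinite(lp) and np.all(np.isfinite(g))):
                ok = False
                break
            dz = zt - mu
            g_mu += g
            g_om += g * dz
            if nc:
                # d z_loc / d omega_scale and / d kappa go through the
                # conditional sd exp(omega_loc + kappa * du_scale)
                extra = g[loc_idx] * dz[loc_idx] * kappa * dz[scale_idx]
                np.add.at(g_om, scale_idx, extra)
                g_ka += g[loc_idx] * dz[loc_idx] * dz[scale_idx]
            elbo += lp
        if ok:
            g_mu /= opts.n_mc_samples
            g_om /= opts.n_mc_samples
            g_ka /= opts.n_mc_samples
            g_om += 1.0  # entropy gradient (identical for the coupled family)
            elbo = elbo / opts.n_mc_samples + np.sum(omega) \
                + 0.5 * n * (1.0 + np.log(2.0 * np.pi))
            n_bad = 0
        else:
            elbo = np.nan
            n_bad += 1
            if n_bad > 100:
                raise DivergenceError(
                    "ELBO non-finite for >100 consecutive steps; "
                    "try a smaller learning_rate"
                )
        elbo_trace[step] = elbo

        if ok:
            grad = np.concatenate([g_mu, g_om, g_ka])
            norm = np.linalg.norm(grad)
            if norm > opts.clip_grad_norm:
                grad *= opts.clip_grad_norm / norm
            m = b1 * m + (1 - b1) * grad
            v = b2 * v + (1 - b2) * grad**2
            mhat = m / (1 - b1 ** (step + 1))
            vhat = v / (1 - b2 ** (step + 1))
            update = lr * mhat / (np.sqrt(vhat) + adam_eps)
            mu = mu + update[:n]
            omega = omega + update[n:2 * n]
            kappa = kappa + update[2 * n:]
        lr *= decay

    Eps = rng.standard_normal((opts.n_posterior_draws, n))
    Du = np.exp(omega)[None, :] * Eps
    Z = mu[None, :] + Du
    if nc:
        clog = omega[loc_idx][None, :] + kappa[None, :] * Du[:, scale_idx]
        Z[:, loc_idx] = mu[loc_idx][None, :] + np.exp(clog) * Eps[:, loc_idx]
    draws = model.constrain_draws(Z, store_frequencies=opts.store_frequencies)
    prov = {
        "method": "advi-scale-coupled" if nc else "advi-meanfield",
        "model": _model_hash(model),
        "model_json": model.to_json(),
        "seed": opts.seed,
        "n_steps": opts.n_steps,
        "learning_rate": opts.learning_rate,
        "n_posterior_draws": opts.n_posterior_draws,
        "final_elbo": float(np.nanmean(elbo_trace[-100:])),
    }
    samples = PosteriorSamples(draws=draws, provenance=prov, elbo_trace=elbo_trace,
                               meta=model.meta())
    samples._variational = (mu, omega, kappa)  # kept for tests / diagnostics
    return samples


def fit_mcmc(model: BaseModel, n_warmup: int = 1_000, n_samples: int = 2_000,
             seed: int = 0, n_walkers: int | None = None,
             init_scatter: float = 0.01, thin: int = 1,
             p0: np.ndarray | None = None,
             store_frequencies: bool = True) -> PosteriorSamples:
    """Sample the log joint with affine-invariant ensemble MCMC (emcee).

    Intended as a validation oracle on small instances (B up to ~50).
    Split-R-hat and bulk effective sample size are computed across walkers
    with arviz; R-hat > 1.05 on any fitness parameter adds a warning to the
    provenance (not fatal).
    """
    import emcee

    n = model.n_params
    nw = n_walkers or max(2 * n + 2, 48)
    rng = np.random.default_rng(seed)
    if p0 is None:
        p0 = model.init_loc()[None, :] + init_scatter * rng.standard_normal((nw, n))
    elif p0.shape != (nw, n):
        raise ValueError(f"p0 must have shape ({nw}, {n})")

    def _logp(z):
        lp, _ = model.logp_and_grad(z)
        return lp if np.isfinite(lp) else -np.inf

    # differential-evolution moves traverse correlated posteriors far better
    # than the stretch move alone; a stretch component re-expands an
    # under-dispersed ensemble, which DE proposals cannot do quickly
    moves = [(emcee.moves.DEMove(), 0.6), (emcee.moves.DESnookerMove(), 0.2),
             (emcee.moves.StretchMove(), 0.2)]
    sampler = emcee.EnsembleSampler(nw, n, _logp, moves=moves)
    # emcee consumes a legacy RandomState *state tuple*; an object is ignored
    start = emcee.State(p0, random_state=np.random.RandomState(seed).get_state())
    state = sampler.run_mcmc(start, n_warmup, progress=False)
    sampler.reset()
    n_keep_steps = int(np.ceil(n_samples * max(thin, 1) / nw))
    sampler.run_mcmc(state, max(n_keep_steps, 50), progress=False)

    chain = sampler.get_chain()  # (steps, walkers, n)
    warnings = []
    diagnostics = {}
    try:
        import arviz as az

        posterior = np.swapaxes(chain, 0, 1)  # (chains, draws, n)
        for name in ("fitness", "hyper_fitness"):
            if name in model._slices:
                sl = model._slices[name]
                block = posterior[:, :, sl]
                ds = az.convert_to_dataset(block)
                rhat = np.asarray(az.rhat(ds)["x"]).ravel()
                ess = np.asarray(az.ess(ds)["x"]).ravel()
                diagnostics[f"rhat_{name}"] = float(np.nanmax(rhat))
                diagnostics[f"ess_{name}"] = float(np.nanmin(ess))
                if np.nanmax(rhat) > 1.05:
                    warnings.append(
                        f"R-hat {np.nanmax(rhat):.3f} > 1.05 on {name}; "
                        "chains may not have converged"
                    )
    except Exception as exc:  # diagnostics must never kill a finished run
        warnings.append(f"convergence diagnostics unavailable: {exc}")

    flat = chain.reshape(-1, n)
    idx = rng.permutation(flat.shape[0])[:n_samples]
    Z = flat[np.sort(idx)]
    draws = model.constrain_draws(Z, store_frequencies=store_frequencies)
    prov = {
        "method": "emcee-ensemble",
        "model": _model_hash(model),
        "model_json": model.to_json(),
        "seed": seed,
        "n_warmup": n_warmup,
        "n_samples": n_samples,
        "n_walkers": nw,
        "acceptance_fraction": float(np.mean(sampler.acceptance_fraction)),
        "diagnostics": diagnostics,
        "warnings": warnings,
    }
    return PosteriorSamples(draws=draws, provenance=prov, meta=model.meta())


_QLEVELS = np.array([2.5, 16.0, 50.0, 84.0, 97.5])
_QCOLS = ["q2.5", "q16", "q50", "q84", "q97.5"]


def _summary_rows(arr: np.ndarray, parameter: str, ids: dict) -> list[dict]:
    """Summaries for one draw array; ``ids`` gives per-column identity values."""
    flat = arr.reshape(arr.shape[0], -1)
    mean = flat.mean(axis=0)
    sd = flat.std(axis=0, ddof=1) if flat.shape[0] > 1 else np.zeros(flat.shape[1])
    qs = np.percentile(flat, _QLEVELS, axis=0)
    rows = []
    for j in range(flat.shape[1]):
        row = {"parameter": parameter, "index": j, "mean": mean[j], "sd": sd[j]}
        for key, values in ids.items():
            row[key] = values[j]
        for qc, qv in zip(_QCOLS, qs[:, j]):
            row[qc] = qv
        rows.append(row)
    return rows


def summarize(samples: PosteriorSamples,
              table: BarcodeCountTable | None = None) -> FitnessResult:
    """Posterior mean, sd and central quantiles for every fitness dimension.

    The 68% credible region is the ``[q16, q84]`` interval.  If ``table`` is
    given, fitness rows follow the barcode order of the table (first
    appearance); otherwise the model's sorted order is used.
    """
    if not samples.draws:
        raise ValueError("no draws to summarize")
    meta = samples.meta
    variant = meta.get("variant", "single")
    mutant_ids = meta.get("mutant_ids")
    rows: list[dict] = []

    def _barcode_order():
        if table is None or mutant_ids is None:
            return None
        order = [b for b in dict.fromkeys(table.data["barcode"]) if b in set(mutant_ids)]
        return order if sorted(order) == sorted(mutant_ids) else None

    if variant == "multienv":
        envs = meta["environments"]
        arr = samples.draws["fitness"]  # (n, E, M)
        for e, env in enumerate(envs):
            rows += _summary_rows(arr[:, e, :], "fitness",
                                  {"barcode": mutant_ids,
                                   "environment": [env] * len(mutant_ids)})
        sig = samples.draws["sigma_fitness"]
        if sig.ndim == 3:  # per-(mutant, environment) noise scales
            for e, env in enumerate(envs):
                rows += _summary_rows(sig[:, e, :], "sigma_fitness",
                                      {"barcode": mutant_ids,
                                       "environment": [env] * len(mutant_ids)})
        else:
            rows += _summary_rows(sig, "sigma_fitness", {"barcode": mutant_ids})
        rows += _summary_rows(samples.draws["mean_fitness"], "mean_fitness", {})
        rows += _summary_rows(samples.draws["sigma_mean"], "sigma_mean", {})
    elif variant == "replicates":
        K = meta["n_replicates"]
        rows += _summary_rows(samples.draws["hyper_fitness"], "hyper_fitness",
                              {"barcode": mutant_ids})
        rows += _summary_rows(samples.draws["dev_scale"], "dev_scale", {})
        arr = samples.draws["fitness"]  # (n, K, M)
        for k in range(K):
            rows += _summary_rows(arr[:, k, :], "fitness",
                                  {"barcode": mutant_ids,
                                   "replicate": [k + 1] * len(mutant_ids)})
        for k in range(K):
            mf = samples.draws[f"mean_fitness_{k}"]
            rr = _summary_rows(mf, "mean_fitness", {})
            for r in rr:
                r["replicate"] = k + 1
            rows += rr
    elif variant == "genotypes":
        genotypes = meta["genotypes"]
        rows += _summary_rows(samples.draws["hyper_fitness"], "hyper_fitness",
                              {"genotype": genotypes})
        rows += _summary_rows(samples.draws["dev_scale"], "dev_scale", {})
        gidx = meta["genotype_index"]
        rows += _summary_rows(samples.draws["fitness"], "fitness",
                              {"barcode": mutant_ids,
                               "genotype": [genotypes[i] for i in gidx]})
        rows += _summary_rows(samples.draws["mean_fitness"], "mean_fitness", {})
        rows += _summary_rows(samples.draws["sigma_mean"], "sigma_mean", {})
    else:  # single
        rows += _summary_rows(samples.draws["fitness"], "fitness",
                              {"barcode": mutant_ids})
        rows += _summary_rows(samples.draws["sigma_fitness"], "sigma_fitness",
                              {"barcode": mutant_ids})
        rows += _summary_rows(samples.draws["mean_fitness"], "mean_fitness", {})
        rows += _summary_rows(samples.draws["sigma_mean"], "sigma_mean", {})

    df = pd.DataFrame(rows)
    order = _barcode_order()
    if order is not None:
        pos = {b: i for i, b in enumerate(order)}
        is_bc = df["barcode"].notna() if "barcode" in df else pd.Series(False, index=df.index)
        df["_ord"] = np.where(is_bc, df.get("barcode").map(pos), -1)
        df = df.sort_values(["parameter", "_ord", "index"], kind="mergesort") \
            .drop(columns="_ord").reset_index(drop=True)
    return FitnessResult(df)
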