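"""Posterior predictive checks, z-score calibration, and model comparison.

Validation surfaces for simulation studies: credible bands for the observed
per-cycle log frequency ratios (the likelihood's observation scale), the ECDF
of absolute z-scores of ground truth within the posterior (the
"fraction within one posterior sd" headline), and ECDF-based comparison of
competing models on the same truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .infer import PosteriorSamples
from .io import FitnessResult
from .model import BaseModel, naive_frequencies, log_freq_ratios

__all__ = [
    "PPCBands",
    "CalibrationReport",
    "posterior_predictive_bands",
    "zscore_ecdf",
    "compare_models",
    "plot_ppc_bands",
    "plot_error_ecdf",
]


@dataclass
class PPCBands:
    """Central credible bands for replicated log frequency ratios.

    ``bands[level]`` is a ``(2, T-1, B)`` array of lower/upper quantiles of
    the replicated data; ``observed`` holds the observed log ratios.  Bands
    at smaller levels nest inside larger ones by construction.
    """

    levels: tuple
    bands: dict
    observed: np.ndarray
    barcode_ids: list

    def coverage(self, level: float) -> float:
        """Fraction of observed (barcode, transition) points inside the band."""
        lo, hi = self.bands[level]
        inside = (self.observed >= lo) & (self.observed <= hi)
        return float(inside.mean())


def _replicated_logratio_draws(samples: PosteriorSamples, model: BaseModel,
                               rng: np.random.Generator) -> np.ndarray:
    """Draws of replicated log-ratio datasets from the fitted likelihood."""
    d = samples.draws
    n = samples.n_draws
    N = model.N
    Tm1 = model.T - 1
    mu = np.empty((n, Tm1, model.B))
    sig = np.empty_like(mu)
    mu[:, :, :N] = -d["mean_fitness"][:, :, None]
    sig[:, :, :N] = d["sigma_mean"][:, :, None]
    if model.variant == "multienv":
        idx = model.schedule.env_index
        mu[:, :, N:] = d["fitness"][:, idx, :] - d["mean_fitness"][:, :, None]
        sig[:, :, N:] = d["sigma_fitness"][:, idx, :]
    else:
        mu[:, :, N:] = d["fitness"][:, None, :] - d["mean_fitness"][:, :, None]
        sig[:, :, N:] = d["sigma_fitness"][:, None, :]
    return rng.normal(mu, sig)


def posterior_predictive_bands(samples: PosteriorSamples, model: BaseModel,
                               levels=(0.95, 0.68, 0.05), seed: int = 0,
                               pseudocount: float | None = None) -> PPCBands:
    """Central credible bands of replicated log-ratio data at each level.

    For every posterior draw a replicated dataset of per-cycle log frequency
    ratios is generated from the Gaussian likelihood; the band at level ``p``
    spans the central ``p`` mass of the replicates at each (transition,
    barcode).  The observed log ratios use raw count frequencies (a 0.5
    pseudocount is applied automatically if zero counts are present).
    """
    for lev in levels:
        if not (0.0 < lev < 1.0):
            raise ValueError("levels must lie in (0, 1)")
    if samples.n_draws == 0:
        raise ValueError("no posterior draws")
    rng = np.random.default_rng(seed)
    rep = _replicated_logratio_draws(samples, model, rng)

    bands = {}
    for lev in levels:
        lo = np.quantile(rep, 0.5 - lev / 2.0, axis=0)
        hi = np.quantile(rep, 0.5 + lev / 2.0, axis=0)
        bands[lev] = np.stack([lo, hi])

    counts = model.counts
    if pseudocount is None:
        pseudocount = 0.0 if counts.counts.min() > 0 else 0.5
    freqs = naive_frequencies(counts, pseudocount=pseudocount)
    observed = log_freq_ratios(freqs, model.tau)
    return PPCBands(levels=tuple(levels), bands=bands, observed=observed,
                    barcode_ids=list(counts.barcode_ids))


@dataclass
class CalibrationReport:
    """Per-dimension recovery metrics against known ground truth.

    ``data`` has one row per fitness dimension with columns ``z`` (absolute
    z-score ``|truth - posterior mean| / posterior sd``) and ``abs_err``
    (``|posterior mean - truth|``).
    """

    data: pd.DataFrame
    infinite_z: int = 0

    def ecdf_z(self, x) -> np.ndarray:
        """ECDF of |z| evaluated at x (non-decreasing, in [0, 1])."""
        z = np.sort(self.data["z"].to_numpy())
        return np.searchsorted(z, np.atleast_1d(x), side="right") / len(z)

    def ecdf_abs_err(self, x) -> np.ndarray:
        e = np.sort(self.data["abs_err"].to_numpy())
        return np.searchsorted(e, np.atleast_1d(x), side="right") / len(e)

    @property
    def fraction_within_one_sd(self) -> float:
        """Headline statistic: ECDF of |z| at 1."""
        return float(self.ecdf_z(1.0)[0])

    @property
    def mean_abs_error(self) -> float:
        return float(self.data["abs_err"].mean())


def zscore_ecdf(result: FitnessResult, truth: pd.Series,
                parameter: str = "fitness", **selectors) -> CalibrationReport:
    """Absolute z-scores of ground truth within the posterior, as an ECDF.

    ``truth`` is indexed by barcode id (or genotype id for
    ``parameter='hyper_fitness'`` of the genotype model).  ``selectors``
    filter result rows (e.g. ``environment=2`` or ``replicate=1``).
    """
    df = result.data[result.data["parameter"] == parameter]
    for key, val in selectors.items():
        df = df[df[key] == val]
    if df.empty:
        raise ValueError(f"no rows for parameter {parameter!r} with {selectors}")
    key = "barcode"
    if parameter == "hyper_fitness" and "genotype" in df.columns \
            and df["barcode"].isna().all():
        key = "genotype"
    missing = set(df[key]) - set(truth.index)
    if missing:
        raise ValueError(f"truth does not cover {sorted(missing)[:5]}")
    tvals = df[key].map(truth).to_numpy(dtype=float)
    mean = df["mean"].to_numpy(dtype=float)
    sd = df["sd"].to_numpy(dtype=float)
    abs_err = np.abs(mean - tvals)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, abs_err / sd, np.where(abs_err == 0, 0.0, np.inf))
    n_inf = int(np.sum(np.isinf(z)))
    out = pd.DataFrame({key: df[key].to_numpy(), "z": z, "abs_err": abs_err,
                        "mean": mean, "sd": sd, "truth": tvals})
    return CalibrationReport(data=out, infinite_z=n_inf)


def compare_models(reports: dict) -> pd.DataFrame:
    """Rank models by mean absolute error; check ECDF dominance.

    All reports must cover the same dimensions (same truth).  Returns a table
    with one row per model: ``mae``, ``median_abs_err``,
    ``fraction_within_one_sd``, ``mean_posterior_sd``, and ``dominates_all``
    (True when the model's abs-error ECDF is >= every other model's ECDF on a
    common grid, i.e. its errors are stochastically smallest).
    """
    names = list(reports)
    sizes = {len(r.data) for r in reports.values()}
    if len(sizes) > 1:
        raise ValueError("reports cover different numbers of dimensions")
    grid = np.unique(np.concatenate(
        [r.data["abs_err"].to_numpy() for r in reports.values()]))
    ecdfs = {name: reports[name].ecdf_abs_err(grid) for name in names}
    rows = []
    for name in names:
        dominates = all(
            np.all(ecdfs[name] >= ecdfs[other] - 1e-12)
            for other in names if other != name
        )
        r = reports[name]
        rows.append({
            "model": name,
            "mae": r.mean_abs_error,
            "median_abs_err": float(r.data["abs_err"].median()),
            "fraction_within_one_sd": r.fraction_within_one_sd,
            "mean_posterior_sd": float(r.data["sd"].mean()),
            "dominates_all": dominates,
        })
    out = pd.DataFrame(rows).sort_values("mae", kind="mergesort").reset_index(drop=True)
    return out


def plot_ppc_bands(bands: PPCBands, barcodes=None, ncols: int = 4, path=None):
    """Log-ratio trajectories with shaded credible bands, one panel per barcode."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ids = list(bands.barcode_ids)
    if barcodes is None:
        barcodes = ids[: 2 * ncols]
    idx = [ids.index(b) for b in barcodes]
    nrows = int(np.ceil(len(idx) / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(3 * ncols, 2.2 * nrows),
                             squeeze=False, sharex=True)
    t = np.arange(1, bands.observed.shape[0] + 1)
    shades = dict(zip(sorted(bands.levels, reverse=True),
                      np.linspace(0.15, 0.5, len(bands.levels))))
    for ax, j, name in zip(axes.ravel(), idx, barcodes):
        for lev in sorted(bands.levels, reverse=True):
            lo, hi = bands.bands[lev]
            ax.fill_between(t, lo[:, j], hi[:, j], alpha=shades[lev],
                            color="C0", lw=0)
        ax.plot(t, bands.observed[:, j], "k.-", ms=4, lw=1)
        ax.set_title(name, fontsize=8)
    for ax in axes.ravel()[len(idx):]:
        ax.axis("off")
    for ax in axes[-1]:
        ax.set_xlabel("transition")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_error_ecdf(reports: dict, path=None):
    """ECDFs of |posterior mean − truth| for one or more fitted models."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3))
    for name, report in reports.items():
        errs = np.sort(report.data["abs_err"].to_numpy())
        ax.step(errs, np.arange(1, errs.size + 1) / errs.size, where="post",
                label=name)
    ax.set_xlabel("|posterior mean − ground truth|")
    ax.set_ylabel("ECDF")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
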