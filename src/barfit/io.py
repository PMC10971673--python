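"""Reading, validating and reshaping barcode count tables.

The package consumes tidy long-format CSV tables of barcode read counts
with one row per (barcode, time point[, replicate]) and writes tidy
posterior-summary tables.  The canonical column names are

    barcode, time, count, neutral [, env, rep, genotype]

Internally, counts for one replicate are reshaped into a ``T x B`` matrix
split into neutral (reference) and non-neutral (mutant) blocks, the form
all fitness models operate on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "BarcodeCountTable",
    "SplitCounts",
    "FitnessResult",
    "read_count_table",
    "split_counts",
    "write_fitness_result",
]

#: default mapping from canonical field name -> CSV column name
DEFAULT_COLUMNS = {
    "barcode": "barcode",
    "time": "time",
    "count": "count",
    "neutral": "neutral",
    "environment": "env",
    "replicate": "rep",
    "genotype": "genotype",
}

_REQUIRED = ("barcode", "time", "count", "neutral")
_OPTIONAL = ("environment", "replicate", "genotype")


class SchemaError(ValueError):
    """The input file does not have the required columns."""


class ValidationError(ValueError):
    """The input table violates a structural invariant."""


@dataclass
class BarcodeCountTable:
    """Validated tidy table of barcode read counts.

    ``data`` holds canonical columns ``barcode, time, count, neutral`` and
    optionally ``environment, replicate, genotype``.  Time indices are
    re-coded to consecutive integers ``1..T`` within each replicate.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = _validate(self.data)

    # -- convenience accessors -------------------------------------------------
    @property
    def has_replicates(self) -> bool:
        return "replicate" in self.data.columns

    @property
    def has_environments(self) -> bool:
        return "environment" in self.data.columns

    @property
    def has_genotypes(self) -> bool:
        return "genotype" in self.data.columns

    @property
    def replicate_ids(self) -> list:
        if not self.has_replicates:
            return [None]
        return sorted(self.data["replicate"].unique())

    @property
    def n_timepoints(self) -> int:
        return int(self.data["time"].max())

    @property
    def barcodes(self) -> list:
        return sorted(self.data["barcode"].unique())

    @property
    def neutral_barcodes(self) -> list:
        return sorted(self.data.loc[self.data["neutral"], "barcode"].unique())

    @property
    def mutant_barcodes(self) -> list:
        return sorted(self.data.loc[~self.data["neutral"], "barcode"].unique())

    def subset_replicate(self, replicate_id) -> "BarcodeCountTable":
        """Single-replicate slice (drops the replicate column)."""
        if not self.has_replicates:
            return self
        sub = self.data[self.data["replicate"] == replicate_id]
        if sub.empty:
            raise ValidationError(f"no rows for replicate {replicate_id!r}")
        return BarcodeCountTable(sub.drop(columns="replicate").reset_index(drop=True))

    def environment_schedule(self) -> list:
        """Environment label per transition ``t -> t+1``.

        The label of transition ``t`` is the environment in which the culture
        grew between samples ``t`` and ``t+1``, i.e. the environment recorded
        at time point ``t+1``.
        """
        if not self.has_environments:
            raise ValidationError("table has no environment column")
        env = (
            self.data[["time", "environment"]]
            .drop_duplicates()
            .sort_values("time")
        )
        if env["time"].duplicated().any():
            raise ValidationError("conflicting environment labels within a time point")
        return env["environment"].tolist()[1:]

    def genotype_map(self) -> dict:
        """Mapping barcode -> genotype over non-neutral barcodes."""
        if not self.has_genotypes:
            raise ValidationError("table has no genotype column")
        sub = self.data.loc[~self.data["neutral"], ["barcode", "genotype"]].drop_duplicates()
        if sub["barcode"].duplicated().any():
            raise ValidationError("a barcode maps to more than one genotype")
        return dict(zip(sub["barcode"], sub["genotype"]))


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in _REQUIRED:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    counts = df["count"]
    if not np.issubdtype(np.asarray(counts).dtype, np.number):
        raise ValidationError("counts must be numeric integers")
    arr = np.asarray(counts, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr < 0) or np.any(arr != np.round(arr)):
        raise ValidationError("counts must be non-negative integers")
    df["count"] = arr.astype(np.int64)
    df["neutral"] = df["neutral"].astype(bool)

    group_cols = ["replicate"] if "replicate" in df.columns else []
    key_cols = group_cols + ["barcode", "time"]
    if df.duplicated(subset=key_cols).any():
        dup = df[df.duplicated(subset=key_cols)].iloc[0]
        raise ValidationError(
            f"duplicate entry for barcode {dup['barcode']!r} at time {dup['time']!r}"
        )

    # re-code times to consecutive 1..T per replicate; require a rectangular grid
    def _recode(sub: pd.DataFrame) -> pd.DataFrame:
        times = sorted(sub["time"].unique())
        if len(times) < 2:
            raise ValidationError("at least 2 time points are required")
        mapping = {t: i + 1 for i, t in enumerate(times)}
        sub = sub.copy()
        sub["time"] = sub["time"].map(mapping)
        per_bc = sub.groupby("barcode")["time"].agg(["count", "nunique"])
        bad = per_bc[(per_bc["count"] != len(times))].index
        if len(bad):
            raise ValidationError(
                f"barcode {bad[0]!r} lacks entries for some time points "
                f"(expected {len(times)} rows per barcode)"
            )
        return sub

    if group_cols:
        df = pd.concat(
            [_recode(sub) for _, sub in df.groupby("replicate", sort=True)],
            ignore_index=True,
        )
    else:
        df = _recode(df)

    neutral_per_bc = df.groupby("barcode")["neutral"].nunique()
    if (neutral_per_bc > 1).any():
        raise ValidationError("a barcode is flagged both neutral and non-neutral")
    n_neutral = df.loc[df["neutral"], "barcode"].nunique()
    n_mutant = df.loc[~df["neutral"], "barcode"].nunique()
    if n_neutral == 0:
        raise ValidationError("at least one neutral (reference) barcode is required")
    if n_mutant == 0:
        raise ValidationError("at least one non-neutral barcode is required")
    sort_cols = group_cols + ["time", "barcode"]
    return df.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)


def read_count_table(path, column_map: dict | None = None) -> BarcodeCountTable:
    """Read a tidy CSV of barcode counts into a validated table.

    Parameters
    ----------
    path
        CSV file with a header row.
    column_map
        Optional mapping from canonical names (``barcode``, ``time``,
        ``count``, ``neutral``, ``environment``, ``replicate``,
        ``genotype``) to the column names used in the file.  Unmapped
        canonical names fall back to the defaults in ``DEFAULT_COLUMNS``.
    """
    cmap = dict(DEFAULT_COLUMNS)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path)
    out = {}
    for canon in _REQUIRED:
        col = cmap[canon]
        if col not in raw.columns:
            raise SchemaError(f"column {col!r} (field {canon!r}) not found in {path}")
        out[canon] = raw[col]
    for canon in _OPTIONAL:
        col = cmap[canon]
        if col in raw.columns:
            out[canon] = raw[col]
    return BarcodeCountTable(pd.DataFrame(out))


@dataclass
class SplitCounts:
    """Count matrices split into neutral and mutant blocks.

    ``r_neutral`` is ``T x N``, ``r_mutant`` is ``T x M``; columns follow
    ``neutral_ids`` / ``mutant_ids`` (sorted by barcode id, so the split is
    invariant to input row order).  ``total_reads[t]`` is the row sum over
    all barcodes.
    """

    r_neutral: np.ndarray
    r_mutant: np.ndarray
    neutral_ids: list
    mutant_ids: list
    total_reads: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.r_neutral = np.asarray(self.r_neutral, dtype=np.int64)
        self.r_mutant = np.asarray(self.r_mutant, dtype=np.int64)
        if self.r_neutral.ndim != 2 or self.r_mutant.ndim != 2:
            raise ValidationError("count blocks must be 2-D (T x lineages)")
        if self.r_neutral.shape[0] != self.r_mutant.shape[0]:
            raise ValidationError("neutral and mutant blocks disagree on T")
        if self.r_neutral.shape[1] != len(self.neutral_ids):
            raise ValidationError("neutral ids do not match neutral columns")
        if self.r_mutant.shape[1] != len(self.mutant_ids):
            raise ValidationError("mutant ids do not match mutant columns")
        if self.n_neutral < 1:
            raise ValidationError(
                "unusable design: at least one neutral reference lineage is required"
            )
        if self.n_mutant < 1:
            raise ValidationError("no non-neutral barcodes to infer fitness for")
        self.total_reads = self.r_neutral.sum(axis=1) + self.r_mutant.sum(axis=1)

    @property
    def n_timepoints(self) -> int:
        return self.r_neutral.shape[0]

    @property
    def n_neutral(self) -> int:
        return self.r_neutral.shape[1]

    @property
    def n_mutant(self) -> int:
        return self.r_mutant.shape[1]

    @property
    def n_barcodes(self) -> int:
        return self.n_neutral + self.n_mutant

    @property
    def counts(self) -> np.ndarray:
        """Merged ``T x B`` matrix, neutral columns first."""
        return np.hstack([self.r_neutral, self.r_mutant])

    @property
    def barcode_ids(self) -> list:
        return list(self.neutral_ids) + list(self.mutant_ids)


def split_counts(table: BarcodeCountTable) -> SplitCounts:
    """Split a single-replicate table into neutral / mutant count matrices."""
    if table.has_replicates and len(table.replicate_ids) > 1:
        raise ValidationError(
            "split_counts requires a single-replicate slice; "
            "use BarcodeCountTable.subset_replicate first"
        )
    df = table.data
    wide = df.pivot(index="time", columns="barcode", values="count").sort_index()
    neutral_ids = table.neutral_barcodes
    mutant_ids = table.mutant_barcodes
    return SplitCounts(
        r_neutral=wide[neutral_ids].to_numpy(),
        r_mutant=wide[mutant_ids].to_numpy(),
        neutral_ids=neutral_ids,
        mutant_ids=mutant_ids,
    )


_QUANTS = (2.5, 16.0, 50.0, 84.0, 97.5)
_QCOLS = ["q2.5", "q16", "q50", "q84", "q97.5"]


@dataclass
class FitnessResult:
    """Tidy posterior summaries.

    One row per scalar summary dimension with identity columns
    ``parameter, barcode, environment, replicate, genotype, index`` and
    summary columns ``mean, sd, q2.5, q16, q50, q84, q97.5``.  The 68%
    credible region is the ``[q16, q84]`` interval.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"parameter", "mean", "sd", *(_QCOLS)}
        missing = need - set(self.data.columns)
        if missing:
            raise ValidationError(f"summary table missing columns {sorted(missing)}")
        if (self.data["sd"] < 0).any():
            raise ValidationError("posterior sd must be non-negative")
        q = self.data[_QCOLS].to_numpy(dtype=float)
        if np.any(np.diff(q, axis=1) < -1e-9):
            raise ValidationError("quantiles must be monotone non-decreasing")

    def fitness(self) -> pd.DataFrame:
        """Rows for per-barcode relative fitness parameters."""
        return self.data[self.data["parameter"] == "fitness"].reset_index(drop=True)

    def hyper_fitness(self) -> pd.DataFrame:
        return self.data[self.data["parameter"] == "hyper_fitness"].reset_index(drop=True)

    def mean_fitness(self) -> pd.DataFrame:
        """Rows for the per-transition population mean fitness."""
        return self.data[self.data["parameter"] == "mean_fitness"].reset_index(drop=True)


def write_fitness_result(result: FitnessResult, path) -> None:
    """Write a :class:`FitnessResult` to a tidy CSV (round-trip readable)."""
    result.data.to_csv(path, index=False, float_format="%.9g")


def read_fitness_result(path) -> FitnessResult:
    return FitnessResult(pd.read_csv(path))
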