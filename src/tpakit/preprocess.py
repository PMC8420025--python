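"""Perseus-style preprocessing for label-free intensity matrices.

The stack mirrors the standard workflow for LFQ proteomics: log2 transform,
group-presence filtering (keep a protein if it is quantified in at least 70%
of the runs of some group), run-level Pearson correlation on the filtered
values, imputation of the remaining missing values from a down-shifted normal
distribution (width 0.5, down shift 1.8, in units of the run's observed SD),
and row z-scoring ahead of clustering.

Imputation draws per run (column) by default — for run c with observed mean
mu_c and sample SD sd_c, missing cells are replaced by draws from
Normal(mu_c - downshift*sd_c, (width*sd_c)^2) — emulating the low-abundance
origin of proteomic dropout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .io_tables import IntensityMatrix, SampleAnnotation

__all__ = [
    "LogMatrix",
    "log2_transform",
    "filter_by_group_presence",
    "impute_downshifted_gaussian",
    "zscore_rows",
    "pearson_correlation_matrix",
]


@dataclass
class LogMatrix:
    """Protein x run log2 intensities; NaN marks missing cells.

    ``imputed_mask`` is True exactly where a missing value was filled in.
    """

    values: pd.DataFrame
    basis: str = "lfq"  # "raw" | "lfq"
    transformed: bool = True
    imputed_mask: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if self.basis not in ("raw", "lfq"):
            raise ValueError("basis must be 'raw' or 'lfq'")
        if self.imputed_mask is None:
            self.imputed_mask = pd.DataFrame(
                False, index=self.values.index, columns=self.values.columns
            )
        if self.imputed_mask.shape != self.values.shape:
            raise ValueError("imputed_mask shape must match values")

    @property
    def is_complete(self) -> bool:
        return not self.values.isna().any().any()

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def run_ids(self) -> list[str]:
        return list(self.values.columns)


def log2_transform(matrix: IntensityMatrix, basis: str = "lfq") -> LogMatrix:
    """log2-transform raw or LFQ intensities; missing stays missing."""
    source = matrix.lfq if basis == "lfq" else matrix.raw
    vals = source.to_numpy(dtype=float)
    if np.nanmin(vals, initial=0.0) < 0:
        raise ValueError("negative intensities cannot be log-transformed")
    with np.errstate(divide="ignore"):
        logged = np.where(np.isnan(vals), np.nan, np.log2(vals))
    if np.isneginf(logged).any():
        raise ValueError("zero intensity present; read with zero_as_missing=True")
    return LogMatrix(
        values=pd.DataFrame(logged, index=source.index, columns=source.columns),
        basis=basis,
        transformed=True,
    )


def filter_by_group_presence(
    matrix: LogMatrix,
    annotation: SampleAnnotation,
    min_fraction: float = 0.70,
) -> LogMatrix:
    """Keep proteins quantified in >= ``min_fraction`` of the runs of some group.

    Fractions are computed over runs, so technical replicates count
    individually.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    annotation.validate_runs(matrix.run_ids)
    keep = pd.Series(False, index=matrix.values.index)
    for group in annotation.groups:
        runs = [r for r in annotation.runs_in_group(group) if r in matrix.values.columns]
        if not runs:
            raise ValueError(f"group {group!r} has no runs in the matrix")
        frac = matrix.values[runs].notna().sum(axis=1) / len(runs)
        keep |= frac >= min_fraction
    return replace(
        matrix,
        values=matrix.values.loc[keep],
        imputed_mask=matrix.imputed_mask.loc[keep],
    )


def impute_downshifted_gaussian(
    matrix: LogMatrix,
    width: float = 0.5,
    downshift: float = 1.8,
    seed: Optional[int] = None,
    per_column: bool = True,
) -> LogMatrix:
    """Fill missing cells with draws from a down-shifted normal distribution.

    Per run c (default), draws come from Normal(mu_c - downshift*sd_c,
    (width*sd_c)^2) with mu_c/sd_c the mean and sample SD (ddof=1) of the
    observed values; ``per_column=False`` uses whole-matrix moments instead.
    Observed cells are never altered; replacements are recorded in
    ``imputed_mask``.
    """
    if not matrix.transformed:
        raise ValueError("impute on log-transformed values")
    if width < 0 or downshift < 0:
        raise ValueError("width and downshift must be >= 0")
    rng = np.random.default_rng(seed)
    vals = matrix.values.to_numpy(dtype=float).copy()
    missing = np.isnan(vals)

    if per_column:
        for j, run in enumerate(matrix.values.columns):
            observed = vals[~missing[:, j], j]
            if missing[:, j].sum() == 0:
                continue
            if observed.size < 2:
                raise ValueError(
                    f"run {run!r} has fewer than 2 observed values; cannot impute"
                )
            mu, sd = observed.mean(), observed.std(ddof=1)
            n = int(missing[:, j].sum())
            vals[missing[:, j], j] = rng.normal(mu - downshift * sd, width * sd, n)
    else:
        observed = vals[~missing]
        if observed.size < 2:
            raise ValueError("fewer than 2 observed values in the matrix")
        mu, sd = observed.mean(), observed.std(ddof=1)
        vals[missing] = rng.normal(mu - downshift * sd, width * sd, int(missing.sum()))

    mask = matrix.imputed_mask.to_numpy() | missing
    return replace(
        matrix,
        values=pd.DataFrame(vals, index=matrix.values.index, columns=matrix.values.columns),
        imputed_mask=pd.DataFrame(
            mask, index=matrix.values.index, columns=matrix.values.columns
        ),
    )


def zscore_rows(matrix: LogMatrix) -> LogMatrix:
    """Center and scale each protein row to mean 0, population SD 1."""
    if not matrix.is_complete:
        raise ValueError("z-scoring requires a complete (imputed) matrix")
    vals = matrix.values.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=0, keepdims=True)
    flat = np.where(sd[:, 0] == 0)[0]
    if flat.size:
        names = [matrix.values.index[i] for i in flat[:5]]
        raise ValueError(f"zero-variance rows cannot be z-scored: {names}")
    return replace(
        matrix,
        values=pd.DataFrame(
            (vals - mean) / sd, index=matrix.values.index, columns=matrix.values.columns
        ),
    )


def pearson_correlation_matrix(
    matrix: LogMatrix, min_shared: int = 3
) -> pd.DataFrame:
    """Run x run Pearson correlations over pairwise-complete proteins.

    Pairs sharing fewer than ``min_shared`` quantified proteins yield a
    missing entry with a warning.
    """
    if matrix.values.shape[0] < 3:
        raise ValueError("need at least 3 proteins for correlation")
    corr = matrix.values.corr(method="pearson", min_periods=min_shared)
    for run in corr.columns:
        corr.loc[run, run] = 1.0
    off_diag_nan = int(corr.isna().to_numpy().sum()) // 2
    if off_diag_nan:
        warnings.warn(
            f"{off_diag_nan} run pairs share fewer than {min_shared} proteins",
            stacklevel=2,
        )
    return corr
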