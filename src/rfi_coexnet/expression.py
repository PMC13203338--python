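"""Expression matrices: TSV I/O, counts-to-TPM conversion, gene filtering.

The in-memory container is a thin wrapper over a pandas DataFrame
(genes x samples, non-negative) tagged with its unit ("counts" or "TPM").
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "FilterCriteria",
    "counts_to_tpm",
    "filter_genes",
    "read_expression_tsv",
    "write_expression_tsv",
]


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values with an explicit unit tag."""

    values: pd.DataFrame  # index: gene ids, columns: sample ids
    unit: str = "TPM"  # "counts" or "TPM"

    def __post_init__(self) -> None:
        if self.unit not in ("counts", "TPM"):
            raise ValueError(f"unit must be 'counts' or 'TPM', got {self.unit!r}")
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        if self.values.columns.has_duplicates:
            dupes = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes[:5]}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class FilterCriteria:
    """Low-expression / low-variability gene filter.

    A gene is kept only if it exceeds all three thresholds strictly:
    mean TPM > ``min_mean_tpm``, detection rate (fraction of samples with
    TPM > 0) > ``min_detection_rate``, and coefficient of variation
    (sample SD / mean) > ``min_cv``.
    """

    min_mean_tpm: float = 3.0
    min_detection_rate: float = 0.6
    min_cv: float = 0.2

    def __post_init__(self) -> None:
        if self.min_mean_tpm < 0 or self.min_cv < 0:
            raise ValueError("thresholds must be non-negative")
        if not 0 <= self.min_detection_rate <= 1:
            raise ValueError("detection rate threshold must lie in [0, 1]")


def counts_to_tpm(counts: ExpressionMatrix, gene_lengths: pd.Series) -> ExpressionMatrix:
    """Convert raw read counts to transcripts per million.

    Per sample: length-normalised rates ``count/length`` are rescaled so the
    column sums to 1e6.  ``gene_lengths`` is indexed by gene id, in bases.
    """
    if counts.unit != "counts":
        raise ValueError(f"expected a counts matrix, got unit={counts.unit!r}")
    missing = counts.values.index.difference(gene_lengths.index)
    if len(missing):
        raise ValueError(f"missing gene lengths for: {missing.tolist()[:10]}")
    lengths = gene_lengths.reindex(counts.values.index).astype(float)
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0].tolist()
        raise ValueError(f"non-positive gene lengths for: {bad[:10]}")
    rate = counts.values.div(lengths, axis=0)
    tpm = rate.div(rate.sum(axis=0), axis=1) * 1e6
    return ExpressionMatrix(values=tpm, unit="TPM")


def filter_genes(
    expr: ExpressionMatrix, criteria: FilterCriteria = FilterCriteria()
) -> tuple[ExpressionMatrix, dict]:
    """Apply the three-way expression filter; returns (filtered, report).

    All comparisons are strict, so boundary genes (e.g. mean exactly at the
    threshold) are removed.  CV uses the sample (n-1) standard deviation.
    Genes with zero mean fail the mean criterion before CV is evaluated
    (their CV is reported as 0).
    """
    if expr.unit != "TPM":
        raise ValueError(f"filtering is defined on TPM, got unit={expr.unit!r}")
    vals = expr.values
    mean = vals.mean(axis=1)
    detection = (vals > 0).mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    cv = pd.Series(
        np.where(mean > 0, sd / mean.replace(0, np.nan), 0.0), index=vals.index
    ).fillna(0.0)

    pass_mean = mean > criteria.min_mean_tpm
    pass_det = detection > criteria.min_detection_rate
    pass_cv = cv > criteria.min_cv
    keep = pass_mean & pass_det & pass_cv

    report = {
        "n_input": int(len(vals)),
        "n_kept": int(keep.sum()),
        "failed_mean": int((~pass_mean).sum()),
        "failed_detection": int((~pass_det).sum()),
        "failed_cv": int((~pass_cv).sum()),
        "criteria": {
            "min_mean_tpm": criteria.min_mean_tpm,
            "min_detection_rate": criteria.min_detection_rate,
            "min_cv": criteria.min_cv,
        },
    }
    return ExpressionMatrix(values=vals.loc[keep], unit="TPM"), report


def read_expression_tsv(path: str | Path, unit: str = "TPM") -> ExpressionMatrix:
    """Read a genes-x-samples TSV (first column ``gene_id``); gzip ok."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return ExpressionMatrix(values=df.astype(float), unit=unit)


def write_expression_tsv(expr: ExpressionMatrix, path: str | Path) -> None:
    """Write a genes-x-samples TSV at 6 significant digits (round-trips)."""
    out = expr.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.6g")
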