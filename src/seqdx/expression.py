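"""Expression matrix container, TSV I/O and normalization.

The matrix is genes x samples throughout the package.  Raw abundances are
normalized to log2 counts-per-million (log2-CPM with a +1 offset) before any
model fitting; a ``scale`` marker tracks whether a matrix holds raw
abundances or log2 values so that models cannot silently be fed the wrong
scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataFormatError, DegenerateDataError

RAW = "raw"
LOG2 = "log2"


@dataclass
class ExpressionMatrix:
    """Genes x samples abundance table with a scale marker.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample ids as columns.  No missing
        values are allowed; on the raw scale all entries must be >= 0.
    scale
        Either ``"raw"`` (abundances) or ``"log2"`` (normalized values).
    """

    values: pd.DataFrame
    scale: str = RAW

    def __post_init__(self) -> None:
        if self.scale not in (RAW, LOG2):
            raise DataFormatError(f"unknown scale marker {self.scale!r}")
        idx = self.values.index
        if idx.has_duplicates:
            dups = sorted(idx[idx.duplicated()].unique())
            raise DataFormatError(f"duplicate gene ids: {', '.join(map(str, dups))}")
        if self.values.columns.has_duplicates:
            dups = sorted(self.values.columns[self.values.columns.duplicated()].unique())
            raise DataFormatError(f"duplicate sample ids: {', '.join(map(str, dups))}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise DataFormatError("expression values must be numeric")
        if np.isnan(arr).any():
            i, j = np.argwhere(np.isnan(arr))[0]
            raise DataFormatError(
                f"missing value at gene {idx[i]!r}, sample {self.values.columns[j]!r}"
            )
        if self.scale == RAW and (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise DataFormatError(
                f"negative abundance at gene {idx[i]!r}, sample {self.values.columns[j]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise DataFormatError(f"genes absent from matrix: {', '.join(missing)}")
        return ExpressionMatrix(self.values.loc[genes].copy(), scale=self.scale)


def read_expression(path) -> ExpressionMatrix:
    """Read an expression TSV (first column gene id, header of sample ids).

    Returns a matrix with ``scale="raw"``.  Duplicated gene rows and
    non-numeric cells are rejected with a message naming the offender.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise DataFormatError(f"duplicate gene ids in {path}: {', '.join(map(str, dups))}")
    try:
        num = df.astype(float)
    except ValueError:
        for gene, row in df.iterrows():
            for sample, cell in row.items():
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise DataFormatError(
                        f"non-numeric cell in {path} at gene {gene!r}, sample {sample!r}: {cell!r}"
                    ) from None
        raise
    return ExpressionMatrix(num, scale=RAW)


def write_expression(m: ExpressionMatrix, path, float_format: str = "%.10g") -> None:
    """Write a matrix as TSV with the gene id as first column."""
    m.values.to_csv(path, sep="\t", index_label="gene_id", float_format=float_format)


def normalize_log_cpm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Library-size normalize to log2(CPM + 1).

    value := log2(1e6 * x / sample_total + 1).  Invariant to scaling all of a
    sample's abundances by a constant.  Samples with zero total are rejected.
    """
    if m.scale != RAW:
        raise DataFormatError("normalize_log_cpm expects a raw-scale matrix")
    totals = m.values.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise DegenerateDataError(
            f"samples with zero total abundance: {', '.join(map(str, zero.index))}"
        )
    cpm = m.values.divide(totals, axis=1) * 1e6
    return ExpressionMatrix(np.log2(cpm + 1.0), scale=LOG2)
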