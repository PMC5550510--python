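"""Expression matrices and array-style preprocessing.

The pipeline operates on probe-set/gene level log2 intensity matrices
(genes x samples) with a sample-to-group assignment, the form in which
summarized microarray series are distributed.  Preprocessing is the
standard array recipe: optional log2 transformation of linear-scale data
followed by quantile normalization (the normalization component of RMA;
background correction and probe summarization are upstream of this
package and are not reimplemented).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "read_expression_table",
    "log2_transform",
    "quantile_normalize",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of (log2) intensities with group labels.

    Parameters
    ----------
    values
        DataFrame indexed by unique gene ids with unique sample-id columns.
        All entries must be finite.
    group_of
        Mapping from every sample id to its group label.
    """

    values: pd.DataFrame
    group_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        arr = self.values.to_numpy(dtype=float)
        if arr.size and not np.isfinite(arr).all():
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(f"non-finite value at gene {idx[i]!r}, sample {cols[j]!r}")
        missing = [s for s in cols if s not in self.group_of]
        if missing:
            raise ValueError(f"samples missing from group map: {missing}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.group_of[s] == group]

    def to_tsv(self, path: str | Path, group_map_path: str | Path | None = None) -> None:
        """Write the matrix (and optionally the group map) as TSV."""
        df = self.values.copy()
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t")
        if group_map_path is not None:
            with open(group_map_path, "w") as fh:
                for s in self.values.columns:
                    fh.write(f"{s}\t{self.group_of[s]}\n")


def read_group_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV of sample_id -> group label."""
    group_of: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns, got {len(parts)}")
            sample, group = parts
            if sample in group_of:
                raise ValueError(f"{path}: line {lineno}: duplicate sample id {sample!r}")
            group_of[sample] = group
    return group_of


def read_expression_table(path: str | Path, group_map_path: str | Path) -> ExpressionMatrix:
    """Read an expression TSV (first column gene id, header of sample ids).

    Raises :class:`ValueError` naming the offending row/column for
    duplicate ids, non-numeric cells, and samples absent from the group
    map.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene id: {dup!r}")
    try:
        num = df.astype(float)
    except ValueError:
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                gene = df.index[bad.to_numpy().nonzero()[0][0]]
                raise ValueError(
                    f"{path}: non-numeric cell at gene {gene!r}, sample {col!r}"
                ) from None
        raise
    num.index.name = None
    group_of = read_group_map(group_map_path)
    missing = [s for s in num.columns if s not in group_of]
    if missing:
        raise ValueError(f"{path}: samples missing from group map {group_map_path}: {missing}")
    return ExpressionMatrix(values=num, group_of={s: group_of[s] for s in num.columns})


def log2_transform(matrix: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """Replace each value x by log2(x + offset).

    Intended for linear-scale input; pipelines whose input is already on
    the log2 scale skip this step entirely (``already_log2`` in the run
    configuration).
    """
    if offset < 0:
        raise ValueError(f"offset must be nonnegative, got {offset}")
    arr = matrix.values.to_numpy(dtype=float) + offset
    if (arr <= 0).any():
        i, j = np.argwhere(arr <= 0)[0]
        raise ValueError(
            f"nonpositive value after offset at gene {matrix.values.index[i]!r}, "
            f"sample {matrix.values.columns[j]!r}"
        )
    out = pd.DataFrame(np.log2(arr), index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(values=out, group_of=dict(matrix.group_of))


def _quantile_normalize_array(arr: np.ndarray) -> np.ndarray:
    """Quantile-normalize columns of a 2-D array.

    Reference distribution = mean across columns of each column's sorted
    values.  Ties within a column receive the mean of the reference
    values across their tied ranks, so tied inputs stay tied and the
    operation is idempotent.
    """
    n_genes, n_samples = arr.shape
    reference = np.sort(arr, axis=0).mean(axis=1)
    # cumulative sums give O(1) means over rank spans
    ref_cumsum = np.concatenate([[0.0], np.cumsum(reference)])
    out = np.empty_like(arr, dtype=float)
    for j in range(n_samples):
        col = arr[:, j]
        order = np.argsort(col, kind="stable")
        sorted_col = col[order]
        # tie groups over rank spans [start, stop)
        boundaries = np.concatenate([[0], np.nonzero(np.diff(sorted_col))[0] + 1, [n_genes]])
        normalized_sorted = np.empty(n_genes)
        for start, stop in zip(boundaries[:-1], boundaries[1:]):
            normalized_sorted[start:stop] = (ref_cumsum[stop] - ref_cumsum[start]) / (stop - start)
        out[order, j] = normalized_sorted
    return out


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample's value distribution to the rank-wise mean.

    After normalization all columns share an identical sorted vector;
    within-column order of untied values is preserved, and applying the
    operation twice equals applying it once.
    """
    arr = matrix.values.to_numpy(dtype=float)
    if arr.size == 0:
        raise ValueError("cannot quantile-normalize an empty matrix")
    if arr.shape[1] < 2:
        raise ValueError("quantile normalization requires at least 2 samples")
    out = pd.DataFrame(
        _quantile_normalize_array(arr),
        index=matrix.values.index,
        columns=matrix.values.columns,
    )
    return ExpressionMatrix(values=out, group_of=dict(matrix.group_of))
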