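"""Gene-by-sample expression containers and their on-disk TSV formats.

An :class:`ExpressionDataset` holds one case/control microarray-style matrix
under one normalization variant.  Two variants of the same dataset ("A" and
"B", emulating a linear-scale and a log2-scale normalization of the same raw
intensities) are analysed side by side downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CASE = "case"
CONTROL = "control"


@dataclass
class ExpressionDataset:
    """One gene x sample expression matrix with group labels.

    Parameters
    ----------
    id : str
        Dataset name (e.g. ``"DS1"``).
    matrix : pandas.DataFrame
        Genes in rows (index = gene symbols), samples in columns.  Values are
        strictly positive intensities when ``scale == "linear"``, otherwise
        log2 intensities.
    groups : dict
        Sample name -> ``"case"`` or ``"control"``.
    variant : str
        Normalization variant tag, ``"A"`` or ``"B"``.
    scale : str
        ``"linear"`` or ``"log2"``.
    """

    id: str
    matrix: pd.DataFrame
    groups: dict[str, str] = field(repr=False)
    variant: str = "A"
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.variant not in ("A", "B"):
            raise ValueError(f"unknown variant {self.variant!r}")
        unknown = set(self.groups.values()) - {CASE, CONTROL}
        if unknown:
            raise ValueError(f"unknown group labels: {sorted(unknown)}")
        missing = [s for s in self.matrix.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples without group labels: {missing[:5]}")

    @property
    def genes(self) -> pd.Index:
        return self.matrix.index

    @property
    def case_samples(self) -> list[str]:
        return [s for s in self.matrix.columns if self.groups[s] == CASE]

    @property
    def control_samples(self) -> list[str]:
        return [s for s in self.matrix.columns if self.groups[s] == CONTROL]

    def log2_matrix(self) -> pd.DataFrame:
        """The matrix on the log2 scale regardless of the stored scale."""
        if self.scale == "log2":
            return self.matrix
        if (self.matrix.values <= 0).any():
            raise ValueError(f"{self.id}: non-positive intensities on linear scale")
        return np.log2(self.matrix)

    def linear_matrix(self) -> pd.DataFrame:
        """The matrix on the linear scale regardless of the stored scale."""
        if self.scale == "linear":
            return self.matrix
        return 2.0 ** self.matrix

    def subset_samples(self, keep: list[str]) -> "ExpressionDataset":
        """A copy restricted to the given samples (order preserved)."""
        cols = [s for s in self.matrix.columns if s in set(keep)]
        return ExpressionDataset(
            id=self.id,
            matrix=self.matrix[cols],
            groups={s: self.groups[s] for s in cols},
            variant=self.variant,
            scale=self.scale,
        )


def write_expression_tsv(dataset: ExpressionDataset, path: str | Path) -> None:
    """Write the matrix as TSV with a leading ``gene`` column."""
    out = dataset.matrix.copy()
    out.insert(0, "gene", out.index)
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_metadata_tsv(dataset: ExpressionDataset, path: str | Path) -> None:
    """Write sample metadata as TSV with columns ``sample`` and ``group``."""
    rows = [{"sample": s, "group": dataset.groups[s]} for s in dataset.matrix.columns]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_expression_tsv(
    matrix_path: str | Path,
    metadata_path: str | Path,
    *,
    id: str,
    variant: str = "A",
    scale: str = "linear",
) -> ExpressionDataset:
    """Read a matrix TSV (first column ``gene``) plus a sample/group TSV."""
    mat = pd.read_csv(matrix_path, sep="\t")
    if mat.columns[0] != "gene":
        raise ValueError(f"{matrix_path}: first column must be 'gene'")
    mat = mat.set_index("gene")
    meta = pd.read_csv(metadata_path, sep="\t")
    groups = dict(zip(meta["sample"].astype(str), meta["group"].astype(str)))
    return ExpressionDataset(id=id, matrix=mat, groups=groups, variant=variant, scale=scale)
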