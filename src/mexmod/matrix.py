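"""Binary patient x gene alteration matrices.

The universal input of the package: rows are tumor samples, columns are
genes (or meta-genes), entries record presence/absence of a somatic
alteration. Matrices are exchanged as tab-separated text with gene names
in the header row and patient identifiers in the first column.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AlterationMatrix",
    "CountProfile",
    "count_profile",
    "read_matrix",
    "write_matrix",
]


@dataclass(frozen=True)
class AlterationMatrix:
    """Binary n x k alteration matrix with labelled rows and columns.

    Parameters
    ----------
    values
        Integer array of shape ``(n, k)`` with entries in {0, 1}.
    gene_names
        ``k`` distinct column labels.
    patient_ids
        ``n`` distinct row labels.
    """

    values: np.ndarray
    gene_names: tuple[str, ...]
    patient_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 2 or values.shape[0] < 1 or values.shape[1] < 1:
            raise ValueError("alteration matrix must be 2-D with n >= 1 and k >= 1")
        if not np.isin(values, (0, 1)).all():
            bad = np.argwhere(~np.isin(values, (0, 1)))[0]
            raise ValueError(
                f"non-binary entry at patient row {bad[0]}, gene column {bad[1]}"
            )
        object.__setattr__(self, "values", values.astype(np.int8))
        object.__setattr__(self, "gene_names", tuple(map(str, self.gene_names)))
        object.__setattr__(self, "patient_ids", tuple(map(str, self.patient_ids)))
        n, k = values.shape
        if len(self.gene_names) != k:
            raise ValueError(f"expected {k} gene names, got {len(self.gene_names)}")
        if len(self.patient_ids) != n:
            raise ValueError(f"expected {n} patient ids, got {len(self.patient_ids)}")
        if len(set(self.gene_names)) != k:
            raise ValueError("gene names must be distinct")
        if len(set(self.patient_ids)) != n:
            raise ValueError("patient ids must be distinct")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_values(
        cls,
        values,
        gene_names: Sequence[str] | None = None,
        patient_ids: Sequence[str] | None = None,
    ) -> "AlterationMatrix":
        """Build a matrix, auto-generating ``g1..gk`` / ``p1..pn`` labels."""
        values = np.asarray(values)
        if values.ndim != 2:
            raise ValueError("values must be 2-D")
        n, k = values.shape
        if gene_names is None:
            gene_names = [f"g{j + 1}" for j in range(k)]
        if patient_ids is None:
            patient_ids = [f"p{i + 1}" for i in range(n)]
        return cls(values, tuple(gene_names), tuple(patient_ids))

    def subset(self, genes: Sequence[str] | Sequence[int]) -> "AlterationMatrix":
        """Restrict to the given genes (by name or column index)."""
        if len(genes) == 0:
            raise ValueError("gene subset must be non-empty")
        if all(isinstance(g, (int, np.integer)) for g in genes):
            idx = [int(g) for g in genes]
        else:
            pos = {g: j for j, g in enumerate(self.gene_names)}
            missing = [g for g in genes if g not in pos]
            if missing:
                raise KeyError(f"unknown genes: {missing}")
            idx = [pos[g] for g in genes]
        return AlterationMatrix(
            self.values[:, idx],
            tuple(self.gene_names[j] for j in idx),
            self.patient_ids,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.patient_ids, name="patient"),
            columns=list(self.gene_names),
        )


@dataclass(frozen=True)
class CountProfile:
    """Histogram ``counts[m]`` of rows with exactly m observed alterations.

    This is the sufficient statistic for the exchangeable mutual-exclusivity
    likelihood: once rows are summarized by their number of 1s, the model
    likelihood can be evaluated in O(k), independent of n.
    """

    counts: np.ndarray
    n: int
    k: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 1 or counts.shape[0] != self.k + 1:
            raise ValueError("counts must have length k + 1")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if counts.sum() != self.n:
            raise ValueError("counts must sum to n")


def count_profile(matrix: AlterationMatrix) -> CountProfile:
    """Histogram the rows of ``matrix`` by their number of alterations."""
    m = matrix.values.sum(axis=1)
    counts = np.bincount(m, minlength=matrix.k + 1)
    return CountProfile(counts=counts, n=matrix.n, k=matrix.k)


def read_matrix(path) -> AlterationMatrix:
    """Read an alteration matrix from tab-separated text.

    Layout: first row gene names, first column patient identifiers,
    remaining cells 0/1. Raises ``ValueError`` naming the offending cell
    for non-binary entries and on duplicate labels or ragged rows.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise ValueError(f"malformed matrix file {path}: {exc}") from exc
    if df.shape[0] < 1 or df.shape[1] < 1:
        raise ValueError(f"matrix file {path} must have >= 1 patient and >= 1 gene")
    raw = df.to_numpy()
    values = np.zeros(raw.shape, dtype=np.int8)
    for (i, j), cell in np.ndenumerate(raw):
        cell = str(cell).strip()
        if cell not in ("0", "1"):
            raise ValueError(
                f"non-binary cell {cell!r} at patient {df.index[i]!r}, "
                f"gene {df.columns[j]!r}"
            )
        values[i, j] = int(cell)
    return AlterationMatrix(values, tuple(df.columns), tuple(df.index))


def write_matrix(matrix: AlterationMatrix, path) -> None:
    """Write a matrix in the tab-separated layout accepted by ``read_matrix``."""
    matrix.to_frame().to_csv(path, sep="\t")
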