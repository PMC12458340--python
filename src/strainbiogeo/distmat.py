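"""Labelled symmetric distance matrices with missing-pair support.

The pairwise distance matrix is the universal currency of this package:
strain genetic distances (1 - conANI), host mitochondrial distances and
great-circle geographic distances all travel through :class:`DistanceMatrix`.
Unlike the dense containers in scikit-bio, entries may be missing (NaN) —
conANI is undefined for sample pairs that share no covered genomic sites —
and missingness must stay symmetric.

On-disk format is a square TSV whose first row and first column carry the
sample labels and whose missing entries are the string ``NA``.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["DistanceMatrix", "common_labels"]

_SYMMETRY_TOL = 1e-9


class DistanceMatrix:
    """Symmetric, hollow, non-negative labelled distance matrix.

    Parameters
    ----------
    values
        Square array of pairwise distances. ``NaN`` marks a missing pair.
    labels
        Unique sample identifiers, one per row/column.
    genetic
        If True, additionally require all present values <= 1 (distances on
        the 1 - ANI scale).
    validate
        Validate invariants on construction (symmetry within 1e-9, repaired
        by averaging; zero diagonal; non-negative entries; symmetric
        missingness).
    """

    __slots__ = ("_values", "_labels", "_index")

    def __init__(
        self,
        values: np.ndarray,
        labels: Sequence[str],
        *,
        genetic: bool = False,
        validate: bool = True,
    ) -> None:
        values = np.asarray(values, dtype=float)
        labels = tuple(str(x) for x in labels)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError(f"distance matrix must be square, got {values.shape}")
        if len(labels) != values.shape[0]:
            raise ValueError("label count does not match matrix size")
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate labels in distance matrix")
        if validate:
            values = self._validated(values, labels, genetic)
        self._values = values
        self._labels = labels
        self._index = {lab: i for i, lab in enumerate(labels)}

    @staticmethod
    def _validated(values: np.ndarray, labels: tuple, genetic: bool) -> np.ndarray:
        miss = np.isnan(values)
        if not np.array_equal(miss, miss.T):
            raise ValueError("missing entries are not symmetric")
        with np.errstate(invalid="ignore"):
            asym = np.nanmax(np.abs(values - values.T)) if values.size else 0.0
        if np.isfinite(asym) and asym > _SYMMETRY_TOL:
            raise ValueError(f"matrix asymmetric beyond tolerance ({asym:.3g} > 1e-9)")
        values = (values + values.T) / 2.0  # repair sub-tolerance asymmetry
        diag = np.diag(values)
        if np.any(np.isnan(diag)) or np.any(np.abs(diag) > _SYMMETRY_TOL):
            raise ValueError("diagonal must be exactly zero")
        np.fill_diagonal(values, 0.0)
        off = values[~np.eye(len(labels), dtype=bool)]
        off = off[~np.isnan(off)]
        if off.size and off.min() < 0:
            raise ValueError("negative distances are not allowed")
        if genetic and off.size and off.max() > 1 + _SYMMETRY_TOL:
            raise ValueError("genetic distances must lie in [0, 1]")
        return values

    # ------------------------------------------------------------------ api
    @property
    def labels(self) -> tuple:
        return self._labels

    @property
    def values(self) -> np.ndarray:
        return self._values

    @property
    def n(self) -> int:
        return len(self._labels)

    def __len__(self) -> int:
        return self.n

    def __getitem__(self, pair: tuple) -> float:
        i, j = pair
        return float(self._values[self._index[i], self._index[j]])

    def __contains__(self, label: str) -> bool:
        return label in self._index

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DistanceMatrix):
            return NotImplemented
        return self._labels == other._labels and np.array_equal(
            self._values, other._values, equal_nan=True
        )

    def __repr__(self) -> str:
        return f"<DistanceMatrix n={self.n}>"

    def restrict(self, labels: Iterable[str]) -> "DistanceMatrix":
        """Submatrix for ``labels``, preserving the requested order."""
        labels = list(labels)
        missing = [x for x in labels if x not in self._index]
        if missing:
            raise KeyError(f"labels not in matrix: {missing}")
        idx = np.array([self._index[x] for x in labels], dtype=int)
        return DistanceMatrix(self._values[np.ix_(idx, idx)], labels, validate=False)

    def complete(self) -> bool:
        """True if no off-diagonal entry is missing."""
        off = ~np.eye(self.n, dtype=bool)
        return not np.isnan(self._values[off]).any()

    # ------------------------------------------------------------------- io
    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self._values, index=self._labels, columns=self._labels)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", na_rep="NA", index_label="")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kw) -> "DistanceMatrix":
        if list(df.index) != list(df.columns):
            raise ValueError("row and column labels differ")
        return cls(df.to_numpy(dtype=float), list(df.index), **kw)

    @classmethod
    def read_tsv(cls, path, **kw) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return cls.from_dataframe(df, **kw)


def common_labels(*matrices: DistanceMatrix) -> list:
    """Labels shared by all matrices, in the first matrix's order."""
    if not matrices:
        return []
    shared = set(matrices[0].labels)
    for m in matrices[1:]:
        shared &= set(m.labels)
    return [x for x in matrices[0].labels if x in shared]
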