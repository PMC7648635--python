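"""Labelled symmetric distance matrices with square-CSV I/O."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DistanceMatrix"]


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative dissimilarity matrix with a zero diagonal."""

    labels: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels in distance matrix")
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite distance")
        if np.any(self.values < 0):
            raise ValueError("negative distance")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.abs(np.diag(self.values)) > 1e-12):
            raise ValueError("nonzero diagonal")
        self.values = (self.values + self.values.T) / 2
        np.fill_diagonal(self.values, 0.0)

    def __len__(self) -> int:
        return len(self.labels)

    def get(self, a, b) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def submatrix(self, labels) -> "DistanceMatrix":
        labels = list(labels)
        missing = [l for l in labels if l not in self.labels]
        if missing:
            raise KeyError(f"labels not in matrix: {missing}")
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(labels, self.values[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError("square CSV must have matching row/column labels")
        return cls(list(df.index), df.to_numpy(dtype=float))
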