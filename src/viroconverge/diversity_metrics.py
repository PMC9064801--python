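"""Pairwise beta-diversity metrics on RPK abundances.

Weighted Bray–Curtis, Sorensen (presence/absence) and Hellinger distance
are implemented directly from their defining formulas; pairs that are
undefined (both samples empty) are reported as NaN rather than zero, since
zeroing would fabricate similarity.

Distance matrices are returned as :class:`skbio.DistanceMatrix` when every
pair is defined, else as a plain symmetric DataFrame with NaN holes; the
:class:`DistanceResult` wrapper carries the metric name either way.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DistanceResult", "bray_curtis", "sorensen", "hellinger"]


@dataclass
class DistanceResult:
    """Symmetric sample × sample dissimilarity matrix plus provenance."""

    matrix: pd.DataFrame
    metric: str
    transformation: str = ""

    def __post_init__(self) -> None:
        m = self.matrix.to_numpy()
        if m.shape[0] != m.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(np.nan_to_num(m), np.nan_to_num(m.T), atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("distance matrix diagonal must be 0")

    @property
    def sample_ids(self) -> list[str]:
        return self.matrix.columns.tolist()

    def value(self, a: str, b: str) -> float:
        return float(self.matrix.loc[a, b])

    def condensed(self) -> np.ndarray:
        n = len(self.sample_ids)
        iu = np.triu_indices(n, k=1)
        return self.matrix.to_numpy()[iu]

    def to_tsv(self, path: str) -> None:
        self.matrix.to_csv(path, sep="\t", index_label="sample_id", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str, metric: str = "unknown") -> "DistanceResult":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.columns = df.columns.astype(str)
        df.index = df.index.astype(str)
        return cls(df, metric=metric)


def _pairwise(values: np.ndarray, ids: list[str], fn, metric: str, transformation: str = "") -> DistanceResult:
    n = values.shape[1]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = fn(values[:, i], values[:, j])
    return DistanceResult(pd.DataFrame(d, index=ids, columns=ids), metric=metric, transformation=transformation)


def bray_curtis(abundance) -> DistanceResult:
    """Weighted Bray–Curtis: BC(x, y) = Σ|x_i − y_i| / Σ(x_i + y_i) on RPK."""
    data = abundance.data if hasattr(abundance, "data") else abundance

    def bc(x: np.ndarray, y: np.ndarray) -> float:
        denom = (x + y).sum()
        if denom == 0:
            return np.nan  # two empty samples: undefined
        return float(np.abs(x - y).sum() / denom)

    return _pairwise(data.to_numpy(dtype=float), data.columns.tolist(), bc, "bray_curtis")


def sorensen(presence: pd.DataFrame) -> DistanceResult:
    """Sorensen dissimilarity on presence/absence: 1 − 2|A∩B| / (|A| + |B|)."""

    def soer(x: np.ndarray, y: np.ndarray) -> float:
        a, b = x.astype(bool), y.astype(bool)
        denom = a.sum() + b.sum()
        if denom == 0:
            return np.nan
        return float(1.0 - 2.0 * (a & b).sum() / denom)

    return _pairwise(presence.to_numpy(), presence.columns.tolist(), soer, "sorensen")


def hellinger(abundance, log_transform: bool = True) -> DistanceResult:
    """Hellinger distance on (optionally ln(1+x)-transformed) RPK.

    D(x, y) = sqrt( Σ (sqrt(x_i/Σx) − sqrt(y_i/Σy))² ); the log transform is
    applied before closing the composition, matching a log-RPK analysis.
    """
    data = abundance.data if hasattr(abundance, "data") else abundance
    values = data.to_numpy(dtype=float)
    if log_transform:
        values = np.log1p(values)

    def hel(x: np.ndarray, y: np.ndarray) -> float:
        sx, sy = x.sum(), y.sum()
        if sx == 0 or sy == 0:
            return np.nan
        return float(np.sqrt(((np.sqrt(x / sx) - np.sqrt(y / sy)) ** 2).sum()))

    return _pairwise(
        values, data.columns.tolist(), hel, "hellinger", transformation="log1p" if log_transform else ""
    )
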