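"""Edge (cofluctuation) time series.

The edge time series of a pair of regions (i, j) is the frame-wise
product of their z-scored signals, z_i(t) * z_j(t).  Summing a column
over frames and dividing by T - 1 recovers the Pearson correlation of
the parents, so each edge series is a temporal decomposition of a static
functional connection into frame-wise contributions.  Standardization
uses the whole run with the T - 1 denominator, which makes that identity
exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Tuple

import numpy as np
import pandas as pd
from scipy import signal as _signal

__all__ = [
    "EdgeIndex",
    "EdgeMatrix",
    "DegenerateSeriesError",
    "standardize",
    "standardize_columns",
    "edge_series",
    "rss",
    "periodogram",
    "vector_to_matrix",
    "matrix_to_vector",
]


class DegenerateSeriesError(ValueError):
    """A series has zero sample variance and cannot be standardized."""


@dataclass(frozen=True)
class EdgeIndex:
    """Canonical (i < j) edge ordering: row-major over the upper triangle."""

    n_regions: int

    def __post_init__(self) -> None:
        if self.n_regions < 2:
            raise ValueError("need at least 2 regions")

    @property
    def n_edges(self) -> int:
        n = self.n_regions
        return n * (n - 1) // 2

    @property
    def pairs(self) -> List[Tuple[int, int]]:
        iu = np.triu_indices(self.n_regions, k=1)
        return list(zip(iu[0].tolist(), iu[1].tolist()))

    def position(self, i: int, j: int) -> int:
        """Flat position of edge (i, j); order of i, j is immaterial."""
        if i == j:
            raise ValueError("diagonal is not an edge")
        if i > j:
            i, j = j, i
        if not (0 <= i < j < self.n_regions):
            raise ValueError(f"pair ({i}, {j}) out of range")
        n = self.n_regions
        return i * (2 * n - i - 1) // 2 + (j - i - 1)

    def pair(self, position: int) -> Tuple[int, int]:
        if not (0 <= position < self.n_edges):
            raise ValueError("edge position out of range")
        n = self.n_regions
        i = 0
        offset = position
        while offset >= n - i - 1:
            offset -= n - i - 1
            i += 1
        return i, i + 1 + offset

    def incident(self, region: int) -> np.ndarray:
        """Flat positions of the n_regions - 1 edges touching ``region``."""
        return np.array(
            [self.position(region, other) for other in range(self.n_regions) if other != region]
        )


@dataclass
class EdgeMatrix:
    """Frames x edges cofluctuation table with its EdgeIndex."""

    values: np.ndarray
    index: EdgeIndex
    tr: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != self.index.n_edges:
            raise ValueError("edge values shape does not match the index")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("edge values must be finite")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_edges(self) -> int:
        return self.values.shape[1]

    def column_names(self, region_ids=None) -> List[str]:
        if region_ids is None:
            region_ids = [str(i + 1) for i in range(self.index.n_regions)]
        return [f"{region_ids[i]}_{region_ids[j]}" for i, j in self.index.pairs]

    def to_tsv(self, path) -> None:
        path = Path(path)
        pd.DataFrame(self.values, columns=self.column_names()).to_csv(path, sep="\t", index=False)
        sidecar = {"n_regions": self.index.n_regions, "tr": self.tr}
        path.with_suffix(".json").write_text(json.dumps(sidecar))

    @classmethod
    def from_tsv(cls, path) -> "EdgeMatrix":
        path = Path(path)
        values = pd.read_csv(path, sep="\t").to_numpy(dtype=float)
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(values, EdgeIndex(int(meta["n_regions"])), float(meta["tr"]))


def standardize(x: np.ndarray) -> np.ndarray:
    """Z-score a series: zero mean, unit sample sd (denominator T - 1)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("standardize expects a 1-D series of >= 2 frames")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateSeriesError("constant series cannot be standardized")
    return (x - x.mean()) / sd


def standardize_columns(X: np.ndarray) -> np.ndarray:
    """Column-wise z-scoring (denominator T - 1)."""
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = np.where(sd == 0)[0].tolist()
        raise DegenerateSeriesError(f"constant columns cannot be standardized: {bad}")
    return (X - X.mean(axis=0)) / sd


def edge_series(Z: np.ndarray, tr: float = 1.0, check_tol: float = 1e-6) -> EdgeMatrix:
    """Edge time series from standardized region series.

    Column (i, j) of the result is the frame-wise product Z[:, i] * Z[:, j]
    for every i < j in EdgeIndex order.  Inputs must already be z-scored
    (checked to ``check_tol``).
    """
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2 or Z.shape[1] < 2:
        raise ValueError("need a frames x regions matrix with >= 2 regions")
    means = Z.mean(axis=0)
    sds = Z.std(axis=0, ddof=1)
    if np.any(np.abs(means) > check_tol) or np.any(np.abs(sds - 1) > check_tol):
        raise ValueError("input series are not standardized (mean 0, sd 1 with ddof=1)")
    iu = np.triu_indices(Z.shape[1], k=1)
    values = Z[:, iu[0]] * Z[:, iu[1]]
    return EdgeMatrix(values, EdgeIndex(Z.shape[1]), tr)


def rss(E: EdgeMatrix) -> np.ndarray:
    """Root sum of squares across edges at each frame (global cofluctuation)."""
    if E.n_edges < 1:
        raise ValueError("need at least one edge")
    return np.sqrt(np.sum(E.values**2, axis=1))


def periodogram(
    series: np.ndarray, tr: float, method: str = "periodogram"
) -> Tuple[np.ndarray, np.ndarray]:
    """Spectrum of the demeaned series; plain periodogram by default.

    ``method="welch"`` gives the averaged-segment (Welch) estimate
    instead.  Returns frequencies in Hz up to the Nyquist rate
    1 / (2 * tr) and the corresponding power.
    """
    series = np.asarray(series, dtype=float)
    if series.size < 4:
        raise ValueError("need at least 4 frames")
    demeaned = series - series.mean()
    if method == "periodogram":
        freqs, power = _signal.periodogram(demeaned, fs=1.0 / tr, window="boxcar", detrend=False)
    elif method == "welch":
        freqs, power = _signal.welch(demeaned, fs=1.0 / tr)
    else:
        raise ValueError(f"unknown spectral method {method!r}")
    return freqs, power


def vector_to_matrix(vec: np.ndarray, index: EdgeIndex, diagonal: float = 0.0) -> np.ndarray:
    """Expand an edge vector to the symmetric n x n matrix."""
    vec = np.asarray(vec, dtype=float)
    if vec.shape[0] != index.n_edges:
        raise ValueError("vector length does not match edge index")
    n = index.n_regions
    M = np.full((n, n), diagonal, dtype=float)
    iu = np.triu_indices(n, k=1)
    M[iu] = vec
    M[(iu[1], iu[0])] = vec
    return M


def matrix_to_vector(M: np.ndarray, index: EdgeIndex) -> np.ndarray:
    """Upper-triangular entries of a symmetric matrix in EdgeIndex order."""
    M = np.asarray(M, dtype=float)
    if M.shape != (index.n_regions, index.n_regions):
        raise ValueError("matrix shape does not match edge index")
    iu = np.triu_indices(index.n_regions, k=1)
    return M[iu]
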